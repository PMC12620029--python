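# haplopop

Haploid-aware population genomics for mixed-ploidy SNP data.

`haplopop` implements an analysis chain for species where haploid tissue
(e.g., conifer megagametophytes) is genotyped alongside diploids, and the
genome is repetitive enough that paralog collapse is a first-order error
source:

* **`synthio`** — synthetic datasets with known ground truth:
  Balding–Nichols nuclear SNPs with a target differentiation level,
  admixed individuals, rare pool-private alleles, two haploid organellar
  compartments with asymmetric seed/pollen migration, and
  paralog-collapse errors clustered in 250 bp windows.
* **`variant_qc`** — four per-locus error criteria (heterozygous haploid
  calls, diploid heterozygosity > 60%, pooled read-ratio deviation |D| > 20,
  exact Hardy–Weinberg failure in multiple populations), a 250 bp windowed
  error-rate screen (> 10% excluded), depth/missingness filters, LD pruning
  (r² > 0.8 in 10 kb windows) and random splitting of diploids into
  pseudo-haploids.
* **`sitediv`** — codon degeneracy classes (0-fold / 4-fold), per-population
  π and π₀/π₄, Tajima's D, folded SFS with hypergeometric projection, and
  Stairway-plot-2 blueprint export.
* **`popstruct`** — Weir–Cockerham multilocus F_st (diploid and
  allele-count designs), two-level haplotypic AMOVA, PCA, and
  shared-ancestry profiles as convex combinations of source-pool PC
  centroids (nonnegative least squares).
* **`geneflow`** — haversine distances, permutation Mantel tests,
  Rousset regression (Nm = 1/slope, with refugium-conditioned pair
  subsets), and island-model pollen/seed flow ratios from maternal,
  paternal and biparental marker differentiation.
* **`rareshare`** — PSRA: per-individual proportions of shared rare
  alleles with each source pool, conditioned on the minor-allele count
  c = 1..8 in the pooled sources.
* **`organelle`** — relaxed-depth organelle QC, Hamming distances,
  minimum spanning networks with tie retention, and weighted Louvain
  communities (distance transformed to similarity `1/(1+d)`).
* **`vcfio` / `pipeline` / `cli`** — VCF 4.2 / TSV / BED interchange and a
  stage-graph runner with per-stage manifests.

## CLI

```sh
haplopop simulate --n-pops 8 --samples-per-pop 10 --n-loci 2000 \
    --haploid-pops P09,P10 --error-windows 10 --seed 1 --out sim/

haplopop qc --vcf sim/nuclear.vcf --sheet sim/samples.tsv --out qc/
haplopop structure --vcf qc/filtered.vcf --sheet sim/samples.tsv --out st/
haplopop geneflow --fst-matrix st/fst_matrix.tsv --sheet sim/samples.tsv \
    --subset all --out ibd/
haplopop psra --vcf qc/filtered.vcf --sheet sim/samples.tsv --out psra/
haplopop organelle --vcf sim/mito.vcf --sheet sim/samples.tsv \
    --compartment mito --out org/
haplopop sfs-export --vcf sim/nuclear.vcf --sheet sim/samples.tsv \
    --length 500000 --out blueprint.txt
haplopop run-all --config run.yaml
```

All stochastic stages take an explicit `--seed`; identical configuration
and seed reproduce outputs byte for byte.  Coordinates are 1-based in
VCF and 0-based half-open in BED.

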