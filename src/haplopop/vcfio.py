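"""VCF / TSV / BED interchange.

VCF 4.2 is the sole genotype interchange format.  Coordinates are
1-based in VCF and 0-based half-open in BED.  Haploid samples are
written with single-allele GT, except raw heterozygous haploid calls
(pre-QC evidence), which are written diploid-coded so they round-trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .core import MISSING, GenotypeMatrix, SampleSheet, SHEET_COLUMNS
from .synthio import CONTIG_BP


def write_vcf(g: GenotypeMatrix, path: str | Path) -> Path:
    """Write a genotype matrix as an uncompressed VCF 4.2 text file."""
    path = Path(path)
    has_depth = g.depth is not None
    has_ad = g.ad_ref is not None and g.ad_alt is not None
    fmt = "GT" + (":DP" if has_depth else "") + (":AD" if has_ad else "")
    lines = ["##fileformat=VCFv4.2",
             f"##source=haplopop(compartment={g.compartment})"]
    for contig in pd.unique(g.contigs):
        lines.append(f"##contig=<ID={contig},length={CONTIG_BP}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_depth:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if has_ad:
        lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples))

    for locus in range(g.n_loci):
        cells = []
        for s in range(g.n_samples):
            dos = int(g.dosages[s, locus])
            hap = g.ploidy[s] == 1
            raw_het = (g.haploid_het is not None and hap
                       and bool(g.haploid_het[s, locus]))
            if dos == MISSING:
                gt = "." if hap else "./."
            elif raw_het:
                gt = "0/1"
            elif hap:
                gt = str(dos)
            else:
                gt = ("0/0", "0/1", "1/1")[dos]
            parts = [gt]
            if has_depth:
                parts.append(str(int(g.depth[s, locus])))
            if has_ad:
                parts.append(f"{int(g.ad_ref[s, locus])},{int(g.ad_alt[s, locus])}")
            cells.append(":".join(parts))
        lines.append("\t".join([
            str(g.contigs[locus]), str(int(g.positions[locus])), ".",
            str(g.ref[locus]), str(g.alt[locus]), ".", "PASS", ".", fmt, *cells]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path, ploidy_map: Optional[dict[str, int]] = None,
             compartment: str = "nuclear") -> tuple[GenotypeMatrix, dict]:
    """Read biallelic SNP records into a genotype matrix.

    ``ploidy_map`` assigns each sample ploidy 1 or 2 (default all
    diploid); haploid samples are accepted with single-allele GT or as
    diploid-coded calls (a diploid-coded heterozygote in a haploid sample
    is recorded in ``haploid_het``).  Non-biallelic or non-SNP records
    are skipped and counted.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    ploidy_map = ploidy_map or {}
    unknown = set(ploidy_map) - set(samples)
    if unknown:
        raise ValueError(f"ploidy_map names absent from VCF: {sorted(unknown)}")
    ploidy = np.array([ploidy_map.get(s, 2) for s in samples], dtype=np.int8)

    contigs, positions, refs, alts = [], [], [], []
    dosage_rows, depth_rows, adr_rows, ada_rows, het_rows = [], [], [], [], []
    n_skipped = 0
    has_depth = has_ad = False
    for rec in vf.fetch() if vf.index else vf:
        if (rec.alts is None or len(rec.alts) != 1
                or len(rec.ref) != 1 or len(rec.alts[0]) != 1):
            n_skipped += 1
            continue
        dos = np.full(len(samples), MISSING, dtype=np.int16)
        dep = np.zeros(len(samples), dtype=np.int32)
        adr = np.zeros(len(samples), dtype=np.int32)
        ada = np.zeros(len(samples), dtype=np.int32)
        hh = np.zeros(len(samples), dtype=bool)
        for i, s in enumerate(samples):
            sm = rec.samples[s]
            gt = tuple(a for a in (sm.get("GT") or ()) if a is not None)
            if gt:
                if ploidy[i] == 1:
                    if len(gt) == 2 and gt[0] != gt[1]:
                        hh[i] = True
                        dos[i] = 1
                    else:
                        dos[i] = gt[0]
                else:
                    dos[i] = sum(gt) if len(gt) == 2 else MISSING
            if sm.get("DP") is not None:
                dep[i] = sm["DP"]
                has_depth = True
            ad = sm.get("AD")
            if ad is not None and len(ad) == 2 and ad[0] is not None:
                adr[i], ada[i] = ad
                has_ad = True
        contigs.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(rec.ref)
        alts.append(rec.alts[0])
        dosage_rows.append(dos)
        depth_rows.append(dep)
        adr_rows.append(adr)
        ada_rows.append(ada)
        het_rows.append(hh)

    stack = lambda rows: np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0))
    g = GenotypeMatrix(
        samples=samples,
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosages=stack(dosage_rows).astype(np.int16),
        ploidy=ploidy,
        compartment=compartment,
        depth=stack(depth_rows).astype(np.int32) if has_depth else None,
        ad_ref=stack(adr_rows).astype(np.int32) if has_ad else None,
        ad_alt=stack(ada_rows).astype(np.int32) if has_ad else None,
        haploid_het=stack(het_rows).astype(bool) if (ploidy == 1).any() else None,
    )
    return g, {"n_skipped": n_skipped}


def write_sheet(sheet: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    sheet.table[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_sheet(path: str | Path) -> SampleSheet:
    table = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str,
                                               "region": str, "source_pool": str})
    return SampleSheet(table)


def write_bed(intervals, path: str | Path, header: bool = True) -> Path:
    """Write (contig, start, end) intervals, 0-based half-open."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("# 0-based half-open intervals\n")
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{int(start)}\t{int(end)}\n")
    return path


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        contig, start, end = line.split("\t")[:3]
        out.append((contig, int(start), int(end)))
    return out


def write_site_classes(g: GenotypeMatrix, classes: np.ndarray, path: str | Path) -> Path:
    pd.DataFrame({"contig": g.contigs, "pos": g.positions,
                  "site_class": classes}).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_site_classes(path: str | Path, g: GenotypeMatrix) -> np.ndarray:
    """Per-locus classes aligned to ``g``; unannotated loci become neutral."""
    t = pd.read_csv(path, sep="\t")
    lookup = {(r.contig, r.pos): r.site_class for r in t.itertuples()}
    return np.array([lookup.get((c, p), "neutral")
                     for c, p in zip(g.contigs, g.positions)], dtype=object)
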