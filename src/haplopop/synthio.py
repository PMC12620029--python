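"""Synthetic mixed-ploidy SNP datasets with known ground truth.

Generates the statistical structure the downstream analyses assume:

* multi-population nuclear SNPs under the Balding–Nichols model with a
  target differentiation level, plus optional admixed individuals,
* an excess of low-frequency alleles private to single source pools,
* two haploid organellar compartments forward-simulated under an island
  model with asymmetric (seed-only vs pollen+seed) migration,
* paralog-collapse genotyping errors clustered in 250 bp windows,
  detectable through haploid samples.

Every stochastic choice a downstream stage might estimate is recorded in
the returned ``truth`` mapping.  All output is deterministic given the
config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import ConfigError, GenotypeMatrix, SampleSheet, SHEET_COLUMNS

CONTIG_BP = 10_000  # one synthetic contig per 10 kb block


@dataclass
class AdmixGroup:
    """A group of admixed individuals drawing alleles from source pools."""

    name: str
    weights: dict[str, float]
    n_individuals: int = 10
    ploidy: int = 2

    def validate(self, pools: list[str]) -> None:
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ConfigError(f"admixture weights for {self.name} do not sum to 1")
        unknown = set(self.weights) - set(pools)
        if unknown:
            raise ConfigError(f"admixture group {self.name} references unknown pools {unknown}")
        if self.ploidy not in (1, 2):
            raise ConfigError("admixture group ploidy must be 1 or 2")


@dataclass
class SimConfig:
    n_pops: int = 8
    samples_per_pop: int = 10
    ploidy_per_pop: dict[str, int] = field(default_factory=dict)  # default diploid
    n_loci: int = 2000
    fst_target: float = 0.05
    n_sources: int = 3
    admixture_spec: list[AdmixGroup] = field(default_factory=list)
    rare_private_fraction: float = 0.0
    organelle_migration: tuple[float, float] = (0.001, 0.02)  # (m_seed, m_pollen)
    n_loci_organelle: int = 300
    organelle_ne: int = 200
    organelle_generations: int = 100
    error_window_spec: tuple[int, int, float] = (0, 250, 0.5)  # (n_windows, len_bp, p_err)
    min_snps_per_window: int = 1
    depth_mean: float = 20.0
    loci_per_contig: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.samples_per_pop < 1 or self.n_loci < 1:
            raise ConfigError("n_pops, samples_per_pop, n_loci must be positive")
        if not (0.0 <= self.fst_target < 1.0) or not math.isfinite(self.fst_target):
            raise ConfigError("fst_target must be a finite fraction in [0, 1)")
        if not (0.0 <= self.rare_private_fraction <= 1.0):
            raise ConfigError("rare_private_fraction must be in [0, 1]")
        m_seed, m_pollen = self.organelle_migration
        for m in (m_seed, m_pollen):
            if not (0.0 <= m <= 1.0) or not math.isfinite(m):
                raise ConfigError("migration fractions must be finite and in [0, 1]")
        n_win, win_len, p_err = self.error_window_spec
        if n_win < 0 or win_len <= 0 or not (0.0 <= p_err <= 1.0):
            raise ConfigError("invalid error_window_spec")
        if self.depth_mean <= 0 or not math.isfinite(self.depth_mean):
            raise ConfigError("depth_mean must be positive and finite")
        self.n_sources = min(self.n_sources, self.n_pops)
        for pop, p in self.ploidy_per_pop.items():
            if p not in (1, 2):
                raise ConfigError(f"ploidy for {pop} must be 1 or 2")
        for grp in self.admixture_spec:
            grp.validate(self.source_pool_names())

    # populations P01.. ; the first n_sources are singleton source pools S1..
    def population_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pops)]

    def source_pool_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_sources)]

    def source_pool_of(self, pop: str) -> Optional[str]:
        pops = self.population_names()
        i = pops.index(pop)
        return f"S{i + 1}" if i < self.n_sources else None

    def ploidy_of(self, pop: str) -> int:
        return int(self.ploidy_per_pop.get(pop, 2))


@dataclass
class SyntheticDataset:
    nuclear: GenotypeMatrix
    mito: GenotypeMatrix
    chloro: GenotypeMatrix
    sheet: SampleSheet
    truth: dict


# ---------------------------------------------------------------------------
# helpers


def _positions(n_loci: int, loci_per_contig: int, rng: np.random.Generator):
    """Lay loci on consecutive 10 kb contigs, sorted distinct positions."""
    contigs, positions = [], []
    n_contigs = math.ceil(n_loci / loci_per_contig)
    left = n_loci
    for c in range(n_contigs):
        k = min(loci_per_contig, left)
        left -= k
        pos = np.sort(rng.choice(np.arange(1, CONTIG_BP + 1), size=k, replace=False))
        contigs.extend([f"ctg{c + 1:04d}"] * k)
        positions.extend(pos.tolist())
    return np.array(contigs, dtype=object), np.array(positions, dtype=np.int64)


def _balding_nichols(p: np.ndarray, fst: float, n_pops: int, rng) -> np.ndarray:
    """Per-population frequencies around ancestral ``p``; rows are populations."""
    if fst == 0.0:
        return np.tile(p, (n_pops, 1))
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b, size=(n_pops, len(p)))


def _simulate_depth(dosages, ploidy, depth_mean, rng):
    n_samples, n_loci = dosages.shape
    depth = rng.poisson(depth_mean, size=dosages.shape).astype(np.int32)
    ad_alt = np.zeros_like(depth)
    dip = ploidy[:, None] == 2
    het = dip & (dosages == 1)
    ad_alt[het] = rng.binomial(depth[het], 0.5)
    ad_alt[dosages == 2] = depth[dosages == 2]
    hap_alt = (~dip) & (dosages == 1)
    ad_alt[hap_alt] = depth[hap_alt]
    ad_ref = depth - ad_alt
    return depth, ad_ref, ad_alt


def build_sheet(cfg: SimConfig) -> SampleSheet:
    """Sample sheet matching :func:`simulate_nuclear` sample layout."""
    rows = []
    for i, pop in enumerate(cfg.population_names()):
        pool = cfg.source_pool_of(pop)
        region = "refugium" if pool is not None else "expansion"
        lat = 40.0 + 1.5 * i
        lon = -5.0 + 4.0 * i
        plo = cfg.ploidy_of(pop)
        for j in range(cfg.samples_per_pop):
            rows.append([f"{pop}_s{j + 1:02d}", pop, region, pool or "-", lat, lon, plo])
    for grp in cfg.admixture_spec:
        for j in range(grp.n_individuals):
            rows.append([f"{grp.name}_s{j + 1:02d}", grp.name, "admixed", "-",
                         62.0, 20.0, grp.ploidy])
    return SampleSheet(pd.DataFrame(rows, columns=SHEET_COLUMNS))


# ---------------------------------------------------------------------------
# nuclear simulation


def simulate_nuclear(cfg: SimConfig) -> tuple[GenotypeMatrix, dict]:
    """Balding–Nichols nuclear SNPs plus rare pool-private alleles.

    Returns the genotype matrix and a truth record holding ancestral and
    per-population allele frequencies, the private-locus assignment and
    per-individual admixture weights.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = cfg.population_names()
    pools = cfg.source_pool_names()

    ancestral = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    freqs = _balding_nichols(ancestral, cfg.fst_target, cfg.n_pops, rng)

    # Overwrite a fraction of loci with a minor allele private to one pool.
    n_private = int(round(cfg.rare_private_fraction * cfg.n_loci))
    private_mask = np.zeros(cfg.n_loci, dtype=bool)
    private_pool = np.full(cfg.n_loci, "", dtype=object)
    if n_private > 0:
        idx = rng.choice(cfg.n_loci, size=n_private, replace=False)
        pool_pick = np.array(pools, dtype=object)[idx % cfg.n_sources]
        for locus, pool in zip(idx, pool_pick):
            freqs[:, locus] = 0.0
            owner = pools.index(pool)  # singleton pool -> population index
            freqs[owner, locus] = rng.uniform(0.01, 0.1)
        private_mask[idx] = True
        private_pool[idx] = pool_pick

    contigs, positions = _positions(cfg.n_loci, cfg.loci_per_contig, rng)

    sheet = build_sheet(cfg)
    samples = sheet.samples
    ploidy = sheet.table["ploidy"].to_numpy(dtype=np.int8)
    pop_of = sheet.table["population"].to_numpy(dtype=object)

    dosages = np.zeros((len(samples), cfg.n_loci), dtype=np.int16)
    admix_truth: dict[str, dict[str, float]] = {}
    pool_freq = {pl: freqs[pools.index(pl)] for pl in pools}

    for s in range(len(samples)):
        pop = pop_of[s]
        if pop in pops:
            f = freqs[pops.index(pop)]
            dosages[s] = rng.binomial(ploidy[s], f)
        else:
            grp = next(g for g in cfg.admixture_spec if g.name == pop)
            admix_truth[samples[s]] = dict(grp.weights)
            names = list(grp.weights)
            w = np.array([grp.weights[k] for k in names])
            total = np.zeros(cfg.n_loci, dtype=np.int16)
            for _copy in range(ploidy[s]):
                choice = rng.choice(len(names), size=cfg.n_loci, p=w)
                f = np.stack([pool_freq[names[k]] for k in range(len(names))])
                total += rng.binomial(1, f[choice, np.arange(cfg.n_loci)]).astype(np.int16)
            dosages[s] = total

    depth, ad_ref, ad_alt = _simulate_depth(dosages, ploidy, cfg.depth_mean, rng)
    g = GenotypeMatrix(
        samples=samples,
        contigs=contigs,
        positions=positions,
        ref=np.array(["A"] * cfg.n_loci, dtype=object),
        alt=np.array(["T"] * cfg.n_loci, dtype=object),
        dosages=dosages,
        ploidy=ploidy,
        compartment="nuclear",
        depth=depth,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        haploid_het=np.zeros(dosages.shape, dtype=bool),
    )
    truth = {
        "ancestral_freq": ancestral,
        "pop_freqs": freqs,
        "populations": pops,
        "private_mask": private_mask,
        "private_pool": private_pool,
        "admixture": admix_truth,
        "fst_target": cfg.fst_target,
    }
    return g, truth


# ---------------------------------------------------------------------------
# organelles


def _island_forward(p0: np.ndarray, n_pops: int, m: float, ne: int,
                    generations: int, rng) -> np.ndarray:
    """Forward-simulate island-model haplotype frequencies with drift."""
    x = np.tile(p0, (n_pops, 1))
    for _ in range(generations):
        xbar = x.mean(axis=0)
        x = (1.0 - m) * x + m * xbar
        x = rng.binomial(ne, x) / ne
    return x


def simulate_organelles(cfg: SimConfig) -> tuple[GenotypeMatrix, GenotypeMatrix, dict]:
    """Maternal (seed-only) and paternal (pollen+seed) haploid compartments.

    Maternal migration is ``m_seed``; paternal is ``m_seed + m_pollen``,
    reflecting that pollen-carried genomes also move in seeds.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    m_seed, m_pollen = cfg.organelle_migration
    sheet = build_sheet(cfg)
    samples = sheet.samples
    pops = cfg.population_names()
    pop_of = sheet.table["population"].to_numpy(dtype=object)

    out = []
    realized = {}
    for compartment, m in (("mito", m_seed), ("chloro", min(1.0, m_seed + m_pollen))):
        p0 = rng.uniform(0.05, 0.95, size=cfg.n_loci_organelle)
        x = _island_forward(p0, cfg.n_pops, m, cfg.organelle_ne,
                            cfg.organelle_generations, rng)
        dosages = np.zeros((len(samples), cfg.n_loci_organelle), dtype=np.int16)
        for s in range(len(samples)):
            pop = pop_of[s]
            f = x[pops.index(pop)] if pop in pops else x.mean(axis=0)
            dosages[s] = rng.binomial(1, f)
        contigs, positions = _positions(cfg.n_loci_organelle, cfg.loci_per_contig, rng)
        g = GenotypeMatrix(
            samples=samples,
            contigs=np.array([f"{compartment}_{c}" for c in contigs], dtype=object),
            positions=positions,
            ref=np.array(["A"] * cfg.n_loci_organelle, dtype=object),
            alt=np.array(["T"] * cfg.n_loci_organelle, dtype=object),
            dosages=dosages,
            ploidy=np.ones(len(samples), dtype=np.int8),
            compartment=compartment,
        )
        out.append(g)
        realized[compartment] = {"migration": m, "final_freqs": x}

    truth = {
        "m_seed": m_seed,
        "m_pollen": m_pollen,
        "compartments": realized,
        "single_deme": cfg.n_pops == 1,
    }
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# paralog-collapse error injection


def inject_paralog_errors(g: GenotypeMatrix, cfg: SimConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> tuple[GenotypeMatrix, dict]:
    """Corrupt loci inside randomly chosen 250 bp windows.

    Within each chosen window every locus is independently corrupted with
    the configured probability: haploid samples gain heterozygous raw
    calls, diploid heterozygosity is inflated above 0.6 and allelic read
    ratios are skewed.  Data outside the windows is untouched.  Truth
    records the 0-based half-open window coordinates and the corrupted
    locus mask.
    """
    if g.depth is None:
        raise ValueError("error injection requires per-genotype depth fields")
    n_windows, win_len, p_err = cfg.error_window_spec
    if win_len > CONTIG_BP:
        raise ConfigError("error window longer than contig")
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng

    out = g.take_loci(np.arange(g.n_loci))  # deep copy
    truth = {"windows": [], "corrupted": np.zeros(g.n_loci, dtype=bool)}
    if n_windows == 0:
        return out, truth

    # enumerate candidate tiles (anchored at position 1) with enough SNPs
    tiles = {}
    tile_idx = (g.positions - 1) // win_len
    for i in range(g.n_loci):
        tiles.setdefault((g.contigs[i], int(tile_idx[i])), []).append(i)
    candidates = [k for k, v in tiles.items() if len(v) >= cfg.min_snps_per_window]
    if len(candidates) < n_windows:
        raise ConfigError(
            f"only {len(candidates)} windows hold >= {cfg.min_snps_per_window} SNPs, "
            f"{n_windows} requested")
    order = rng.permutation(len(candidates))[:n_windows]

    haploid = out.ploidy == 1
    diploid = ~haploid
    for k in order:
        contig, t = candidates[k]
        start = t * win_len
        truth["windows"].append((contig, start, start + win_len))
        for locus in tiles[(contig, t)]:
            if rng.random() >= p_err:
                continue
            truth["corrupted"][locus] = True
            # haploid samples: raw heterozygous calls appear
            hap_hit = haploid & (rng.random(out.n_samples) < 0.9)
            out.haploid_het[hap_hit, locus] = True
            out.dosages[hap_hit, locus] = 1
            # diploid samples: heterozygosity inflated above 0.6
            dip_hit = diploid & (rng.random(out.n_samples) < 0.85)
            out.dosages[dip_hit, locus] = 1
            # allelic read ratios skew away from 1:1 at heterozygotes
            dep = out.depth[dip_hit, locus]
            alt = rng.binomial(np.maximum(dep, 0), 0.12)
            out.ad_alt[dip_hit, locus] = alt
            out.ad_ref[dip_hit, locus] = dep - alt
    truth["windows"].sort()
    return out, truth


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Full synthetic dataset: nuclear (+ injected errors), organelles, sheet."""
    nuclear, truth_nuc = simulate_nuclear(cfg)
    if cfg.error_window_spec[0] > 0:
        nuclear, truth_err = inject_paralog_errors(nuclear, cfg)
    else:
        truth_err = {"windows": [], "corrupted": np.zeros(nuclear.n_loci, dtype=bool)}
    mito, chloro, truth_org = simulate_organelles(cfg)
    sheet = build_sheet(cfg)
    truth = {"nuclear": truth_nuc, "errors": truth_err, "organelle": truth_org}
    return SyntheticDataset(nuclear=nuclear, mito=mito, chloro=chloro,
                            sheet=sheet, truth=truth)
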