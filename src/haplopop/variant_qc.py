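"""Haploid-aware variant QC.

Four per-locus error criteria (heterozygous calls in haploid samples,
excess diploid heterozygosity, read-ratio deviation, multi-population
Hardy–Weinberg failure), a 250 bp windowed error-rate screen, depth and
missingness filters, LD pruning and splitting of diploid samples into
pseudo-haploids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SampleSheet, population_indices


@dataclass
class ErrorFlags:
    """Per-locus error criteria.  ``*_ok`` marks where a criterion is evaluable."""

    n_loci: int
    haploid_het: Optional[np.ndarray] = None
    haploid_het_ok: Optional[np.ndarray] = None
    het_excess: Optional[np.ndarray] = None
    het_excess_ok: Optional[np.ndarray] = None
    read_ratio: Optional[np.ndarray] = None
    read_ratio_ok: Optional[np.ndarray] = None
    d_score: Optional[np.ndarray] = None
    hwe: Optional[np.ndarray] = None
    hwe_ok: Optional[np.ndarray] = None

    def union(self) -> np.ndarray:
        """A SNP is erroneous if any evaluable criterion flags it (counted once)."""
        out = np.zeros(self.n_loci, dtype=bool)
        for flag, ok in ((self.haploid_het, self.haploid_het_ok),
                         (self.het_excess, self.het_excess_ok),
                         (self.read_ratio, self.read_ratio_ok),
                         (self.hwe, self.hwe_ok)):
            if flag is not None:
                out |= flag & (ok if ok is not None else True)
        return out

    def to_frame(self, g: GenotypeMatrix) -> pd.DataFrame:
        def col(a, fill=False):
            return a if a is not None else np.full(self.n_loci, fill)
        return pd.DataFrame({
            "contig": g.contigs, "pos": g.positions,
            "haploid_het": col(self.haploid_het),
            "het_excess": col(self.het_excess),
            "read_ratio": col(self.read_ratio),
            "hwe_multi_pop": col(self.hwe),
            "d_score": col(self.d_score, np.nan),
            "any_error": self.union(),
        })


class NotEvaluable(RuntimeError):
    """A criterion's preconditions are not met (distinct from 'no flags')."""


# ---------------------------------------------------------------------------
# criterion 1: heterozygous calls in haploid samples


@dataclass
class HaploidHetResult:
    flags: np.ndarray
    sample_het_counts: dict[str, int]
    contaminated: list[str]
    masked: GenotypeMatrix  # contaminated samples' het calls set missing


def flag_haploid_hets(g: GenotypeMatrix, mad_factor: float = 5.0) -> HaploidHetResult:
    """Flag loci with a raw heterozygous call in any haploid sample.

    Haploid samples whose het count is an outlier (> median + ``mad_factor``
    * MAD among haploids; MAD floored at 1 count) are treated as
    contaminated by diploid tissue: their het positions are set missing and
    do not flag loci on their own.
    """
    if g.haploid_het is None or not (g.ploidy == 1).any():
        raise NotEvaluable("no haploid samples with raw diploid-coded calls")
    hap_rows = np.flatnonzero(g.ploidy == 1)
    het = g.haploid_het[hap_rows]
    counts = het.sum(axis=1)
    med = np.median(counts)
    mad = max(np.median(np.abs(counts - med)), 1.0)
    bad = counts > med + mad_factor * mad
    contaminated = [g.samples[hap_rows[i]] for i in np.flatnonzero(bad)]

    masked = g.take_loci(np.arange(g.n_loci))
    for i in np.flatnonzero(bad):
        row = hap_rows[i]
        pos = masked.haploid_het[row]
        masked.dosages[row, pos] = MISSING
        masked.haploid_het[row, pos] = False

    flags = het[~bad].any(axis=0) if (~bad).any() else np.zeros(g.n_loci, dtype=bool)
    return HaploidHetResult(
        flags=flags,
        sample_het_counts={g.samples[hap_rows[i]]: int(counts[i]) for i in range(len(hap_rows))},
        contaminated=contaminated,
        masked=masked,
    )


# ---------------------------------------------------------------------------
# criterion 2: diploid heterozygosity above threshold


def het_excess(g: GenotypeMatrix, max_het: float = 0.6) -> tuple[np.ndarray, np.ndarray]:
    """Flag loci whose diploid heterozygote fraction strictly exceeds ``max_het``.

    Returns ``(flags, evaluable)``; loci with zero non-missing diploid
    calls are not evaluable.
    """
    dip = g.ploidy == 2
    if not dip.any():
        raise NotEvaluable("no diploid samples")
    dos = g.dosages[dip]
    called = dos != MISSING
    n_called = called.sum(axis=0)
    n_het = ((dos == 1) & called).sum(axis=0)
    evaluable = n_called > 0
    with np.errstate(invalid="ignore"):
        frac = np.where(evaluable, n_het / np.maximum(n_called, 1), 0.0)
    return (frac > max_het) & evaluable, evaluable


# ---------------------------------------------------------------------------
# criterion 3: read-ratio deviation score D


def read_ratio_D(g: GenotypeMatrix, d_max: float = 20.0):
    """Pooled binomial z-score of allele balance at heterozygous diploids.

    ``D = (A - N/2) / sqrt(N/4)`` with ``A`` the reads supporting the
    alternate allele pooled over all heterozygous diploid genotypes at the
    locus and ``N`` the total reads there.  Loci without heterozygotes (or
    without read support) have undefined D (NaN).  Flags ``|D| > d_max``.
    """
    if g.ad_alt is None or g.ad_ref is None:
        raise NotEvaluable("allelic depths unavailable")
    dip = g.ploidy == 2
    het = (g.dosages == 1) & dip[:, None]
    A = np.where(het, g.ad_alt, 0).sum(axis=0).astype(float)
    N = np.where(het, g.ad_alt + g.ad_ref, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(N > 0, (A - N / 2.0) / np.sqrt(N / 4.0), np.nan)
    flags = np.abs(np.nan_to_num(d)) > d_max
    evaluable = N > 0
    flags &= evaluable
    return flags, evaluable, d


# ---------------------------------------------------------------------------
# criterion 4: Hardy-Weinberg failure in multiple populations


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value.

    Full enumeration of heterozygote counts conditional on the observed
    allele counts; the p-value sums the probabilities of all
    configurations no more probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele copies
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalized log-probabilities of each heterozygote count
    from scipy.special import gammaln

    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (hets * np.log(2.0)
            - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.flatnonzero(hets == n_het)[0]]
    return float(p[p <= obs * (1 + 1e-12)].sum())


def hwe_multi_pop(g: GenotypeMatrix, sheet: SampleSheet, alpha: float = 0.05,
                  base_count: int = 3, base_pops: int = 8):
    """Flag loci failing the exact HWE test in too many diploid populations.

    With at least ``base_pops`` diploid populations the literal rule is
    "more than ``base_count``"; with fewer the threshold is scaled to
    ``floor(base_count * n / base_pops)``.
    """
    pops = population_indices(sheet.aligned_to(g.samples), g.samples)
    dip_pops = {p: idx[g.ploidy[idx] == 2] for p, idx in pops.items()}
    dip_pops = {p: idx for p, idx in dip_pops.items() if len(idx) >= 2}
    n_pops = len(dip_pops)
    if n_pops < 2:
        raise NotEvaluable("fewer than 2 diploid populations")
    threshold = base_count if n_pops >= base_pops else (base_count * n_pops) // base_pops

    n_fail = np.zeros(g.n_loci, dtype=np.int32)
    any_eval = np.zeros(g.n_loci, dtype=bool)
    for idx in dip_pops.values():
        dos = g.dosages[idx]
        for locus in range(g.n_loci):
            col = dos[:, locus]
            col = col[col != MISSING]
            if len(col) == 0:
                continue
            any_eval[locus] = True
            n_aa = int((col == 0).sum())
            n_ab = int((col == 1).sum())
            n_bb = int((col == 2).sum())
            if hwe_exact_p(n_aa, n_ab, n_bb) < alpha:
                n_fail[locus] += 1
    return n_fail > threshold, any_eval, n_fail


def compute_flags(g: GenotypeMatrix, sheet: Optional[SampleSheet] = None,
                  max_het: float = 0.6, d_max: float = 20.0,
                  hwe_alpha: float = 0.05, hwe_count: int = 3,
                  mad_factor: float = 5.0) -> tuple[ErrorFlags, GenotypeMatrix]:
    """Run every evaluable criterion; returns flags plus the matrix with
    contaminated-haploid het calls masked."""
    flags = ErrorFlags(n_loci=g.n_loci)
    masked = g
    try:
        hh = flag_haploid_hets(g, mad_factor=mad_factor)
        flags.haploid_het = hh.flags
        flags.haploid_het_ok = np.ones(g.n_loci, dtype=bool)
        masked = hh.masked
    except NotEvaluable:
        pass
    try:
        flags.het_excess, flags.het_excess_ok = het_excess(masked, max_het=max_het)
    except NotEvaluable:
        pass
    try:
        flags.read_ratio, flags.read_ratio_ok, flags.d_score = read_ratio_D(masked, d_max=d_max)
    except NotEvaluable:
        pass
    if sheet is not None:
        try:
            flags.hwe, flags.hwe_ok, _ = hwe_multi_pop(masked, sheet, alpha=hwe_alpha,
                                                       base_count=hwe_count)
        except NotEvaluable:
            pass
    return flags, masked


# ---------------------------------------------------------------------------
# 250 bp window screen


@dataclass
class WindowReport:
    windows: pd.DataFrame  # contig, start, end (0-based half-open), n_snps, n_flagged, error_rate, excluded
    kept_loci: np.ndarray  # boolean over input loci
    excluded_bp: int

    def excluded_bed(self) -> pd.DataFrame:
        w = self.windows
        return w.loc[w["excluded"], ["contig", "start", "end"]].reset_index(drop=True)


def window_screen(error: np.ndarray, g: GenotypeMatrix, window_bp: int = 250,
                  max_error_rate: float = 0.10) -> WindowReport:
    """Tile each contig in non-overlapping windows anchored at position 1 and
    exclude windows whose flagged-SNP fraction strictly exceeds the threshold.

    Windows without SNPs are not evaluated (vacuously retained).
    """
    error = np.asarray(error, dtype=bool)
    tile = (g.positions - 1) // window_bp
    key = pd.DataFrame({"contig": g.contigs, "tile": tile, "err": error})
    grouped = key.groupby(["contig", "tile"], sort=True)
    rows = []
    kept = np.ones(g.n_loci, dtype=bool)
    excluded_bp = 0
    for (contig, t), sub in grouped:
        n = len(sub)
        n_flag = int(sub["err"].sum())
        rate = n_flag / n
        excl = rate > max_error_rate
        rows.append((contig, int(t) * window_bp, (int(t) + 1) * window_bp,
                     n, n_flag, rate, excl))
        if excl:
            kept[sub.index.to_numpy()] = False
            excluded_bp += window_bp
    windows = pd.DataFrame(rows, columns=["contig", "start", "end", "n_snps",
                                          "n_flagged", "error_rate", "excluded"])
    return WindowReport(windows=windows, kept_loci=kept, excluded_bp=excluded_bp)


# ---------------------------------------------------------------------------
# depth / missingness filters


def depth_missing_filter(g: GenotypeMatrix, sheet: SampleSheet, min_depth: int = 6,
                         max_missing: float = 0.6, min_pop_call: float = 0.5,
                         pre_max_missing: Optional[float] = None) -> GenotypeMatrix:
    """Mask low-depth diploid genotypes, then drop high-missingness loci and
    loci under-called in any single population.  Idempotent."""
    out = g.take_loci(np.arange(g.n_loci))
    if out.depth is not None:
        low = (out.depth < min_depth) & (out.ploidy[:, None] == 2)
        out.dosages[low] = MISSING
        if out.haploid_het is not None:
            out.haploid_het[low] = False
    miss = (out.dosages == MISSING).mean(axis=0)
    keep = np.ones(out.n_loci, dtype=bool)
    if pre_max_missing is not None:
        keep &= miss <= pre_max_missing
    keep &= miss <= max_missing
    pops = population_indices(sheet.aligned_to(out.samples), out.samples)
    for idx in pops.values():
        call = (out.dosages[idx] != MISSING).mean(axis=0)
        keep &= call >= min_pop_call
    return out.take_loci(keep)


# ---------------------------------------------------------------------------
# LD pruning


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete dosages; NaN if
    either locus is monomorphic on the complete subset."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return np.nan
    x, y = a[ok].astype(float), b[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return r * r


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.8, window_bp: int = 10_000,
             seed: int = 0) -> GenotypeMatrix:
    """Within windows, keep one member (uniformly at random, seeded) of each
    locus pair with dosage-correlation r^2 above ``r2_max``.

    Pairs are evaluated in position order; monomorphic loci are skipped
    from the r^2 computation and always retained.
    """
    rng = np.random.default_rng(seed)
    alive = np.ones(g.n_loci, dtype=bool)
    tile = (g.positions - 1) // window_bp
    groups = pd.DataFrame({"contig": g.contigs, "tile": tile}).groupby(
        ["contig", "tile"], sort=True).indices
    for key in sorted(groups):
        loci = np.sort(groups[key])
        for ai in range(len(loci)):
            i = loci[ai]
            if not alive[i]:
                continue
            for bj in range(ai + 1, len(loci)):
                j = loci[bj]
                if not alive[j] or not alive[i]:
                    continue
                r2 = _dosage_r2(g.dosages[:, i], g.dosages[:, j])
                if np.isnan(r2) or r2 <= r2_max:
                    continue
                drop = i if rng.random() < 0.5 else j
                alive[drop] = False
                if drop == i:
                    break
    return g.take_loci(alive)


# ---------------------------------------------------------------------------
# diploid splitting


def split_diploids(g: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Split each diploid sample into two pseudo-haploids, assigning the two
    alleles at each locus uniformly at random and independently across loci.

    Haploid samples pass through unchanged.  Per-locus pooled allele
    counts are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    new_rows, new_samples, new_ploidy = [], [], []
    for s in range(g.n_samples):
        dos = g.dosages[s]
        if g.ploidy[s] == 1:
            new_rows.append(dos.copy())
            new_samples.append(g.samples[s])
            new_ploidy.append(1)
            continue
        a = np.where(dos == MISSING, MISSING, (dos == 2).astype(np.int16))
        b = a.copy()
        het = dos == 1
        coin = rng.random(g.n_loci) < 0.5
        a[het] = np.where(coin[het], 1, 0)
        b[het] = 1 - a[het]
        for tag, row in (("a", a), ("b", b)):
            new_rows.append(row.astype(np.int16))
            new_samples.append(f"{g.samples[s]}__{tag}")
            new_ploidy.append(1)
    return GenotypeMatrix(
        samples=new_samples,
        contigs=g.contigs.copy(),
        positions=g.positions.copy(),
        ref=g.ref.copy(),
        alt=g.alt.copy(),
        dosages=np.vstack(new_rows),
        ploidy=np.array(new_ploidy, dtype=np.int8),
        compartment=g.compartment,
    )


def split_sheet(sheet: SampleSheet, samples_after: list[str]) -> SampleSheet:
    """Sheet rows for a split matrix: pseudo-haploids inherit their parent's
    metadata with ploidy 1."""
    base = sheet.table.set_index("sample")
    rows = []
    for s in samples_after:
        parent = s.rsplit("__", 1)[0] if "__" in s else s
        r = base.loc[parent].copy()
        r["ploidy"] = 1
        rows.append([s] + r[["population", "region", "source_pool", "lat", "lon", "ploidy"]].tolist())
    return SampleSheet(pd.DataFrame(rows, columns=["sample", "population", "region",
                                                   "source_pool", "lat", "lon", "ploidy"]))
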