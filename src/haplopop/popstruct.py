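"""Population structure: Weir–Cockerham F_st, two-level AMOVA, PCA and
reference-pool shared-ancestry profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import MISSING, GenotypeMatrix, SampleSheet, population_indices


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta


def _wc_components_haploid(counts: list[tuple[np.ndarray, np.ndarray]]):
    """Per-locus (a, a+b) variance components for an allele-count design.

    ``counts`` holds, per population, arrays of per-locus alternate and
    total allele counts.  With haploid data the within-individual terms
    of the diploid estimator collapse, leaving a one-way ANOVA on allele
    frequencies.
    """
    alts = np.stack([c[0] for c in counts]).astype(float)
    tots = np.stack([c[1] for c in counts]).astype(float)
    r = alts.shape[0]
    valid = (tots >= 1).all(axis=0) & (tots.sum(axis=0) > r)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tots > 0, alts / np.maximum(tots, 1), 0.0)
        n_sum = tots.sum(axis=0)
        n_c = (n_sum - (tots**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = alts.sum(axis=0) / n_sum
        msp = (tots * (p - pbar) ** 2).sum(axis=0) / (r - 1)
        msg_den = (tots - 1).sum(axis=0)
        msg = np.where(msg_den > 0,
                       (tots * p * (1 - p)).sum(axis=0) / np.maximum(msg_den, 1), 0.0)
        a = (msp - msg) / np.maximum(n_c, 1e-300)
        ab = (msp + (n_c - 1) * msg) / np.maximum(n_c, 1e-300)
    a = np.where(valid & (n_c > 0), a, 0.0)
    ab = np.where(valid & (n_c > 0), ab, 0.0)
    return a, ab


def _wc_components_diploid(groups: list[np.ndarray]):
    """Per-locus (a, b, c) components of Weir & Cockerham (1984) for diploid
    genotype matrices (one dosage matrix per population, missing = -1)."""
    r = len(groups)
    n_i = np.stack([(gd != MISSING).sum(axis=0) for gd in groups]).astype(float)
    alt_i = np.stack([np.where(gd != MISSING, gd, 0).sum(axis=0) for gd in groups]).astype(float)
    het_i = np.stack([((gd == 1) & (gd != MISSING)).sum(axis=0) for gd in groups]).astype(float)
    valid = (n_i >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / np.maximum(2 * n_i, 1)
        h_i = het_i / np.maximum(n_i, 1)
        n_sum = n_i.sum(axis=0)
        nbar = n_sum / r
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_sum
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a = (nbar / n_c) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
    ok = valid & (nbar > 1) & (n_c > 0)
    zero = lambda x: np.where(ok, np.nan_to_num(x), 0.0)
    return zero(a), zero(b), zero(c)


def wc_fst(g: GenotypeMatrix, sheet: SampleSheet,
           pops: Optional[Sequence[str]] = None) -> float:
    """Multilocus Weir–Cockerham theta over the given populations.

    The multilocus value is the ratio of summed among-population
    components to summed total components.  All-diploid data uses the
    full 1984 estimator (a, b, c); any haploid sample switches the locus
    set to the allele-frequency-only design.  Negative values are
    reported as computed.
    """
    idx = population_indices(sheet.aligned_to(g.samples), g.samples)
    if pops is None:
        pops = sorted(idx)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    groups = [idx[p] for p in pops]
    all_diploid = all((g.ploidy[gi] == 2).all() for gi in groups)
    if all_diploid:
        a, b, c = _wc_components_diploid([g.dosages[gi] for gi in groups])
        num, den = a.sum(), (a + b + c).sum()
    else:
        counts = [g.allele_counts(gi) for gi in groups]
        a, ab = _wc_components_haploid(counts)
        num, den = a.sum(), ab.sum()
    if den == 0:
        raise ValueError("no informative loci shared by the populations")
    return float(num / den)


def fst_matrix(g: GenotypeMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Symmetric pairwise multilocus theta matrix (diagonal zero)."""
    pops = sorted(population_indices(sheet.aligned_to(g.samples), g.samples))
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            theta = wc_fst(g, sheet, (a, b))
            out.loc[a, b] = out.loc[b, a] = theta
    return out


# ---------------------------------------------------------------------------
# two-level AMOVA on haplotypic (allele-mismatch) distances


@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    df_among: int
    df_within: int


def _pairwise_mismatch(dosages: np.ndarray) -> np.ndarray:
    """Counts of mismatching jointly non-missing loci between sample pairs."""
    n = dosages.shape[0]
    d = np.zeros((n, n))
    ok = dosages != MISSING
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        diff = (dosages[i] != dosages[i + 1:]) & both
        d[i, i + 1:] = diff.sum(axis=1)
    return d + d.T


def amova_two_level(g: GenotypeMatrix, sheet: SampleSheet) -> AmovaResult:
    """Among- vs within-population variance components from pairwise
    allele-mismatch distances (haplotypic AMOVA).

    Requires haploid samples (split diploids first).  Percentages sum to
    100 exactly.
    """
    if not (g.ploidy == 1).all():
        raise ValueError("AMOVA operates on haploid samples; split diploids first")
    idx = population_indices(sheet.aligned_to(g.samples), g.samples)
    if len(idx) < 2:
        raise ValueError("AMOVA undefined for a single population")
    # mismatch counts between 0/1 haplotypes are already squared Euclidean
    d2 = _pairwise_mismatch(g.dosages)
    N = g.n_samples
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    sizes = []
    for rows in idx.values():
        n_g = len(rows)
        sizes.append(n_g)
        sub = d2[np.ix_(rows, rows)]
        ss_within += sub[np.triu_indices(n_g, 1)].sum() / n_g
    r = len(idx)
    ss_among = ss_total - ss_within
    df_among, df_within = r - 1, N - r
    ms_among = ss_among / df_among
    sigma_w = ss_within / df_within
    n_prime = (N - sum(s**2 for s in sizes) / N) / (r - 1)
    sigma_a = (ms_among - sigma_w) / n_prime
    total = sigma_a + sigma_w
    return AmovaResult(
        sigma_among=float(sigma_a),
        sigma_within=float(sigma_w),
        pct_among=float(100.0 * sigma_a / total),
        pct_within=float(100.0 * sigma_w / total),
        df_among=df_among,
        df_within=df_within,
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: np.ndarray        # samples x axes
    eigenvalues: np.ndarray
    explained: np.ndarray     # fraction of variance per axis
    samples: list[str]

    def frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"sample": self.samples, **cols})


def pca(g: GenotypeMatrix, n_axes: Optional[int] = None) -> PcaResult:
    """PCA of the standardized dosage matrix.

    Each locus is mean-centered and scaled by sqrt(p(1-p)) of its mean
    allele frequency; missing genotypes are imputed to the locus mean
    (zero after centering).  Monomorphic loci are dropped.
    """
    freq = np.where(g.dosages != MISSING,
                    g.dosages / g.ploidy[:, None], np.nan).astype(float)
    p = np.nanmean(freq, axis=0)
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if poly.sum() < 2 or g.n_samples < 2:
        raise ValueError("need at least 2 samples and 2 polymorphic loci")
    x = (freq[:, poly] - p[poly]) / np.sqrt(p[poly] * (1 - p[poly]))
    x = np.nan_to_num(x)
    cov = x @ x.T / x.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    k = n_axes or min(g.n_samples - 1, len(vals))
    scores = vecs[:, :k] * np.sqrt(vals[:k])
    explained = vals / vals.sum() if vals.sum() > 0 else vals
    return PcaResult(scores=scores, eigenvalues=vals[:k],
                     explained=explained[:k], samples=list(g.samples))


# ---------------------------------------------------------------------------
# shared ancestry by PC-space projection


@dataclass
class AncestryProfile:
    weights: pd.DataFrame   # samples x source pools, rows sum to 1
    n_pcs: int
    identifiable: bool


def eigmix_ancestry(pcs: PcaResult, source_pools: dict[str, Sequence[str]],
                    n_pcs: int = 20) -> AncestryProfile:
    """Express each sample's PC-space position as a convex combination of
    source-pool centroids (nonnegative least squares, renormalized).

    Collinear centroids make the profile non-identifiable; this is
    flagged rather than raising.
    """
    n_pcs = min(n_pcs, pcs.scores.shape[1])
    pools = sorted(source_pools)
    if any(len(source_pools[p]) < 2 for p in pools):
        raise ValueError("each source pool needs at least 2 samples")
    row_of = {s: i for i, s in enumerate(pcs.samples)}
    centroids = np.stack([
        pcs.scores[[row_of[s] for s in source_pools[p]], :n_pcs].mean(axis=0)
        for p in pools])
    spread = centroids - centroids.mean(axis=0)
    identifiable = np.linalg.matrix_rank(spread, tol=1e-9) >= len(pools) - 1

    w = np.zeros((len(pcs.samples), len(pools)))
    # sum-to-one enforced through a heavily weighted extra equation, which
    # keeps the problem a plain NNLS while making the solution convex
    lam = 1e6 * max(1.0, float(np.abs(centroids).max()))
    A = np.vstack([centroids.T, lam * np.ones(len(pools))])
    for i in range(len(pcs.samples)):
        b = np.append(pcs.scores[i, :n_pcs], lam)
        sol, _ = nnls(A, b)
        total = sol.sum()
        w[i] = sol / total if total > 0 else np.full(len(pools), 1.0 / len(pools))
    frame = pd.DataFrame(w, index=list(pcs.samples), columns=pools)
    return AncestryProfile(weights=frame, n_pcs=n_pcs, identifiable=bool(identifiable))
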