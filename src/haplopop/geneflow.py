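"""Isolation by distance and gene-flow estimation.

Great-circle distances, Mantel tests with permutation p-values, Rousset's
regression of linearized F_st on log distance (Nm = 1/slope, optionally on
refugium-conditioned pair subsets), and island-model pollen/seed flow
ratios from maternally, paternally and biparentally inherited markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


def geo_distance(latlon_a: tuple[float, float], latlon_b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km."""
    for lat, lon in (latlon_a, latlon_b):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    la1, lo1, la2, lo2 = map(math.radians, (*latlon_a, *latlon_b))
    h = (math.sin((la2 - la1) / 2) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    warning: Optional[str] = None


def mantel(gen_mat: np.ndarray, geo_mat: np.ndarray, n_perm: int = 999,
           seed: int = 0) -> MantelResult:
    """Two-sided Mantel test of matrix association.

    Pearson correlation of off-diagonal entries; the p-value is
    ``(1 + #{|r*| >= |r|}) / (n_perm + 1)`` over seeded joint row/column
    permutations of one matrix.
    """
    a = np.asarray(gen_mat, dtype=float)
    b = np.asarray(geo_mat, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    x, y = a[iu], b[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r = float(np.mean(xs * ys))

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    # permuted upper-triangle of a, vectorized over permutations
    pa = a[perms[:, iu[0]], perms[:, iu[1]]]
    pa_s = (pa - pa.mean(axis=1, keepdims=True)) / pa.std(axis=1, keepdims=True)
    r_perm = (pa_s * ys).mean(axis=1)
    p = float((1 + np.sum(np.abs(r_perm) >= abs(r) - 1e-15)) / (n_perm + 1))
    warning = "fewer than 4 populations: permutation p unreliable" if n < 4 else None
    return MantelResult(r=r, p=p, n_perm=n_perm, warning=warning)


# ---------------------------------------------------------------------------
# Rousset regression


@dataclass
class DistancePair:
    pop_a: str
    pop_b: str
    geo_km: float
    lin_fst: float
    refugium_tag: str = ""


@dataclass
class NmEstimate:
    slope: float
    intercept: float
    nm: float  # NaN when slope <= 0
    n_pairs: int
    subset: str = "all"


def linearize_fst(fst: float) -> float:
    if fst >= 1.0:
        raise ValueError("F_st must be below 1 for linearization")
    return fst / (1.0 - fst)


def build_pairs(fst: pd.DataFrame, coords: dict[str, tuple[float, float]],
                refugium_of: Optional[dict[str, str]] = None) -> list[DistancePair]:
    """Pair table from a pairwise F_st matrix and population coordinates."""
    refugium_of = refugium_of or {}
    pops = list(fst.index)
    pairs = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            tags = sorted(t for t in (refugium_of.get(a, ""), refugium_of.get(b, "")) if t)
            pairs.append(DistancePair(
                pop_a=a, pop_b=b,
                geo_km=geo_distance(coords[a], coords[b]),
                lin_fst=linearize_fst(float(fst.loc[a, b])),
                refugium_tag="+".join(tags),
            ))
    return pairs


def select_pairs(pairs: Sequence[DistancePair], subset: str = "all",
                 refugium_of: Optional[dict[str, str]] = None) -> list[DistancePair]:
    """Pair subsets: 'all', a focal refugium name (pairs joining one focal
    population with any non-focal one), or 'exclude:<tag1,tag2>'."""
    refugium_of = refugium_of or {}
    if subset == "all":
        return list(pairs)
    if subset.startswith("exclude:"):
        banned = set(subset.split(":", 1)[1].split(","))
        return [p for p in pairs
                if refugium_of.get(p.pop_a, "") not in banned
                and refugium_of.get(p.pop_b, "") not in banned]
    focal = subset
    out = []
    for p in pairs:
        ta, tb = refugium_of.get(p.pop_a, ""), refugium_of.get(p.pop_b, "")
        if (ta == focal) != (tb == focal):
            out.append(p)
    return out


def rousset_nm(pairs: Sequence[DistancePair], subset: str = "all") -> NmEstimate:
    """OLS of linearized F_st on ln(geographic distance); Nm = 1/slope.

    Same-location pairs (zero distance) are excluded.  A non-positive
    slope yields an undefined (NaN) Nm with a warning.
    """
    use = [p for p in pairs if p.geo_km > 0]
    if len(use) < 3:
        raise ValueError("need at least 3 pairs with positive distance")
    x = np.log([p.geo_km for p in use])
    y = np.array([p.lin_fst for p in use])
    slope, intercept = np.polyfit(x, y, 1)
    if slope > 0:
        nm = 1.0 / slope
    else:
        warnings.warn("non-positive IBD slope: Nm undefined")
        nm = math.nan
    return NmEstimate(slope=float(slope), intercept=float(intercept),
                      nm=float(nm), n_pairs=len(use), subset=subset)


# ---------------------------------------------------------------------------
# pollen/seed flow ratio (island-model equilibrium algebra)


def ennos_ratio(fst_bi: Optional[float] = None, fst_mat: Optional[float] = None,
                fst_pat: Optional[float] = None) -> tuple[float, float]:
    """Pollen-to-seed gene-flow ratios from marker-specific differentiation.

    ``r_eq5`` contrasts biparental with maternal markers:
    ``[(1/fst_bi - 1) - 2 (1/fst_mat - 1)] / (1/fst_mat - 1)``.
    ``r_eq6`` contrasts paternal with maternal markers (the paternal
    marker moves through both pollen and seed):
    ``(1/fst_pat - 1) / (1/fst_mat - 1) - 1``.
    Either ratio is NaN when its inputs are absent; a negative ratio
    (model violation) triggers a warning but is returned as computed.
    """
    if fst_mat is None:
        raise ValueError("maternal F_st is required")
    for name, v in (("fst_bi", fst_bi), ("fst_mat", fst_mat), ("fst_pat", fst_pat)):
        if v is not None and not (0.0 < v < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1)")
    mig_mat = 1.0 / fst_mat - 1.0
    r5 = r6 = math.nan
    if fst_bi is not None:
        r5 = ((1.0 / fst_bi - 1.0) - 2.0 * mig_mat) / mig_mat
    if fst_pat is not None:
        r6 = (1.0 / fst_pat - 1.0) / mig_mat - 1.0
    for r in (r5, r6):
        if not math.isnan(r) and r < 0:
            warnings.warn("negative pollen/seed ratio: island-model assumptions violated")
    return r5, r6
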