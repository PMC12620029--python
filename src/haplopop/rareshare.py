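"""Proportions of shared rare alleles (PSRA).

For each individual and each minor-allele count ``c`` in the pooled
reference (source) samples, the PSRA toward source ``j`` is the average,
over loci where the individual carries the minor allele, of source ``j``'s
share of the summed source allele frequencies:

    PSRA(c)_{i,j} = (1/n) * sum_l f_{l,j} / sum_s f_{l,s}

with ``n`` the number of such loci.  The three source shares of a defined
cell sum to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SampleSheet


@dataclass
class MinorAlleleInfo:
    c: np.ndarray             # per-locus minor-allele count in the pooled sources
    minor_is_alt: np.ndarray  # bool; ties resolved to the alternate allele
    tie: np.ndarray
    usable: np.ndarray        # pooled non-missing allele count >= 1


def minor_allele_counts(g: GenotypeMatrix,
                        source_pools: dict[str, Sequence[str]]) -> MinorAlleleInfo:
    """Minor-allele count and identity per locus in the pooled source samples."""
    row_of = {s: i for i, s in enumerate(g.samples)}
    rows = sorted({row_of[s] for pool in source_pools.values() for s in pool})
    alt, tot = g.allele_counts(np.array(rows))
    ref = tot - alt
    minor_is_alt = alt <= ref  # tie -> alternate allele
    c = np.minimum(alt, ref)
    return MinorAlleleInfo(c=c, minor_is_alt=minor_is_alt,
                           tie=(alt == ref) & (tot > 0), usable=tot >= 1)


def _minor_freqs(g: GenotypeMatrix, source_pools: dict[str, Sequence[str]],
                 minor_is_alt: np.ndarray,
                 exclude: Optional[str] = None) -> np.ndarray:
    """Per-(source, locus) frequency of the minor allele on non-missing calls."""
    row_of = {s: i for i, s in enumerate(g.samples)}
    pools = sorted(source_pools)
    f = np.zeros((len(pools), g.n_loci))
    for j, pool in enumerate(pools):
        rows = np.array([row_of[s] for s in source_pools[pool] if s != exclude])
        alt, tot = g.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_alt = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
        f[j] = np.where(minor_is_alt, f_alt, np.where(tot > 0, 1.0 - f_alt, 0.0))
    return f


def _carries_minor(g: GenotypeMatrix, row: int, minor_is_alt: np.ndarray) -> np.ndarray:
    """Dosage >= 1 copy of the minor allele (carrying, not dosage-weighted)."""
    dos = g.dosages[row]
    ok = dos != MISSING
    carries_alt = ok & (dos >= 1)
    carries_ref = ok & (dos < g.ploidy[row])
    return np.where(minor_is_alt, carries_alt, carries_ref)


@dataclass
class PSRATable:
    """Long-form PSRA entries and the source-pool names used."""

    entries: pd.DataFrame  # individual, population, source, c, psra, n_loci
    sources: list[str]
    c_max: int

    def cell(self, individual: str, c: int) -> dict[str, float]:
        sub = self.entries[(self.entries["individual"] == individual)
                           & (self.entries["c"] == c)]
        return dict(zip(sub["source"], sub["psra"]))

    def summary(self) -> pd.DataFrame:
        """Unweighted population mean and SD of PSRA over individuals and
        counts 1..c_max, per source."""
        grp = self.entries.groupby(["population", "source"])["psra"]
        out = grp.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"mean": "psra_mean", "std": "psra_sd",
                                   "count": "n_cells"})


def psra_table(g: GenotypeMatrix, source_pools: dict[str, Sequence[str]],
               sheet: SampleSheet, c_max: int = 8,
               individuals: Optional[Sequence[str]] = None,
               leave_one_out: bool = False) -> PSRATable:
    """PSRA for every individual and minor-allele count 1..``c_max``.

    Loci where the minor allele is absent from every source
    (``sum_s f = 0``) are excluded: the share is undefined there.
    Undefined (individual, c) cells (no carried loci) are omitted, not
    reported as zero.  With ``leave_one_out`` a source member's own calls
    are excluded from its pool's counts and frequencies.
    """
    pools = sorted(source_pools)
    info = minor_allele_counts(g, source_pools)
    f = _minor_freqs(g, source_pools, info.minor_is_alt)
    fsum = f.sum(axis=0)
    member_of = {s: pool for pool in pools for s in source_pools[pool]}

    pop_of = dict(zip(sheet.table["sample"], sheet.table["population"]))
    individuals = list(individuals) if individuals is not None else list(g.samples)
    row_of = {s: i for i, s in enumerate(g.samples)}

    rows = []
    for ind in individuals:
        i = row_of[ind]
        if leave_one_out and ind in member_of:
            info_i = minor_allele_counts(
                g, {p: [s for s in source_pools[p] if s != ind] for p in pools})
            f_i = _minor_freqs(g, source_pools, info_i.minor_is_alt, exclude=ind)
            c_i, minor_i, usable_i = info_i.c, info_i.minor_is_alt, info_i.usable
            fsum_i = f_i.sum(axis=0)
        else:
            c_i, minor_i, usable_i, f_i, fsum_i = (info.c, info.minor_is_alt,
                                                   info.usable, f, fsum)
        carries = _carries_minor(g, i, minor_i)
        base = carries & usable_i & (fsum_i > 0)
        for c in range(1, c_max + 1):
            loci = base & (c_i == c)
            n = int(loci.sum())
            if n == 0:
                continue
            share = f_i[:, loci] / fsum_i[loci]
            vals = share.mean(axis=1)
            for j, pool in enumerate(pools):
                rows.append((ind, pop_of.get(ind, ""), pool, c, float(vals[j]), n))
    entries = pd.DataFrame(rows, columns=["individual", "population", "source",
                                          "c", "psra", "n_loci"])
    return PSRATable(entries=entries, sources=pools, c_max=c_max)


def psra(g: GenotypeMatrix, source_pools: dict[str, Sequence[str]],
         sheet: SampleSheet, individual: str, c: int) -> dict[str, float]:
    """The three source shares for one (individual, c) cell.

    Raises ``ValueError`` when the cell is undefined (no carried loci at
    that count).
    """
    table = psra_table(g, source_pools, sheet, c_max=c, individuals=[individual])
    cell = table.cell(individual, c)
    if not cell:
        raise ValueError(f"PSRA undefined for {individual} at c={c}")
    return cell
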