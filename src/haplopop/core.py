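"""Core data containers shared by every analysis stage.

Genotypes are stored as alternate-allele dosages in a dense
``samples x loci`` integer matrix with ``-1`` as the missing sentinel.
Samples carry an explicit per-sample ploidy (1 or 2); a haploid sample's
dosage is in ``{0, 1}`` and a diploid's in ``{0, 1, 2}``.  Raw
diploid-coded heterozygous calls observed in haploid samples (genotyping
errors by construction) are kept in a separate boolean matrix so QC can
use them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

COMPARTMENTS = ("nuclear", "mito", "chloro")


class ConfigError(ValueError):
    """Raised for invalid or out-of-range configuration values."""


@dataclass
class GenotypeMatrix:
    """Dense biallelic genotype matrix with per-sample ploidy.

    Attributes
    ----------
    samples : list of sample identifiers (rows).
    contigs : per-locus contig name, shape ``(n_loci,)``.
    positions : per-locus 1-based position, strictly increasing within
        each contig.
    ref, alt : per-locus alleles.
    dosages : ``(n_samples, n_loci)`` int16 alternate-allele counts,
        ``-1`` where missing.
    ploidy : ``(n_samples,)`` array of 1 or 2.
    compartment : one of ``nuclear``, ``mito``, ``chloro``.
    depth : optional per-genotype read depth.
    ad_ref, ad_alt : optional per-genotype allelic depths.
    haploid_het : optional boolean matrix marking raw heterozygous calls
        in haploid samples (always False on diploid rows).
    """

    samples: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    ploidy: np.ndarray
    compartment: str = "nuclear"
    depth: Optional[np.ndarray] = None
    ad_ref: Optional[np.ndarray] = None
    ad_alt: Optional[np.ndarray] = None
    haploid_het: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.dosages.shape != (len(self.samples), len(self.positions)):
            raise ValueError("dosage matrix shape inconsistent with samples/loci")
        if not np.isin(self.ploidy, (1, 2)).all():
            raise ValueError("ploidy must be 1 or 2")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.positions)

    @property
    def missing(self) -> np.ndarray:
        return self.dosages == MISSING

    @property
    def called(self) -> np.ndarray:
        return self.dosages != MISSING

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        ok = self.called
        if (self.dosages[ok] > self.ploidy[:, None].repeat(self.n_loci, 1)[ok]).any():
            raise ValueError("dosage exceeds ploidy")
        if (self.dosages[ok] < 0).any():
            raise ValueError("negative non-missing dosage")
        for contig in pd.unique(self.contigs):
            pos = self.positions[self.contigs == contig]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {contig}")

    # -- subsetting ----------------------------------------------------------

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the given locus index or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        pick = lambda a: None if a is None else a[:, index].copy()
        return replace(
            self,
            contigs=self.contigs[index].copy(),
            positions=self.positions[index].copy(),
            ref=self.ref[index].copy(),
            alt=self.alt[index].copy(),
            dosages=self.dosages[:, index].copy(),
            depth=pick(self.depth),
            ad_ref=pick(self.ad_ref),
            ad_alt=pick(self.ad_alt),
            haploid_het=pick(self.haploid_het),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        pick = lambda a: None if a is None else a[index, :].copy()
        return replace(
            self,
            samples=[self.samples[i] for i in index],
            dosages=self.dosages[index, :].copy(),
            ploidy=self.ploidy[index].copy(),
            depth=pick(self.depth),
            ad_ref=pick(self.ad_ref),
            ad_alt=pick(self.ad_alt),
            haploid_het=pick(self.haploid_het),
        )

    # -- summaries -----------------------------------------------------------

    def allele_counts(self, sample_index: Optional[np.ndarray] = None):
        """Return per-locus (alt_count, total_alleles) over non-missing calls."""
        dos = self.dosages if sample_index is None else self.dosages[sample_index]
        plo = self.ploidy if sample_index is None else self.ploidy[sample_index]
        ok = dos != MISSING
        alt = np.where(ok, dos, 0).sum(axis=0)
        tot = (ok * plo[:, None]).sum(axis=0)
        return alt, tot

    def alt_freq(self, sample_index: Optional[np.ndarray] = None) -> np.ndarray:
        alt, tot = self.allele_counts(sample_index)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)


SHEET_COLUMNS = ["sample", "population", "region", "source_pool", "lat", "lon", "ploidy"]


@dataclass
class SampleSheet:
    """Per-sample metadata: population, region, source pool, coordinates, ploidy."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique().tolist())

    def population_of(self, samples: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.table["sample"], self.table["population"]))
        return np.array([lookup[s] for s in samples], dtype=object)

    def ploidy_map(self) -> dict[str, int]:
        return dict(zip(self.table["sample"], self.table["ploidy"].astype(int)))

    def coords(self) -> dict[str, tuple[float, float]]:
        """Population centroid (lat, lon), mean over member samples."""
        g = self.table.groupby("population")[["lat", "lon"]].mean()
        return {p: (float(r["lat"]), float(r["lon"])) for p, r in g.iterrows()}

    def source_pools(self) -> dict[str, list[str]]:
        """Mapping source-pool name -> member sample ids (unpooled samples excluded)."""
        t = self.table[self.table["source_pool"].notna() & (self.table["source_pool"] != "-")]
        return {k: v["sample"].tolist() for k, v in t.groupby("source_pool")}

    def aligned_to(self, samples: Sequence[str]) -> "SampleSheet":
        """Reorder rows to match a genotype matrix's sample order."""
        idx = self.table.set_index("sample").loc[list(samples)].reset_index()
        return SampleSheet(idx)


def population_indices(sheet: SampleSheet, samples: Sequence[str]) -> dict[str, np.ndarray]:
    """Row indices into ``samples`` for each population in the sheet."""
    pops = sheet.population_of(samples)
    return {p: np.flatnonzero(pops == p) for p in sorted(set(pops))}
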