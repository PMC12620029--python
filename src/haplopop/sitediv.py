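"""Diversity statistics by site class.

Codon-degeneracy annotation, per-population nucleotide diversity (pi) and
pi_0/pi_4, Tajima's D, folded site-frequency spectra with hypergeometric
projection, and Stairway-plot-2 blueprint export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .core import MISSING, GenotypeMatrix, SampleSheet, population_indices

SITE_CLASSES = ("fold0", "fold4", "neutral", "other")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SiteAnnotation:
    """Per-locus functional class plus accessible length per class."""

    classes: np.ndarray  # per-locus class label
    accessible_bp: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=object)
        bad = set(self.classes) - set(SITE_CLASSES)
        if bad:
            raise ValueError(f"unknown site classes {bad}")

    def mask(self, cls: str) -> np.ndarray:
        return self.classes == cls


def classify_degeneracy(cds: str, frame: int = 0, strand: str = "+") -> list[str]:
    """Classify each CDS position as fold0 / fold4 / other.

    A position is fold4 if all three substitutions are synonymous, fold0
    if none are.  Positions in codons with ambiguous bases, and positions
    outside complete codons, are "other".
    """
    seq = cds.upper()
    if strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    out = ["other"] * len(seq)
    coding = seq[frame:]
    for c0 in range(0, len(coding) - 2, 3):
        codon = coding[c0:c0 + 3]
        if any(b not in _BASES for b in codon):
            continue
        aa = _CODON_TABLE[codon]
        for offset in range(3):
            syn = sum(
                _CODON_TABLE[codon[:offset] + b + codon[offset + 1:]] == aa
                for b in _BASES if b != codon[offset])
            cls = "fold4" if syn == 3 else ("fold0" if syn == 0 else "other")
            idx = frame + c0 + offset
            out[idx] = cls
    if strand == "-":
        out = out[::-1]
    return out


# ---------------------------------------------------------------------------
# nucleotide diversity


def _pi_numerator(dosages: np.ndarray, ploidy: np.ndarray) -> float:
    """Sum over loci of the unbiased per-site heterozygosity 2*p*q*n/(n-1)."""
    ok = dosages != MISSING
    alt = np.where(ok, dosages, 0).sum(axis=0).astype(float)
    tot = (ok * ploidy[:, None]).sum(axis=0).astype(float)
    use = tot > 1
    p = alt[use] / tot[use]
    n = tot[use]
    return float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1.0)))


def pi(g: GenotypeMatrix, ann: SiteAnnotation, cls: str,
       sheet: Optional[SampleSheet] = None) -> dict[str, float]:
    """Average pairwise diversity per site for one site class.

    Monomorphic accessible sites contribute zero to the numerator and
    their full length to the denominator (``accessible_bp``).
    Returns a mapping population -> pi; key ``"overall"`` when no sheet
    is given.
    """
    L = ann.accessible_bp.get(cls, 0)
    if L <= 0:
        raise ValueError(f"no accessible length for class {cls!r}")
    sub = g.take_loci(ann.mask(cls))
    if sheet is None:
        return {"overall": _pi_numerator(sub.dosages, sub.ploidy) / L}
    out = {}
    for pop, idx in population_indices(sheet.aligned_to(g.samples), g.samples).items():
        out[pop] = _pi_numerator(sub.dosages[idx], sub.ploidy[idx]) / L
    return out


def pi_ratio(g: GenotypeMatrix, ann: SiteAnnotation,
             sheet: Optional[SampleSheet] = None) -> dict[str, float]:
    """pi_0 / pi_4 per population; NaN where pi_4 is zero."""
    p0 = pi(g, ann, "fold0", sheet)
    p4 = pi(g, ann, "fold4", sheet)
    return {k: (p0[k] / p4[k] if p4[k] > 0 else math.nan) for k in p0}


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: float) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, int(n)))
    a2 = sum(1.0 / i**2 for i in range(1, int(n)))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d_counts(alt: np.ndarray, tot: np.ndarray) -> float:
    """Tajima's D from per-site alternate and total allele counts.

    Per-site statistics use the site's own sample size; the variance
    constants use the median sample size over segregating sites.
    """
    alt = np.asarray(alt, dtype=float)
    tot = np.asarray(tot, dtype=float)
    seg = (alt > 0) & (alt < tot) & (tot > 1)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    n_med = float(np.median(tot[seg]))
    if n_med < 4:
        return math.nan
    p = alt[seg] / tot[seg]
    n = tot[seg]
    pi_hat = float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1.0)))
    k = _tajima_constants(n_med)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    if var <= 0:
        return math.nan
    return (pi_hat - theta_w) / math.sqrt(var)


def tajimas_d(g: GenotypeMatrix, ann: Optional[SiteAnnotation] = None,
              cls: str = "fold4", sheet: Optional[SampleSheet] = None
              ) -> dict[str, float]:
    """Tajima's D per population on one site class (default 4-fold)."""
    sub = g.take_loci(ann.mask(cls)) if ann is not None else g
    groups = ({"overall": np.arange(sub.n_samples)} if sheet is None else
              population_indices(sheet.aligned_to(g.samples), g.samples))
    out = {}
    for pop, idx in groups.items():
        alt, tot = sub.allele_counts(idx)
        out[pop] = tajimas_d_counts(alt, tot)
    return out


# ---------------------------------------------------------------------------
# folded SFS with hypergeometric projection


@dataclass
class FoldedSFS:
    """Folded spectrum after hypergeometric projection to ``n_proj`` copies."""

    n_proj: int
    counts: np.ndarray  # mass at minor-allele classes 1..n_proj//2
    L: int = 0
    n_input_sites: int = 0
    retained_mass: float = 0.0
    discarded_monomorphic: float = 0.0
    n_skipped: int = 0

    @property
    def n_classes(self) -> int:
        return self.n_proj // 2


def default_projection(n_initial: int) -> int:
    """Half the initial haploid sample size, rounded down to an even number."""
    half = n_initial // 2
    return half - (half % 2)


def folded_sfs_project(g: GenotypeMatrix, n_proj: Optional[int] = None,
                       sample_index: Optional[np.ndarray] = None,
                       L: int = 0) -> FoldedSFS:
    """Project each SNP's allele count down to ``n_proj`` copies.

    A SNP with ``k`` alternate alleles among ``n`` non-missing copies
    spreads hypergeometric mass ``P(j | k, n, n_proj)`` over projected
    counts ``j``; mass at ``j = 0`` and ``j = n_proj`` is discarded as
    monomorphic and the rest folded (``j`` pooled with ``n_proj - j``).
    Sites with fewer than ``n_proj`` non-missing copies are skipped and
    counted.
    """
    alt, tot = g.allele_counts(sample_index)
    seg = (alt > 0) & (alt < tot)
    alt, tot = alt[seg], tot[seg]
    if n_proj is None:
        n_proj = default_projection(int(tot.max()) if len(tot) else 0)
    if n_proj < 2:
        raise ValueError("projection size must be at least 2")

    counts = np.zeros(n_proj // 2 + 1)  # index = folded class, 0 unused
    discarded = 0.0
    skipped = 0
    j = np.arange(n_proj + 1)
    folded_class = np.minimum(j, n_proj - j)
    for k, n in zip(alt, tot):
        if n < n_proj:
            skipped += 1
            continue
        mass = hypergeom.pmf(j, int(n), int(k), n_proj)
        discarded += mass[0] + mass[-1]
        np.add.at(counts, folded_class[1:-1], mass[1:-1])
    return FoldedSFS(
        n_proj=n_proj,
        counts=counts[1:],
        L=L,
        n_input_sites=int(seg.sum()),
        retained_mass=float(counts[1:].sum()),
        discarded_monomorphic=float(discarded),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Stairway plot 2 blueprint export


def export_stairway_input(sfs: FoldedSFS, popid: str, path: str | Path,
                          mu: float = 15.9e-9, gen_time: float = 20.0,
                          pct_training: float = 0.67, seed: int = 6) -> Path:
    """Write a Stairway-plot-2 blueprint for a folded spectrum (no fitting)."""
    if sfs.L <= 0:
        raise ValueError("accessible length L must be positive")
    path = Path(path)
    nseq = sfs.n_proj
    nrand = sorted({max(1, (nseq - 2) // 4), max(1, (nseq - 2) // 2),
                    max(1, (nseq - 2) * 3 // 4), max(1, nseq - 2)})
    sfs_line = " ".join(repr(float(x)) for x in sfs.counts)
    text = "\n".join([
        f"popid: {popid}",
        f"nseq: {nseq}",
        f"L: {sfs.L}",
        "whether_folded: true",
        f"SFS: {sfs_line}",
        "smallest_size_of_SFS_bin_used_for_estimation: 1",
        f"largest_size_of_SFS_bin_used_for_estimation: {sfs.n_classes}",
        f"pct_training: {pct_training}",
        f"nrand: {' '.join(str(x) for x in nrand)}",
        f"project_dir: {popid}_stairway",
        "stairway_plot_dir: stairway_plot_es",
        "ninput: 200",
        f"random_seed: {seed}",
        f"mu: {mu}",
        f"year_per_generation: {gen_time}",
        f"plot_title: {popid}",
        "xrange: 0,0",
        "yrange: 0,0",
        "xspacing: 2",
        "yspacing: 2",
        "fontsize: 12",
        "",
    ])
    path.write_text(text)
    return path


def parse_stairway_blueprint(path: str | Path) -> dict:
    """Parse the fields written by :func:`export_stairway_input`."""
    fields = {}
    for line in Path(path).read_text().splitlines():
        if ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    sfs = np.array([float(x) for x in fields["SFS"].split()])
    return {
        "popid": fields["popid"],
        "nseq": int(fields["nseq"]),
        "L": int(fields["L"]),
        "folded": fields["whether_folded"] == "true",
        "sfs": sfs,
        "mu": float(fields["mu"]),
        "gen_time": float(fields["year_per_generation"]),
    }
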