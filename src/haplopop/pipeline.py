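"""Pipeline orchestration: stage graph, parameters, manifests.

Stages run in a fixed order (qc -> prune/split -> diversity -> structure
-> geneflow -> psra -> organelle); each stage appends a manifest entry
(parameters, seed, counts in/out) to the run log, and stages whose inputs
are unavailable are skipped with a logged reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import geneflow as gf
from . import organelle as org
from . import popstruct, rareshare, sitediv, variant_qc
from .core import GenotypeMatrix, SampleSheet
from .vcfio import read_sheet, read_vcf, write_bed, write_vcf

_KNOWN_KEYS = {
    "nuclear_vcf", "mito_vcf", "chloro_vcf", "sheet", "site_classes",
    "out_dir", "seed", "stages",
    "het_max", "d_max", "hwe_alpha", "hwe_pops", "window", "window_err",
    "min_depth", "max_miss", "pop_call", "r2", "ld_window",
    "resolution", "c_max", "n_pcs", "accessible_bp",
}

_ALL_STAGES = ("qc", "prune_split", "diversity", "structure",
               "geneflow", "psra", "organelle")


@dataclass
class RunConfig:
    nuclear_vcf: Optional[str] = None
    mito_vcf: Optional[str] = None
    chloro_vcf: Optional[str] = None
    sheet: Optional[str] = None
    site_classes: Optional[str] = None
    out_dir: str = "haplopop_out"
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    # stage parameters; defaults follow the published thresholds
    het_max: float = 0.6
    d_max: float = 20.0
    hwe_alpha: float = 0.05
    hwe_pops: int = 3
    window: int = 250
    window_err: float = 0.10
    min_depth: int = 6
    max_miss: float = 0.6
    pop_call: float = 0.5
    r2: float = 0.8
    ld_window: int = 10_000
    resolution: float = 0.2
    c_max: int = 8
    n_pcs: int = 20
    accessible_bp: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.entries: list[dict[str, Any]] = []

    def log(self, stage: str, **info: Any) -> None:
        self.entries.append({"stage": stage, **info})
        self.path.write_text(json.dumps(self.entries, indent=2, default=str))


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns in-memory artifacts."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out_dir / "manifest.json")
    artifacts: dict[str, Any] = {}

    if cfg.sheet is None or cfg.nuclear_vcf is None:
        raise ValueError("pipeline requires at least a nuclear VCF and a sample sheet")
    sheet = read_sheet(cfg.sheet)
    g, info = read_vcf(cfg.nuclear_vcf, sheet.ploidy_map())
    manifest.log("load", vcf=cfg.nuclear_vcf, digest=_digest(Path(cfg.nuclear_vcf)),
                 n_samples=g.n_samples, n_loci=g.n_loci, skipped=info["n_skipped"])

    # ---- qc ---------------------------------------------------------------
    if "qc" in cfg.stages:
        n_in = g.n_loci
        flags, g = variant_qc.compute_flags(
            g, sheet, max_het=cfg.het_max, d_max=cfg.d_max,
            hwe_alpha=cfg.hwe_alpha, hwe_count=cfg.hwe_pops)
        flags.to_frame(g).to_csv(out_dir / "error_flags.tsv", sep="\t", index=False)
        report = variant_qc.window_screen(flags.union(), g, window_bp=cfg.window,
                                          max_error_rate=cfg.window_err)
        g = g.take_loci(report.kept_loci)
        g = variant_qc.depth_missing_filter(
            g, sheet, min_depth=cfg.min_depth, max_missing=cfg.max_miss,
            min_pop_call=cfg.pop_call)
        write_bed(report.excluded_bed().itertuples(index=False, name=None),
                  out_dir / "excluded_windows.bed")
        write_vcf(g, out_dir / "nuclear_filtered.vcf")
        manifest.log("qc", seed=cfg.seed, n_in=n_in, n_out=g.n_loci,
                     n_dropped=n_in - g.n_loci, excluded_bp=report.excluded_bp)
        artifacts["qc_report"] = report
    artifacts["nuclear"] = g

    # ---- prune + split ----------------------------------------------------
    if "prune_split" in cfg.stages:
        n_in = g.n_loci
        hap = g.take_samples(g.ploidy == 1)
        dip = g.take_samples(g.ploidy == 2)
        kept = None
        for part in (p for p in (hap, dip) if p.n_samples):
            pruned = variant_qc.ld_prune(part, r2_max=cfg.r2,
                                         window_bp=cfg.ld_window, seed=cfg.seed)
            keys = set(zip(pruned.contigs, pruned.positions))
            kept = keys if kept is None else (kept & keys)
        mask = np.array([(c, p) in kept for c, p in zip(g.contigs, g.positions)])
        pruned = g.take_loci(mask)
        split = variant_qc.split_diploids(pruned, seed=cfg.seed)
        split_sheet = variant_qc.split_sheet(sheet, split.samples)
        write_vcf(split, out_dir / "nuclear_pruned_split.vcf")
        manifest.log("prune_split", seed=cfg.seed, n_in=n_in, n_out=pruned.n_loci,
                     n_samples_out=split.n_samples)
        artifacts["split"] = split
        artifacts["split_sheet"] = split_sheet

    # ---- diversity --------------------------------------------------------
    if "diversity" in cfg.stages:
        if cfg.site_classes:
            from .vcfio import read_site_classes
            classes = read_site_classes(cfg.site_classes, g)
        else:
            classes = np.array(["neutral"] * g.n_loci, dtype=object)
        accessible = dict(cfg.accessible_bp)
        for cls in sitediv.SITE_CLASSES:
            accessible.setdefault(cls, max(int((classes == cls).sum()), 1))
        ann = sitediv.SiteAnnotation(classes=classes, accessible_bp=accessible)
        rows = []
        has4 = (classes == "fold4").any()
        pis = sitediv.pi(g, ann, "fold4" if has4 else "neutral", sheet)
        tds = sitediv.tajimas_d(g, ann if has4 else None,
                                cls="fold4", sheet=sheet)
        ratios = (sitediv.pi_ratio(g, ann, sheet)
                  if has4 and (classes == "fold0").any() else {})
        for pop in pis:
            rows.append((pop, pis[pop], ratios.get(pop, float("nan")), tds[pop]))
        div = pd.DataFrame(rows, columns=["population", "pi_4", "pi0_pi4", "tajimas_d"])
        div.to_csv(out_dir / "diversity.tsv", sep="\t", index=False)
        manifest.log("diversity", populations=len(rows))
        artifacts["diversity"] = div

    # ---- structure --------------------------------------------------------
    if "structure" in cfg.stages and "split" in artifacts:
        split, ssheet = artifacts["split"], artifacts["split_sheet"]
        fst = popstruct.fst_matrix(split, ssheet)
        fst.to_csv(out_dir / "fst_matrix.tsv", sep="\t")
        amova = popstruct.amova_two_level(split, ssheet)
        pcs = popstruct.pca(split)
        pcs.frame().to_csv(out_dir / "pca_scores.tsv", sep="\t", index=False)
        artifacts.update(fst=fst, amova=amova, pca=pcs)
        pools = {k: [s for s in v if s in split.samples] or
                    [s for s in split.samples
                     if s.rsplit("__", 1)[0] in set(v)]
                 for k, v in sheet.source_pools().items()}
        pools = {k: v for k, v in pools.items() if len(v) >= 2}
        if len(pools) >= 2:
            profile = popstruct.eigmix_ancestry(pcs, pools, n_pcs=cfg.n_pcs)
            profile.weights.to_csv(out_dir / "ancestry.tsv", sep="\t")
            artifacts["ancestry"] = profile
        manifest.log("structure", pct_among=amova.pct_among,
                     n_pops=fst.shape[0])

    # ---- geneflow ---------------------------------------------------------
    if "geneflow" in cfg.stages:
        if sheet.table[["lat", "lon"]].isna().any().any() or "fst" not in artifacts:
            manifest.log("geneflow", skipped="missing coordinates or F_st matrix")
        else:
            fst = artifacts["fst"]
            coords = sheet.coords()
            pops = list(fst.index)
            geo = np.zeros_like(fst.to_numpy())
            for i, a in enumerate(pops):
                for j, b in enumerate(pops):
                    geo[i, j] = gf.geo_distance(coords[a], coords[b])
            lin = fst.to_numpy() / (1 - fst.to_numpy())
            mt = gf.mantel(lin, np.log(np.where(geo > 0, geo, 1.0)),
                           seed=cfg.seed)
            pairs = gf.build_pairs(fst, coords)
            nm = gf.rousset_nm(pairs)
            pd.DataFrame([vars(p) for p in pairs]).to_csv(
                out_dir / "ibd_pairs.tsv", sep="\t", index=False)
            manifest.log("geneflow", mantel_r=mt.r, mantel_p=mt.p, nm=nm.nm)
            artifacts.update(mantel=mt, nm=nm, pairs=pairs)

    # ---- psra -------------------------------------------------------------
    if "psra" in cfg.stages and "split" in artifacts:
        split, ssheet = artifacts["split"], artifacts["split_sheet"]
        pools = {k: v for k, v in ssheet.source_pools().items() if len(v) >= 2}
        if len(pools) < 2:
            manifest.log("psra", skipped="fewer than 2 source pools in sheet")
        else:
            table = rareshare.psra_table(split, pools, ssheet, c_max=cfg.c_max)
            table.entries.to_csv(out_dir / "psra.tsv", sep="\t", index=False)
            table.summary().to_csv(out_dir / "psra_summary.tsv", sep="\t", index=False)
            manifest.log("psra", n_cells=len(table.entries))
            artifacts["psra"] = table

    # ---- organelle --------------------------------------------------------
    if "organelle" in cfg.stages:
        for compartment, path in (("mito", cfg.mito_vcf), ("chloro", cfg.chloro_vcf)):
            if path is None:
                manifest.log("organelle", compartment=compartment, skipped="no VCF")
                continue
            go, _ = read_vcf(path, {s: 1 for s in sheet.samples}, compartment)
            go = org.organelle_filter(go)
            if go.n_samples < 2:
                manifest.log("organelle", compartment=compartment,
                             skipped="fewer than 2 samples after filtering")
                continue
            d, _low = org.hamming_matrix(go)
            net = org.build_network(d, go.samples)
            net = org.detect_communities(net, resolution=cfg.resolution,
                                         seed=cfg.seed)
            net.edge_list().to_csv(out_dir / f"{compartment}_network.tsv",
                                   sep="\t", index=False)
            pd.Series(net.communities, name="community").rename_axis("sample") \
                .to_csv(out_dir / f"{compartment}_communities.tsv", sep="\t")
            manifest.log("organelle", compartment=compartment,
                         n_samples=go.n_samples, n_loci=go.n_loci,
                         n_communities=len(set(net.communities.values())))
            artifacts[f"{compartment}_network"] = net

    return artifacts
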