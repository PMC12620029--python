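"""Organelle-compartment analyses: relaxed-depth QC, haplotype distances,
minimum spanning networks and weighted Louvain communities."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


def organelle_filter(g: GenotypeMatrix, max_locus_missing: float = 0.25,
                     max_sample_missing: float = 0.25) -> GenotypeMatrix:
    """QC for haploid organellar matrices.

    Order is fixed: heterozygous calls are set missing, loci where any
    heterozygote was observed are dropped, then samples and finally loci
    exceeding the missingness ceilings are removed.  An empty result is
    permitted.
    """
    if g.compartment not in ("mito", "chloro"):
        raise ValueError("organelle_filter expects a mito or chloro matrix")
    out = g.take_loci(np.arange(g.n_loci))
    het = out.dosages == 1
    het &= out.ploidy[:, None] == 2
    if out.haploid_het is not None:
        het |= out.haploid_het
    out.dosages[het] = MISSING
    out = out.take_loci(~het.any(axis=0))
    sample_miss = (out.dosages == MISSING).mean(axis=1)
    out = out.take_samples(sample_miss <= max_sample_missing)
    if out.n_samples:
        locus_miss = (out.dosages == MISSING).mean(axis=0)
        out = out.take_loci(locus_miss <= max_locus_missing)
    return out


def hamming_matrix(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise mismatch counts over jointly non-missing loci.

    Also returns a boolean matrix flagging low-confidence pairs (fewer
    than 50% jointly non-missing loci).  Under missingness the triangle
    inequality may fail; flagged, not repaired.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    ok = g.dosages != MISSING
    n = g.n_samples
    d = np.zeros((n, n), dtype=np.int64)
    joint = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        diff = (g.dosages[i] != g.dosages[i + 1:]) & both
        d[i, i + 1:] = diff.sum(axis=1)
        joint[i, i + 1:] = both.sum(axis=1)
    d += d.T
    joint += joint.T
    low_conf = joint < 0.5 * g.n_loci
    np.fill_diagonal(low_conf, False)
    return d, low_conf


@dataclass
class HaploNetwork:
    graph: nx.Graph                      # nodes = sample/haplotype ids
    communities: dict[str, int] | None = None
    resolution: float | None = None

    def edge_list(self) -> pd.DataFrame:
        rows = [(a, b, d["mutations"], d["weight"])
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "mutations", "weight"])


def build_network(dist: np.ndarray, labels: list[str]) -> HaploNetwork:
    """Minimum spanning network: MST edges plus all equal-length ties.

    Kruskal-style: edges are processed in ascending distance; within each
    distance class every edge joining two still-separate components is
    kept, and components merge only after the whole class is processed,
    so alternative equally-short connections are all retained.  Edge
    weight is the similarity ``1 / (1 + d)`` used for community
    detection; the raw mutation count is kept alongside.
    """
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = sorted((dist[i, j], i, j) for i in range(n) for j in range(i + 1, n))
    k = 0
    while k < len(edges):
        d = edges[k][0]
        batch = []
        while k < len(edges) and edges[k][0] == d:
            _, i, j = edges[k]
            if find(i) != find(j):
                batch.append((i, j))
            k += 1
        for i, j in batch:
            graph.add_edge(labels[i], labels[j],
                           mutations=int(d), weight=1.0 / (1.0 + float(d)))
        for i, j in batch:
            parent[find(i)] = find(j)
    return HaploNetwork(graph=graph)


def detect_communities(net: HaploNetwork, resolution: float = 0.2,
                       seed: int = 0) -> HaploNetwork:
    """Louvain modularity communities on similarity weights.

    Distances are already transformed to affinities ``1/(1+d)`` by
    :func:`build_network`, so longer mutation paths weaken ties.  The
    node ordering is seeded for reproducibility.
    """
    if net.graph.number_of_nodes() == 0:
        return HaploNetwork(graph=net.graph, communities={}, resolution=resolution)
    parts = nx.community.louvain_communities(
        net.graph, weight="weight", resolution=resolution, seed=seed)
    communities: dict[str, int] = {}
    for cid, members in enumerate(sorted(parts, key=lambda s: sorted(s)[0])):
        for node in members:
            communities[node] = cid
    return HaploNetwork(graph=net.graph, communities=communities,
                        resolution=resolution)
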