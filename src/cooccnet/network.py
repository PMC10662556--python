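"""Gene similarity networks from a distance matrix.

Three network modes mirror how the matrix is explored in practice:

* **global** — every gene pair within a distance threshold;
* **ego** — a seed gene and its within-threshold neighbors (the "local
  network" of a gene), optionally with neighbor-neighbor edges;
* **intersection** — genes simultaneously within threshold of two seeds.

The canonical edge weight is the DISTANCE (0 = most similar, since
delta(x, x) = 0); every export also carries similarity = 1 - distance so
either orientation can be read off directly. Threshold comparison uses
``<=`` with a 1e-9 absolute tolerance so "distance exactly 0" networks
are robust to float noise.

Exports target Gephi-compatible formats (GEXF, GraphML) via networkx,
plus a plain edge-list TSV; node and edge ordering is lexicographic, so
output files are deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx

from .cooccurrence import DistanceMatrix
from .errors import CooccnetError, UnknownGeneError

logger = logging.getLogger(__name__)

#: Absolute tolerance for the distance <= threshold comparison.
THRESHOLD_TOL = 1e-9

Mode = Literal["global", "ego", "intersection"]
ExportFormat = Literal["gexf", "graphml", "tsv"]


@dataclass
class GeneNetwork:
    """Nodes (genes) and weighted edges surviving a distance threshold."""

    nodes: list[str]
    edges: list[tuple[str, str, float, float]]  # (a, b, distance, similarity)
    threshold: float
    mode: Mode
    seed_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        node_set = set(self.nodes)
        for a, b, d, s in self.edges:
            if a == b:
                raise CooccnetError(f"self-edge on {a!r}")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise CooccnetError(f"duplicate edge {key}")
            seen.add(key)
            if d > self.threshold + THRESHOLD_TOL:
                raise CooccnetError(
                    f"edge ({a}, {b}) distance {d} exceeds threshold {self.threshold}"
                )
            if a not in node_set or b not in node_set:
                raise CooccnetError(f"edge endpoint missing from node list: {a}, {b}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_set(self, gene: str) -> set[str]:
        out = set()
        for a, b, _, _ in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(threshold=self.threshold, mode=self.mode)
        g.add_nodes_from(sorted(self.nodes))
        for a, b, d, s in sorted(self.edges):
            g.add_edge(a, b, distance=d, similarity=s, threshold=self.threshold)
        return g


def _edge(a: str, b: str, d: float) -> tuple[str, str, float, float]:
    a, b = sorted((a, b))
    return (a, b, d, 1.0 - d)


def _check_threshold(threshold: float) -> None:
    if not 0.0 <= threshold <= 1.0:
        raise CooccnetError(f"threshold must be in [0, 1], got {threshold}")


def build_network(
    matrix: DistanceMatrix,
    threshold: float,
    *,
    include_isolated: bool = False,
) -> GeneNetwork:
    """Global network: all gene pairs with distance <= threshold.

    By default only genes with at least one surviving edge appear;
    ``include_isolated`` keeps every gene in the matrix as a node.
    """
    _check_threshold(threshold)
    n = len(matrix.genes)
    edges = []
    connected: set[str] = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = float(matrix.values[i, j])
            if d <= threshold + THRESHOLD_TOL:
                edges.append(_edge(matrix.genes[i], matrix.genes[j], d))
                connected.update((matrix.genes[i], matrix.genes[j]))
    nodes = sorted(matrix.genes) if include_isolated else sorted(connected)
    return GeneNetwork(
        nodes=nodes, edges=sorted(edges), threshold=threshold, mode="global"
    )


def ego_network(
    matrix: DistanceMatrix,
    seed: str,
    threshold: float,
    *,
    include_neighbor_edges: bool = False,
) -> GeneNetwork:
    """Local network of a seed gene: its within-threshold neighbors.

    Seed-neighbor edges are always present; neighbor-neighbor edges are
    added only when ``include_neighbor_edges`` is set and the pair itself
    is within threshold.
    """
    _check_threshold(threshold)
    i = matrix.index_of(seed)
    neighbors = [
        g
        for j, g in enumerate(matrix.genes)
        if g != seed and float(matrix.values[i, j]) <= threshold + THRESHOLD_TOL
    ]
    edges = [_edge(seed, g, matrix.distance(seed, g)) for g in neighbors]
    if include_neighbor_edges:
        for a_idx in range(len(neighbors)):
            for b_idx in range(a_idx + 1, len(neighbors)):
                a, b = neighbors[a_idx], neighbors[b_idx]
                d = matrix.distance(a, b)
                if d <= threshold + THRESHOLD_TOL:
                    edges.append(_edge(a, b, d))
    return GeneNetwork(
        nodes=sorted({seed, *neighbors}),
        edges=sorted(edges),
        threshold=threshold,
        mode="ego",
        seed_genes=[seed],
    )


def intersection_network(
    matrix: DistanceMatrix,
    seed_a: str,
    seed_b: str,
    threshold: float,
) -> GeneNetwork:
    """Genes within threshold of BOTH seeds, each linked to both seeds."""
    _check_threshold(threshold)
    if seed_a == seed_b:
        logger.info("identical seeds %r: degenerating to ego network", seed_a)
        net = ego_network(matrix, seed_a, threshold)
        return GeneNetwork(
            nodes=net.nodes,
            edges=net.edges,
            threshold=threshold,
            mode="intersection",
            seed_genes=[seed_a, seed_b],
        )
    ia, ib = matrix.index_of(seed_a), matrix.index_of(seed_b)
    qualifying = [
        g
        for j, g in enumerate(matrix.genes)
        if g not in (seed_a, seed_b)
        and float(matrix.values[ia, j]) <= threshold + THRESHOLD_TOL
        and float(matrix.values[ib, j]) <= threshold + THRESHOLD_TOL
    ]
    edges = []
    for g in qualifying:
        edges.append(_edge(seed_a, g, matrix.distance(seed_a, g)))
        edges.append(_edge(seed_b, g, matrix.distance(seed_b, g)))
    return GeneNetwork(
        nodes=sorted({seed_a, seed_b, *qualifying}),
        edges=sorted(edges),
        threshold=threshold,
        mode="intersection",
        seed_genes=[seed_a, seed_b],
    )


def export_network(net: GeneNetwork, path: str | Path, format: ExportFormat) -> None:
    """Write a network as GEXF, GraphML, or edge-list TSV.

    GEXF and GraphML carry ``distance`` and ``similarity`` on every edge
    (GraphML also carries the threshold as a graph-level key; GEXF notes
    it in the meta description and on each edge). The TSV has columns
    gene_a, gene_b, distance, similarity in lexicographic edge order.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_a", "gene_b", "distance", "similarity"])
            for a, b, d, s in sorted(net.edges):
                writer.writerow([a, b, f"{d:.10g}", f"{s:.10g}"])
    elif fmt == "gexf":
        g = net.to_networkx()
        g.graph["description"] = f"mode={net.mode} threshold={net.threshold}"
        nx.write_gexf(g, path)
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise CooccnetError(f"unknown export format {format!r}")


def read_edge_tsv(path: str | Path, threshold: float = 1.0) -> GeneNetwork:
    """Re-read an edge-list TSV written by :func:`export_network`."""
    edges = []
    nodes: set[str] = set()
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            a, b = row["gene_a"], row["gene_b"]
            d = float(row["distance"])
            edges.append(_edge(a, b, d))
            nodes.update((a, b))
    return GeneNetwork(
        nodes=sorted(nodes), edges=sorted(edges), threshold=threshold, mode="global"
    )
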