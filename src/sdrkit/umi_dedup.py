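"""Directional-network UMI deduplication with indel tolerance.

Observed UMIs within one (cell, sample, gene) group are collapsed by a
directional network: a directed edge A -> B is drawn when the two UMIs are
at free divergence 1 (one edit, counting indels) *and* n_A >= 2*n_B - 1,
reflecting that each extra error to a true UMI should roughly halve the
frequency of observing the derived sequence.  Every node then keeps at most
one incoming "parent" edge (highest-count parent; ties go to the
lexicographically smallest sequence) to avoid artifactual chains through
singletons.  The molecule count is the number of weakly connected components
of the resulting graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import networkx as nx

from .barcode_correction import free_divergence

__all__ = [
    "UmiNode",
    "UmiGraph",
    "build_umi_graph",
    "assign_single_parents",
    "count_umi_components",
    "dedup_umis",
]


@dataclass(frozen=True)
class UmiNode:
    sequence: str
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"UMI {self.sequence!r}: read count must be >= 1")


@dataclass
class UmiGraph:
    graph: nx.DiGraph  # nodes: UMI strings with attribute n; edges: parent -> child

    @property
    def counts(self) -> dict[str, int]:
        return {u: self.graph.nodes[u]["n"] for u in self.graph.nodes}


def _free_div_is_one(a: str, b: str) -> bool:
    # k=1 lets the aligner abandon early once the distance exceeds 1
    d = edlib.align(a, b, mode="SHW", task="distance", k=1)["editDistance"]
    return d == 1


def build_umi_graph(counts: Mapping[str, int]) -> UmiGraph:
    """Build the directional connectivity graph of observed UMIs.

    Edge A -> B iff free_divergence(A, B) == 1 and n_A >= 2*n_B - 1.  The
    free-divergence metric is asymmetric, so both orientations of every pair
    are tested; the count rule decides direction.
    """
    g = nx.DiGraph()
    for umi in sorted(counts):
        n = counts[umi]
        if n < 1:
            raise ValueError(f"UMI {umi!r}: read count must be >= 1")
        g.add_node(umi, n=n)
    umis = sorted(counts)
    for i, a in enumerate(umis):
        na = counts[a]
        for b in umis[i + 1 :]:
            nb = counts[b]
            if na >= 2 * nb - 1 and _free_div_is_one(a, b):
                g.add_edge(a, b)
            if nb >= 2 * na - 1 and _free_div_is_one(b, a):
                g.add_edge(b, a)
    return UmiGraph(g)


def assign_single_parents(graph: UmiGraph) -> UmiGraph:
    """Keep at most one incoming edge per node: the highest-count parent,
    ties broken by lexicographically smallest parent sequence."""
    g = graph.graph
    for child in list(g.nodes):
        parents = list(g.predecessors(child))
        if len(parents) <= 1:
            continue
        keep = min(parents, key=lambda p: (-g.nodes[p]["n"], p))
        for p in parents:
            if p != keep:
                g.remove_edge(p, child)
    return graph


def count_umi_components(graph: UmiGraph) -> int:
    """Number of weakly connected components (0 for an empty graph)."""
    return nx.number_weakly_connected_components(graph.graph)


def dedup_umis(umis: Mapping[str, int] | Sequence[tuple[str, int]]) -> int:
    """Collapse a UMI multiset to a molecule count.

    Accepts a mapping UMI -> read count or a sequence of (UMI, count) pairs
    (repeated UMIs in a sequence are summed).
    """
    if not isinstance(umis, Mapping):
        acc: dict[str, int] = {}
        for umi, n in umis:
            acc[umi] = acc.get(umi, 0) + n
        umis = acc
    if not umis:
        return 0
    graph = build_umi_graph(umis)
    assign_single_parents(graph)
    return count_umi_components(graph)
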