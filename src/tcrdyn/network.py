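"""Per-patient CDR3 similarity networks from Levenshtein distance.

Each patient's productive amino-acid CDR3 sequences (both timepoints
pooled, one node per unique sequence-timepoint combination) are connected
whenever their edit distance is at most 1. Connected clusters of the
distance-<=1 graph are the *convergent groups*; the network is summarized
by its diameter — the longest shortest path over any connected pair,
computed by breadth-first search from every node and maximized over
components. Cohorts are dichotomized at the median diameter (the median
itself falls in the "low" group).

Distances are computed with the banded alignment of ``edlib``; the
pairwise search skips pairs whose length difference already exceeds the
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from .types import PatientCourse, Repertoire, Timepoint

__all__ = [
    "SequenceNode",
    "ConvergenceGraph",
    "levenshtein",
    "pairwise_distance_matrix",
    "convergent_groups",
    "build_network",
    "network_diameter",
    "dichotomize_by_median_diameter",
    "network_summary_table",
]


@dataclass(frozen=True)
class SequenceNode:
    """One network node: an amino-acid CDR3 at one timepoint, with its frequency."""

    aa_cdr3: str
    timepoint: Timepoint
    frequency: float


@dataclass
class ConvergenceGraph:
    """A patient's similarity network with its components and diameter.

    ``edges`` holds (i, j, distance) index triples into ``nodes``;
    ``diameter`` is in edge units by default (see ``diameter_units``).
    """

    patient_id: str
    nodes: list[SequenceNode] = field(default_factory=list)
    edges: list[tuple[int, int, int]] = field(default_factory=list)
    components: list[set[int]] = field(default_factory=list)
    diameter: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_weighted_edges_from(self.edges, weight="distance")
        return g


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def _bounded_distance(a: str, b: str, k: int) -> int:
    """Edit distance if <= k, else -1 (early-abandoned)."""
    if abs(len(a) - len(b)) > k:
        return -1
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def pairwise_distance_matrix(sequences: list[str], max_relevant: int = 1) -> list[tuple[int, int, int]]:
    """All unordered index pairs (i, j, d) with edit distance d <= max_relevant.

    Equivalent to thresholding the dense distance matrix; implemented with
    length bucketing (a pair whose lengths differ by more than
    ``max_relevant`` cannot be within threshold) and k-bounded alignment.
    """
    by_length: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_length.setdefault(len(s), []).append(i)

    pairs = []
    for length, idxs in by_length.items():
        # candidate partners: same bucket plus strictly longer buckets within range
        candidates = list(idxs)
        for other in range(length + 1, length + max_relevant + 1):
            candidates.extend(by_length.get(other, []))
        for a_pos, i in enumerate(idxs):
            si = sequences[i]
            for j in candidates[a_pos + 1 :]:
                d = _bounded_distance(si, sequences[j], max_relevant)
                if d >= 0:
                    pairs.append((i, j, d) if i < j else (j, i, d))
    return pairs


def convergent_groups(sequences: list[str], max_dist: int = 1) -> list[set[int]]:
    """Single-linkage clusters: connected components of the distance-<=max_dist graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(sequences)))
    g.add_edges_from((i, j) for i, j, _ in pairwise_distance_matrix(sequences, max_dist))
    return [set(c) for c in nx.connected_components(g)]


def build_network(course: PatientCourse, max_dist: int = 1, top_n: int | None = None) -> ConvergenceGraph:
    """Build one patient's pooled-timepoint similarity network.

    One node per unique (amino-acid CDR3, timepoint) among productive
    clones; an edge joins every node pair at edit distance <= ``max_dist``.
    The same sequence at both timepoints yields two nodes joined by a
    distance-0 edge. ``top_n`` optionally caps nodes per timepoint to the
    most frequent sequences (default: no cap).
    """
    nodes: list[SequenceNode] = []
    for rep in (course.baseline, course.post):
        if rep is None:
            continue
        freq_by_aa: dict[str, float] = {}
        for rec in rep.productive_records():
            if not rec.aa_cdr3:
                continue
            freq_by_aa[rec.aa_cdr3] = freq_by_aa.get(rec.aa_cdr3, 0.0) + rec.frequency
        items = sorted(freq_by_aa.items(), key=lambda kv: (-kv[1], kv[0]))
        if top_n is not None:
            items = items[:top_n]
        nodes.extend(SequenceNode(aa, rep.timepoint, f) for aa, f in items)

    seqs = [n.aa_cdr3 for n in nodes]
    edges = []
    for i, j, d in pairwise_distance_matrix(seqs, max_dist):
        # distance-0 pairs can only arise across timepoints (aa unique within one)
        edges.append((i, j, d))

    graph = ConvergenceGraph(patient_id=course.patient_id, nodes=nodes, edges=edges)
    g = graph.to_networkx()
    graph.components = [set(c) for c in nx.connected_components(g)]
    graph.diameter = network_diameter(graph)
    return graph


def network_diameter(graph: ConvergenceGraph | nx.Graph) -> int:
    """Longest shortest path (in edges) over all connected pairs; 0 if edgeless.

    Runs a breadth-first search from every node; unreachable pairs never
    contribute, so a disconnected graph reports the maximum over its
    components.
    """
    g = graph.to_networkx() if isinstance(graph, ConvergenceGraph) else graph
    diameter = 0
    for source in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, source)
        ecc = max(lengths.values(), default=0)
        if ecc > diameter:
            diameter = ecc
    return diameter


def dichotomize_by_median_diameter(diameters: dict[str, int]) -> tuple[dict[str, str], float]:
    """Label each patient high/low against the cohort median diameter.

    Returns (labels, median). The median itself is labelled low (the split
    is strictly greater-than); an even cohort uses the midpoint of the two
    central order statistics.
    """
    if len(diameters) < 2:
        raise ValueError("need >= 2 patients with defined diameters")
    values = np.array(list(diameters.values()), dtype=float)
    m = float(np.median(values))
    if values.min() == values.max():
        warnings.warn("all diameters equal; every patient labelled 'low'", stacklevel=2)
    labels = {pid: ("high" if d > m else "low") for pid, d in diameters.items()}
    return labels, m


def network_summary_table(graphs: list[ConvergenceGraph]) -> pd.DataFrame:
    """Per-patient network summary, with the median-diameter group attached."""
    rows = [
        {
            "patient_id": g.patient_id,
            "n_nodes": g.n_nodes,
            "n_edges": g.n_edges,
            "n_components": len(g.components),
            "diameter": g.diameter,
        }
        for g in graphs
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "n_nodes", "n_edges", "n_components", "diameter"])
    if len(df) >= 2:
        labels, _ = dichotomize_by_median_diameter(dict(zip(df["patient_id"], df["diameter"])))
        df["diameter_group"] = df["patient_id"].map(labels)
    else:
        df["diameter_group"] = None
    return df
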