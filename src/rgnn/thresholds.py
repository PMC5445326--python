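"""SSN thresholding and clustering.

An SSN is filtered by removing all edges whose similarity score falls below
a threshold Th; the connected components of the filtered network are the
sequence clusters.  Two data-driven threshold recommendations are computed
from the threshold profile of the network:

* **A-Th** — scan Th over an integer grid and track the edges-per-connected-
  node ratio ``Nsv(Th) = SE(Th) / Nn(Th)``, where SE counts surviving edges
  and Nn counts nodes still incident to at least one edge.  Raising Th first
  strips low-score inter-family edges (Nsv falls); once intra-family edges
  start to go, nodes become isolated and Nsv rises.  A-Th is the lowest grid
  threshold at which Nsv rises relative to the previous grid point.

* **S-Th** — a smoothed variant for dense networks, based on the relative
  series ``relNn(Th) = Nn(Th)/Nn(Th_min)`` and ``relSE(Th) = SE(Th)/SE(Th_min)``
  (Th_min = smallest observed score).  S-Th is the lowest grid value Th_t at
  which the step to Th_{t+1} loses relatively more connected nodes than
  edges: ``relNn(Th_t) − relNn(Th_{t+1}) > relSE(Th_t) − relSE(Th_{t+1})``.

Both comparisons are evaluated in exact integer arithmetic (cross-
multiplied counts), so grid decisions never depend on floating-point
rounding.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .model import Cluster, ClusterAssignment, SSNDocument

__all__ = [
    "ThresholdProfile",
    "compute_threshold_profile",
    "compute_a_th",
    "compute_s_th",
    "apply_threshold",
    "cluster_components",
    "filter_clusters",
]


@dataclass
class ThresholdProfile:
    """Per-threshold network statistics over an integer Th grid.

    ``nsv`` entries are ``None`` where ``nn == 0`` (the ratio is undefined
    once no connected node survives).
    """

    thresholds: list[int]
    nn: list[int]
    se: list[int]
    nsv: list[Optional[float]]
    rel_nn: list[float]
    rel_se: list[float]

    def __post_init__(self) -> None:
        n = len(self.thresholds)
        if not all(len(x) == n for x in (self.nn, self.se, self.nsv, self.rel_nn, self.rel_se)):
            raise ValueError("profile series have unequal lengths")


def compute_threshold_profile(ssn: SSNDocument, step: int = 1) -> ThresholdProfile:
    """Scan thresholds from floor(min score) to floor(max score)+1.

    An edge survives threshold Th iff its score >= Th; ``nn`` counts nodes
    incident to at least one surviving edge (isolated nodes are excluded
    from Nn but are never deleted from the document).
    """
    if step < 1:
        raise ValueError(f"step must be a positive integer, got {step}")
    if ssn.n_edges == 0:
        raise ValueError("threshold profile requires an SSN with at least one edge")

    scores = sorted(ssn.edges.values())
    # a node survives Th iff the strongest edge incident to it survives
    node_max: dict[str, float] = {}
    for (u, v), s in ssn.edges.items():
        if s > node_max.get(u, -math.inf):
            node_max[u] = s
        if s > node_max.get(v, -math.inf):
            node_max[v] = s
    max_incident = sorted(node_max.values())

    t0 = math.floor(scores[0])
    t_end = math.floor(scores[-1]) + 1
    thresholds = list(range(t0, t_end + 1, step))

    nn: list[int] = []
    se: list[int] = []
    for th in thresholds:
        se.append(len(scores) - bisect_left(scores, th))
        nn.append(len(max_incident) - bisect_left(max_incident, th))
    nsv = [s / n if n > 0 else None for s, n in zip(se, nn)]
    rel_nn = [n / nn[0] for n in nn]
    rel_se = [s / se[0] for s in se]
    return ThresholdProfile(thresholds, nn, se, nsv, rel_nn, rel_se)


def compute_a_th(profile: ThresholdProfile) -> Optional[int]:
    """Lowest grid threshold at which Nsv rises; ``None`` if it never does.

    Equality is not a rise; pairs where either Nsv is undefined are skipped.
    """
    for i in range(1, len(profile.thresholds)):
        if profile.nn[i] == 0 or profile.nn[i - 1] == 0:
            continue
        # se[i]/nn[i] > se[i-1]/nn[i-1], cross-multiplied (nn > 0)
        if profile.se[i] * profile.nn[i - 1] > profile.se[i - 1] * profile.nn[i]:
            return profile.thresholds[i]
    return None


def compute_s_th(profile: ThresholdProfile) -> Optional[int]:
    """Lowest grid Th_t whose step to Th_{t+1} loses relatively more
    connected nodes than edges; ``None`` if no step qualifies."""
    nn0, se0 = profile.nn[0], profile.se[0]
    for i in range(len(profile.thresholds) - 1):
        d_nn = profile.nn[i] - profile.nn[i + 1]
        d_se = profile.se[i] - profile.se[i + 1]
        # d_nn/nn0 > d_se/se0, cross-multiplied (nn0, se0 > 0)
        if d_nn * se0 > d_se * nn0:
            return profile.thresholds[i]
    return None


def apply_threshold(ssn: SSNDocument, th: float) -> SSNDocument:
    """Copy of the SSN keeping exactly the edges with score >= th.

    Nodes are all retained: thresholding isolates, it never deletes.
    """
    if th < 0:
        raise ValueError(f"threshold must be non-negative, got {th}")
    out = SSNDocument(ssn.metadata)
    for node in ssn.nodes.values():
        out.add_node(node.copy())
    for (u, v), score in ssn.edges.items():
        if score >= th:
            out.add_edge(u, v, score)
    return out


def cluster_components(ssn: SSNDocument) -> ClusterAssignment:
    """Number the connected components of a (thresholded) SSN.

    Multi-node components come first, ordered by descending SeqCount (sum
    of member seq_count, i.e. represented accessions) with ties broken by
    the lexicographically smallest member node id; singleton components
    follow under the same ordering.  The numbering is therefore independent
    of node insertion order.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ssn.nodes)
    graph.add_edges_from(ssn.edges)
    components = [sorted(c) for c in nx.connected_components(graph)]

    def seq_count(members: list[str]) -> int:
        return sum(ssn.nodes[m].seq_count for m in members)

    multi = [c for c in components if len(c) > 1]
    single = [c for c in components if len(c) == 1]
    ordered = sorted(multi, key=lambda c: (-seq_count(c), c[0])) + sorted(
        single, key=lambda c: (-seq_count(c), c[0])
    )
    clusters = []
    for cid, members in enumerate(ordered, start=1):
        acc_taxids: dict[str, int] = {}
        for m in members:
            node = ssn.nodes[m]
            acc_taxids.update(zip(node.accessions, node.taxids))
        clusters.append(
            Cluster(
                id=cid,
                members=members,
                accessions=sorted(acc_taxids),
                accession_taxids=acc_taxids,
            )
        )
    return ClusterAssignment(clusters)


def filter_clusters(assignment: ClusterAssignment, min_seq_count: int) -> ClusterAssignment:
    """Drop clusters with SeqCount below ``min_seq_count``.

    Surviving cluster ids are preserved (never renumbered) so that results
    stay referable across filter settings.
    """
    if min_seq_count < 0:
        raise ValueError(f"min_seq_count must be >= 0, got {min_seq_count}")
    kept = [c for c in assignment.clusters.values() if c.seq_count >= min_seq_count]
    return ClusterAssignment(kept)
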