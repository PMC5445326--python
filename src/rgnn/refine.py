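"""Refinement of a raw GNN into an rGNN.

The refinement steps are independent and composable:

* enzyme-whitelist filtering of Pfam-nodes;
* phylogenetic debiasing of the SSN (drop subspecies accessions, keep at
  most one sequence per species within each cluster);
* PhylumStat — the normalized phylum frequency spectrum of each cluster;
* GO/description annotation of Pfam-nodes;
* hypergeometric uniqueness statistics.

Uniqueness of an edge between cluster c (n member sequences) and Pfam p is
``−log10 P(X = k)`` under the hypergeometric distribution with population
size N (all sequences of the displayed GNN), M successes (sequences linked
to p anywhere) and n draws, where k is the number of c's sequences linked
to p.  Cluster and Pfam uniqueness are the sums of their incident edge
values, treating Pfam occurrences as independent.  A high cluster value
therefore flags a genome neighborhood made of many, exclusively linked
Pfam domains.  All probabilities are evaluated in log-space (log-gamma):
real families produce values in the thousands, far below the underflow
limit of a direct probability.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .model import (
    ClusterAssignment,
    GNNDocument,
    IntegrityError,
    PfamAnnotationTable,
    PfamWhitelist,
    SSNDocument,
    TaxonomyTable,
    UNKNOWN_TAXID,
)

__all__ = [
    "UniquenessReport",
    "SubspeciesResult",
    "hypergeom_log10_pmf",
    "edge_uniqueness",
    "compute_uniqueness",
    "apply_whitelist",
    "build_enzyme_whitelist",
    "eliminate_subspecies",
    "dedup_species_per_cluster",
    "compute_phylum_stat",
    "annotate_pfam_nodes",
]

_LN10 = math.log(10.0)


def _log10_comb(n, k):
    """log10 of the binomial coefficient, vectorized, via log-gamma."""
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return (gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)) / _LN10


def log10_pmf_arrays(N, M, n, k) -> np.ndarray:
    """Vectorized log10 hypergeometric pmf; inputs must already be valid."""
    return np.minimum(
        _log10_comb(M, k) + _log10_comb(np.asarray(N) - M, np.asarray(n) - k) - _log10_comb(N, n),
        0.0,
    )


def _check_hypergeom_args(N: int, M: int, n: int, k: int) -> None:
    for name, val in (("N", N), ("M", M), ("n", n), ("k", k)):
        if int(val) != val:
            raise ValueError(f"{name} must be an integer, got {val!r}")
    if N < 0:
        raise ValueError(f"N must be >= 0, violated: N={N}")
    if not 0 <= M <= N:
        raise ValueError(f"bound 0 <= M <= N violated: M={M}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"bound 0 <= n <= N violated: n={n}, N={N}")
    if not 0 <= k <= min(n, M):
        raise ValueError(f"bound 0 <= k <= min(n, M) violated: k={k}, n={n}, M={M}")
    if n - k > N - M:
        raise ValueError(f"bound n - k <= N - M violated: n={n}, k={k}, N={N}, M={M}")


def hypergeom_log10_pmf(N: int, M: int, n: int, k: int) -> float:
    """log10 of C(M,k)·C(N−M,n−k)/C(N,n), computed in log-space.

    Drawing n sequences from a population of N that contains M marked
    ones, this is the log-probability of seeing exactly k marks.
    """
    _check_hypergeom_args(N, M, n, k)
    return float(log10_pmf_arrays(N, M, n, k))


def edge_uniqueness(N: int, M: int, n: int, k: int) -> float:
    """Uniqueness of a cluster–Pfam edge: ``−log10`` of the point probability."""
    return -hypergeom_log10_pmf(N, M, n, k)


@dataclass
class UniquenessReport:
    """Background counts and per-edge/cluster/Pfam uniqueness values."""

    total_n: int  # N: all sequences of the clusters displayed in the GNN
    pfam_m: dict[str, int] = field(default_factory=dict)  # M per Pfam
    cluster_n: dict[int, int] = field(default_factory=dict)  # n per cluster
    edge: dict[tuple[int, str], float] = field(default_factory=dict)
    cluster: dict[int, float] = field(default_factory=dict)
    pfam: dict[str, float] = field(default_factory=dict)


def compute_uniqueness(
    gnn: GNNDocument, assignment: Optional[ClusterAssignment] = None
) -> UniquenessReport:
    """Annotate a GNN in place with uniqueness values and return the report.

    N is the total sequence count of the clusters present in the GNN (the
    network actually displayed, after any filtering), M_l sums the
    supporting counts of Pfam l over all clusters, n is the cluster's
    SeqCount and k the edge's supporting count.  Cluster and Pfam values
    are the sums of their edges' values.
    """
    if assignment is not None:
        for cid, node in gnn.cluster_nodes.items():
            cluster = assignment.clusters.get(cid)
            if cluster is not None and cluster.seq_count != node.seq_count:
                raise IntegrityError(
                    f"cluster {cid}: GNN SeqCount {node.seq_count} != "
                    f"assignment SeqCount {cluster.seq_count}"
                )
    total_n = sum(node.seq_count for node in gnn.cluster_nodes.values())
    report = UniquenessReport(total_n=total_n)
    for cid, node in gnn.cluster_nodes.items():
        report.cluster_n[cid] = node.seq_count
        if node.seq_count > total_n:
            raise IntegrityError(f"cluster {cid}: n={node.seq_count} exceeds N={total_n}")
    for (cid, pid), e in gnn.edges.items():
        if e.supporting_count > gnn.cluster_nodes[cid].seq_count:
            raise IntegrityError(
                f"edge ({cid}, {pid}): k={e.supporting_count} exceeds "
                f"cluster SeqCount {gnn.cluster_nodes[cid].seq_count}"
            )
        report.pfam_m[pid] = report.pfam_m.get(pid, 0) + e.supporting_count

    for (cid, pid), e in sorted(gnn.edges.items()):
        value = edge_uniqueness(
            total_n, report.pfam_m[pid], report.cluster_n[cid], e.supporting_count
        )
        report.edge[(cid, pid)] = value
        e.uniqueness = value
        report.cluster[cid] = report.cluster.get(cid, 0.0) + value
        report.pfam[pid] = report.pfam.get(pid, 0.0) + value
    for cid, node in gnn.cluster_nodes.items():
        node.uniqueness = report.cluster.get(cid, 0.0)
    for pid, node in gnn.pfam_nodes.items():
        node.uniqueness = report.pfam.get(pid, 0.0)
    return report


# ---------------------------------------------------------------------------
# Whitelist


def apply_whitelist(gnn: GNNDocument, whitelist: PfamWhitelist) -> GNNDocument:
    """Drop Pfam-nodes not admitted by the whitelist, with their edges.

    Composite Pfam-node ids pass if any dash-separated component passes;
    cluster-nodes are always retained.  Idempotent.
    """
    out = GNNDocument()
    for node in gnn.cluster_nodes.values():
        out.add_cluster_node(node)
    for pid, node in gnn.pfam_nodes.items():
        if whitelist.admits(pid):
            out.add_pfam_node(node)
    for key, edge in gnn.edges.items():
        if edge.pfam_id in out.pfam_nodes:
            out.add_edge(edge)
    return out


#: EC numbers are four dot-separated fields; trailing fields of provisional
#: or partial classifications may be "-".
_EC_RE = re.compile(r"(?:\bEC[\s:]*)?\b\d+\.(?:\d+|-)\.(?:\d+|-)\.(?:\d+|-)")
_ENZYME_RE = re.compile(r"enzyme|catalytic", re.IGNORECASE)


def build_enzyme_whitelist(annotations: PfamAnnotationTable) -> PfamWhitelist:
    """Whitelist of Pfams whose description references an enzymatic function:
    an EC number, or the substrings "enzyme" / "catalytic" (case-insensitive)."""
    ids = set()
    for pfam_id, ann in annotations.items():
        if _EC_RE.search(ann.description) or _ENZYME_RE.search(ann.description):
            ids.add(pfam_id)
    return PfamWhitelist(ids)


# ---------------------------------------------------------------------------
# Phylogenetic debiasing


@dataclass
class SubspeciesResult:
    """Filtered SSN plus the taxids the taxonomy table did not cover."""

    ssn: SSNDocument
    unknown_taxids: tuple[int, ...]


def eliminate_subspecies(ssn: SSNDocument, taxonomy: TaxonomyTable) -> SubspeciesResult:
    """Remove every accession whose taxid is a subspecies.

    Accessions at taxid 0 or at taxids the taxonomy does not cover are kept
    (and the uncovered taxids reported); nodes left with no accession are
    deleted together with their edges.  Idempotent.
    """
    out = SSNDocument(ssn.metadata)
    unknown: set[int] = set()
    dropped_nodes: set[str] = set()
    for node in ssn.nodes.values():
        kept_acc: list[str] = []
        kept_tax: list[int] = []
        for acc, taxid in zip(node.accessions, node.taxids):
            if taxid != UNKNOWN_TAXID and taxid not in taxonomy:
                unknown.add(taxid)
            if taxonomy.is_subspecies(taxid):
                continue
            kept_acc.append(acc)
            kept_tax.append(taxid)
        if kept_acc:
            out.add_node(type(node)(node.id, kept_acc, kept_tax))
        else:
            dropped_nodes.add(node.id)
    for (u, v), score in ssn.edges.items():
        if u not in dropped_nodes and v not in dropped_nodes:
            out.add_edge(u, v, score)
    return SubspeciesResult(out, tuple(sorted(unknown)))


def dedup_species_per_cluster(
    assignment: ClusterAssignment, ssn: SSNDocument, taxonomy: TaxonomyTable
) -> tuple[ClusterAssignment, SSNDocument]:
    """Keep at most one sequence per species within each cluster.

    Among the accessions of a cluster anchored to the same species taxid,
    the lexicographically smallest accession survives (deterministic and
    data-independent).  Accessions with unknown or uncovered taxids are
    never removed.  The SSN and the assignment are both updated; nodes or
    clusters emptied by the removal disappear (surviving cluster ids are
    unchanged).  Idempotent.
    """
    remove: set[str] = set()  # accessions to drop, globally unique per node set
    for cluster in assignment.clusters.values():
        by_anchor: dict[int, list[str]] = {}
        for acc in cluster.accessions:
            taxid = cluster.accession_taxids.get(acc, UNKNOWN_TAXID)
            if taxid == UNKNOWN_TAXID or taxid not in taxonomy:
                continue
            by_anchor.setdefault(taxonomy.anchor(taxid), []).append(acc)
        for anchor, accs in by_anchor.items():
            accs.sort()
            remove.update(accs[1:])

    new_ssn = SSNDocument(ssn.metadata)
    dropped_nodes: set[str] = set()
    for node in ssn.nodes.values():
        kept = [(a, t) for a, t in zip(node.accessions, node.taxids) if a not in remove]
        if kept:
            new_ssn.add_node(type(node)(node.id, [a for a, _ in kept], [t for _, t in kept]))
        else:
            dropped_nodes.add(node.id)
    for (u, v), score in ssn.edges.items():
        if u not in dropped_nodes and v not in dropped_nodes:
            new_ssn.add_edge(u, v, score)

    new_clusters = []
    for cluster in assignment.clusters.values():
        members = [m for m in cluster.members if m not in dropped_nodes]
        if not members:
            continue
        acc_taxids = {
            a: t for a, t in cluster.accession_taxids.items() if a not in remove
        }
        new_clusters.append(
            type(cluster)(
                id=cluster.id,
                members=members,
                accessions=sorted(acc_taxids),
                accession_taxids=acc_taxids,
            )
        )
    return ClusterAssignment(new_clusters), new_ssn


def compute_phylum_stat(
    assignment: ClusterAssignment, ssn: SSNDocument, taxonomy: TaxonomyTable
) -> dict[int, dict[str, float]]:
    """Normalized phylum frequencies per cluster.

    Only accessions with a covered, non-zero taxid enter the denominator;
    a cluster with no such accession gets an empty map.  Each non-empty map
    sums to 1 up to floating-point rounding.
    """
    stats: dict[int, dict[str, float]] = {}
    for cid, cluster in assignment.clusters.items():
        counts: dict[str, int] = {}
        for acc in cluster.accessions:
            taxid = cluster.accession_taxids.get(acc, UNKNOWN_TAXID)
            if taxid == UNKNOWN_TAXID or taxid not in taxonomy:
                continue
            phylum = taxonomy.phylum(taxid) or ""
            counts[phylum] = counts.get(phylum, 0) + 1
        total = sum(counts.values())
        stats[cid] = {p: c / total for p, c in counts.items()} if total else {}
    return stats


# ---------------------------------------------------------------------------
# Annotation


def annotate_pfam_nodes(gnn: GNNDocument, annotations: PfamAnnotationTable) -> GNNDocument:
    """Attach descriptions and GO terms to Pfam-nodes, in place.

    Composite ids receive the component annotations joined with "; " and
    the concatenated GO lists; Pfams absent from the table keep empty
    fields.
    """
    for pid, node in gnn.pfam_nodes.items():
        descriptions: list[str] = []
        go_terms: list[str] = []
        for part in pid.split("-"):
            ann = annotations.get(part)
            if ann is None:
                continue
            descriptions.append(ann.description)
            go_terms.extend(ann.go_terms)
        if descriptions:
            node.description = "; ".join(descriptions)
        if go_terms:
            node.go_terms = tuple(go_terms)
    return gnn
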