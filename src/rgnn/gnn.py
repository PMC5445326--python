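"""Genome neighborhood extraction and GNN assembly.

The genome neighborhood (GN) of a query gene is the set of Pfam ids carried
by the nb genes on either side of it, irrespective of strand; the query
gene itself is excluded, linear contigs truncate at their ends and circular
genomes wrap around.  The GNN links each sequence cluster (hub) to the Pfam
domains (spokes) that occur in the neighborhoods of enough of its member
sequences: an edge is drawn iff the fraction of supporting members reaches
the co-occurrence lower limit, and that same fraction is reported as the
edge's coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .model import (
    ClusterAssignment,
    ClusterPfamEdge,
    GNNClusterNode,
    GNNDocument,
    GNNPfamNode,
    GenomeTable,
    IntegrityError,
    NeighborhoodRecord,
)

__all__ = ["NB_RANGE", "NeighborhoodResult", "extract_neighborhoods", "build_gnn"]

#: Neighborhood half-width accepted without the explicit override.
NB_RANGE = (3, 10)


@dataclass
class NeighborhoodResult:
    """Extracted records plus the skip report of unmatched targets."""

    records: list[NeighborhoodRecord]
    missing_targets: frozenset[str]

    def __iter__(self) -> Iterator[NeighborhoodRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _neighbor_indices(i: int, n: int, nb: int, circular: bool) -> list[int]:
    if circular:
        if 2 * nb >= n - 1:
            return [j for j in range(n) if j != i]
        return [(i + d) % n for d in range(-nb, nb + 1) if d != 0]
    return [j for j in range(max(0, i - nb), min(n - 1, i + nb) + 1) if j != i]


def extract_neighborhoods(
    genomes: Sequence[GenomeTable],
    targets: Iterable[str],
    nb: int,
    no_limit: bool = False,
) -> NeighborhoodResult:
    """Collect the ±nb genome neighborhood of every target gene.

    ``nb`` must lie in [3, 10] unless ``no_limit`` is set (the range the
    interactive services accept; the override exists for experimentation).
    Targets matching no gene in any genome end up in the skip report rather
    than aborting the run.  A target may occur in several genomes (one gene
    per genome at most) and yields one record per occurrence.
    """
    if nb < 1:
        raise ValueError(f"nb must be >= 1, got {nb}")
    if not no_limit and not (NB_RANGE[0] <= nb <= NB_RANGE[1]):
        raise ValueError(
            f"nb={nb} outside the accepted range [{NB_RANGE[0]}, {NB_RANGE[1]}] "
            "(pass no_limit=True to override)"
        )
    target_set = set(targets)
    records: list[NeighborhoodRecord] = []
    seen: set[str] = set()
    for genome in genomes:
        genes = genome.genes
        hits: dict[str, int] = {}
        for i, gene in enumerate(genes):
            acc = gene.sequence_accession
            if acc is None or acc not in target_set:
                continue
            if acc in hits:
                raise IntegrityError(
                    f"genome {genome.genome_id!r}: target {acc!r} matches more than one gene"
                )
            hits[acc] = i
        for acc, i in sorted(hits.items()):
            pfams: set[str] = set()
            for j in _neighbor_indices(i, len(genes), nb, genome.circular):
                pfams.update(genes[j].pfam_ids)
            records.append(
                NeighborhoodRecord(
                    sequence_accession=acc,
                    genome_id=genome.genome_id,
                    neighborhood_pfams=frozenset(pfams),
                )
            )
            seen.add(acc)
    return NeighborhoodResult(records, frozenset(target_set - seen))


def build_gnn(
    assignment: ClusterAssignment,
    records: Iterable[NeighborhoodRecord],
    cooccurrence_limit: float,
) -> GNNDocument:
    """Assemble the hub-and-spoke GNN.

    For cluster c and Pfam p, ``k`` counts the member sequences whose
    neighborhood contains p; members without any neighborhood record stay
    in the denominator but support nothing, and a sequence occurring in
    several genomes contributes the union of its neighborhoods while
    counting once.  An edge is emitted iff ``100·k >= cooccurrence_limit·n_c``
    (evaluated exactly), Pfam-nodes exist only for emitted edges, and every
    cluster of the assignment gets a hub node even if edgeless.
    """
    if not (1 <= cooccurrence_limit <= 100):
        raise ValueError(
            f"cooccurrence_limit must lie in [1, 100], got {cooccurrence_limit}"
        )
    if isinstance(records, NeighborhoodResult):
        records = records.records
    acc_to_cluster = assignment.accession_to_cluster()
    # union of neighborhoods per accession (multi-genome occurrences merge)
    per_acc: dict[str, set[str]] = {}
    for rec in records:
        if rec.sequence_accession not in acc_to_cluster:
            continue
        per_acc.setdefault(rec.sequence_accession, set()).update(rec.neighborhood_pfams)

    gnn = GNNDocument()
    counts: dict[int, dict[str, int]] = {}
    for acc, pfams in per_acc.items():
        cid = acc_to_cluster[acc]
        bucket = counts.setdefault(cid, {})
        for p in pfams:
            bucket[p] = bucket.get(p, 0) + 1

    for cid in sorted(assignment.clusters):
        cluster = assignment.clusters[cid]
        gnn.add_cluster_node(GNNClusterNode(cluster_id=cid, seq_count=cluster.seq_count))
    for cid in sorted(counts):
        n_c = assignment.clusters[cid].seq_count
        for pfam, k in sorted(counts[cid].items()):
            if 100 * k >= cooccurrence_limit * n_c:
                if pfam not in gnn.pfam_nodes:
                    gnn.add_pfam_node(GNNPfamNode(pfam_id=pfam))
                gnn.add_edge(
                    ClusterPfamEdge(
                        cluster_id=cid,
                        pfam_id=pfam,
                        supporting_count=k,
                        coverage=k / n_c,
                    )
                )
    return gnn
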