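"""Domain types shared across the toolkit.

The central containers are :class:`SSNDocument` (a weighted sequence
similarity network whose nodes may be representative nodes carrying several
accessions), :class:`ClusterAssignment` (the partition of an SSN into
numbered sequence clusters) and :class:`GNNDocument` (the bipartite genome
neighborhood network linking sequence clusters to Pfam domains found in
their genomic context).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "FormatError",
    "IntegrityError",
    "SequenceNode",
    "SSNDocument",
    "TaxonRecord",
    "TaxonomyTable",
    "PfamWhitelist",
    "PfamAnnotation",
    "PfamAnnotationTable",
    "Gene",
    "GenomeTable",
    "NeighborhoodRecord",
    "Cluster",
    "ClusterAssignment",
    "GNNClusterNode",
    "GNNPfamNode",
    "ClusterPfamEdge",
    "GNNDocument",
    "PFAM_ACCESSION_RE",
    "UNKNOWN_TAXID",
]

#: NCBI taxid used for sequences with no taxonomic annotation.  Every
#: taxonomy-dependent operation treats it as "unknown": it is never counted
#: in phylum statistics and never flagged as a subspecies.
UNKNOWN_TAXID = 0

#: A single Pfam accession.  Composite identifiers such as "PF04055-PF13394"
#: (fused domains reported as one neighborhood entry) are treated as opaque
#: node identifiers whose dash-separated components each match this pattern.
PFAM_ACCESSION_RE = re.compile(r"^PF\d{5}$")


class FormatError(ValueError):
    """Malformed input file (bad XML, wrong column count, bad taxid...)."""


class IntegrityError(ValueError):
    """Mutually inconsistent documents (e.g. edge counts exceeding cluster sizes)."""


# ---------------------------------------------------------------------------
# SSN


@dataclass
class SequenceNode:
    """A node of an SSN.

    A plain node represents a single sequence (``seq_count == 1``); a
    rep-node represents every accession collapsed into it.  ``taxids`` is
    aligned index-by-index with ``accessions``.
    """

    id: str
    accessions: list[str]
    taxids: list[int]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise IntegrityError(f"node {self.id!r}: empty accession list")
        if len(self.taxids) != len(self.accessions):
            raise IntegrityError(
                f"node {self.id!r}: {len(self.accessions)} accessions but "
                f"{len(self.taxids)} taxids"
            )

    @classmethod
    def simple(cls, node_id: str) -> "SequenceNode":
        """A node with no metadata: one accession equal to its id, unknown taxid."""
        return cls(id=node_id, accessions=[node_id], taxids=[UNKNOWN_TAXID])

    @property
    def seq_count(self) -> int:
        return len(self.accessions)

    def copy(self) -> "SequenceNode":
        return SequenceNode(self.id, list(self.accessions), list(self.taxids))


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class SSNDocument:
    """A sequence similarity network.

    Nodes are :class:`SequenceNode`; undirected edges carry a non-negative
    similarity score.  At most one edge exists per unordered node pair and
    self-edges are rejected.
    """

    def __init__(self, metadata: Optional[Mapping[str, str]] = None) -> None:
        self.nodes: dict[str, SequenceNode] = {}
        self._edges: dict[tuple[str, str], float] = {}
        self.metadata: dict[str, str] = dict(metadata or {})

    # -- construction -------------------------------------------------------

    def add_node(self, node: SequenceNode | str) -> SequenceNode:
        if isinstance(node, str):
            node = SequenceNode.simple(node)
        self.nodes[node.id] = node
        return node

    def add_edge(self, u: str, v: str, score: float) -> None:
        """Add an undirected edge, creating missing endpoints.

        Duplicate edges for the same unordered pair are collapsed keeping
        the maximum score.  Self-edges are silently dropped (BLAST-derived
        SSNs routinely contain them and they carry no clustering signal).
        """
        if u == v:
            return
        if score < 0:
            raise ValueError(f"edge ({u!r}, {v!r}): negative score {score}")
        for n in (u, v):
            if n not in self.nodes:
                self.add_node(n)
        key = _edge_key(u, v)
        prev = self._edges.get(key)
        if prev is None or score > prev:
            self._edges[key] = float(score)

    # -- access -------------------------------------------------------------

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        """Mapping of sorted ``(u, v)`` pairs to scores."""
        return self._edges

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [(u, v, s) for (u, v), s in sorted(self._edges.items())]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def scores(self) -> list[float]:
        return list(self._edges.values())

    def remove_node(self, node_id: str) -> None:
        self.nodes.pop(node_id, None)
        self._edges = {k: s for k, s in self._edges.items() if node_id not in k}

    def copy(self) -> "SSNDocument":
        doc = SSNDocument(self.metadata)
        for node in self.nodes.values():
            doc.add_node(node.copy())
        doc._edges = dict(self._edges)
        return doc

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SSNDocument):
            return NotImplemented
        return (
            {k: (n.accessions, n.taxids) for k, n in self.nodes.items()}
            == {k: (n.accessions, n.taxids) for k, n in other.nodes.items()}
            and self._edges == other._edges
            and self.metadata == other.metadata
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<SSNDocument nodes={self.n_nodes} edges={self.n_edges}>"


# ---------------------------------------------------------------------------
# Side tables


@dataclass(frozen=True)
class TaxonRecord:
    species_anchor_taxid: int
    phylum: str

    @property
    def is_subspecies(self) -> bool:
        # applies only when compared against the taxid that owns the record;
        # TaxonomyTable.is_subspecies performs that comparison.
        raise AttributeError("use TaxonomyTable.is_subspecies(taxid)")


class TaxonomyTable:
    """taxid -> (species anchor taxid, phylum).

    A species-level taxid anchors to itself; a subspecies taxid anchors to
    its parent species.  Taxids absent from the table (and the reserved
    unknown taxid 0) are treated as unknown everywhere.
    """

    def __init__(self, rows: Mapping[int, tuple[int, str]] | None = None) -> None:
        self._rows: dict[int, tuple[int, str]] = {
            int(t): (int(a), str(p)) for t, (a, p) in (rows or {}).items()
        }

    def add(self, taxid: int, species_anchor_taxid: int, phylum: str) -> None:
        self._rows[int(taxid)] = (int(species_anchor_taxid), str(phylum))

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def anchor(self, taxid: int) -> Optional[int]:
        row = self._rows.get(taxid)
        return None if row is None else row[0]

    def phylum(self, taxid: int) -> Optional[str]:
        row = self._rows.get(taxid)
        return None if row is None else row[1]

    def is_subspecies(self, taxid: int) -> bool:
        """True iff the taxid is covered and anchors to a different species taxid."""
        row = self._rows.get(taxid)
        return row is not None and row[0] != taxid

    def items(self) -> Iterator[tuple[int, tuple[int, str]]]:
        return iter(sorted(self._rows.items()))


class PfamWhitelist:
    """Set of Pfam accessions regarded as enzymatic; set semantics."""

    def __init__(self, ids: Iterable[str] = ()) -> None:
        self.ids: frozenset[str] = frozenset(ids)
        bad = sorted(i for i in self.ids if not PFAM_ACCESSION_RE.match(i))
        if bad:
            raise FormatError(f"invalid Pfam accession(s) in whitelist: {', '.join(bad)}")

    def __contains__(self, pfam_id: str) -> bool:
        return pfam_id in self.ids

    def __len__(self) -> int:
        return len(self.ids)

    def admits(self, node_id: str) -> bool:
        """Whitelist test for a Pfam-node id.

        Composite ids ("PF04055-PF13394") pass if any dash-separated
        component passes.
        """
        return any(part in self.ids for part in node_id.split("-"))


@dataclass(frozen=True)
class PfamAnnotation:
    description: str
    go_terms: tuple[str, ...] = ()


class PfamAnnotationTable:
    """pfam_id -> free-text description and GO term list."""

    def __init__(self, rows: Mapping[str, PfamAnnotation] | None = None) -> None:
        self._rows: dict[str, PfamAnnotation] = dict(rows or {})

    def add(self, pfam_id: str, description: str, go_terms: Sequence[str] = ()) -> None:
        self._rows[pfam_id] = PfamAnnotation(description, tuple(go_terms))

    def get(self, pfam_id: str) -> Optional[PfamAnnotation]:
        return self._rows.get(pfam_id)

    def __contains__(self, pfam_id: str) -> bool:
        return pfam_id in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def items(self) -> Iterator[tuple[str, PfamAnnotation]]:
        return iter(sorted(self._rows.items()))


# ---------------------------------------------------------------------------
# Genomes and neighborhoods


@dataclass(frozen=True)
class Gene:
    gene_id: str
    strand: str  # "+" or "-"
    pfam_ids: tuple[str, ...]
    sequence_accession: Optional[str] = None


@dataclass
class GenomeTable:
    """An annotated genome: an ordered gene list, optionally circular."""

    genome_id: str
    circular: bool
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"genome {self.genome_id!r}: duplicate gene ids")


@dataclass(frozen=True)
class NeighborhoodRecord:
    """The genome neighborhood (GN) of one query gene: the set of Pfam ids
    found on the ±nb flanking genes, the query gene itself excluded."""

    sequence_accession: str
    genome_id: str
    neighborhood_pfams: frozenset[str]


# ---------------------------------------------------------------------------
# Clusters


@dataclass
class Cluster:
    """One sequence cluster: a connected component of the thresholded SSN."""

    id: int
    members: list[str]  # node ids, sorted
    accessions: list[str]  # expanded over rep-nodes, sorted
    accession_taxids: dict[str, int] = field(default_factory=dict)

    @property
    def seq_count(self) -> int:
        return len(self.accessions)


class ClusterAssignment:
    """node-id -> cluster-id map plus per-cluster membership and SeqCount."""

    def __init__(self, clusters: Iterable[Cluster] = ()) -> None:
        self.clusters: dict[int, Cluster] = {c.id: c for c in clusters}
        self.node_to_cluster: dict[str, int] = {}
        for c in self.clusters.values():
            for m in c.members:
                self.node_to_cluster[m] = c.id

    def accession_to_cluster(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.clusters.values():
            for acc in c.accessions:
                if acc in out and out[acc] != c.id:
                    raise IntegrityError(
                        f"accession {acc!r} appears in clusters {out[acc]} and {c.id}"
                    )
                out[acc] = c.id
        return out

    @property
    def total_seq_count(self) -> int:
        return sum(c.seq_count for c in self.clusters.values())

    def __len__(self) -> int:
        return len(self.clusters)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ClusterAssignment clusters={len(self.clusters)} seqs={self.total_seq_count}>"


# ---------------------------------------------------------------------------
# GNN


@dataclass
class GNNClusterNode:
    cluster_id: int
    seq_count: int
    uniqueness: Optional[float] = None
    phylum_stat: Optional[dict[str, float]] = None


@dataclass
class GNNPfamNode:
    pfam_id: str
    description: Optional[str] = None
    go_terms: tuple[str, ...] = ()
    uniqueness: Optional[float] = None


@dataclass
class ClusterPfamEdge:
    cluster_id: int
    pfam_id: str
    supporting_count: int  # k: member sequences whose GN contains the Pfam
    coverage: float  # k / cluster seq_count
    uniqueness: Optional[float] = None


class GNNDocument:
    """Bipartite genome neighborhood network.

    Hub nodes are sequence clusters, spoke nodes are Pfam domains; an edge
    records how many of the cluster's sequences carry the Pfam in their
    genome neighborhood (``supporting_count``) and the corresponding
    fraction (``coverage``).
    """

    def __init__(self) -> None:
        self.cluster_nodes: dict[int, GNNClusterNode] = {}
        self.pfam_nodes: dict[str, GNNPfamNode] = {}
        self.edges: dict[tuple[int, str], ClusterPfamEdge] = {}

    def add_cluster_node(self, node: GNNClusterNode) -> None:
        self.cluster_nodes[node.cluster_id] = node

    def add_pfam_node(self, node: GNNPfamNode) -> None:
        self.pfam_nodes[node.pfam_id] = node

    def add_edge(self, edge: ClusterPfamEdge) -> None:
        if edge.cluster_id not in self.cluster_nodes:
            raise IntegrityError(f"edge references unknown cluster {edge.cluster_id}")
        if edge.pfam_id not in self.pfam_nodes:
            raise IntegrityError(f"edge references unknown Pfam node {edge.pfam_id!r}")
        if not (0 < edge.coverage <= 1 + 1e-12):
            raise IntegrityError(
                f"edge ({edge.cluster_id}, {edge.pfam_id}): coverage {edge.coverage} outside (0, 1]"
            )
        self.edges[(edge.cluster_id, edge.pfam_id)] = edge

    def edges_of_cluster(self, cluster_id: int) -> list[ClusterPfamEdge]:
        return [e for e in self.edges.values() if e.cluster_id == cluster_id]

    def edges_of_pfam(self, pfam_id: str) -> list[ClusterPfamEdge]:
        return [e for e in self.edges.values() if e.pfam_id == pfam_id]

    def copy(self) -> "GNNDocument":
        doc = GNNDocument()
        for c in self.cluster_nodes.values():
            doc.add_cluster_node(replace(c, phylum_stat=dict(c.phylum_stat) if c.phylum_stat else None))
        for p in self.pfam_nodes.values():
            doc.add_pfam_node(replace(p))
        for e in self.edges.values():
            doc.add_edge(replace(e))
        return doc

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GNNDocument):
            return NotImplemented
        return (
            self.cluster_nodes == other.cluster_nodes
            and self.pfam_nodes == other.pfam_nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<GNNDocument clusters={len(self.cluster_nodes)} "
            f"pfams={len(self.pfam_nodes)} edges={len(self.edges)}>"
        )
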