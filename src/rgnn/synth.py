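"""Synthetic families with known ground truth.

The generator emits the full input bundle of the pipeline — an SSN, one
annotated genome per sequence, a taxonomy table — together with the ground
truth that produced it, so every stage can be validated end to end without
external data.

Planted structure:

* **clusters** — block-structured SSN: every intra-cluster pair is an edge
  with a score drawn uniformly from ``intra_score_range``; inter-cluster
  pairs become edges with probability ``inter_edge_prob``, scored from the
  disjoint, lower ``inter_score_range``.  Any threshold between the two
  supports separates the blocks exactly.
* **operons** — each cluster owns a set of marker Pfams planted on the
  genes flanking the target gene (within ``nb_span``), each included
  independently per sequence with its inclusion probability, so realized
  edge coverages are binomial around that probability.
* **background** — every other gene carries, with ``background_rate``, one
  Pfam drawn from a shared pool; pool Pfams are frequent overall but rare
  per neighborhood, so they fall below any reasonable co-occurrence limit.
* **taxonomy** — each sequence gets its own species-level taxid with a
  phylum drawn from per-cluster weights; ``subspecies_rate`` duplicates a
  sequence (same genome content, same edges) under a subspecies taxid, the
  worst case of phylogenetic bias and the case the subspecies filter must
  undo completely.

Scores are drawn uniformly: the threshold heuristics only use the ordering
of scores, so no attempt is made to imitate the score distribution of real
all-vs-all comparisons.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    Gene,
    GenomeTable,
    SSNDocument,
    SequenceNode,
    TaxonomyTable,
)

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticDataset", "generate"]

_DEFAULT_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Actinobacteria",
    "Bacteroidetes",
    "Cyanobacteria",
)

#: Pfam id carried by every target gene (the enzyme family under study).
FAMILY_PFAM = "PF00001"


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic family."""

    n_clusters: int = 2
    sequences_per_cluster: int = 200
    intra_score_range: tuple[float, float] = (90.0, 100.0)
    inter_score_range: tuple[float, float] = (20.0, 40.0)
    inter_edge_prob: float = 0.02
    #: per-cluster operon as (pfam_id, inclusion probability); None builds
    #: ``operon_size`` markers per cluster at ``operon_inclusion`` each.
    operons: Optional[list[list[tuple[str, float]]]] = None
    operon_size: int = 3
    operon_inclusion: float = 0.6
    background_pool: int = 100
    background_rate: float = 0.1
    genome_length: int = 21
    nb_span: int = 3
    #: per-cluster phylum weight maps; None assigns each cluster a dominant
    #: phylum (0.75) plus the next one in the roster (0.25).
    phyla: Optional[list[dict[str, float]]] = None
    subspecies_rate: float = 0.0
    paralog_pairs: int = 0  # genomes carrying two target genes each
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1 or self.sequences_per_cluster < 1:
            raise ValueError("need at least one cluster and one sequence per cluster")
        ilo, ihi = self.intra_score_range
        jlo, jhi = self.inter_score_range
        if not (jlo <= jhi < ilo <= ihi):
            raise ValueError(
                "score ranges must be disjoint with intra above inter, got "
                f"intra={self.intra_score_range}, inter={self.inter_score_range}"
            )
        for name, p in (
            ("inter_edge_prob", self.inter_edge_prob),
            ("operon_inclusion", self.operon_inclusion),
            ("background_rate", self.background_rate),
            ("subspecies_rate", self.subspecies_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.genome_length <= 2 * self.nb_span:
            raise ValueError(
                f"genome_length ({self.genome_length}) must exceed twice "
                f"nb_span ({self.nb_span})"
            )
        if self.operons is not None and len(self.operons) != self.n_clusters:
            raise ValueError("operons must list one operon per cluster")
        if self.operons is None and self.operon_size > 2 * self.nb_span:
            raise ValueError("operon_size exceeds the available flanking positions")


@dataclass
class GroundTruth:
    """What was planted: the key for every downstream assertion."""

    cluster_of: dict[str, int]  # accession -> planted cluster (1-based)
    operons: dict[int, list[tuple[str, float]]]
    species_taxid: dict[str, int]  # accession -> taxid carried in the SSN
    subspecies_accessions: frozenset[str]
    background_pfams: frozenset[str]

    def partition_labels(self, accessions: Sequence[str]) -> list[int]:
        return [self.cluster_of[a] for a in accessions]


@dataclass
class SyntheticDataset:
    ssn: SSNDocument
    genomes: list[GenomeTable]
    taxonomy: TaxonomyTable
    truth: GroundTruth


def _default_operon(cluster: int, size: int, p: float) -> list[tuple[str, float]]:
    return [(f"PF{90000 + (cluster - 1) * 100 + j:05d}", p) for j in range(size)]


def _operon_offsets(size: int) -> list[int]:
    # alternate right/left of the target: +1, -1, +2, -2, ...
    out = []
    for j in range(size):
        d = j // 2 + 1
        out.append(d if j % 2 == 0 else -d)
    return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the dataset described by ``spec``; reproducible from its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    phyla_roster = _DEFAULT_PHYLA

    operons = {
        c: (
            list(spec.operons[c - 1])
            if spec.operons is not None
            else _default_operon(c, spec.operon_size, spec.operon_inclusion)
        )
        for c in range(1, spec.n_clusters + 1)
    }
    background = [f"PF{10000 + i:05d}" for i in range(spec.background_pool)]

    ssn = SSNDocument(metadata={"generator": "rgnn.synth", "seed": str(spec.seed)})
    genomes: list[GenomeTable] = []
    cluster_of: dict[str, int] = {}
    species_taxid: dict[str, int] = {}
    subspecies_accs: set[str] = set()
    members: dict[int, list[str]] = {c: [] for c in operons}

    target_idx = spec.genome_length // 2
    offsets = {c: _operon_offsets(len(ops)) for c, ops in operons.items()}
    seq_no = 0

    def make_genome(acc: str, cluster: int, realized: Sequence[bool], bg_draw) -> GenomeTable:
        genes: list[Gene] = []
        slot_pfams = {
            target_idx + off: pfam
            for (pfam, _p), off, inc in zip(operons[cluster], offsets[cluster], realized)
            if inc
        }
        for i in range(spec.genome_length):
            strand = "+" if bg_draw() < 0.5 else "-"
            if i == target_idx:
                genes.append(Gene(f"{acc}_g{i:03d}", strand, (FAMILY_PFAM,), acc))
            elif i in slot_pfams:
                genes.append(Gene(f"{acc}_g{i:03d}", strand, (slot_pfams[i],)))
            else:
                pfams = ()
                if bg_draw() < spec.background_rate:
                    pfams = (background[int(bg_draw() * len(background))],)
                genes.append(Gene(f"{acc}_g{i:03d}", strand, pfams))
        return GenomeTable(genome_id=f"G_{acc}", circular=False, genes=genes)

    taxonomy = TaxonomyTable()
    for c in range(1, spec.n_clusters + 1):
        if spec.phyla is not None:
            weights = spec.phyla[c - 1]
        else:
            a = phyla_roster[(c - 1) % len(phyla_roster)]
            b = phyla_roster[c % len(phyla_roster)]
            weights = {a: 0.75, b: 0.25}
        phylum_names = sorted(weights)
        phylum_p = np.array([weights[p] for p in phylum_names], dtype=float)
        phylum_p = phylum_p / phylum_p.sum()
        for i in range(spec.sequences_per_cluster):
            seq_no += 1
            acc = f"c{c}s{i:03d}"
            taxid = 100000 + seq_no
            phylum = phylum_names[int(rng.choice(len(phylum_names), p=phylum_p))]
            taxonomy.add(taxid, taxid, phylum)
            realized = [rng.random() < p for (_pf, p) in operons[c]]
            genome = make_genome(acc, c, realized, rng.random)
            genomes.append(genome)
            ssn.add_node(SequenceNode(acc, [acc], [taxid]))
            cluster_of[acc] = c
            species_taxid[acc] = taxid
            members[c].append(acc)
            if rng.random() < spec.subspecies_rate:
                sub_acc = f"{acc}sub"
                sub_taxid = 900000 + seq_no
                taxonomy.add(sub_taxid, taxid, phylum)
                sub_genes = [
                    Gene(
                        g.gene_id.replace(acc, sub_acc, 1),
                        g.strand,
                        g.pfam_ids,
                        sub_acc if g.sequence_accession == acc else None,
                    )
                    for g in genome.genes
                ]
                genomes.append(GenomeTable(f"G_{sub_acc}", False, sub_genes))
                ssn.add_node(SequenceNode(sub_acc, [sub_acc], [sub_taxid]))
                cluster_of[sub_acc] = c
                species_taxid[sub_acc] = sub_taxid
                subspecies_accs.add(sub_acc)
                members[c].append(sub_acc)

    # paralog genomes: two target genes of the same cluster share one genome,
    # exercising the composite-neighborhood caveat of multi-copy families
    for j in range(spec.paralog_pairs):
        c = (j % spec.n_clusters) + 1
        pool = members[c]
        a1, a2 = pool[(2 * j) % len(pool)], pool[(2 * j + 1) % len(pool)]
        if a1 == a2:
            continue
        realized = [rng.random() < p for (_pf, p) in operons[c]]
        base = make_genome(f"p{j:03d}x", c, realized, rng.random)
        genes = list(base.genes)
        genes[target_idx] = Gene(genes[target_idx].gene_id, "+", (FAMILY_PFAM,), a1)
        far = spec.genome_length - 1
        genes[far] = Gene(genes[far].gene_id, "+", (FAMILY_PFAM,), a2)
        genomes.append(GenomeTable(f"G_paralog{j:03d}", False, genes))

    # SSN edges: complete within clusters, sparse across
    intra_lo, intra_hi = spec.intra_score_range
    inter_lo, inter_hi = spec.inter_score_range
    for c, accs in members.items():
        for i in range(len(accs)):
            for j in range(i + 1, len(accs)):
                ssn.add_edge(accs[i], accs[j], float(rng.uniform(intra_lo, intra_hi)))
    cluster_ids = sorted(members)
    for ci in range(len(cluster_ids)):
        for cj in range(ci + 1, len(cluster_ids)):
            a_list, b_list = members[cluster_ids[ci]], members[cluster_ids[cj]]
            mask = rng.random((len(a_list), len(b_list))) < spec.inter_edge_prob
            scores = rng.uniform(inter_lo, inter_hi, size=mask.shape)
            for ia, ib in zip(*np.nonzero(mask)):
                ssn.add_edge(a_list[ia], b_list[ib], float(scores[ia, ib]))

    truth = GroundTruth(
        cluster_of=cluster_of,
        operons=operons,
        species_taxid=species_taxid,
        subspecies_accessions=frozenset(subspecies_accs),
        background_pfams=frozenset(background),
    )
    return SyntheticDataset(ssn=ssn, genomes=genomes, taxonomy=taxonomy, truth=truth)
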