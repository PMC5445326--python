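"""Readers and writers for the tab-separated side tables.

All files are UTF-8 text; blank lines and lines starting with ``#`` are
skipped.  Errors carry the offending line number.  Dialects:

* taxonomy — 3 columns: taxid, species_anchor_taxid, phylum
* whitelist — one Pfam accession per line
* pfam_annotation — 2–3 columns: pfam_id, description, semicolon-joined GO ids
* neighborhood — 3 columns: sequence_accession, genome_id, semicolon-joined
  Pfam ids (empty third column = empty neighborhood)
* genomes — 6–7 columns: genome_id, circular(0/1), gene_index, gene_id,
  strand, semicolon-joined pfam_ids, optional sequence_accession
"""

from __future__ import annotations

from typing import Iterable, Iterator

from .model import (
    Cluster,
    ClusterAssignment,
    FormatError,
    Gene,
    GenomeTable,
    NeighborhoodRecord,
    PfamAnnotationTable,
    PfamWhitelist,
    TaxonomyTable,
)

__all__ = [
    "read_table",
    "read_genome_tables",
    "write_neighborhood_table",
    "write_cluster_table",
    "write_profile_table",
    "write_edge_table",
    "taxonomy_from_categories",
]

_KINDS = ("taxonomy", "whitelist", "pfam_annotation", "neighborhood")


def _data_lines(path, header: bool) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        first_data = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header and first_data:
                first_data = False
                continue
            first_data = False
            yield lineno, line


def _split(path, lineno: int, line: str, n_min: int, n_max: int) -> list[str]:
    fields = line.split("\t")
    if not (n_min <= len(fields) <= n_max):
        want = str(n_min) if n_min == n_max else f"{n_min}-{n_max}"
        raise FormatError(
            f"{path}:{lineno}: expected {want} tab-separated columns, got {len(fields)}"
        )
    return fields


def _int(path, lineno: int, text: str, what: str) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer {what} {text!r}") from exc


def read_table(path, kind: str, header: bool = False):
    """Read a side table; ``kind`` selects the dialect (see module docstring)."""
    if kind not in _KINDS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {_KINDS}")
    if kind == "whitelist":
        ids = set()
        for lineno, line in _data_lines(path, header):
            ids.add(line.strip())
        return PfamWhitelist(ids)
    if kind == "taxonomy":
        table = TaxonomyTable()
        for lineno, line in _data_lines(path, header):
            taxid_s, anchor_s, phylum = _split(path, lineno, line, 3, 3)
            table.add(
                _int(path, lineno, taxid_s, "taxid"),
                _int(path, lineno, anchor_s, "species anchor taxid"),
                phylum.strip(),
            )
        return table
    if kind == "pfam_annotation":
        table = PfamAnnotationTable()
        for lineno, line in _data_lines(path, header):
            fields = _split(path, lineno, line, 2, 3)
            go = tuple(t for t in fields[2].split(";") if t) if len(fields) == 3 else ()
            table.add(fields[0].strip(), fields[1].strip(), go)
        return table
    # neighborhood
    records = []
    for lineno, line in _data_lines(path, header):
        acc, genome_id, pfams = _split(path, lineno, line, 3, 3)
        records.append(
            NeighborhoodRecord(
                sequence_accession=acc.strip(),
                genome_id=genome_id.strip(),
                neighborhood_pfams=frozenset(p for p in pfams.split(";") if p),
            )
        )
    return records


def read_genome_tables(path, header: bool = False) -> list[GenomeTable]:
    """Read annotated genomes from a single TSV, grouped by genome id and
    ordered by gene index within each genome."""
    rows: dict[str, list[tuple[int, Gene, bool]]] = {}
    circular_flags: dict[str, bool] = {}
    for lineno, line in _data_lines(path, header):
        fields = _split(path, lineno, line, 6, 7)
        genome_id = fields[0].strip()
        circ_s = fields[1].strip()
        if circ_s not in ("0", "1"):
            raise FormatError(f"{path}:{lineno}: circular flag must be 0 or 1, got {circ_s!r}")
        index = _int(path, lineno, fields[2], "gene index")
        strand = fields[4].strip()
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
        gene = Gene(
            gene_id=fields[3].strip(),
            strand=strand,
            pfam_ids=tuple(p for p in fields[5].split(";") if p),
            sequence_accession=fields[6].strip() or None if len(fields) == 7 else None,
        )
        prev = circular_flags.setdefault(genome_id, circ_s == "1")
        if prev != (circ_s == "1"):
            raise FormatError(f"{path}:{lineno}: inconsistent circular flag for {genome_id!r}")
        rows.setdefault(genome_id, []).append((index, gene, circ_s == "1"))
    genomes = []
    for genome_id in sorted(rows):
        ordered = sorted(rows[genome_id], key=lambda t: t[0])
        genomes.append(
            GenomeTable(
                genome_id=genome_id,
                circular=circular_flags[genome_id],
                genes=[g for _, g, _ in ordered],
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# Writers (deterministic row order)


def write_neighborhood_table(records: Iterable[NeighborhoodRecord], path) -> None:
    rows = sorted(
        (r.sequence_accession, r.genome_id, ";".join(sorted(r.neighborhood_pfams)))
        for r in records
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# sequence_accession\tgenome_id\tpfam_ids\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_cluster_table(assignment: ClusterAssignment, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# node_id\tcluster_id\tseq_count\n")
        for cid in sorted(assignment.clusters):
            cluster = assignment.clusters[cid]
            for node_id in cluster.members:
                fh.write(f"{node_id}\t{cid}\t{cluster.seq_count}\n")


def write_profile_table(profile, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# threshold\tnn\tse\tnsv\trel_nn\trel_se\n")
        for i, th in enumerate(profile.thresholds):
            nsv = "" if profile.nsv[i] is None else repr(profile.nsv[i])
            fh.write(
                f"{th}\t{profile.nn[i]}\t{profile.se[i]}\t{nsv}\t"
                f"{profile.rel_nn[i]!r}\t{profile.rel_se[i]!r}\n"
            )


def write_edge_table(gnn, report, path) -> None:
    """Per-edge statistics: cluster, Pfam, k, M, coverage, uniqueness."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# cluster_id\tpfam_id\tk\tM\tcoverage\tuniqueness\n")
        for (cid, pid) in sorted(gnn.edges):
            edge = gnn.edges[(cid, pid)]
            m = report.pfam_m.get(pid, "") if report is not None else ""
            uniq = "" if edge.uniqueness is None else repr(edge.uniqueness)
            fh.write(f"{cid}\t{pid}\t{edge.supporting_count}\t{m}\t{edge.coverage!r}\t{uniq}\n")


# ---------------------------------------------------------------------------
# NCBI categories.dmp converter


def taxonomy_from_categories(categories_path, phylum_path) -> TaxonomyTable:
    """Build a taxonomy table from the NCBI ``categories.dmp`` dialect.

    ``categories.dmp`` rows are (category letter, species-level taxid,
    taxid); it carries no phylum, so ``phylum_path`` must supply a 2-column
    TSV (taxid, phylum).  Phyla listed for a species-level taxid propagate
    to the taxids anchored to it when those lack their own entry.
    """
    phyla: dict[int, str] = {}
    for lineno, line in _data_lines(phylum_path, header=False):
        taxid_s, phylum = _split(phylum_path, lineno, line, 2, 2)
        phyla[_int(phylum_path, lineno, taxid_s, "taxid")] = phylum.strip()
    table = TaxonomyTable()
    for lineno, line in _data_lines(categories_path, header=False):
        fields = _split(categories_path, lineno, line, 3, 3)
        anchor = _int(categories_path, lineno, fields[1], "species taxid")
        taxid = _int(categories_path, lineno, fields[2], "taxid")
        phylum = phyla.get(taxid, phyla.get(anchor, ""))
        table.add(taxid, anchor, phylum)
    return table
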