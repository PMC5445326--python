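"""End-to-end orchestration: SSN -> thresholded SSN -> clusters -> rGNN.

``run_pipeline`` executes the stages in a fixed order — threshold profile,
threshold selection, edge filtering, optional subspecies elimination,
clustering, optional per-species deduplication, neighborhood derivation or
import, GNN assembly, whitelist filtering, annotation, uniqueness and
PhylumStat — and writes the results plus a JSON manifest that records every
parameter, the selected threshold, input checksums and the tool version.
Outputs contain no timestamps, so identical configuration and inputs yield
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .gnn import build_gnn, extract_neighborhoods
from .model import ClusterAssignment, SSNDocument
from .refine import (
    annotate_pfam_nodes,
    apply_whitelist,
    build_enzyme_whitelist,
    compute_phylum_stat,
    compute_uniqueness,
    dedup_species_per_cluster,
    eliminate_subspecies,
)
from .tables import (
    read_genome_tables,
    read_table,
    write_cluster_table,
    write_edge_table,
    write_profile_table,
)
from .thresholds import (
    apply_threshold,
    cluster_components,
    compute_a_th,
    compute_s_th,
    compute_threshold_profile,
    filter_clusters,
)
from .xgmml import DEFAULT_SCORE_ATTR, read_ssn_xgmml, write_gnn_xgmml, write_ssn_xgmml

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "CLUSTER_PALETTE"]

log = logging.getLogger("rgnn")

#: 20 visually distinct fill colors, cycled by cluster rank.
CLUSTER_PALETTE = (
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
    "#AEC7E8", "#FFBB78", "#98DF8A", "#FF9896", "#C5B0D5",
    "#C49C94", "#F7B6D2", "#C7C7C7", "#DBDB8D", "#9EDAE5",
)


class PipelineError(RuntimeError):
    """A stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Everything one run needs; serialized verbatim into the manifest."""

    ssn: str
    out_dir: str
    score_attr: str = DEFAULT_SCORE_ATTR
    threshold_mode: str = "s-th"  # "a-th", "s-th" or "fixed:<value>"
    step: int = 1
    nb: int = 10
    no_nb_limit: bool = False
    cooccurrence_limit: float = 20.0
    min_seq_count: int = 0
    subspecies_filter: bool = False
    dedup_species: bool = False
    whitelist: Optional[str] = None  # path, or "builtin-rule" (needs annotations)
    taxonomy: Optional[str] = None
    annotations: Optional[str] = None
    genomes: Optional[str] = None  # genome tables TSV -> neighborhoods derived
    targets: Optional[str] = None  # one accession per line; default: all clustered
    neighborhoods: Optional[str] = None  # precomputed neighborhood TSV
    seed: int = 0

    def validate(self) -> None:
        mode = self.threshold_mode
        if mode not in ("a-th", "s-th") and not mode.startswith("fixed:"):
            raise ValueError(f"threshold_mode must be 'a-th', 's-th' or 'fixed:<value>', got {mode!r}")
        if mode.startswith("fixed:"):
            float(mode.split(":", 1)[1])  # raises if malformed
        if not (1 <= self.cooccurrence_limit <= 100):
            raise ValueError(f"cooccurrence_limit outside [1, 100]: {self.cooccurrence_limit}")
        if not self.no_nb_limit and not (3 <= self.nb <= 10):
            raise ValueError(f"nb outside [3, 10]: {self.nb} (set no_nb_limit to override)")
        if self.genomes is None and self.neighborhoods is None:
            raise ValueError("either genomes or neighborhoods must be supplied")
        if (self.subspecies_filter or self.dedup_species) and self.taxonomy is None:
            raise ValueError("subspecies_filter/dedup_species require a taxonomy table")
        if self.whitelist == "builtin-rule" and self.annotations is None:
            raise ValueError("whitelist 'builtin-rule' requires an annotation table")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def cluster_colors(assignment: ClusterAssignment) -> dict[str, str]:
    """Node-id -> fill color, cycling the palette by cluster rank."""
    colors: dict[str, str] = {}
    for rank, cid in enumerate(sorted(assignment.clusters)):
        color = CLUSTER_PALETTE[rank % len(CLUSTER_PALETTE)]
        for node_id in assignment.clusters[cid].members:
            colors[node_id] = color
    return colors


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to the output dir).

    Any stage error aborts with the stage name and removes files already
    written to the output directory.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    try:
        stage = "read-ssn"
        log.info("reading SSN from %s", config.ssn)
        ssn = read_ssn_xgmml(config.ssn, score_attr=config.score_attr)

        stage = "threshold-profile"
        profile = compute_threshold_profile(ssn, step=config.step)
        a_th = compute_a_th(profile)
        s_th = compute_s_th(profile)
        log.info("threshold profile: A-Th=%s S-Th=%s", a_th, s_th)
        write_profile_table(profile, emit("profile.tsv"))

        stage = "threshold-selection"
        if config.threshold_mode == "a-th":
            if a_th is None:
                raise ValueError("A-Th undefined for this SSN (Nsv never rises)")
            th: float = a_th
        elif config.threshold_mode == "s-th":
            if s_th is None:
                raise ValueError("S-Th undefined for this SSN")
            th = s_th
        else:
            th = float(config.threshold_mode.split(":", 1)[1])
        log.info("applying threshold %s (mode %s)", th, config.threshold_mode)

        stage = "edge-filter"
        ssn = apply_threshold(ssn, th)

        unknown_taxids: tuple[int, ...] = ()
        taxonomy = None
        if config.taxonomy is not None:
            taxonomy = read_table(config.taxonomy, "taxonomy")
        if config.subspecies_filter:
            stage = "subspecies-filter"
            result = eliminate_subspecies(ssn, taxonomy)
            ssn, unknown_taxids = result.ssn, result.unknown_taxids
            if unknown_taxids:
                log.warning("taxonomy lacks %d taxid(s)", len(unknown_taxids))

        stage = "cluster"
        assignment = cluster_components(ssn)
        if config.min_seq_count > 0:
            assignment = filter_clusters(assignment, config.min_seq_count)
        log.info("%d cluster(s) after filtering", len(assignment))

        if config.dedup_species:
            stage = "dedup-species"
            assignment, ssn = dedup_species_per_cluster(assignment, ssn, taxonomy)

        stage = "neighborhoods"
        missing_targets: tuple[str, ...] = ()
        if config.neighborhoods is not None:
            records = read_table(config.neighborhoods, "neighborhood")
        else:
            genomes = read_genome_tables(config.genomes)
            if config.targets is not None:
                with open(config.targets, encoding="utf-8") as fh:
                    targets = {t.strip() for t in fh if t.strip() and not t.startswith("#")}
            else:
                targets = {a for c in assignment.clusters.values() for a in c.accessions}
            result = extract_neighborhoods(genomes, targets, config.nb, no_limit=config.no_nb_limit)
            records, missing_targets = result.records, tuple(sorted(result.missing_targets))
            if missing_targets:
                log.warning("%d target(s) matched no gene", len(missing_targets))

        stage = "build-gnn"
        gnn = build_gnn(assignment, records, config.cooccurrence_limit)
        log.info("raw GNN: %d Pfam-node(s), %d edge(s)", len(gnn.pfam_nodes), len(gnn.edges))

        annotations = None
        if config.annotations is not None:
            annotations = read_table(config.annotations, "pfam_annotation")
        if config.whitelist is not None:
            stage = "whitelist"
            if config.whitelist == "builtin-rule":
                whitelist = build_enzyme_whitelist(annotations)
            else:
                whitelist = read_table(config.whitelist, "whitelist")
            gnn = apply_whitelist(gnn, whitelist)
            log.info("after whitelist: %d Pfam-node(s)", len(gnn.pfam_nodes))
        if annotations is not None:
            stage = "annotate"
            annotate_pfam_nodes(gnn, annotations)

        stage = "uniqueness"
        report = compute_uniqueness(gnn, assignment)
        if taxonomy is not None:
            stats = compute_phylum_stat(assignment, ssn, taxonomy)
            for cid, node in gnn.cluster_nodes.items():
                node.phylum_stat = stats.get(cid, {})

        stage = "write"
        write_gnn_xgmml(gnn, emit("rgnn.xgmml"))
        write_ssn_xgmml(ssn, emit("colored_ssn.xgmml"), node_colors=cluster_colors(assignment))
        write_cluster_table(assignment, emit("clusters.tsv"))
        write_edge_table(gnn, report, emit("edges.tsv"))

        stage = "manifest"
        checksums = {
            key: _sha256(path)
            for key, path in (
                ("ssn", config.ssn),
                ("taxonomy", config.taxonomy),
                ("annotations", config.annotations),
                ("genomes", config.genomes),
                ("targets", config.targets),
                ("neighborhoods", config.neighborhoods),
                ("whitelist", None if config.whitelist == "builtin-rule" else config.whitelist),
            )
            if path is not None
        }
        manifest = {
            "tool": "rgnn",
            "version": __version__,
            "config": asdict(config),
            "a_th": a_th,
            "s_th": s_th,
            "applied_threshold": th,
            "input_checksums": checksums,
            "skip_report": {
                "unknown_taxids": list(unknown_taxids),
                "missing_targets": list(missing_targets),
            },
            "counts": {
                "ssn_nodes": ssn.n_nodes,
                "ssn_edges": ssn.n_edges,
                "clusters": len(assignment),
                "total_sequences": assignment.total_seq_count,
                "gnn_pfam_nodes": len(gnn.pfam_nodes),
                "gnn_edges": len(gnn.edges),
            },
        }
        path = emit("manifest.json")
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
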