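"""XGMML reading and writing (Cytoscape dialect).

Writers emit a deterministic, namespace-free XGMML document: graph-level
attributes sorted by key, then nodes sorted by id, then edges sorted by
endpoint pair.  Identical documents therefore serialize to byte-identical
files, and ``read(write(doc)) == doc`` holds exactly (scores and coverages
are written with full ``repr`` precision).

The SSN reader accepts a configurable edge-score attribute name because the
attribute schema of externally produced SSNs varies; the default is
``alignment_score``.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Mapping, Optional

from .model import (
    ClusterPfamEdge,
    FormatError,
    GNNClusterNode,
    GNNDocument,
    GNNPfamNode,
    SSNDocument,
    SequenceNode,
    UNKNOWN_TAXID,
)

__all__ = [
    "DEFAULT_SCORE_ATTR",
    "read_ssn_xgmml",
    "write_ssn_xgmml",
    "read_gnn_xgmml",
    "write_gnn_xgmml",
]

DEFAULT_SCORE_ATTR = "alignment_score"

_LIST_SEP = ";"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _att(parent: ET.Element, name: str, value: str, type_: str) -> None:
    ET.SubElement(parent, "att", {"name": name, "value": value, "type": type_})

def _atts_of(elem: ET.Element) -> dict[str, str]:
    out = {}
    for child in elem:
        if _localname(child.tag) == "att" and "name" in child.attrib:
            out[child.attrib["name"]] = child.attrib.get("value", "")
    return out


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _parse(path) -> ET.Element:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise FormatError(f"{path}: malformed XML at line {line}, column {col}") from exc
    root = tree.getroot()
    if _localname(root.tag) != "graph":
        raise FormatError(f"{path}: root element is {root.tag!r}, expected 'graph'")
    return root


# ---------------------------------------------------------------------------
# SSN


def write_ssn_xgmml(
    ssn: SSNDocument,
    path,
    node_colors: Optional[Mapping[str, str]] = None,
) -> None:
    """Write an SSN as Cytoscape-loadable XGMML.

    ``node_colors`` maps node ids to fill colors (e.g. cluster colors for a
    colored SSN); nodes absent from the map get no color attribute.
    """
    root = ET.Element("graph", {"label": "SSN", "directed": "0"})
    for key in sorted(ssn.metadata):
        _att(root, key, ssn.metadata[key], "string")
    for node_id in sorted(ssn.nodes):
        node = ssn.nodes[node_id]
        el = ET.SubElement(root, "node", {"id": node.id, "label": node.id})
        _att(el, "accessions", _LIST_SEP.join(node.accessions), "string")
        _att(el, "taxids", _LIST_SEP.join(str(t) for t in node.taxids), "string")
        _att(el, "seq_count", str(node.seq_count), "integer")
        if node_colors and node.id in node_colors:
            _att(el, "node.fillColor", node_colors[node.id], "string")
    for (u, v), score in sorted(ssn.edges.items()):
        el = ET.SubElement(root, "edge", {"id": f"{u}|{v}", "source": u, "target": v})
        _att(el, DEFAULT_SCORE_ATTR, _fmt_float(score), "real")
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def read_ssn_xgmml(path, score_attr: str = DEFAULT_SCORE_ATTR) -> SSNDocument:
    """Read an SSN from XGMML.

    Node attributes absent from the file default to ``accessions = [id]``
    and ``taxids = [0]`` (unknown).  Duplicate undirected edges are
    collapsed keeping the maximum score; self-edges are dropped.
    """
    root = _parse(path)
    ssn = SSNDocument()
    for child in root:
        if _localname(child.tag) == "att" and "name" in child.attrib:
            ssn.metadata[child.attrib["name"]] = child.attrib.get("value", "")
    for child in root:
        if _localname(child.tag) != "node":
            continue
        node_id = child.attrib.get("id") or child.attrib.get("label")
        if node_id is None:
            raise FormatError(f"{path}: node element without id or label")
        atts = _atts_of(child)
        accessions = (
            atts["accessions"].split(_LIST_SEP) if atts.get("accessions") else [node_id]
        )
        if atts.get("taxids"):
            try:
                taxids = [int(t) for t in atts["taxids"].split(_LIST_SEP)]
            except ValueError as exc:
                raise FormatError(f"{path}: node {node_id!r}: non-integer taxid") from exc
        else:
            taxids = [UNKNOWN_TAXID] * len(accessions)
        ssn.add_node(SequenceNode(node_id, accessions, taxids))
    for child in root:
        if _localname(child.tag) != "edge":
            continue
        u = child.attrib.get("source")
        v = child.attrib.get("target")
        if u is None or v is None:
            raise FormatError(f"{path}: edge element without source/target")
        atts = _atts_of(child)
        if score_attr not in atts:
            raise FormatError(
                f"{path}: edge ({u}, {v}): missing score attribute {score_attr!r}"
            )
        try:
            score = float(atts[score_attr])
        except ValueError as exc:
            raise FormatError(
                f"{path}: edge ({u}, {v}): non-numeric score {atts[score_attr]!r}"
            ) from exc
        ssn.add_edge(u, v, score)
    return ssn


# ---------------------------------------------------------------------------
# GNN

_CLUSTER_PREFIX = "cluster:"


def _phylum_stat_str(stat: Mapping[str, float]) -> str:
    return _LIST_SEP.join(f"{p}:{_fmt_float(f)}" for p, f in sorted(stat.items()))


def _parse_phylum_stat(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if not text:
        return out
    for item in text.split(_LIST_SEP):
        phylum, _, freq = item.rpartition(":")
        out[phylum] = float(freq)
    return out


def write_gnn_xgmml(gnn: GNNDocument, path) -> None:
    """Write a (refined) GNN as bipartite XGMML.

    Cluster-nodes carry SeqCount, uniqueness and PhylumStat; Pfam-nodes
    carry description, GO terms and uniqueness; edges carry coverage and
    the supporting sequence count, so that all statistics are visible in
    Cytoscape's node and edge tables.
    """
    root = ET.Element("graph", {"label": "GNN", "directed": "0"})
    for cid in sorted(gnn.cluster_nodes):
        node = gnn.cluster_nodes[cid]
        nid = f"{_CLUSTER_PREFIX}{cid}"
        el = ET.SubElement(root, "node", {"id": nid, "label": f"Cluster {cid}"})
        _att(el, "node_type", "cluster", "string")
        _att(el, "cluster_id", str(cid), "integer")
        _att(el, "seq_count", str(node.seq_count), "integer")
        if node.uniqueness is not None:
            _att(el, "uniqueness", _fmt_float(node.uniqueness), "real")
        if node.phylum_stat is not None:
            _att(el, "phylum_stat", _phylum_stat_str(node.phylum_stat), "string")
    for pid in sorted(gnn.pfam_nodes):
        node = gnn.pfam_nodes[pid]
        el = ET.SubElement(root, "node", {"id": pid, "label": pid})
        _att(el, "node_type", "pfam", "string")
        _att(el, "pfam_id", pid, "string")
        if node.description is not None:
            _att(el, "description", node.description, "string")
        if node.go_terms:
            _att(el, "go_terms", _LIST_SEP.join(node.go_terms), "string")
        if node.uniqueness is not None:
            _att(el, "uniqueness", _fmt_float(node.uniqueness), "real")
    for (cid, pid) in sorted(gnn.edges):
        edge = gnn.edges[(cid, pid)]
        src = f"{_CLUSTER_PREFIX}{cid}"
        el = ET.SubElement(root, "edge", {"id": f"{src}|{pid}", "source": src, "target": pid})
        _att(el, "coverage", _fmt_float(edge.coverage), "real")
        _att(el, "seq_count", str(edge.supporting_count), "integer")
        if edge.uniqueness is not None:
            _att(el, "uniqueness", _fmt_float(edge.uniqueness), "real")
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def read_gnn_xgmml(path) -> GNNDocument:
    """Read a GNN written by :func:`write_gnn_xgmml` (lossless round-trip)."""
    root = _parse(path)
    gnn = GNNDocument()
    for child in root:
        if _localname(child.tag) != "node":
            continue
        atts = _atts_of(child)
        ntype = atts.get("node_type")
        if ntype == "cluster":
            try:
                cid = int(atts["cluster_id"])
                seq_count = int(atts["seq_count"])
            except (KeyError, ValueError) as exc:
                raise FormatError(
                    f"{path}: cluster node {child.attrib.get('id')!r}: "
                    "missing or non-integer cluster_id/seq_count"
                ) from exc
            uniq = float(atts["uniqueness"]) if "uniqueness" in atts else None
            stat = _parse_phylum_stat(atts["phylum_stat"]) if "phylum_stat" in atts else None
            gnn.add_cluster_node(GNNClusterNode(cid, seq_count, uniq, stat))
        elif ntype == "pfam":
            pid = atts.get("pfam_id") or child.attrib.get("id")
            if pid is None:
                raise FormatError(f"{path}: pfam node without id")
            gnn.add_pfam_node(
                GNNPfamNode(
                    pfam_id=pid,
                    description=atts.get("description"),
                    go_terms=tuple(atts["go_terms"].split(_LIST_SEP)) if atts.get("go_terms") else (),
                    uniqueness=float(atts["uniqueness"]) if "uniqueness" in atts else None,
                )
            )
        else:
            raise FormatError(
                f"{path}: node {child.attrib.get('id')!r}: missing node_type attribute"
            )
    for child in root:
        if _localname(child.tag) != "edge":
            continue
        src = child.attrib.get("source", "")
        tgt = child.attrib.get("target", "")
        if src.startswith(_CLUSTER_PREFIX):
            cid_s, pid = src[len(_CLUSTER_PREFIX):], tgt
        elif tgt.startswith(_CLUSTER_PREFIX):
            cid_s, pid = tgt[len(_CLUSTER_PREFIX):], src
        else:
            raise FormatError(f"{path}: edge ({src}, {tgt}) links no cluster node")
        atts = _atts_of(child)
        try:
            coverage = float(atts["coverage"])
            k = int(atts["seq_count"])
        except (KeyError, ValueError) as exc:
            raise FormatError(
                f"{path}: edge ({src}, {tgt}): missing or malformed coverage/seq_count"
            ) from exc
        gnn.add_edge(
            ClusterPfamEdge(
                cluster_id=int(cid_s),
                pfam_id=pid,
                supporting_count=k,
                coverage=coverage,
                uniqueness=float(atts["uniqueness"]) if "uniqueness" in atts else None,
            )
        )
    return gnn
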