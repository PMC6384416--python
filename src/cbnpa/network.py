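"""Causal network containers, statement compilation and graph file I/O.

A causal network is a directed, signed graph over biological entities.  Nodes
are canonical serializations of :class:`EntityRef` terms (``p(HGNC:EGFR)``,
``bp(GO:"cilium assembly")`` ...); edges carry a sign (+1 activation, -1
inhibition), a direct/indirect flag, a weight and an evidence count.

Two file formats are supported for round-tripping compiled networks:

* node-link JSON — nodes with ``id``/``kind``/``namespace``/``name``, links
  with ``source``/``target``/``sign``/``direct``/``weight``/``evidence_count``;
* TSV edge tables — columns ``source``, ``relation``, ``target`` plus optional
  ``weight`` and ``evidence_count``.

Both writers emit records in a canonical sorted order so that identical
networks produce byte-identical files.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "EntityRef",
    "Statement",
    "CausalEdge",
    "CausalNetwork",
    "NetworkFormatError",
    "CAUSAL_RELATIONS",
    "compile_network",
    "network_to_statements",
    "read_network",
    "write_network",
]

#: relation name -> (sign, direct)
CAUSAL_RELATIONS: dict[str, tuple[int, bool]] = {
    "increases": (+1, False),
    "directlyIncreases": (+1, True),
    "decreases": (-1, False),
    "directlyDecreases": (-1, True),
}

_RELATION_NAME = {(+1, False): "increases", (+1, True): "directlyIncreases",
                  (-1, False): "decreases", (-1, True): "directlyDecreases"}

_KIND_FUNC = {
    "protein": "p",
    "rna": "r",
    "abundance": "a",
    "bioprocess": "bp",
    "complex": "complex",
    "activity": "act",
    "other": "x",
}

_BARE_ID = re.compile(r"^[A-Za-z0-9_.\-]+$")


class NetworkFormatError(ValueError):
    """Raised when a graph file violates the expected schema."""


def _quote_if_needed(identifier: str) -> str:
    if _BARE_ID.match(identifier):
        return identifier
    return '"' + identifier.replace('"', '\\"') + '"'


@dataclass(frozen=True)
class EntityRef:
    """A biological entity term.

    ``kind`` is one of ``protein``, ``rna``, ``abundance``, ``bioprocess``,
    ``complex``, ``activity``, ``other``.  Activity terms wrap an inner
    entity (``act(p(HGNC:EGFR))``) and have an empty namespace/identifier of
    their own.
    """

    kind: str
    namespace: str = ""
    identifier: str = ""
    wrapped: Optional["EntityRef"] = None

    def __post_init__(self) -> None:
        if self.kind == "activity":
            if self.wrapped is None:
                raise ValueError("activity term requires a wrapped entity")
            if self.wrapped.kind == "activity":
                raise ValueError("activity terms cannot be nested")
        else:
            if not self.identifier:
                raise ValueError(f"{self.kind} term requires an identifier")
            if not self.namespace:
                raise ValueError(f"{self.kind} term requires a namespace")

    @property
    def canonical(self) -> str:
        """Canonical single-line serialization, e.g. ``bp(GO:"cilium assembly")``."""
        if self.kind == "activity":
            assert self.wrapped is not None
            return f"act({self.wrapped.canonical})"
        return (f"{_KIND_FUNC[self.kind]}({self.namespace}:"
                f"{_quote_if_needed(self.identifier)})")

    def collapse_activity(self) -> "EntityRef":
        """The backbone identity of this term: activity wrappers denote the
        same entity as what they wrap."""
        return self.wrapped if self.kind == "activity" else self


@dataclass(frozen=True)
class Statement:
    """One causal statement: subject --relation--> object, with annotations."""

    subject: EntityRef
    relation: str  # key of CAUSAL_RELATIONS or "unsupported"
    object: EntityRef
    annotations: Mapping[str, str] = field(default_factory=dict)
    evidence: Optional[str] = None
    source_line: int = 0

    @property
    def is_causal(self) -> bool:
        return self.relation in CAUSAL_RELATIONS


@dataclass
class CausalEdge:
    source: str
    target: str
    sign: int
    direct: bool = False
    weight: float = 1.0
    evidence_count: int = 1
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")
        if self.weight <= 0:
            raise ValueError("edge weight must be positive")
        if self.evidence_count < 1:
            raise ValueError("evidence_count must be >= 1")


@dataclass
class CausalNetwork:
    """A compiled causal network: node id -> entity, plus signed edges.

    ``node_attrs`` carries optional per-node analysis annotations (inferred
    direction, contribution) attached by downstream stages.
    """

    nodes: dict[str, EntityRef] = field(default_factory=dict)
    edges: list[CausalEdge] = field(default_factory=list)
    provenance: str = ""
    node_attrs: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise NetworkFormatError(
                        f"edge references undeclared node {endpoint!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[CausalEdge]:
        return sorted(self.edges, key=lambda e: (e.source, e.target, -e.sign))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalNetwork):
            return NotImplemented
        mine = [(e.source, e.target, e.sign, e.direct, e.weight, e.evidence_count)
                for e in self.sorted_edges()]
        theirs = [(e.source, e.target, e.sign, e.direct, e.weight, e.evidence_count)
                  for e in other.sorted_edges()]
        return self.nodes == other.nodes and mine == theirs


def compile_network(statements: Iterable[Statement],
                    weight_by_evidence: bool = False) -> CausalNetwork:
    """Compile statements into a cohesive knowledge-assembly network.

    Non-causal (``unsupported``) statements are skipped.  Parallel statements
    with the same (source, target, sign) merge into one edge with an
    incremented evidence count; opposite-sign edges between the same pair are
    retained side by side (contradictions are captured, not resolved).
    Activity wrappers collapse onto the wrapped entity for node identity; the
    wrapping is recorded on the edge annotations.
    """
    nodes: dict[str, EntityRef] = {}
    merged: dict[tuple[str, str, int], CausalEdge] = {}
    for st in statements:
        if not st.is_causal:
            continue
        sign, direct = CAUSAL_RELATIONS[st.relation]
        subj = st.subject.collapse_activity()
        obj = st.object.collapse_activity()
        src, tgt = subj.canonical, obj.canonical
        nodes.setdefault(src, subj)
        nodes.setdefault(tgt, obj)
        key = (src, tgt, sign)
        if key in merged:
            edge = merged[key]
            edge.evidence_count += 1
            edge.direct = edge.direct or direct
        else:
            ann = dict(st.annotations)
            if st.subject.kind == "activity":
                ann["subject_activity"] = "true"
            if st.object.kind == "activity":
                ann["object_activity"] = "true"
            merged[key] = CausalEdge(src, tgt, sign, direct=direct,
                                     annotations=ann)
    if weight_by_evidence:
        for edge in merged.values():
            edge.weight = float(edge.evidence_count)
    return CausalNetwork(nodes=nodes, edges=list(merged.values()))


def network_to_statements(network: CausalNetwork) -> list[Statement]:
    """Invert compilation: one statement per edge per unit of evidence."""
    out: list[Statement] = []
    for e in network.sorted_edges():
        rel = _RELATION_NAME[(e.sign, e.direct)]
        for _ in range(e.evidence_count):
            out.append(Statement(network.nodes[e.source], rel,
                                 network.nodes[e.target]))
    return out


# ---------------------------------------------------------------------------
# file formats

def write_network(network: CausalNetwork, path, format: str) -> None:
    """Write a network to ``path`` as ``node-link-json`` or ``edge-tsv``.

    Output order is canonical (sorted nodes, sorted edges), so writing the
    same network twice produces byte-identical files.
    """
    path = Path(path)
    if format == "node-link-json":
        doc = {
            "directed": True,
            "provenance": network.provenance,
            "nodes": [
                {"id": nid, "kind": ref.kind, "namespace": ref.namespace,
                 "name": ref.identifier}
                for nid, ref in sorted(network.nodes.items())
            ],
            "links": [
                {"source": e.source, "target": e.target, "sign": e.sign,
                 "direct": e.direct, "weight": e.weight,
                 "evidence_count": e.evidence_count}
                for e in network.sorted_edges()
            ],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n",
                        encoding="utf-8")
    elif format == "edge-tsv":
        lines = ["source\trelation\ttarget\tweight\tevidence_count"]
        for e in network.sorted_edges():
            rel = _RELATION_NAME[(e.sign, e.direct)]
            lines.append(f"{e.source}\t{rel}\t{e.target}\t{e.weight!r}"
                         f"\t{e.evidence_count}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise NetworkFormatError(f"unknown output format {format!r}")


def _entity_from_id(node_id: str) -> EntityRef:
    """Best-effort entity for a bare node id from an edge table."""
    from . import bel
    try:
        return bel.parse_term(node_id)
    except bel.BelParseError:
        return EntityRef("other", "LOCAL", node_id)


def read_network(path, format: str) -> CausalNetwork:
    """Read a network from ``bel``, ``node-link-json`` or ``edge-tsv``."""
    path = Path(path)
    if format == "bel":
        from . import bel
        statements = bel.parse_script(
            path.read_text(encoding="utf-8").splitlines())
        return compile_network(statements)
    if format == "node-link-json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise NetworkFormatError(f"{path}: not valid JSON: {exc}") from exc
        nodes: dict[str, EntityRef] = {}
        for rec in doc.get("nodes", []):
            for key in ("id", "kind", "namespace", "name"):
                if key not in rec:
                    raise NetworkFormatError(
                        f"{path}: node record missing {key!r}: {rec!r}")
            if rec["kind"] == "activity":
                raise NetworkFormatError(
                    f"{path}: node {rec['id']!r} has kind 'activity'; "
                    "activities are edge attributes, not nodes")
            nodes[rec["id"]] = EntityRef(rec["kind"], rec["namespace"],
                                         rec["name"])
        edges = []
        for rec in doc.get("links", []):
            for key in ("source", "target", "sign"):
                if key not in rec:
                    raise NetworkFormatError(
                        f"{path}: link record missing {key!r}: {rec!r}")
            for endpoint in (rec["source"], rec["target"]):
                if endpoint not in nodes:
                    raise NetworkFormatError(
                        f"{path}: link references undeclared node "
                        f"{endpoint!r}")
            edges.append(CausalEdge(
                rec["source"], rec["target"], int(rec["sign"]),
                direct=bool(rec.get("direct", False)),
                weight=float(rec.get("weight", 1.0)),
                evidence_count=int(rec.get("evidence_count", 1))))
        return CausalNetwork(nodes=nodes, edges=edges,
                             provenance=doc.get("provenance", ""))
    if format == "edge-tsv":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"source", "relation", "target"}
        if not required.issubset(df.columns):
            raise NetworkFormatError(
                f"{path}: edge table must have columns {sorted(required)}, "
                f"got {list(df.columns)}")
        nodes: dict[str, EntityRef] = {}
        edges = []
        for rec in df.to_dict("records"):
            rel = rec["relation"]
            if rel not in CAUSAL_RELATIONS:
                raise NetworkFormatError(
                    f"{path}: unknown relation {rel!r} in row "
                    f"{rec['source']!r} -> {rec['target']!r}")
            sign, direct = CAUSAL_RELATIONS[rel]
            for nid in (rec["source"], rec["target"]):
                if nid not in nodes:
                    nodes[nid] = _entity_from_id(nid)
            weight = float(rec.get("weight") or 1.0)
            count = int(float(rec.get("evidence_count") or 1))
            edges.append(CausalEdge(rec["source"], rec["target"], sign,
                                    direct=direct, weight=weight,
                                    evidence_count=count))
        return CausalNetwork(nodes=nodes, edges=edges)
    raise NetworkFormatError(f"unknown input format {format!r}")
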