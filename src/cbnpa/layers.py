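"""Two-layer model construction: backbone/downstream split, trimming, hubs.

The scoring substrate is a *two-layer* model: a backbone of non-measurable
entities (proteins, abundances, processes) and a downstream layer of signed
links from backbone nodes to measurable gene transcripts.  RNA nodes in a
compiled network are not scored directly — each backbone→RNA edge becomes a
downstream link whose sign encodes the expected transcriptional response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx

from .network import CausalEdge, CausalNetwork

__all__ = [
    "DownstreamEdge", "TwoLayerModel", "TrimReport", "DegreeRow",
    "ModelDiagnostics", "ComponentInfo", "LayerWarning",
    "split_layers", "trim_dangling", "degree_table", "validate_model",
]


class LayerWarning(UserWarning):
    """Recoverable issue while building or checking a two-layer model."""


@dataclass(frozen=True)
class DownstreamEdge:
    """Signed link from a backbone node to a measurable gene symbol."""

    backbone_node: str
    gene: str
    sign: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("downstream sign must be +1 or -1")
        if self.weight <= 0:
            raise ValueError("downstream weight must be positive")


@dataclass
class TwoLayerModel:
    backbone: CausalNetwork
    downstream: list[DownstreamEdge] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        for ref in self.backbone.nodes.values():
            if ref.kind == "rna":
                raise ValueError(
                    f"backbone contains an rna node {ref.canonical!r}; "
                    "run split_layers first")
        for d in self.downstream:
            if d.backbone_node not in self.backbone.nodes:
                raise ValueError(
                    f"downstream edge references unknown backbone node "
                    f"{d.backbone_node!r}")

    @property
    def genes(self) -> set[str]:
        return {d.gene.upper() for d in self.downstream}


@dataclass
class TrimReport:
    removed_nodes: list[str]
    removed_edges: int
    iterations: int


@dataclass(frozen=True)
class DegreeRow:
    node: str
    indegree: int
    outdegree: int

    @property
    def total(self) -> int:
        return self.indegree + self.outdegree


@dataclass
class ComponentInfo:
    nodes: list[str]
    n_downstream: int


@dataclass
class ModelDiagnostics:
    components: list[ComponentInfo]
    flags: list[str]

    @property
    def ok(self) -> bool:
        return not self.flags


def _backbone_digraph(network: CausalNetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    g.add_nodes_from(network.nodes)
    for e in network.edges:
        g.add_edge(e.source, e.target)
    return g


def split_layers(network: CausalNetwork, name: str = "") -> TwoLayerModel:
    """Split a compiled network into backbone and downstream layers.

    Every backbone→RNA edge becomes a downstream link (gene = the RNA node's
    identifier).  Edges out of RNA nodes cannot carry reverse-causal
    information about the backbone and are dropped with a warning, as are
    gene links whose merged signs contradict each other.
    """
    rna_ids = {nid for nid, ref in network.nodes.items() if ref.kind == "rna"}
    backbone_nodes = {nid: ref for nid, ref in network.nodes.items()
                      if nid not in rna_ids}
    backbone_edges: list[CausalEdge] = []
    raw_downstream: dict[tuple[str, str], list[CausalEdge]] = {}
    n_dropped = 0
    for e in network.edges:
        src_rna, tgt_rna = e.source in rna_ids, e.target in rna_ids
        if not src_rna and not tgt_rna:
            backbone_edges.append(e)
        elif not src_rna and tgt_rna:
            gene = network.nodes[e.target].identifier
            raw_downstream.setdefault((e.source, gene), []).append(e)
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} edge(s) out of rna nodes: rna "
                      "nodes are measurements, not causes, in this model",
                      LayerWarning, stacklevel=2)
    downstream: list[DownstreamEdge] = []
    for (node, gene), group in raw_downstream.items():
        signs = {e.sign for e in group}
        if len(signs) > 1:
            warnings.warn(f"contradictory downstream signs for ({node}, "
                          f"{gene}); link dropped", LayerWarning, stacklevel=2)
            continue
        downstream.append(DownstreamEdge(node, gene, group[0].sign,
                                         weight=group[0].weight))
    backbone = CausalNetwork(nodes=backbone_nodes, edges=backbone_edges,
                             provenance=network.provenance)
    return TwoLayerModel(backbone=backbone, downstream=downstream, name=name)


def trim_dangling(model: TwoLayerModel, undirected: bool = False,
                  allow_no_bioprocess: bool = False
                  ) -> tuple[TwoLayerModel, TrimReport]:
    """Remove hanging backbone nodes that never lead to a biological process.

    A node survives iff it has a (directed, by default) path to at least one
    ``bioprocess`` node; bioprocess nodes always survive.  Removal repeats to
    a fixpoint; downstream links of removed nodes are removed too.
    """
    bp_nodes = {nid for nid, ref in model.backbone.nodes.items()
                if ref.kind == "bioprocess"}
    if not bp_nodes:
        if allow_no_bioprocess:
            return model, TrimReport([], 0, 0)
        raise ValueError(
            "model has no bioprocess node to trim toward; pass "
            "allow_no_bioprocess=True to skip trimming")
    nodes = dict(model.backbone.nodes)
    edges = list(model.backbone.edges)
    removed: list[str] = []
    iterations = 0
    while True:
        g = nx.MultiDiGraph()
        g.add_nodes_from(nodes)
        for e in edges:
            g.add_edge(e.source, e.target)
        reach = g.to_undirected() if undirected else g
        keep = set(bp_nodes)
        for bp in bp_nodes:
            keep |= nx.ancestors(reach, bp)
        doomed = set(nodes) - keep
        if not doomed:
            break
        iterations += 1
        removed.extend(sorted(doomed))
        nodes = {nid: ref for nid, ref in nodes.items() if nid not in doomed}
        edges = [e for e in edges
                 if e.source not in doomed and e.target not in doomed]
    kept_downstream = [d for d in model.downstream
                       if d.backbone_node in nodes]
    n_removed_edges = (len(model.backbone.edges) - len(edges)
                       + len(model.downstream) - len(kept_downstream))
    trimmed = TwoLayerModel(
        backbone=CausalNetwork(nodes=nodes, edges=edges,
                               provenance=model.backbone.provenance),
        downstream=kept_downstream, name=model.name)
    return trimmed, TrimReport(sorted(removed), n_removed_edges, iterations)


def degree_table(network: CausalNetwork, k: Optional[int] = None
                 ) -> list[DegreeRow]:
    """Top-``k`` nodes by total degree (each parallel signed edge counts once).

    Ties break by indegree (descending) then node id.  ``k=None`` returns all
    nodes.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    indeg: dict[str, int] = {nid: 0 for nid in network.nodes}
    outdeg: dict[str, int] = {nid: 0 for nid in network.nodes}
    for e in network.edges:
        outdeg[e.source] += 1
        indeg[e.target] += 1
    rows = [DegreeRow(nid, indeg[nid], outdeg[nid]) for nid in network.nodes]
    rows.sort(key=lambda r: (-r.total, -r.indegree, r.node))
    return rows if k is None else rows[:k]


def validate_model(model: TwoLayerModel) -> ModelDiagnostics:
    """Diagnostics: connected components, downstream coverage, duplicates."""
    g = _backbone_digraph(model.backbone).to_undirected()
    per_node_ds: dict[str, int] = {}
    for d in model.downstream:
        per_node_ds[d.backbone_node] = per_node_ds.get(d.backbone_node, 0) + 1
    components: list[ComponentInfo] = []
    flags: list[str] = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        members = sorted(comp)
        n_ds = sum(per_node_ds.get(nid, 0) for nid in members)
        components.append(ComponentInfo(members, n_ds))
        if n_ds == 0:
            flags.append(f"component containing {members[0]!r} "
                         f"({len(members)} node(s)) has no downstream edges "
                         "and cannot be scored")
    seen: dict[tuple[str, str], int] = {}
    for d in model.downstream:
        key = (d.backbone_node, d.gene.upper())
        seen[key] = seen.get(key, 0) + 1
    for (node, gene), count in sorted(seen.items()):
        if count > 1:
            flags.append(f"duplicate downstream pair ({node}, {gene}) "
                         f"appears {count} times")
    return ModelDiagnostics(components, flags)
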