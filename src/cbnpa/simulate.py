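"""Synthetic two-layer models and expression tables with known ground truth.

Real inputs to this pipeline are curated causal networks and
differential-expression tables; both are expensive to produce, so every
stage is exercised here on generated stand-ins whose generating truth is
known exactly.  The backbone is a uniform random spanning tree plus extra
chords (connected by construction, with one designated bioprocess node so
trimming has something to trim toward); each backbone node gets a fixed
number of private synthetic genes with equiprobable downstream signs.

True node effects are drawn i.i.d. ``Normal(0, effect_sd^2)`` by default; a
"coherent" mode instead propagates a root value of ``effect_sd`` through
edge signs so the truth is maximally consistent with the wiring (the
signature of a real biological perturbation travelling through a causal
graph).  Gene fold-changes are ``beta_g = s * f_true(x) + Normal(0,
noise_sd^2)`` with the reported variance equal to ``noise_sd^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .layers import DownstreamEdge, TwoLayerModel
from .network import CausalEdge, CausalNetwork, EntityRef
from .scoring import ExpressionTable

__all__ = ["SynthConfig", "SynthTruth", "generate_model",
           "simulate_expression", "null_expression", "recovery_metrics"]


@dataclass(frozen=True)
class SynthConfig:
    n_backbone: int = 30
    n_edges: int = 60
    p_negative: float = 0.3
    genes_per_node: int = 10
    effect_sd: float = 1.0
    noise_sd: float = 0.2
    seed: int = 0
    coherent: bool = False
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        if self.n_backbone < 2:
            raise ValueError("n_backbone must be >= 2")
        max_edges = self.n_backbone * (self.n_backbone - 1) // 2
        if not self.n_backbone - 1 <= self.n_edges <= max_edges:
            raise ValueError(
                f"n_edges must be in [{self.n_backbone - 1}, {max_edges}] "
                f"for a connected simple graph, got {self.n_edges}")
        if not 0 <= self.p_negative <= 1:
            raise ValueError("p_negative must be in [0, 1]")
        if self.genes_per_node < 1:
            raise ValueError("genes_per_node must be >= 1")
        if self.effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("effect_sd and noise_sd must be >= 0")


@dataclass
class SynthTruth:
    model: TwoLayerModel
    f_true: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.model.backbone.nodes) - set(self.f_true)
        if missing:
            raise ValueError(f"f_true missing nodes {sorted(missing)[:5]}")


def _node_ref(i: int, bioprocess: bool) -> EntityRef:
    if bioprocess:
        return EntityRef("bioprocess", "SYN", f"N{i:03d}")
    return EntityRef("protein", "SYN", f"N{i:03d}")


def generate_model(config: SynthConfig,
                   rng: Optional[np.random.Generator] = None) -> SynthTruth:
    """Generate a connected two-layer model plus ground-truth node effects.

    Backbone = uniform random spanning tree on ``n_backbone`` nodes plus
    ``n_edges - n_backbone + 1`` extra distinct chords.  Node 0 is the
    bioprocess node and tree edges are oriented toward it, so the untrimmed
    model survives trimming intact.  Every node gets ``genes_per_node``
    unique synthetic gene symbols with +/-1 downstream signs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_backbone
    tree_seed = int(rng.integers(2 ** 31 - 1))
    tree = nx.random_labeled_tree(n, seed=tree_seed)
    tree_edges = set(frozenset(e) for e in tree.edges)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if frozenset((i, j)) not in tree_edges]
    n_extra = config.n_edges - (n - 1)
    extra_idx = rng.choice(len(all_pairs), size=n_extra, replace=False) \
        if n_extra else np.array([], dtype=int)
    root = 0
    # orient tree edges child -> parent so every node reaches the bioprocess
    parents = dict(nx.bfs_predecessors(tree, root))
    directed: list[tuple[int, int]] = [(c, p) for c, p in parents.items()]
    tree_count = len(directed)
    for idx in extra_idx:
        i, j = all_pairs[int(idx)]
        directed.append((i, j) if rng.random() < 0.5 else (j, i))
    signs = np.where(rng.random(len(directed)) < config.p_negative, -1, 1)

    refs = {i: _node_ref(i, bioprocess=(i == root)) for i in range(n)}
    ids = {i: refs[i].canonical for i in range(n)}

    # ground-truth node effects
    f = np.empty(n)
    if config.coherent:
        f[root] = config.effect_sd
        sign_of = {}
        for k, (u, v) in enumerate(directed[:tree_count]):
            sign_of[frozenset((u, v))] = k
        for child in nx.bfs_tree(tree, root).nodes:
            if child == root:
                continue
            parent = parents[child]
            k = sign_of[frozenset((child, parent))]
            f[child] = signs[k] * f[parent]
        # make chord signs consistent with the propagated values
        for k in range(tree_count, len(directed)):
            u, v = directed[k]
            signs[k] = 1 if f[u] * f[v] > 0 else -1
    else:
        f = rng.normal(0.0, config.effect_sd, size=n)

    edges = [CausalEdge(ids[u], ids[v], int(s))
             for (u, v), s in zip(directed, signs)]
    backbone = CausalNetwork(
        nodes={ids[i]: refs[i] for i in range(n)}, edges=edges,
        provenance=f"synthetic backbone (seed={config.seed})")
    ds_signs = np.where(rng.random(n * config.genes_per_node) < 0.5, -1, 1)
    downstream = [
        DownstreamEdge(ids[i], f"{config.gene_prefix}{i:03d}X{j}",
                       int(ds_signs[i * config.genes_per_node + j]))
        for i in range(n) for j in range(config.genes_per_node)
    ]
    model = TwoLayerModel(backbone, downstream,
                          name=f"synthetic-{config.seed}")
    return SynthTruth(model, {ids[i]: float(f[i]) for i in range(n)})


def simulate_expression(truth: SynthTruth, noise_sd: float,
                        rng: np.random.Generator) -> ExpressionTable:
    """Fold-changes from the model's own downstream layer plus noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ds = truth.model.downstream
    eps = rng.normal(0.0, noise_sd, size=len(ds)) if noise_sd > 0 \
        else np.zeros(len(ds))
    beta = np.array([d.sign * truth.f_true[d.backbone_node]
                     for d in ds]) + eps
    return ExpressionTable([d.gene for d in ds], beta,
                           np.full(len(ds), noise_sd ** 2))


def null_expression(model: TwoLayerModel, noise_sd: float,
                    rng: np.random.Generator) -> ExpressionTable:
    """Pure-noise fold-changes: the global null (no backbone effect)."""
    truth = SynthTruth(model, {nid: 0.0 for nid in model.backbone.nodes})
    return simulate_expression(truth, noise_sd, rng)


def recovery_metrics(f_true: dict[str, float], f_hat: dict[str, float]
                     ) -> tuple[float, float]:
    """(pearson_r, rmse) between true and inferred node effects."""
    if set(f_true) != set(f_hat):
        raise ValueError("f_true and f_hat must cover the same node set")
    keys = sorted(f_true)
    a = np.array([f_true[k] for k in keys])
    b = np.array([f_hat[k] for k in keys])
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance: pearson correlation undefined",
                      UserWarning, stacklevel=2)
        return float("nan"), rmse
    r = float(np.corrcoef(a, b)[0, 1])
    return r, rmse
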