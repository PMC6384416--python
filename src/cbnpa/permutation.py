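"""O/K permutation companion statistics for NPA specificity.

The NPA score alone says nothing about whether a high amplitude reflects the
biology encoded in the model.  Two permutation nulls probe that:

* **O** — permute which gene label sits in each downstream slot (signs and
  weights stay with the slot; backbone untouched).  Destroys the
  gene-to-backbone biology while preserving the downstream layer's size and
  sign balance.
* **K** — permute the head endpoints of the backbone edges (tails, signs and
  weights stay with each edge; downstream untouched).  Destroys backbone
  wiring while preserving node set, edge count and sign multiset;
  self-loops produced by a draw are re-drawn up to 100 times, then accepted.

For each permutation the full assemble → infer → score pipeline is re-run on
the permuted model with the unchanged expression table.  The p-value uses
the add-one estimator ``p = (1 + #{permuted >= observed}) / (n_perm + 1)``,
which never reaches zero.  When the number of distinct permutations is at
most 10,000 an exhaustive mode enumerates them all for an exact p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .layers import DownstreamEdge, TwoLayerModel
from .network import CausalEdge, CausalNetwork
from .scoring import (ExpressionTable, NPAResult, match_expression)

__all__ = [
    "PermutationConfig", "PermutationNull",
    "permute_downstream", "permute_backbone",
    "permutation_pvalue", "annotate_significance",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class PermutationConfig:
    kind: str  # "O" or "K"
    n_perm: int = 500
    seed: int = 0
    alpha_strong: float = 0.05
    alpha_weak: float = 0.1
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("O", "K"):
            raise ValueError("kind must be 'O' or 'K'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha_strong < self.alpha_weak < 1:
            raise ValueError("need 0 < alpha_strong < alpha_weak < 1")

    def rng(self) -> np.random.Generator:
        """Child stream for this statistic, derived from the master seed."""
        key = 0 if self.kind == "O" else 1
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class PermutationNull:
    kind: str
    values: list[float]
    observed: float
    p: float
    n_redraws: int = 0
    exhaustive: bool = False
    scheme: str = ""

    def __post_init__(self) -> None:
        n = len(self.values)
        assert 1 / (n + 1) <= self.p <= 1 + 1e-12


# ---------------------------------------------------------------------------
# model-level permutation operators

def permute_downstream(model: TwoLayerModel,
                       rng: np.random.Generator) -> TwoLayerModel:
    """Randomly permute gene labels across downstream slots (O null)."""
    if not model.downstream:
        raise ValueError("downstream layer is empty")
    genes = [d.gene for d in model.downstream]
    perm = rng.permutation(len(genes))
    new_ds = [DownstreamEdge(d.backbone_node, genes[perm[i]], d.sign,
                             d.weight)
              for i, d in enumerate(model.downstream)]
    return TwoLayerModel(model.backbone, new_ds, model.name)


def permute_backbone(model: TwoLayerModel,
                     rng: np.random.Generator,
                     max_selfloop_redraws: int = 100) -> TwoLayerModel:
    """Randomly permute backbone edge heads (K null).

    Tails, signs and weights stay with their edge, so node set, edge count
    and sign multiset are conserved.
    """
    edges = model.backbone.edges
    if len(edges) < 2:
        raise ValueError("backbone needs >= 2 edges to permute")
    tails = [e.source for e in edges]
    heads = [e.target for e in edges]
    for _ in range(max_selfloop_redraws):
        perm = rng.permutation(len(edges))
        if all(tails[i] != heads[perm[i]] for i in range(len(edges))):
            break
    new_edges = [CausalEdge(tails[i], heads[perm[i]], e.sign, direct=e.direct,
                            weight=e.weight, evidence_count=e.evidence_count)
                 for i, e in enumerate(edges)]
    backbone = CausalNetwork(nodes=dict(model.backbone.nodes),
                             edges=new_edges,
                             provenance=model.backbone.provenance)
    return TwoLayerModel(backbone, list(model.downstream), model.name)


# ---------------------------------------------------------------------------
# fast array core (same arithmetic as assemble_system + infer + score)

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


class _Core:
    """Array form of one model + matched table for repeated rescoring.

    Mirrors assemble_system/infer_backbone/npa_score exactly: equality with
    the public route is asserted in the test suite.
    """

    def __init__(self, model: TwoLayerModel, matched: ExpressionTable,
                 ridge: float = 1e-10, mode: str = "mean-square"):
        self.mode = mode
        self.ridge = ridge
        self.nodes = sorted(model.backbone.nodes)
        pos = {nid: i for i, nid in enumerate(self.nodes)}
        n = len(self.nodes)
        edges = [e for e in model.backbone.edges if e.source != e.target]
        self.bb_u = np.array([pos[e.source] for e in edges], dtype=np.intp)
        self.bb_v = np.array([pos[e.target] for e in edges], dtype=np.intp)
        self.bb_sw = np.array([e.sign * e.weight for e in edges])
        self.bb_aw = np.array([e.weight for e in edges])
        # downstream slots: all of them; matched status travels with the gene
        genes = sorted({d.gene.upper() for d in model.downstream})
        gpos = {g: j for j, g in enumerate(genes)}
        self.slot_node = np.array([pos[d.backbone_node]
                                   for d in model.downstream], dtype=np.intp)
        self.slot_gene = np.array([gpos[d.gene.upper()]
                                   for d in model.downstream], dtype=np.intp)
        self.slot_sw = np.array([d.sign * d.weight for d in model.downstream])
        self.slot_aw = np.array([d.weight for d in model.downstream])
        matched_set = {str(g).upper() for g in matched.genes}
        lookup = {str(g).upper(): b
                  for g, b in zip(matched.genes, matched.beta)}
        self.gene_matched = np.array([g in matched_set for g in genes])
        self.gene_beta = np.array([lookup.get(g, 0.0) for g in genes])
        self.n_nodes = n

    def _components(self, bb_u: np.ndarray, bb_v: np.ndarray) -> np.ndarray:
        uf = _UnionFind(self.n_nodes)
        for i, j in zip(bb_u.tolist(), bb_v.tolist()):
            uf.union(i, j)
        return np.array([uf.find(i) for i in range(self.n_nodes)])

    def score(self, slot_gene: Optional[np.ndarray] = None,
              bb_v: Optional[np.ndarray] = None) -> Optional[float]:
        """Assemble and score one (possibly permuted) configuration.

        Returns None when some backbone component has no matched downstream
        gene (the caller re-draws such permutations) — the scored node set
        must stay comparable across the null.
        """
        slot_gene = self.slot_gene if slot_gene is None else slot_gene
        bb_v = self.bb_v if bb_v is None else bb_v
        n = self.n_nodes
        matched_slot = self.gene_matched[slot_gene]
        comp = self._components(self.bb_u, bb_v)
        have = np.zeros(n, dtype=bool)
        have[self.slot_node[matched_slot]] = True
        comp_ok = np.zeros(n, dtype=bool)
        for root in np.unique(comp):
            members = comp == root
            comp_ok[members] = have[members].any()
        if not comp_ok.all():
            return None
        # self-loops (possible after an accepted K draw) carry no
        # cross-node constraint and are skipped, as in assemble_system
        keep = self.bb_u != bb_v
        bb_u, bb_sw, bb_aw = self.bb_u[keep], self.bb_sw[keep], self.bb_aw[keep]
        bb_v = bb_v[keep]
        L = np.zeros((n, n))
        np.add.at(L, (bb_u, bb_v), -bb_sw)
        np.add.at(L, (bb_v, bb_u), -bb_sw)
        diag = np.zeros(n)
        np.add.at(diag, bb_u, bb_aw)
        np.add.at(diag, bb_v, bb_aw)
        L_backbone = L + np.diag(diag)
        ds_diag = np.zeros(n)
        np.add.at(ds_diag, self.slot_node[matched_slot],
                  self.slot_aw[matched_slot])
        L_bb = L_backbone + np.diag(ds_diag + self.ridge)
        rhs = np.zeros(n)
        np.add.at(rhs, self.slot_node[matched_slot],
                  self.slot_sw[matched_slot]
                  * self.gene_beta[slot_gene[matched_slot]])
        f = cho_solve(cho_factor(L_bb, check_finite=False), rhs,
                      check_finite=False)
        if self.mode == "mean-square":
            return float(f @ f) / n
        return float(f @ (L_backbone @ f)) / n


# ---------------------------------------------------------------------------
# p-values

def _pvalue(values: list[float], observed: float) -> float:
    return (1 + sum(v >= observed for v in values)) / (len(values) + 1)


def permutation_pvalue(model: TwoLayerModel, expression: ExpressionTable,
                       config: PermutationConfig, mode: str = "mean-square",
                       ridge: float = 1e-10) -> PermutationNull:
    """Permutation null distribution and p-value for one statistic.

    Fully reproducible given ``config.seed`` (O and K use independent child
    streams of the same master seed).  Permutations that leave some backbone
    component without matched genes are re-drawn, up to ``10 * n_perm``
    redraws in total.
    """
    matched, _ = match_expression(model, expression)
    core = _Core(model, matched, ridge=ridge, mode=mode)
    observed = core.score()
    if observed is None:
        raise ValueError("model is not scoreable: some backbone component "
                         "has no matched downstream gene")
    scheme = ("gene-label permutation over downstream slots"
              if config.kind == "O"
              else "edge-head permutation over backbone edges (tail-degree "
                   "preserving)")

    if config.exhaustive:
        count_items = (len(core.slot_gene) if config.kind == "O"
                       else len(core.bb_v))
        if config.kind == "K" and count_items < 2:
            raise ValueError("backbone needs >= 2 edges for K")
        if math.factorial(count_items) > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"{count_items}! permutations exceed the exhaustive limit "
                f"of {EXHAUSTIVE_LIMIT}; use sampling instead")
        values: list[float] = []
        base = (core.slot_gene if config.kind == "O" else core.bb_v)
        for perm in itertools.permutations(range(count_items)):
            arr = base[np.array(perm, dtype=np.intp)]
            s = (core.score(slot_gene=arr) if config.kind == "O"
                 else core.score(bb_v=arr))
            if s is not None:
                values.append(s)
        return PermutationNull(config.kind, values, observed,
                               _pvalue(values, observed), 0, True, scheme)

    rng = config.rng()
    values = []
    n_redraws = 0
    max_redraws = 10 * config.n_perm
    while len(values) < config.n_perm:
        if config.kind == "O":
            perm = rng.permutation(len(core.slot_gene))
            s = core.score(slot_gene=core.slot_gene[perm])
        else:
            if len(core.bb_v) < 2:
                raise ValueError("backbone needs >= 2 edges for K")
            for _ in range(100):
                perm = rng.permutation(len(core.bb_v))
                bb_v = core.bb_v[perm]
                if not np.any(bb_v == core.bb_u):
                    break
            s = core.score(bb_v=bb_v)
        if s is None:
            n_redraws += 1
            if n_redraws > max_redraws:
                raise ValueError(
                    f"exceeded {max_redraws} redraws of unscoreable "
                    "permutations; the model is too fragmented to permute")
            continue
        values.append(s)
    return PermutationNull(config.kind, values, observed,
                           _pvalue(values, observed), n_redraws, False,
                           scheme)


def annotate_significance(result: NPAResult, o: Optional[PermutationNull],
                          k: Optional[PermutationNull],
                          config: PermutationConfig) -> NPAResult:
    """Attach O/K p-values and significance flags to a result.

    ``star`` marks an interval excluding zero; ``*_strong`` marks
    ``p < alpha_strong``; ``*_weak`` marks ``alpha_strong <= p < alpha_weak``.
    """
    flags = dict(result.flags)
    flags["star"] = bool(result.ci_low > 0)
    p_O = float(o.p) if o is not None else None
    p_K = float(k.p) if k is not None else None
    for name, p in (("O", p_O), ("K", p_K)):
        if p is None:
            continue
        flags[f"{name}_strong"] = bool(p < config.alpha_strong)
        flags[f"{name}_weak"] = bool(config.alpha_strong <= p
                                     < config.alpha_weak)
    return replace(result, p_O=p_O, p_K=p_K, flags=flags)
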