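"""Network perturbation amplitude (NPA) scoring.

Backbone differential values are inferred from gene log2 fold-changes by
minimizing the signed quadratic

    sum over backbone edges  w * (f(x) - sigma * f(y))^2
  + sum over matched downstream links  w * (f(x) - s * beta_g)^2
  + ridge * sum f^2 ,

whose normal equations are ``L_bb f = -L_bg beta`` with ``L_bb`` the signed
Laplacian augmented by downstream diagonal mass and ``L_bg`` the
backbone-by-gene coupling.  Edges are treated as undirected and signed for
inference (information flows from measured genes up into the backbone);
direction is used only for trimming and display.

The NPA score is a quadratic form of the inferred values.  The default
"mean-square" amplitude is ``score = (1/|V_b|) * sum f(x)^2`` with per-node
contributions ``f(x)^2 / |V_b|``; the alternative "backbone-laplacian" form
is ``(1/|V_b|) * f' L~ f`` with ``L~`` the backbone-only signed Laplacian
(contributions may then be negative).  Confidence intervals propagate
per-gene fold-change variances through the linear inference map with the
first-order delta method; a Monte-Carlo interval is available as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .layers import TwoLayerModel, validate_model

__all__ = [
    "ExpressionTable", "LaplacianSystem", "BackboneState", "LeadingNode",
    "NPAResult", "ScoringWarning", "collapse_probes", "match_expression",
    "assemble_system", "infer_backbone", "npa_score", "confidence_interval",
    "leading_nodes", "leading_subnetwork",
]

CONDITION_LIMIT = 1e12
DIRECTION_TOL = 1e-12


class ScoringWarning(UserWarning):
    """Recoverable issue during matching or assembly."""


# ---------------------------------------------------------------------------
# expression tables

class ExpressionTable:
    """Per-gene differential expression: log2 fold-change and its variance.

    One row per gene symbol; multiple probes must be collapsed first (see
    :func:`collapse_probes`).
    """

    def __init__(self, genes: Sequence[str], beta: Sequence[float],
                 variance: Sequence[float]):
        self.genes = np.asarray(genes, dtype=object)
        self.beta = np.asarray(beta, dtype=float)
        self.variance = np.asarray(variance, dtype=float)
        if not (len(self.genes) == len(self.beta) == len(self.variance)):
            raise ValueError("genes, beta and variance must be equal length")
        if np.any(self.variance < 0):
            raise ValueError("variances must be non-negative")
        upper = [str(g).upper() for g in self.genes]
        if len(set(upper)) != len(upper):
            dupes = sorted({g for g in upper if upper.count(g) > 1})
            raise ValueError(
                f"duplicate gene symbols {dupes[:5]}; collapse probes first")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "beta": self.beta,
                             "variance": self.variance})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionTable":
        """Build from a data frame with (gene, logFC, SE) or
        (gene, logFC, variance) columns; column names are matched
        case-insensitively, ``beta`` is accepted for ``logFC``."""
        cols = {c.lower(): c for c in df.columns}
        gene_col = next((cols[n] for n in ("gene", "symbol", "genes")
                         if n in cols), None)
        beta_col = next((cols[n] for n in ("logfc", "beta", "log2fc", "lfc")
                         if n in cols), None)
        if gene_col is None or beta_col is None:
            raise ValueError(
                f"need gene and logFC columns, got {list(df.columns)}")
        if any(n in cols for n in ("variance", "var")):
            var_col = cols.get("variance", cols.get("var"))
            variance = df[var_col].to_numpy(dtype=float)
        elif "se" in cols:
            variance = df[cols["se"]].to_numpy(dtype=float) ** 2
        else:
            raise ValueError(
                f"need an SE or variance column, got {list(df.columns)}")
        return cls(df[gene_col].astype(str).to_numpy(),
                   df[beta_col].to_numpy(dtype=float), variance)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ExpressionTable":
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        return cls.from_frame(pd.read_csv(path, sep=sep))


def collapse_probes(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple probes per gene: mean beta, mean variance / n.

    The variance rule treats probes as independent replicate measurements of
    the same fold-change, so averaging n probes divides the variance by n.
    """
    table = ExpressionTable  # reuse column sniffing
    cols = {c.lower(): c for c in df.columns}
    gene_col = next((cols[n] for n in ("gene", "symbol", "genes")
                     if n in cols), None)
    beta_col = next((cols[n] for n in ("logfc", "beta", "log2fc", "lfc")
                     if n in cols), None)
    var_col = cols.get("variance", cols.get("var"))
    if var_col is None and "se" in cols:
        df = df.copy()
        df["variance"] = df[cols["se"]].astype(float) ** 2
        var_col = "variance"
    if gene_col is None or beta_col is None or var_col is None:
        raise ValueError(f"unrecognized columns {list(df.columns)}")
    key = df[gene_col].astype(str).str.upper()
    grouped = df.groupby(key)
    out = pd.DataFrame({
        "gene": grouped[gene_col].first(),
        "beta": grouped[beta_col].mean(),
        "variance": grouped[var_col].mean() / grouped[var_col].count(),
    }).reset_index(drop=True)
    return out


def match_expression(model: TwoLayerModel, table: ExpressionTable
                     ) -> tuple[ExpressionTable, float]:
    """Restrict a table to genes present in the downstream layer.

    Matching is case-insensitive (symbols canonicalized to upper case).
    Returns the matched table and the coverage fraction (matched distinct
    downstream genes / all distinct downstream genes).
    """
    targets = model.genes
    if not targets:
        raise ValueError("model has no downstream genes")
    upper = np.array([str(g).upper() for g in table.genes], dtype=object)
    mask = np.isin(upper, sorted(targets))
    coverage = len(set(upper[mask])) / len(targets)
    if coverage == 0:
        raise ValueError("no measurable overlap between the expression "
                         "table and the model's downstream genes")
    if coverage <= 0.5:
        warnings.warn(f"expression table covers only {coverage:.1%} of the "
                      "model's downstream genes", ScoringWarning, stacklevel=2)
    matched = ExpressionTable(upper[mask], table.beta[mask],
                              table.variance[mask])
    return matched, coverage


# ---------------------------------------------------------------------------
# system assembly and inference

@dataclass
class LaplacianSystem:
    """Assembled linear system for backbone inference.

    ``L_bb`` is the signed backbone Laplacian plus matched-downstream
    diagonal mass plus ridge; ``L_bg[x, g] = -sign(x, g) * weight``.
    ``L_backbone`` is the backbone-only signed Laplacian used by the
    "backbone-laplacian" score mode.
    """

    backbone_index: list[str]
    gene_index: list[str]
    L_bb: np.ndarray
    L_bg: np.ndarray
    L_backbone: np.ndarray
    ridge: float
    dropped_components: list[list[str]] = field(default_factory=list)

    @property
    def n_backbone(self) -> int:
        return len(self.backbone_index)

    def align_beta(self, table: ExpressionTable) -> np.ndarray:
        """Beta vector over ``gene_index`` (order-insensitive lookup)."""
        lookup = {str(g).upper(): b
                  for g, b in zip(table.genes, table.beta)}
        try:
            return np.array([lookup[g] for g in self.gene_index])
        except KeyError as exc:
            raise ValueError(f"table has no value for gene {exc}") from exc

    def align_variance(self, table: ExpressionTable) -> np.ndarray:
        lookup = {str(g).upper(): v
                  for g, v in zip(table.genes, table.variance)}
        return np.array([lookup[g] for g in self.gene_index])


def assemble_system(model: TwoLayerModel, matched: ExpressionTable,
                    ridge: float = 1e-10) -> LaplacianSystem:
    """Build the signed-Laplacian blocks for a model and matched table.

    Backbone components without any matched downstream link have no data to
    anchor them; they are dropped with a warning before assembly (the score
    averages over scored nodes only).
    """
    import networkx as nx

    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    matched_genes = {str(g).upper() for g in matched.genes}
    g = nx.Graph()
    g.add_nodes_from(model.backbone.nodes)
    for e in model.backbone.edges:
        g.add_edge(e.source, e.target)
    per_node_matched: dict[str, int] = {}
    for d in model.downstream:
        if d.gene.upper() in matched_genes:
            per_node_matched[d.backbone_node] = \
                per_node_matched.get(d.backbone_node, 0) + 1
    kept: set[str] = set()
    dropped: list[list[str]] = []
    for comp in nx.connected_components(g):
        if any(per_node_matched.get(nid, 0) for nid in comp):
            kept |= comp
        else:
            dropped.append(sorted(comp))
    if dropped:
        n = sum(len(c) for c in dropped)
        warnings.warn(f"dropped {len(dropped)} backbone component(s) "
                      f"({n} node(s)) with no matched downstream genes",
                      ScoringWarning, stacklevel=2)
    if not kept:
        raise ValueError("no backbone component has matched downstream "
                         "genes; nothing to score")
    backbone_index = sorted(kept)
    node_pos = {nid: i for i, nid in enumerate(backbone_index)}
    gene_index = sorted({d.gene.upper() for d in model.downstream
                         if d.gene.upper() in matched_genes
                         and d.backbone_node in kept})
    gene_pos = {gid: j for j, gid in enumerate(gene_index)}
    n, m = len(backbone_index), len(gene_index)
    L_backbone = np.zeros((n, n))
    for e in model.backbone.edges:
        if e.source not in kept or e.source == e.target:
            continue
        i, j = node_pos[e.source], node_pos[e.target]
        L_backbone[i, j] -= e.sign * e.weight
        L_backbone[j, i] -= e.sign * e.weight
        L_backbone[i, i] += e.weight
        L_backbone[j, j] += e.weight
    L_bb = L_backbone.copy()
    L_bg = np.zeros((n, m))
    for d in model.downstream:
        if d.backbone_node not in kept or d.gene.upper() not in gene_pos:
            continue
        i = node_pos[d.backbone_node]
        L_bb[i, i] += d.weight
        L_bg[i, gene_pos[d.gene.upper()]] -= d.sign * d.weight
    L_bb[np.diag_indices(n)] += ridge
    return LaplacianSystem(backbone_index, gene_index, L_bb, L_bg,
                           L_backbone, ridge, dropped)


@dataclass
class BackboneState:
    """Inferred differential values over the scored backbone nodes."""

    system: LaplacianSystem
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.system.backbone_index, self.values.tolist()))


def infer_backbone(system: LaplacianSystem,
                   beta: Union[np.ndarray, ExpressionTable]) -> BackboneState:
    """Solve ``f = -L_bb^{-1} L_bg beta``.

    Equivalently the unique minimizer of the signed quadratic objective in
    the module docstring (asserted against an independent least-squares
    oracle in the test suite).
    """
    if isinstance(beta, ExpressionTable):
        beta = system.align_beta(beta)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(system.gene_index),):
        raise ValueError(f"beta must have length {len(system.gene_index)}")
    eigvals = np.linalg.eigvalsh(system.L_bb)
    if eigvals[0] <= 0 or eigvals[-1] / eigvals[0] > CONDITION_LIMIT:
        raise ValueError(
            "L_bb is singular or ill-conditioned (condition number > "
            f"{CONDITION_LIMIT:g}); run validate_model to locate backbone "
            "components without matched downstream genes")
    f = cho_solve(cho_factor(system.L_bb), -system.L_bg @ beta)
    return BackboneState(system, f)


# ---------------------------------------------------------------------------
# scores, intervals, leading nodes

def npa_score(state: BackboneState, mode: str = "mean-square"
              ) -> tuple[float, dict[str, float], dict[str, int]]:
    """Score a backbone state; returns (score, contributions, directions).

    Contributions always sum to the score.  In ``backbone-laplacian`` mode
    individual contributions may be negative (flagged with a warning).
    """
    f = state.values
    n = len(f)
    if mode == "mean-square":
        contrib = f ** 2 / n
    elif mode == "backbone-laplacian":
        contrib = f * (state.system.L_backbone @ f) / n
        if np.any(contrib < -DIRECTION_TOL):
            warnings.warn("backbone-laplacian mode produced negative "
                          "contributions", ScoringWarning, stacklevel=2)
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    score = float(contrib.sum())
    directions = np.sign(f) * (np.abs(f) >= DIRECTION_TOL)
    index = state.system.backbone_index
    return (score,
            dict(zip(index, contrib.tolist())),
            dict(zip(index, (int(d) for d in directions))))


def confidence_interval(system: LaplacianSystem, beta: np.ndarray,
                        variances: np.ndarray, level: float = 0.95,
                        mode: str = "mean-square", method: str = "delta",
                        n_draws: int = 2000,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[float, float]:
    """CI for the score via the first-order delta method (default).

    With ``M = -L_bb^{-1} L_bg`` and ``score = q(M beta)``,
    ``Var(score) ~= sum_g (d score / d beta_g)^2 Var(beta_g)``.
    ``method="monte-carlo"`` instead resamples ``beta ~ Normal(beta, Var)``
    and takes percentile bounds.
    """
    beta = np.asarray(beta, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if np.any(variances < 0):
        raise ValueError("variances must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    M = cho_solve(cho_factor(system.L_bb), -system.L_bg)
    n = system.n_backbone

    def q(f: np.ndarray) -> float:
        if mode == "mean-square":
            return float(f @ f) / n
        if mode == "backbone-laplacian":
            return float(f @ (system.L_backbone @ f)) / n
        raise ValueError(f"unknown score mode {mode!r}")

    f = M @ beta
    score = q(f)
    if method == "monte-carlo":
        rng = rng if rng is not None else np.random.default_rng(0)
        draws = rng.normal(beta, np.sqrt(variances),
                           size=(n_draws, len(beta)))
        scores = np.array([q(M @ b) for b in draws])
        lo, hi = np.quantile(scores, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)
    if method != "delta":
        raise ValueError(f"unknown CI method {method!r}")
    if mode == "mean-square":
        grad = (2.0 / n) * (f @ M)
    else:
        grad = (2.0 / n) * ((system.L_backbone @ f) @ M)
    var = float(np.sum(grad ** 2 * variances))
    half = float(norm.ppf((1 + level) / 2) * np.sqrt(var))
    return float(score - half), float(score + half)


@dataclass(frozen=True)
class LeadingNode:
    node: str
    contribution: float
    pct: float
    cum_pct: float
    rank: int
    direction: int = 0


def leading_nodes(contributions: dict[str, float], threshold: float = 0.8,
                  directions: Optional[dict[str, int]] = None
                  ) -> list[LeadingNode]:
    """Smallest prefix of |contribution|-ranked nodes reaching ``threshold``.

    Nodes are sorted by absolute contribution (descending, ties by node id);
    the leading set is the shortest prefix whose cumulative share of the
    total absolute contribution is at least ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    total = sum(abs(c) for c in contributions.values())
    if total == 0:
        warnings.warn("all contributions are zero; no leading nodes",
                      ScoringWarning, stacklevel=2)
        return []
    ranked = sorted(contributions.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    out: list[LeadingNode] = []
    cum = 0.0
    for rank, (node, c) in enumerate(ranked, start=1):
        cum += abs(c)
        out.append(LeadingNode(node, c, 100 * abs(c) / total,
                               100 * cum / total, rank,
                               (directions or {}).get(node, 0)))
        if cum / total >= threshold:
            break
    return out


def leading_subnetwork(model: TwoLayerModel, leading: list[LeadingNode]):
    """Induced backbone subgraph on the leading nodes, annotated with each
    node's inferred direction and contribution."""
    from .network import CausalNetwork

    keep = {ln.node for ln in leading}
    missing = keep - set(model.backbone.nodes)
    if missing:
        raise ValueError(f"leading nodes not in backbone: {sorted(missing)}")
    nodes = {nid: ref for nid, ref in model.backbone.nodes.items()
             if nid in keep}
    edges = [e for e in model.backbone.edges
             if e.source in keep and e.target in keep]
    attrs = {ln.node: {"direction": ln.direction,
                       "contribution": ln.contribution,
                       "pct": ln.pct, "rank": ln.rank}
             for ln in leading}
    return CausalNetwork(nodes=nodes, edges=edges,
                         provenance=f"leading-node subnetwork of "
                                    f"{model.name or 'model'}",
                         node_attrs=attrs)


@dataclass
class NPAResult:
    """Full scoring result for one model x contrast."""

    score: float
    ci_low: float
    ci_high: float
    contributions: dict[str, float]
    directions: dict[str, int]
    leading: list[LeadingNode]
    mode: str = "mean-square"
    coverage: float = float("nan")
    p_O: Optional[float] = None
    p_K: Optional[float] = None
    flags: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": "cbnpa-result/1",
            "score": self.score,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "mode": self.mode,
            "coverage": self.coverage,
            "p_O": self.p_O,
            "p_K": self.p_K,
            "flags": dict(self.flags),
            "contributions": self.contributions,
            "directions": self.directions,
            "leading": [
                {"node": ln.node, "contribution": ln.contribution,
                 "pct": ln.pct, "cum_pct": ln.cum_pct, "rank": ln.rank,
                 "direction": ln.direction}
                for ln in self.leading
            ],
        }
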