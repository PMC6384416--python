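"""Validation suites: oracle equivalence, calibration, power, recovery.

These are the package's own end-to-end checks, runnable from the CLI
(``cbnpa benchmark``) and re-used by the acceptance script.  Every check
regenerates its inputs from a seed and computes its quantity from scratch.

The inference oracle here is deliberately independent of the scoring
engine's Laplacian route: it stacks the signed quadratic objective into an
explicit least-squares design matrix and solves it with ``numpy.linalg
.lstsq``.  Agreement of the two routes on random models is the primary
correctness guarantee for the solver.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .layers import DownstreamEdge, TwoLayerModel
from .network import CausalEdge, CausalNetwork, EntityRef
from .permutation import PermutationConfig, permutation_pvalue
from .scoring import (ExpressionTable, assemble_system, infer_backbone,
                      match_expression, npa_score)
from .simulate import (SynthConfig, generate_model, null_expression,
                       recovery_metrics, simulate_expression)

__all__ = ["least_squares_reference", "toy_model", "toy_expression",
           "oracle_equivalence", "null_calibration", "power_specificity",
           "parameter_recovery", "run_benchmarks"]


def least_squares_reference(model: TwoLayerModel, table: ExpressionTable,
                            ridge: float = 1e-10) -> dict[str, float]:
    """Minimize the signed quadratic objective directly via lstsq.

    Stacks one row per backbone edge (f(x) - sigma f(y) -> 0), one row per
    matched downstream link (f(x) -> s * beta_g), and ridge rows, then
    solves the least-squares problem.  Shares no code with the Laplacian
    normal-equations route in :mod:`cbnpa.scoring`.
    """
    matched, _ = match_expression(model, table)
    beta = {str(g).upper(): b for g, b in zip(matched.genes, matched.beta)}
    nodes = sorted(model.backbone.nodes)
    pos = {nid: i for i, nid in enumerate(nodes)}
    n = len(nodes)
    rows: list[np.ndarray] = []
    targets: list[float] = []
    for e in model.backbone.edges:
        if e.source == e.target:
            continue
        row = np.zeros(n)
        sw = np.sqrt(e.weight)
        row[pos[e.source]] = sw
        row[pos[e.target]] = -e.sign * sw
        rows.append(row)
        targets.append(0.0)
    for d in model.downstream:
        g = d.gene.upper()
        if g not in beta:
            continue
        row = np.zeros(n)
        sw = np.sqrt(d.weight)
        row[pos[d.backbone_node]] = sw
        rows.append(row)
        targets.append(sw * d.sign * beta[g])
    for i in range(n):
        row = np.zeros(n)
        row[i] = np.sqrt(ridge)
        rows.append(row)
        targets.append(0.0)
    sol, *_ = np.linalg.lstsq(np.vstack(rows), np.array(targets), rcond=None)
    return dict(zip(nodes, sol.tolist()))


# ---------------------------------------------------------------------------
# worked toy models

def toy_model(flipped: bool = False) -> TwoLayerModel:
    """Two-node worked example.

    Default: backbone edge x -> y with sign +1, downstream links
    (x, G1, +1) and (y, G2, -1).  ``flipped=True`` applies the gauge
    (switching) transformation at y: edge sign -1, downstream (y, G2, +1).
    """
    x = EntityRef("protein", "SYN", "X")
    y = EntityRef("protein", "SYN", "Y")
    xs, ys = x.canonical, y.canonical
    edge_sign, g2_sign = (-1, +1) if flipped else (+1, -1)
    backbone = CausalNetwork(
        nodes={xs: x, ys: y},
        edges=[CausalEdge(xs, ys, edge_sign)])
    downstream = [DownstreamEdge(xs, "G1", +1),
                  DownstreamEdge(ys, "G2", g2_sign)]
    return TwoLayerModel(backbone, downstream,
                         name="toy-flipped" if flipped else "toy")


def toy_expression(variance: float = 0.0) -> ExpressionTable:
    """The worked contrast for the toy model: beta = (G1: 2, G2: -2)."""
    return ExpressionTable(["G1", "G2"], [2.0, -2.0], [variance, variance])


# ---------------------------------------------------------------------------
# suites

def _random_small_model(rng: np.random.Generator) -> TwoLayerModel:
    n = int(rng.integers(2, 9))
    max_edges = n * (n - 1) // 2
    n_edges = int(rng.integers(n - 1, max_edges + 1))
    config = SynthConfig(n_backbone=n, n_edges=n_edges,
                         p_negative=float(rng.uniform(0, 1)),
                         genes_per_node=int(rng.integers(1, 4)),
                         seed=int(rng.integers(2 ** 31 - 1)))
    return generate_model(config, rng).model


def oracle_equivalence(seed: int = 1, n_models: int = 100) -> float:
    """Max relative disagreement between the Laplacian solver and the
    least-squares oracle over random small models (<= 8 backbone nodes)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                       spawn_key=(10,)))
    worst = 0.0
    for _ in range(n_models):
        model = _random_small_model(rng)
        truth = {nid: float(rng.normal()) for nid in model.backbone.nodes}
        beta = np.array([d.sign * truth[d.backbone_node]
                         + rng.normal(0, 0.5) for d in model.downstream])
        table = ExpressionTable([d.gene for d in model.downstream], beta,
                                np.full(len(model.downstream), 0.25))
        matched, _ = match_expression(model, table)
        system = assemble_system(model, matched)
        state = infer_backbone(system, system.align_beta(matched))
        f_hat = state.as_dict()
        f_ref = least_squares_reference(model, table)
        a = np.array([f_hat[k] for k in sorted(f_hat)])
        b = np.array([f_ref[k] for k in sorted(f_ref)])
        denom = max(np.linalg.norm(b), 1e-30)
        worst = max(worst, float(np.linalg.norm(a - b) / denom))
    return worst


def null_calibration(seed: int = 1, n_datasets: int = 500,
                     n_perm: int = 200, noise_sd: float = 1.0) -> float:
    """Fraction of O-statistic p-values below 0.05 under the global null.

    One fixed synthetic model (30 backbone nodes, 60 edges, 10 genes per
    node); each dataset is pure noise with sd ``noise_sd``.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(11,))
    rng = np.random.default_rng(ss)
    config = SynthConfig(n_backbone=30, n_edges=60, genes_per_node=10,
                         noise_sd=noise_sd,
                         seed=int(rng.integers(2 ** 31 - 1)))
    model = generate_model(config, rng).model
    hits = 0
    for i in range(n_datasets):
        table = null_expression(model, noise_sd, rng)
        pconf = PermutationConfig("O", n_perm=n_perm,
                                  seed=int(rng.integers(2 ** 31 - 1)))
        null = permutation_pvalue(model, table, pconf)
        hits += null.p < 0.05
    return hits / n_datasets


def power_specificity(seed: int = 1, n_runs: int = 100, n_perm: int = 200,
                      effect_sd: float = 1.0, noise_sd: float = 0.1
                      ) -> tuple[float, float, float]:
    """(power_O, power_K, decoy_null_rate) over ``n_runs`` simulations.

    Power: network-consistent truth simulated from the generating model;
    fraction of runs with p < 0.05 for each statistic.  Specificity: the
    same data renamed onto the genes of an independently generated,
    gene-disjoint decoy model; fraction of runs with p_O >= 0.05 (the decoy
    should *not* light up).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                       spawn_key=(12,)))
    hits_o = hits_k = decoy_null = 0
    for _ in range(n_runs):
        config_a = SynthConfig(n_backbone=30, n_edges=60, genes_per_node=10,
                               effect_sd=effect_sd, noise_sd=noise_sd,
                               coherent=True,
                               seed=int(rng.integers(2 ** 31 - 1)))
        truth = generate_model(config_a, rng)
        table = simulate_expression(truth, noise_sd, rng)
        pseed = int(rng.integers(2 ** 31 - 1))
        p_o = permutation_pvalue(
            truth.model, table, PermutationConfig("O", n_perm, pseed)).p
        p_k = permutation_pvalue(
            truth.model, table, PermutationConfig("K", n_perm, pseed)).p
        hits_o += p_o < 0.05
        hits_k += p_k < 0.05
        config_b = SynthConfig(n_backbone=30, n_edges=60, genes_per_node=10,
                               gene_prefix="H",
                               seed=int(rng.integers(2 ** 31 - 1)))
        decoy = generate_model(config_b, rng).model
        decoy_genes = [d.gene for d in decoy.downstream]
        renamed = ExpressionTable(decoy_genes,
                                  rng.permutation(table.beta),
                                  table.variance)
        p_decoy = permutation_pvalue(
            decoy, renamed,
            PermutationConfig("O", n_perm,
                              int(rng.integers(2 ** 31 - 1)))).p
        decoy_null += p_decoy >= 0.05
    return hits_o / n_runs, hits_k / n_runs, decoy_null / n_runs


def parameter_recovery(seed: int = 1, n_replicates: int = 20) -> float:
    """Mean Pearson r between true and inferred node effects.

    30 backbone nodes, 60 edges, 10 genes per node, effect sd 1, noise sd
    0.2, fresh model and data each replicate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                       spawn_key=(13,)))
    rs = []
    for _ in range(n_replicates):
        config = SynthConfig(n_backbone=30, n_edges=60, genes_per_node=10,
                             effect_sd=1.0, noise_sd=0.2,
                             seed=int(rng.integers(2 ** 31 - 1)))
        truth = generate_model(config, rng)
        table = simulate_expression(truth, config.noise_sd, rng)
        matched, _ = match_expression(truth.model, table)
        system = assemble_system(truth.model, matched)
        state = infer_backbone(system, system.align_beta(matched))
        r, _ = recovery_metrics(truth.f_true, state.as_dict())
        rs.append(r)
    return float(np.mean(rs))


def run_benchmarks(seed: int = 1, quick: bool = False
                   ) -> list[tuple[str, float, int, str]]:
    """All suites; returns (name, value, n, criterion description) rows."""
    n_models = 20 if quick else 100
    n_datasets = 50 if quick else 500
    n_runs = 20 if quick else 100
    n_reps = 5 if quick else 20
    rows: list[tuple[str, float, int, str]] = []
    rows.append(("oracle_max_rel_error", oracle_equivalence(seed, n_models),
                 n_models, "<= 1e-8"))
    model = toy_model()
    table = toy_expression()
    matched, _ = match_expression(model, table)
    system = assemble_system(model, matched)
    state = infer_backbone(system, system.align_beta(matched))
    score, _, _ = npa_score(state)
    rows.append(("toy_score", score, 2, "= 4.0"))
    rows.append(("null_calibration_rate",
                 null_calibration(seed, n_datasets), n_datasets,
                 "in [0.03, 0.07]"))
    power_o, power_k, decoy = power_specificity(seed, n_runs)
    rows.append(("power_rate_O", power_o, n_runs, ">= 0.95"))
    rows.append(("power_rate_K", power_k, n_runs, ">= 0.95"))
    rows.append(("decoy_null_rate", decoy, n_runs, ">= 0.90"))
    rows.append(("recovery_pearson_r", parameter_recovery(seed, n_reps),
                 n_reps, ">= 0.9"))
    return rows
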