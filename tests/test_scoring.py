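"""NPA engine: matching, assembly, inference, scores, CIs, leading nodes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cbnpa.benchmarks import least_squares_reference
from cbnpa.layers import DownstreamEdge, TwoLayerModel
from cbnpa.network import CausalEdge, CausalNetwork
from cbnpa.scoring import (ExpressionTable, ScoringWarning, assemble_system,
                           collapse_probes, confidence_interval,
                           infer_backbone, leading_nodes, leading_subnetwork,
                           match_expression, npa_score)
from cbnpa.simulate import SynthConfig, generate_model, simulate_expression

from conftest import make_model


def _pipeline_f(model, table, ridge=1e-10):
    matched, _ = match_expression(model, table)
    system = assemble_system(model, matched, ridge=ridge)
    return system, infer_backbone(system, system.align_beta(matched))


class TestExpressionTable:
    def test_from_frame_with_se(self):
        df = pd.DataFrame({"gene": ["A", "B"], "logFC": [1.0, -2.0],
                           "SE": [0.5, 2.0]})
        t = ExpressionTable.from_frame(df)
        assert np.allclose(t.variance, [0.25, 4.0])

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="collapse"):
            ExpressionTable(["A", "a"], [1.0, 2.0], [0.1, 0.1])

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTable(["A"], [1.0], [-0.1])

    def test_collapse_probes_mean_beta_mean_var_over_n(self):
        df = pd.DataFrame({"gene": ["A", "A", "B"], "logFC": [1.0, 3.0, 5.0],
                           "variance": [0.2, 0.4, 0.9]})
        out = collapse_probes(df)
        a = out[out.gene == "A"].iloc[0]
        assert a.beta == pytest.approx(2.0)
        assert a.variance == pytest.approx(0.3 / 2)
        assert out[out.gene == "B"].iloc[0].variance == pytest.approx(0.9)


class TestMatchExpression:
    def test_partial_coverage_warns(self, toy):
        table = ExpressionTable(["G1", "XX"], [1.0, 2.0], [0.0, 0.0])
        with pytest.warns(ScoringWarning):
            matched, coverage = match_expression(toy, table)
        assert coverage == 0.5
        assert list(matched.genes) == ["G1"]

    def test_case_insensitive(self, toy):
        table = ExpressionTable(["g1", "g2"], [1.0, 2.0], [0.0, 0.0])
        matched, coverage = match_expression(toy, table)
        assert coverage == 1.0
        assert sorted(matched.genes) == ["G1", "G2"]

    def test_disjoint_genes_error(self, toy):
        table = ExpressionTable(["XX"], [1.0], [0.0])
        with pytest.raises(ValueError, match="no measurable overlap"):
            match_expression(toy, table)


class TestAssembleSystem:
    def test_worked_toy_matrices(self, toy, toy_beta):
        matched, _ = match_expression(toy, toy_beta)
        system = assemble_system(toy, matched, ridge=0.0)
        assert system.backbone_index == ["p(SYN:X)", "p(SYN:Y)"]
        assert system.gene_index == ["G1", "G2"]
        assert np.allclose(system.L_bb, [[2, -1], [-1, 2]])
        assert np.allclose(system.L_bg, [[-1, 0], [0, 1]])

    def test_single_node_no_edges(self):
        model, _ = make_model([], [("a", "G1", 1)], extra_nodes=["a"])
        table = ExpressionTable(["G1"], [1.0], [0.0])
        matched, _ = match_expression(model, table)
        system = assemble_system(model, matched, ridge=0.0)
        assert np.allclose(system.L_bb, [[1.0]])

    def test_unmatched_gene_column_absent(self, toy):
        table = ExpressionTable(["G1"], [2.0], [0.0])
        with pytest.warns(ScoringWarning):
            matched, _ = match_expression(toy, table)
        system = assemble_system(toy, matched)
        assert system.gene_index == ["G1"]
        assert system.L_bg.shape == (2, 1)

    def test_component_without_matched_genes_dropped(self):
        model, ids = make_model([("a", "b", 1), ("c", "d", 1)],
                                [("a", "G1", 1), ("c", "G2", 1)])
        table = ExpressionTable(["G1"], [1.0], [0.0])
        with pytest.warns(ScoringWarning):
            matched, _ = match_expression(model, table)
        with pytest.warns(ScoringWarning, match="dropped"):
            system = assemble_system(model, matched)
        assert set(system.backbone_index) == {ids["a"], ids["b"]}


class TestInference:
    def test_worked_toy(self, toy, toy_beta):
        _, state = _pipeline_f(toy, toy_beta)
        f = state.as_dict()
        assert f["p(SYN:X)"] == pytest.approx(2.0, abs=1e-6)
        assert f["p(SYN:Y)"] == pytest.approx(2.0, abs=1e-6)

    def test_zero_beta_gives_zero_state(self, toy):
        table = ExpressionTable(["G1", "G2"], [0.0, 0.0], [0.0, 0.0])
        _, state = _pipeline_f(toy, table)
        assert np.allclose(state.values, 0.0)

    def test_linearity_in_beta(self, toy, toy_beta):
        _, state1 = _pipeline_f(toy, toy_beta)
        scaled = ExpressionTable(toy_beta.genes, 3 * toy_beta.beta,
                                 toy_beta.variance)
        _, state3 = _pipeline_f(toy, scaled)
        assert np.allclose(state3.values, 3 * state1.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        config = SynthConfig(n_backbone=6, n_edges=9, genes_per_node=2,
                             seed=seed)
        truth = generate_model(config, rng)
        table = simulate_expression(truth, 0.3, rng)
        _, state = _pipeline_f(truth.model, table)
        ref = least_squares_reference(truth.model, table)
        for node, value in state.as_dict().items():
            assert value == pytest.approx(ref[node], rel=1e-8, abs=1e-10)


class TestScore:
    def test_worked_toy_mean_square(self, toy, toy_beta):
        _, state = _pipeline_f(toy, toy_beta)
        score, contributions, directions = npa_score(state)
        assert score == pytest.approx(4.0, abs=1e-6)
        assert contributions["p(SYN:X)"] == pytest.approx(2.0, abs=1e-6)
        assert directions == {"p(SYN:X)": 1, "p(SYN:Y)": 1}

    def test_gauge_flip_preserves_score_and_flips_direction(
            self, toy_flipped, toy_beta):
        _, state = _pipeline_f(toy_flipped, toy_beta)
        score, _, directions = npa_score(state)
        f = state.as_dict()
        assert f["p(SYN:X)"] == pytest.approx(2.0, abs=1e-6)
        assert f["p(SYN:Y)"] == pytest.approx(-2.0, abs=1e-6)
        assert score == pytest.approx(4.0, abs=1e-6)
        assert directions["p(SYN:Y)"] == -1

    def test_zero_state(self, toy):
        table = ExpressionTable(["G1", "G2"], [0.0, 0.0], [0.0, 0.0])
        _, state = _pipeline_f(toy, table)
        score, contributions, directions = npa_score(state)
        assert score == 0.0
        assert all(v == 0 for v in contributions.values())
        assert all(v == 0 for v in directions.values())

    def test_contributions_sum_to_score_both_modes(self, rng):
        config = SynthConfig(n_backbone=12, n_edges=20, genes_per_node=3,
                             seed=5)
        truth = generate_model(config, rng)
        table = simulate_expression(truth, 0.3, rng)
        _, state = _pipeline_f(truth.model, table)
        for mode in ("mean-square", "backbone-laplacian"):
            score, contributions, _ = npa_score(state, mode=mode)
            total = sum(contributions.values())
            assert total == pytest.approx(score, rel=1e-9)

    def test_unknown_mode_rejected(self, toy, toy_beta):
        _, state = _pipeline_f(toy, toy_beta)
        with pytest.raises(ValueError):
            npa_score(state, mode="bogus")


class TestConfidenceInterval:
    def test_zero_variance_collapses_to_score(self, toy, toy_beta):
        system, state = _pipeline_f(toy, toy_beta)
        score, _, _ = npa_score(state)
        lo, hi = confidence_interval(system, system.align_beta(
            match_expression(toy, toy_beta)[0]), np.zeros(2))
        assert lo == pytest.approx(score) and hi == pytest.approx(score)

    def test_gradient_matches_finite_differences(self, toy, toy_beta):
        system, _ = _pipeline_f(toy, toy_beta)
        matched, _ = match_expression(toy, toy_beta)
        beta = system.align_beta(matched)

        def full_score(b):
            state = infer_backbone(system, b)
            return npa_score(state)[0]

        # recover the implied gradient from the delta-method half-width
        variances = np.zeros(2)
        h = 1e-6
        for g in range(2):
            e = np.zeros(2)
            e[g] = 1.0
            fd = (full_score(beta + h * e) - full_score(beta - h * e)) / (2 * h)
            variances[:] = 0.0
            variances[g] = 1.0
            lo, hi = confidence_interval(system, beta, variances, level=0.95)
            from scipy.stats import norm
            implied = (hi - lo) / 2 / norm.ppf(0.975)
            assert implied == pytest.approx(abs(fd), rel=1e-6)

    def test_doubling_variances_scales_halfwidth_sqrt2(self, toy, toy_beta):
        system, _ = _pipeline_f(toy, toy_beta)
        matched, _ = match_expression(toy, toy_beta)
        beta = system.align_beta(matched)
        lo1, hi1 = confidence_interval(system, beta, np.ones(2))
        lo2, hi2 = confidence_interval(system, beta, 2 * np.ones(2))
        assert (hi2 - lo2) == pytest.approx(np.sqrt(2) * (hi1 - lo1))

    def test_negative_variance_rejected(self, toy, toy_beta):
        system, _ = _pipeline_f(toy, toy_beta)
        with pytest.raises(ValueError):
            confidence_interval(system, np.array([2.0, -2.0]),
                                np.array([1.0, -1.0]))

    def test_monte_carlo_agrees_with_delta_roughly(self, toy, toy_beta):
        system, _ = _pipeline_f(toy, toy_beta)
        matched, _ = match_expression(toy, toy_beta)
        beta = system.align_beta(matched)
        var = 0.25 * np.ones(2)
        lo_d, hi_d = confidence_interval(system, beta, var)
        lo_m, hi_m = confidence_interval(
            system, beta, var, method="monte-carlo", n_draws=20000,
            rng=np.random.default_rng(0))
        assert hi_m - lo_m == pytest.approx(hi_d - lo_d, rel=0.15)


class TestLeadingNodes:
    def test_eighty_percent_rule(self):
        leading = leading_nodes({"a": 0.6, "b": 0.3, "c": 0.1})
        assert [ln.node for ln in leading] == ["a", "b"]
        assert leading[-1].cum_pct == pytest.approx(90.0)

    def test_single_node(self):
        leading = leading_nodes({"a": 5.0})
        assert [ln.node for ln in leading] == ["a"]
        assert leading[0].pct == pytest.approx(100.0)

    def test_equal_split_needs_both(self):
        leading = leading_nodes({"a": 0.5, "b": 0.5})
        assert len(leading) == 2

    def test_all_zero_warns_and_returns_empty(self):
        with pytest.warns(ScoringWarning):
            assert leading_nodes({"a": 0.0, "b": 0.0}) == []

    def test_minimality(self):
        contributions = {f"n{i}": c for i, c in
                         enumerate([0.4, 0.25, 0.2, 0.1, 0.05])}
        leading = leading_nodes(contributions, threshold=0.8)
        cum = [ln.cum_pct for ln in leading]
        assert cum[-1] >= 80.0
        assert all(c < 80.0 for c in cum[:-1])

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            leading_nodes({"a": 1.0}, threshold=0.0)


class TestLeadingSubnetwork:
    def test_all_nodes_gives_backbone(self, toy, toy_beta):
        _, state = _pipeline_f(toy, toy_beta)
        _, contributions, directions = npa_score(state)
        leading = leading_nodes(contributions, threshold=1.0,
                                directions=directions)
        sub = leading_subnetwork(toy, leading)
        assert set(sub.nodes) == set(toy.backbone.nodes)
        assert len(sub.edges) == len(toy.backbone.edges)
        assert sub.node_attrs["p(SYN:X)"]["direction"] == 1

    def test_single_node_no_edges(self, toy):
        from cbnpa.scoring import LeadingNode
        sub = leading_subnetwork(
            toy, [LeadingNode("p(SYN:X)", 2.0, 100.0, 100.0, 1, 1)])
        assert list(sub.nodes) == ["p(SYN:X)"] and sub.edges == []

    def test_unknown_node_rejected(self, toy):
        from cbnpa.scoring import LeadingNode
        with pytest.raises(ValueError):
            leading_subnetwork(
                toy, [LeadingNode("p(SYN:ZZ)", 1.0, 100.0, 100.0, 1, 0)])


# ------------------------------------------------------------------
# properties

def _flip_gauge(model, flip_nodes):
    """Switching transformation: negate all signs incident to flip_nodes."""
    edges = []
    for e in model.backbone.edges:
        sign = e.sign
        if (e.source in flip_nodes) != (e.target in flip_nodes):
            sign = -sign
        edges.append(CausalEdge(e.source, e.target, sign, direct=e.direct,
                                weight=e.weight,
                                evidence_count=e.evidence_count))
    downstream = [
        DownstreamEdge(d.backbone_node, d.gene,
                       -d.sign if d.backbone_node in flip_nodes else d.sign,
                       d.weight)
        for d in model.downstream]
    backbone = CausalNetwork(nodes=dict(model.backbone.nodes), edges=edges)
    return TwoLayerModel(backbone, downstream, model.name)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), flip_mask=st.integers(0, 255))
def test_gauge_invariance(seed, flip_mask):
    rng = np.random.default_rng(seed)
    config = SynthConfig(n_backbone=8, n_edges=14, genes_per_node=2,
                         seed=seed)
    truth = generate_model(config, rng)
    table = simulate_expression(truth, 0.3, rng)
    system, state = _pipeline_f(truth.model, table)
    flip_nodes = {nid for i, nid in enumerate(system.backbone_index)
                  if flip_mask >> i & 1}
    flipped = _flip_gauge(truth.model, flip_nodes)
    system_f, state_f = _pipeline_f(flipped, table)
    score, _, _ = npa_score(state)
    score_f, _, _ = npa_score(state_f)
    assert score_f == pytest.approx(score, rel=1e-9, abs=1e-12)
    f, ff = state.as_dict(), state_f.as_dict()
    for nid in f:
        expected = -f[nid] if nid in flip_nodes else f[nid]
        assert ff[nid] == pytest.approx(expected, rel=1e-8, abs=1e-10)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000),
       c=st.floats(-5, 5, allow_nan=False).filter(lambda x: abs(x) > 1e-3))
def test_score_homogeneity(seed, c):
    rng = np.random.default_rng(seed)
    config = SynthConfig(n_backbone=6, n_edges=8, genes_per_node=2, seed=seed)
    truth = generate_model(config, rng)
    table = simulate_expression(truth, 0.3, rng)
    _, state = _pipeline_f(truth.model, table)
    scaled = ExpressionTable(table.genes, c * table.beta, table.variance)
    _, state_c = _pipeline_f(truth.model, scaled)
    assert npa_score(state_c)[0] == pytest.approx(
        c ** 2 * npa_score(state)[0], rel=1e-9)


def test_score_invariant_under_dropped_isolated_component(rng):
    """|V_b| counts scored nodes only, so an unmatched extra component
    changes nothing."""
    model, ids = make_model([("a", "b", 1)], [("a", "G1", 1),
                                              ("b", "G2", -1)])
    table = ExpressionTable(["G1", "G2"], [2.0, -2.0], [0.0, 0.0])
    _, state = _pipeline_f(model, table)
    base_score = npa_score(state)[0]
    bigger, _ = make_model([("a", "b", 1), ("u", "v", 1)],
                           [("a", "G1", 1), ("b", "G2", -1)])
    with pytest.warns(ScoringWarning):
        _, state2 = _pipeline_f(bigger, table)
    assert npa_score(state2)[0] == pytest.approx(base_score, rel=1e-12)
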