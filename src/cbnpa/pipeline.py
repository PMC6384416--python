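"""End-to-end orchestration: model + expression table -> annotated NPAResult."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .layers import TwoLayerModel, trim_dangling
from .permutation import (PermutationConfig, PermutationNull,
                          annotate_significance, permutation_pvalue)
from .scoring import (ExpressionTable, NPAResult, assemble_system,
                      confidence_interval, infer_backbone, leading_nodes,
                      leading_subnetwork, match_expression, npa_score)

__all__ = ["score_pipeline", "PipelineOutput"]


@dataclass
class PipelineOutput:
    result: NPAResult
    state: "object"            # BackboneState
    system: "object"           # LaplacianSystem
    o_null: Optional[PermutationNull]
    k_null: Optional[PermutationNull]
    subnetwork: "object"       # CausalNetwork of leading nodes


def score_pipeline(model: TwoLayerModel, table: ExpressionTable, *,
                   trim: bool = False, mode: str = "mean-square",
                   ridge: float = 1e-10, level: float = 0.95,
                   leading_threshold: float = 0.8,
                   n_perm: int = 500, seed: int = 0,
                   alpha_strong: float = 0.05, alpha_weak: float = 0.1,
                   exhaustive: bool = False,
                   with_permutations: bool = True,
                   ci_method: str = "delta") -> PipelineOutput:
    """Run match -> assemble -> infer -> score -> CI -> O/K -> leading nodes.

    One master ``seed`` drives both permutation statistics through
    independent child streams, so re-running with the same seed reproduces
    every p-value bit-for-bit.
    """
    if trim:
        model, _ = trim_dangling(model)
    matched, coverage = match_expression(model, table)
    system = assemble_system(model, matched, ridge=ridge)
    beta = system.align_beta(matched)
    variances = system.align_variance(matched)
    state = infer_backbone(system, beta)
    score, contributions, directions = npa_score(state, mode=mode)
    ci_low, ci_high = confidence_interval(
        system, beta, variances, level=level, mode=mode, method=ci_method,
        rng=np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(2,))))
    leading = leading_nodes(contributions, threshold=leading_threshold,
                            directions=directions)
    result = NPAResult(score=score, ci_low=ci_low, ci_high=ci_high,
                       contributions=contributions, directions=directions,
                       leading=leading, mode=mode, coverage=coverage)
    o_null = k_null = None
    config = PermutationConfig("O", n_perm=n_perm, seed=seed,
                               alpha_strong=alpha_strong,
                               alpha_weak=alpha_weak, exhaustive=exhaustive)
    if with_permutations:
        o_null = permutation_pvalue(model, table, config, mode=mode,
                                    ridge=ridge)
        if len(model.backbone.edges) >= 2:
            k_null = permutation_pvalue(
                model, table,
                PermutationConfig("K", n_perm=n_perm, seed=seed,
                                  alpha_strong=alpha_strong,
                                  alpha_weak=alpha_weak,
                                  exhaustive=exhaustive),
                mode=mode, ridge=ridge)
    result = annotate_significance(result, o_null, k_null, config)
    subnetwork = leading_subnetwork(model, leading)
    return PipelineOutput(result, state, system, o_null, k_null, subnetwork)
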