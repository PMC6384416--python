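# Methods

## Model compilation

Causal statements are parsed from a restricted BEL 1.0 dialect: entity-level
terms `p()`, `r()`, `a()`, `bp()`, `complex()` and `act()` wrappers, and the
four causal relations `increases`, `directlyIncreases`, `decreases`,
`directlyDecreases`. Statements with any other relation are retained as
`unsupported` and never produce edges; other BEL constructs (`tloc`, `deg`,
`pmod`, ...) are rejected outright because entity-level causal relations are
the only substrate this scoring model uses. Script-level `SET`/`UNSET`
lines scope annotations (species, tissue, ...) onto statements.

Compilation merges parallel same-sign statements into one edge with an
incremented evidence count (edge weight stays 1 by default — evidence
volume is curation intensity, not effect size; `weight_by_evidence`
optionally overrides this). Opposite-sign edges between the same pair are
kept side by side: contradictions in the literature are captured, not
adjudicated. An activity term `act(p(X))` denotes the same backbone entity
as `p(X)` — the wrapper collapses for node identity and is recorded on the
edge. How the published backbones merged activity terms is not documented;
this collapse rule is this package's own convention.

## Two-layer split and trimming

RNA nodes are removed from the backbone: each backbone→RNA edge becomes a
downstream link (gene = the RNA identifier, sign = the edge sign). Edges
*out of* RNA nodes are dropped with a warning — in the reverse-causal
reading, transcripts are measurements, not causes. A (node, gene) pair with
contradictory downstream signs carries no usable direction and is dropped
with a warning.

Trimming removes backbone nodes with no *directed* path to any
`bioprocess` node ("hanging" nodes that never lead to a described
process); an undirected variant is available. One reachability pass is
already a fixpoint — a removed node cannot lie on a surviving node's path
to a process — but the implementation loops to a fixpoint anyway and
reports the pass count. Models with no bioprocess node raise unless
trimming is explicitly skipped.

## Inference

Backbone differential values minimize

    Σ_bb w (f(x) − σ f(y))² + Σ_ds w (f(x) − s β_g)² + ridge · Σ f²,

solved in closed form via the signed Laplacian: `L_bb f = −L_bg β`, where
`L_bb[x,x]` = total absolute incident weight (backbone + *matched*
downstream) + ridge, `L_bb[x,y] = −Σ σw` over backbone edges between x and
y, and `L_bg[x,g] = −s·w`. Only matched downstream links (genes present in
the expression table, matched case-insensitively) enter the objective, so
only they contribute diagonal mass. Backbone edges are treated as
undirected and signed here: diffusion-style inference needs a symmetric
operator, and information flows from measured genes up into the backbone;
direction is kept for trimming and display.

Numerical choices: ridge = 1e−10 on the diagonal (numerical safety on
graphs whose anchoring is weak); the solve refuses matrices with condition
number > 1e12 and points to `validate_model`; components with no matched
downstream gene are dropped with a warning before assembly (they are
unidentifiable); self-loop edges are skipped (a positive self-loop imposes
no constraint); direction calls use a zero tolerance of 1e−12. Multiple
probes per gene must be collapsed beforehand (`collapse_probes`: mean β,
mean variance / n — probes treated as independent replicate measurements).

The solver is validated against an independent oracle that stacks the same
objective into an explicit least-squares design matrix and solves it with
`numpy.linalg.lstsq`; the two routes agree to ~1e−14 relative on random
models (`scripts/acceptance.py` reports the measured maximum).

## Score, contributions, intervals

Default score: mean-square amplitude `(1/|V_b|) Σ f(x)²` with
contributions `f(x)²/|V_b|` — non-negative, summing exactly to the score,
and invariant under sign (gauge) transformations of the network. |V_b|
counts *scored* nodes only, so dropping an unmatched component does not
dilute the score. The alternative `backbone-laplacian` mode uses
`(1/|V_b|) fᵀL̃f` with the backbone-only signed Laplacian; its
contributions `f(x)(L̃f)(x)/|V_b|` can be negative and are flagged. The
exact quadratic form used by the original NPA implementations is not
reproduced here; every result records which mode produced it.

Confidence intervals use the first-order delta method through the linear
map `M = −L_bb⁻¹L_bg`: `Var(score) ≈ Σ_g (∂score/∂β_g)² Var(β_g)` at the
observed β (gradient `2fᵀM/|V_b|` in mean-square mode), with a normal
quantile at the requested level. How the original intervals were computed
is not documented; the delta method is the default and a Monte-Carlo
interval (resampling β ~ Normal(β, Var)) is available. The `star` flag
means the interval excludes zero.

Leading nodes: sort by |contribution| (ties by node id) and take the
shortest prefix reaching 80 % of the total absolute contribution — the set
size adapts when many contributions are nearly equal. The induced subgraph
on that set, annotated with directions and contributions, is exported for
inspection.

## O/K permutation statistics

O permutes gene labels across downstream slots (signs stay with slots); K
permutes backbone edge heads (tails, signs, weights stay with edges;
self-loops re-drawn up to 100 times, then accepted). These are the
smallest perturbations that destroy, respectively, the gene-to-backbone
biology and the backbone wiring while preserving graph scale; K preserves
the tail-degree sequence, a choice recorded in the output metadata. Each
permutation re-runs assemble→infer→score with the unchanged table
(implemented by an array-based core whose equality with the public
pipeline is asserted exhaustively in the tests). p-values use the add-one
estimator `(1 + #{≥ observed})/(n_perm + 1)`; an exhaustive mode
enumerates all permutations when there are ≤ 10 000. One master seed
derives independent child streams for O and K, so runs are bit-for-bit
reproducible. Permutations that strand a backbone component without
matched genes are re-drawn (bounded by 10·n_perm). Flags: strong below
α = 0.05, weak in [0.05, 0.1).

## Synthetic data

The generator emulates the statistical structure the scoring assumes, not
any particular microarray study: a uniform random spanning tree plus
random chords (connected by construction; node 0 is the single bioprocess
node and tree edges are oriented toward it), edge signs negative with
probability `p_negative` = 0.3 by default (curated causal networks skew
activating), and `genes_per_node` = 10 private gene symbols per node with
equiprobable downstream signs. Default scale is 30 backbone nodes / 60
edges. True node effects are i.i.d. Normal(0, effect_sd²) by default; the
`coherent` mode propagates a root value of `effect_sd` through edge signs
(chord signs made consistent with the propagated values), producing a
fully network-consistent truth. Fold-changes are `β_g = s·f_true(x) + ε`,
ε ~ Normal(0, noise_sd²), with the reported variance `noise_sd²` —
β and its variance are generated directly, with no replicate-level
expression matrix or moderated-statistics fitting, because the scoring
consumes (β, Var) regardless of origin.

What passing synthetic tests shows — and what it does not: calibration,
power, specificity and recovery hold under clean Gaussian noise,
one-to-one gene-to-node assignment and full coverage. Real
differential-expression tables have correlated errors, shared genes across
backbone nodes, partial coverage and annotation noise; the pipeline
handles those inputs but the synthetic guarantees do not automatically
transfer.

## Validation suites (problem sizes)

* Oracle agreement: 100 random models with 2–8 backbone nodes.
* Calibration: one fixed 30/60/10 model, 500 pure-noise datasets
  (noise sd 1), 200 O-permutations each; rejection rate at 0.05 expected
  in [0.03, 0.07]. Validity follows from exchangeability of the observed
  score with the permuted scores under i.i.d. β.
* Power/specificity: 100 runs, coherent truth (effect 1, noise sd 0.1) —
  only network-consistent truth gives the K statistic anything to detect,
  since i.i.d. node effects carry no information about wiring; decoy
  check renames the same data onto an independently generated,
  gene-disjoint model.
* Recovery: 20 replicates at 30/60/10, effect sd 1, noise sd 0.2
  (default i.i.d. truth); mean Pearson r between true and inferred values.

These sizes keep the full suite under a minute on one CPU while leaving
the binomial error of the rate estimates well inside the stated bands.

## Known limitations

* Full BEL (modifications, translocations, nested statements) is out of
  scope, as are namespace validation, text mining and graph layout.
* The published mucociliary-clearance models are not redistributable with
  the package; the count benchmarks against them run only when the files
  are downloaded into `data/published/`.
* Coverage below 50 % warns (at most half the downstream layer anchored);
  the score is still computed but increasingly reflects the covered
  subnetwork.
* The K statistic rewires heads only; degree-sequence-preserving rewiring
  is not implemented.
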