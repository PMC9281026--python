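# Methods

## Problem setting

The package targets binary outcome prediction on wide clinical tables —
the motivating case is postpartum hemorrhage (PPH, blood loss > 500 mL
within 24 h of vaginal delivery) predicted from ~149 per-delivery
features in a cohort of ~11,000 records with ~9.5% prevalence. Two
obstacles shape the design: the outcome is rare, and most recorded
features are irrelevant, so the pipeline couples a wrapper feature
selector with a representation-learning classifier and tunes the
classifier's hyperparameters against cross-validated error.

Real cohorts of this kind are not shareable; every experiment in this
repository therefore runs on synthetic data with planted ground truth
(see "Synthetic data" below), and the tests measure recovery of that
ground truth rather than claiming clinical performance.

## Oppositional binary crow search (feature selection)

Each of `n_crows` crows holds a continuous position `x ∈ [0,1]^d` over
the `d` feature axes and a memory `M` of the best position it has found.
Per iteration every crow follows a uniformly chosen flockmate `j`:

    x ← clamp( x + τ · fl · (M_j − x) ),    τ ~ U(0,1),

unless an awareness escape fires (probability `AP`), in which case the
crow jumps to a fresh uniform position. A mask is obtained by strict
thresholding (`x_k > 0.5` selects feature k; an exact tie excludes) and
scored with the wrapper cost

    cost(mask) = (1 − C) + W · (F_sub / F_all),

where `C` is the cross-validated accuracy of a cheap reference
classifier on the masked features, `F_sub` the subset size and `W` a
small parsimony weight. Lower is better. An empty mask is infeasible and
is assigned `+inf` rather than evaluated. A configuration flag
(`as_printed`) exposes the alternative cost form
`C + W·(1 − F_all/F_sub)` for comparison; it is not the default because
its size term is negative and dominant for small subsets, which
contradicts the intended minimisation.

Opposition-based learning is applied to the flight length: each follow
move draws `fl ~ U(fl_min, fl_max)` and evaluates the candidate
positions under both `fl` and its reflection `fl_min + fl_max − fl`
(sharing τ), keeping the cheaper. The reflection is an involution and
maps the admissible interval onto itself. Ownership of `fl` (global,
per-crow or per-move) is not canonical in the algorithm's literature; it
is drawn per crow per iteration here so that every move explores a
short-step/long-step pair.

Defaults: 25 crows, `AP = 0.3`, `fl ∈ [0.1, 1.8]`, 100 iterations,
`W = 0.01`, threshold 0.5. `W = 0.01` makes accuracy dominate while
parsimony breaks ties between equally accurate subsets. The evaluator
`C` is 5-fold cross-validated 1-nearest-neighbour accuracy on
per-fold-standardized masked features — parameterless, fast, and
deterministic given its seed — and is pluggable so that the full
autoencoder can stand in at small scale. Mask costs are cached by the
binarized mask, which is what makes the full default budget cheap: the
flock revisits masks constantly once memories converge.

Bookkeeping: `cost_history[t]` records the best memory cost *entering*
iteration t, so a `t_max = 1` run reports the minimum over the initial
flock; `best_cost` is read after the final iteration's memory updates
and can therefore undercut `cost_history[-1]`. Memory costs never
increase, so the history is non-increasing.

## Sparse stacked autoencoder (classification)

One layer maps `h = σ(Wx + b)` and reconstructs `x̂ = σ(W′h + b′)` with
the logistic σ. The pretraining loss per batch of N samples is

    E = (1/N) Σᵢ ½‖x̂ᵢ − xᵢ‖² + (λ/2)(‖W‖²_F + ‖W′‖²_F) + β KL(ρ̂ ‖ ρ),
    KL(ρ̂ ‖ ρ) = Σⱼ [ ρ ln(ρ/ρ̂ⱼ) + (1−ρ) ln((1−ρ)/(1−ρ̂ⱼ)) ],

with `ρ̂ⱼ` the batch-mean activation of hidden unit j, λ the weight
decay, β the sparsity weight and ρ the sparsity target. Logarithms are
natural. `ρ̂` is a per-mini-batch estimate by default (a full-batch mode
exists); it is clipped to `[1e−6, 1 − 1e−6]` with a warning before the
KL term, since a saturated unit would otherwise produce infinities.

Layers are pretrained greedily — each on the previous layer's code —
by plain mini-batch gradient descent (no momentum). Weights initialize
symmetric-uniform with half-width `√(6/(fan_in+fan_out))` unless an
explicit `init_scale` is given; biases start at zero. A softmax head is
then attached to the last code (zero-initialized, hence uniform
probabilities before fine-tuning, which the tests exploit as a ln 2
fixed point) and the encoder path plus head is fine-tuned end to end on
the multinomial cross-entropy, computed through a log-sum-exp. Decoder
parameters are frozen after pretraining (configurable): fine-tuning
treats the network as the feed-forward classifier path. Encoder/decoder
weights are untied.

Inputs are min–max scaled to [0,1] per feature (constant training
columns map to 0) because sigmoid reconstruction targets require bounded
inputs; the scaler is part of the model. All gradients are analytic and
are verified in the tests against central finite differences using the
norm-ratio statistic `‖g_num − g_ana‖ / (‖g_num‖ + ‖g_ana‖) < 1e−5`
(elementwise relative comparison is meaningless for near-zero entries,
where finite differences lose precision). Argmax prediction breaks ties
toward the lower class index. Two fits with the same config, data and
seed are bit-identical.

Defaults (one hidden layer of 32, lr 0.5, 20 pretraining and 100
fine-tuning epochs, batch 32, λ=1e−4, β=0.1, ρ=0.1) were chosen so that
plain gradient descent trains to convergence on the desk-scale synthetic
cohorts; all of them are exposed to the tuner.

## Equilibrium optimizer (hyperparameter tuning)

EO treats candidate solutions as concentrations relaxing toward an
equilibrium pool — the four best solutions found so far plus their
elementwise mean, sampled uniformly per particle per iteration. With
`t = (1 − Iter/Max_iter)^(a₂·Iter/Max_iter)` decreasing from 1 to 0, a
fresh turnover vector `λ ~ U(0,1)^d` and direction draws `r`:

    F = a₁ · sign(r − 0.5) · (e^(−λt) − 1)
    GCP = 0.5·r₁ if r₂ ≥ GP else 0          (scalar per update)
    G = GCP · (C_eq − λ∘C) ∘ F
    C ← C_eq + (C − C_eq)∘F + (G/(λV))·(1 − F),  clamped to the box.

Defaults `a₁ = 2`, `a₂ = 1`, `GP = 0.5`, `V = 1`. `sign(0)` is defined
as 0. λ is floored at 1e−12 only inside the division. The exponent form
of `t` is used (a literal product form, also implemented behind
`as_printed`, would pin t to 0 at the first iteration and cannot play
the decay role the update requires). The pool updates greedily, so the
best-cost history is non-increasing; populations smaller than four pad
the pool by replicating the best member.

The tuning objective is stratified k-fold (default 10) cross-validated
error of the decoded classifier on the training split: `fitness = 1 −
mean fold fraction-correct`. A fold that diverges during training is
assigned the worst fitness (1.0) with a warning so the search continues.
The search box (`HyperSpace`) names each dimension, log-scales those
spanning decades (weight decay 1e−6..1e−2, sparsity weight 1e−3..3,
learning rate 0.01..1) and rounds integer ones (hidden width 8..64);
sparsity target is linear in 0.02..0.5. EO tunes hyperparameters, not
raw weights: the fitness is defined over cross-validated accuracy, which
is a hyperparameter-level objective, and direct weight search at
149-feature scale is implausible — though nothing prevents pointing
`run_eo` at a flattened-parameter objective for toy networks.

## Metrics

Positive class = outcome present (the minority). From the 2×2 confusion
matrix: precision, recall, accuracy, F (harmonic mean of P and R),
MCC, error rate = 1 − accuracy. Zero-denominator ratios return 0 with a
degeneracy flag instead of raising. ROC is a threshold sweep over
grouped unique scores with trapezoidal AUC (ties move diagonally);
it matches the reference implementation in scikit-learn exactly, which
the tests assert as an independent cross-check. Multi-run aggregation is
the arithmetic mean per metric (confusion matrices are summed); display
rounding is 4 decimals, stored values full precision.

## Pipeline and reproducibility

Per run r: seed_r = master_seed + r; stratified 70/30 split (the
evaluation protocol for the source cohort is not canonical; 70/30 is the
conventional default and configurable); crow-search selection on the
training split; EO tuning on the training split restricted to the
selected mask; final fit on the full training split; single evaluation
on the untouched test split. "Ten dissimilar runs" are realized as ten
split seeds. Feature re-selection per run is the default; a reuse-run-0
mask mode exists. Each stage's training-row identity is checksummed into
the run artifacts, and the tests assert all stages saw exactly the
split's training rows — the leakage guard. The whole pipeline is
bit-reproducible from the master seed.

## Synthetic data

`generate_pph_like` emulates the target cohort's shape: labels are
independent Bernoulli(prevalence) (an exact-count mode exists),
a random subset of `n_informative` columns is shifted by
`effect_size · noise_sd` in the positive class, and all columns carry
Normal(0, noise_sd²) noise. Defaults are the cohort shape itself:
n = 11,000, p = 149, prevalence 1042/11000, 15 informative columns,
effect size 1.5 SD. This is the simplest structure under which wrapper
selection recovery is measurable against ground truth. It deliberately
omits: correlated features, mixed types and codes, nonlinear or
interaction effects, label noise, and missingness (loading rejects
missing values rather than imputing). Passing tests therefore
demonstrate algorithmic correctness and recoverability of independent
additive signal — not performance on real obstetric data.

## Problem sizes used in the checks

The test suite and the acceptance script run at desk scale: cohorts of
120–600 rows for training-loop checks, the full 11,000 × 149 shape only
for label-count and fold-partition checks, selector recovery on
600 × 149 with 15 planted features, and a 2-run smoke pipeline
(600 × 30, 6 informative, prevalence 0.3) with reduced search budgets
(6 crows × 8 iterations; 4 EO particles × 2 iterations; 3-fold CV).
Mask-cost caching makes the selector's full default budget (25 crows ×
100 iterations) affordable, and the planted-feature significance check
runs at that budget: at the reduced budget (10 crows × 25 iterations)
the search reliably *enriches* for planted features (overlap above the
hypergeometric expectation at every seed tried) but leaves ~70-feature
masks, so the enrichment p-value straddles 0.01 from seed to seed;
at the default budget recovery is decisive (all 15 planted features,
p ≈ 1e−5). Both properties are asserted at their respective budgets.

## Known limitations

- Plain gradient descent: no momentum, adaptive rates or early
  stopping; convergence on large cohorts needs generous epoch budgets.
- The 1-NN surrogate rewards feature subsets that help nearest-neighbour
  geometry; subsets optimal for the autoencoder may differ.
- The subset-size pressure `W = 0.01` is deliberately weak; the selector
  finds informative features reliably but prunes redundant noise slowly.
- Binary outcomes only; the softmax head generalizes to more classes but
  nothing else in the pipeline is exercised beyond two.
- Synthetic-data realism as listed above.
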