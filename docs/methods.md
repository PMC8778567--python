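# Methods

## Overview

`hldamalo` implements a two-part screening engine for heart disease from
tabular clinical data: (1) a *hybrid* classifier in which a binary modified
ant lion optimizer (MALO) selects a feature subset and Fisher linear
discriminant analysis (LDA) classifies on it, and (2) a rule-based screen
of vital-sign streams against fixed clinical thresholds.  Both operate on
the standard 14-attribute Cleveland heart-disease schema; a synthetic
generator provides a controlled test bed with planted ground truth.

## Binary modified ant lion optimizer

The ant lion optimizer models ants performing ±1 random walks that are
trapped by ant lions whose trap radius shrinks over the run.  An ant's walk
is the cumulative sum of steps `2·s(r)−1` with `s(r)=1` iff a uniform draw
exceeds 0.5.  Each walk is min–max normalized so its own range maps onto
the current per-dimension bounds `[r, t]`; a constant walk maps to the
bound midpoint.  Bounds shrink by the factor

    J = 10^ω · k/K   for k > 0.1·K,   J = 1 otherwise,

with ω stepping 2 → 3 → 4 → 5 → 6 as the iteration fraction k/K passes
0.1, 0.5, 0.75, 0.9 and 0.95.  `J` is non-decreasing in `k`, so the search
moves monotonically from exploration to exploitation.

The *modified* variant adds, per ant and iteration:

1. two guided continuous positions — one offset from a roulette-selected
   ant lion, one from the elite (best-so-far) ant lion — each the endpoint
   of a fresh 16-step normalized walk inside the shrunken bounds;
2. a Levy-flight perturbation of both positions, sampled elementwise by the
   Mantegna construction with stability exponent λ = 1.5 and step size
   α = 1 **expressed on the current trap scale**: the effective step is
   `α/J`, so heavy-tailed jumps drive exploration early and vanish as the
   trap collapses.  Applying the full-scale step at every iteration would
   keep `|tanh(position)|` near 1 and bias the transfer function toward
   dense masks, defeating exploitation — scaling by the trap radius is the
   reading of "step size connected to the problem's scales" that preserves
   the intended exploration→exploitation schedule;
3. a tanh transfer function, `bit = 1` iff a uniform draw is below
   `|tanh(position)|`;
4. per-bit uniform crossover (rate 0.5) between the two binarized walks.

Roulette selection uses minimization weights `(max_f − f_i) + 1e−12`,
renormalized; the floor keeps the worst candidate selectable.  An ant lion
is replaced by the ant at its index only on strict improvement, so the
elite fitness history is non-increasing by construction.  Ties retain the
incumbent.  All randomness flows through one `numpy` generator seeded from
the config, making runs bit-reproducible.

Fitness functions must be finite everywhere, including the all-zeros mask
(the wrapper fitness returns the worst-case `1 + penalty` there); a
non-finite value aborts the run naming the offending mask.

## Fisher LDA

For classes `j = 1..R` with means `o_j` (counts `n_j`) and grand mean `o`:

    within   M_Y = Σ_j Σ_{z∈j} (z − o_j)(z − o_j)ᵀ
    between  M_Q = Σ_j n_j (o_j − o)(o_j − o)ᵀ

The count weighting of `M_Q` is chosen so that `M_Q + M_Y` equals the total
scatter about `o` exactly — the decomposition identity is asserted in the
tests at 1e−8 relative tolerance.  The projection maximizes the
determinant-ratio criterion `|Yᵀ M_Q Y| / |Yᵀ M_Y Y|` and is obtained from
the generalized symmetric eigenproblem `M_Q y = λ (M_Y + εI) y` via
`scipy.linalg.eigh`.  The ridge defaults to `ε = 1e−6 · trace(M_Y)/d`
(absolute 1e−6 when `M_Y` is zero): clinical features are correlated and
min–max scaled, which can leave `M_Y` ill-conditioned.

`d = min(R−1, rank M_Q)` leading eigenvectors are kept, each unit-length
with its first nonzero component positive (a pure sign convention for
reproducibility).  When class means coincide (`rank M_Q = 0`) one direction
is kept anyway so the model can still emit predictions; this degenerate
input reduces to majority-free nearest-centroid behavior.  Classification
is by nearest projected class centroid in Euclidean distance; exact ties go
to the lowest class label.  This is the canonical Fisher-LDA decision rule;
for two balanced classes it coincides with the Gaussian shared-covariance
classifier, which the test suite cross-checks against an independent
reference implementation.

## Wrapper feature selection

A candidate mask is scored by

    fitness(m) = stratified 5-fold CV error of LDA on the masked columns
                 + γ · |m| / n_features,          γ = 0.01

with the all-zeros mask pinned to `1 + γ`.  Fold assignment is
deterministic given the inner seed (per-class shuffle, round-robin deal),
so fitness is a pure function of the mask and results are cached during a
run.  γ is deliberately small: accuracy dominates and the sparsity term
only breaks near-ties, matching the intent that the classifier, not a
filter, judges feature relevance.  The optimizer budget used throughout
(20 ants, 100 iterations) is the canonical configuration; smaller budgets
select all informative features but prune noise features less reliably.

Honest evaluation is by *nested* stratified cross-validation: selection is
re-run inside every outer training fold (outer fold seeds derived from the
optimizer seed), so reported metrics carry no selection leakage.  A flat
train/test mode is available by calling `fit` and `predict` directly.  The
Cleveland disease label is binarized by default — 0 normal, 1–4 abnormal —
with the multiclass path retained as an option.

## Metrics

Accuracy (as %), precision, recall, specificity, and an F-score with two
variants: `standard` = 2TP/(2TP+FP+FN) (the default) and `as_printed` =
2TP/(2TP+FP+TN), preserved behind a flag because a circulated rendering of
the formula carries TN where FN belongs.  A zero-denominator metric is
reported as undefined (NaN, rendered `NA`), never as 0.

## Vitals screening

Fixed thresholds, applied literally: heart rate normal in [60, 100] bpm
inclusive (the band endpoints are unstated in the source convention and
resolved inclusive-normal); PR interval flagged strictly above 0.2 s;
temperature strictly above 100.4 °F; SpO2 normal at ≥ 95 %.  Blood
pressure follows the standard banding — normal < 120/80, elevated at
systolic 120–129 with diastolic < 80, stage-1 hypertension at systolic
130–139 or diastolic 80–89 — because the colloquial definition of
"elevated" (systolic > 120 and/or diastolic < 80) is internally
inconsistent; readings beyond the stage-1 band keep the stage-1 flag, as
no higher stage is modeled.  Findings are returned canonically sorted and
a sample is abnormal iff any flag fires.

## Synthetic test bed

`generate_cleveland_like` plants `n_informative` unit-variance Gaussian
features whose class means differ by the effect size Δ (default 4 features
at Δ = 2.0 among 14, n = 400, balanced classes) and fills the rest with
independent standard-Gaussian noise.  The Cleveland-record view embeds the
first features into the 13 predictor slots — continuous slots
(age, trestbps, chol, thalach, oldpeak) by affine maps near published
summary statistics, categorical slots by quantile discretization into the
attribute's domain — and samples any leftover slots from class-independent
marginals.  With 14 features, the 14th lives only in the feature matrix.
Missingness is injected completely at random (default 5 %) into predictor
slots only, which guarantees matchable complete records for the
band-matching imputer.

What the generator does **not** emulate: the correlation structure of real
Cleveland attributes, informative discrete features, class-dependent
missingness, and measurement noise beyond Gaussian.  Passing tests
therefore demonstrate correctness of the algorithms under the planted
model, not clinical performance on real records.

`generate_vitals_stream` draws each signal inside its normal band, or
strictly outside it when an abnormality is injected at the configured rate
(with narrow guard margins so rounding never crosses a threshold).  Rule
bands and generator bands are aligned by construction, so screening
verdicts reproduce the injected truth exactly — this validates the rule
wiring, not sensor realism.

## Preprocessing choices

Imputation keys: age in decades, resting blood pressure and cholesterol in
quintile bands computed from the observed values (the matching variables
are fixed; the banding granularity is this package's choice).  Redundancy
removal means exact duplicate rows and constant columns only — relevance
pruning is the optimizer's job.  Chest-pain separation is provided as a
grouping utility; it does not split the model.  Min–max scaling to [0, 1]
precedes LDA/MALO; the scaler is refit on training data only and clips
out-of-range test values with a warning.

## Numerical and size choices

Walks use 16 steps per generated position.  Default problem sizes keep the
whole test suite and the acceptance script to a few minutes on one CPU:
nested CV uses 5 outer folds over 400 records; oracle checks enumerate
1024 ten-bit masks; Monte Carlo calibrations use 1e4–1e5 draws.  Seeds are
explicit everywhere; derived seeds are small offsets of the user seed.
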