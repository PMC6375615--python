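# Methods

## Overview

The engine chains five stages: (1) build a per-cell randomization plan
from the observed dataset; (2) for each simulation and scenario, draw one
complete dataset realization; (3) optionally reinterpret values through
the fuzzy layer; (4) score every area with two-phase VRS DEA; (5) pool
the scores and summarize each distribution with estimators, stability and
entropy indicators. Interventions re-run the whole chain on an edited
dataset (the randomization plan is rebuilt from the edited values) and
compare the pre/post pools.

## Randomization

Each cell value x is replaced by a triangular law T[w_tl·x, x, w_tr·x]
(defaults 0.9/1.1) or, for cells singled out in configuration, a uniform
law U[x, w_ur·x] (default 1.1). Both scale multiplicatively, so zero
cells have no relative range and stay degenerate at 0; the same happens
when the weights are all 1. Sampling uses inverse-CDF on a single
uniform variate per cell, which is exact, fully vectorized and
reproducible across platforms. Which cells are uniform (or exempt from
randomization) is data-driven expert configuration, not a rule; the
shipped `example_uniform_cells.yaml` shows the published Bizkaia choice
(the outpatient frequentation indicator in four areas).

Seeding: the random stream of each (simulation j, scenario i) pair is
spawned from `SeedSequence((seed, j, i))`. Runs are therefore exactly
repeatable, scenario-parallelizable, and both DEA orientations score the
*same* realizations, so input/output comparisons are paired and share
Monte-Carlo noise.

## Fuzzy interpretation

Every fuzzy variable uses five sets — *very little, little, standard,
much, very much* — over an expert universe. The published constraints
(partition of unity, at most two active sets, shoulder extremes,
triangular interior) fix the properties but not the geometry; we place
the five peaks evenly over the universe, with interior triangles
spanning peak to peak and linear shoulders outside the outermost peaks.
This yields the partition-of-unity and ≤2-active-set properties by
construction.

Defuzzification is product-sum gravity, Σ m·c·A / Σ m·A over set
centroids c and areas A. By default every set is treated as a symmetric
equal-area triangle centred on its peak, with the shoulder sets
virtually extended past the universe bounds. Under this choice the
centre of gravity reduces to a membership-weighted average of peaks, so
full membership of an extreme set defuzzifies to the universe bound
itself — needed for the construct boundary conditions (no provision ⇒
score 0, maximal provision ⇒ score 100) — and fuzzify∘defuzzify is the
identity between the outermost peaks.

The D and O constructs min-max-normalize each contributing provision
variable over its expert universe, average per care group, and map the
mean through the 5-set partition onto [0, 100]. The aggregation itself
(mean, then partition) is a design choice — only the inputs and the
output range are fixed by the care model — and is monotone
non-decreasing in every provision variable.

Only one production rule is published; the shipped rule base is the full
5×5 monotone table with consequent index `4 − (i_D + i_O + 1)//2`, which
reproduces the published rule (O *very little* ∧ D *little* ⇒ *much*)
and encodes the care model's causal direction: scarcer day/outpatient
provision raises the residential appropriateness floor. The rule base is
plain data and fully replaceable in configuration. Only residential
(R-group) variables receive rule-based displacement; D and O variables
keep static expert ranges, since D↔O interdependencies are not modelled
(a stated limitation of the prototype this follows). Displacement
preserves the range width *bit-for-bit*: the width is stored on the
range object and carried over, rather than recomputed from the displaced
bounds.

Three value-interpretation profiles ship:

* `identity` — pass-through;
* `width_minus_value` — the literal published transform
  x_int = (x_right − x_left) − x. For values near 1 with a narrow range
  this goes negative (the published worked example evaluates to
  −0.8527); it is kept as a selectable profile but not the default;
* `centred_tent` — the default for interpreted variables:
  x_int = width/2 − |x − centre|, a tent peaking at the range centre,
  matching the stated intent that "the more centred the value the more
  appropriate". Linear and monotone on each side.

Interpreted values can be ≤ 0 either way; DEA inputs are floored at
1e-9 to keep the LPs well-posed.

The default `FuzzyConfig.default_for(dataset)` derives universes from the
data (0 to 1.2× the column maximum) and base ranges from the central
half of each residential column (25th–75th percentiles). Real analyses
should replace these with elicited expert ranges; the derivation exists
so the full pipeline is exercisable end-to-end without privileged
information.

## DEA

Envelopment (not multiplier) form, because the weakly-efficient
classification needs slacks. Phase 1 is the radial BCC program; phase 2
fixes the radial objective and maximizes total slack. Classification:
*efficient* iff |RTE − 1| < tol and Σslacks < tol (tol = 1e-6),
*weakly efficient* iff RTE = 1 with positive slacks, else *inefficient*.
Output-oriented scores are reported as 1/φ so both orientations share
the [0, 1] scale; the raw φ is retained on the result object.

The pipeline defaults to `phase2="boundary"`: the slack LP runs only for
units whose radial score is at the frontier, since slacks cannot change
the class of an inefficient unit (their phase-1 residual slacks are
reported instead). This halves LP count with identical scores and
classes (tested). Solver: scipy `linprog` with the HiGHS backend.
Correctness is cross-checked in the test suite against an independently
coded multiplier-form (dual) LP on random small instances (n ≤ 5,
m, s ≤ 2, both orientations, tolerance 1e-6), plus units-invariance and
monotonicity properties.

## Distribution indicators

Histograms use 20 half-open score bins plus the weakly-efficient and
efficient bins (inttot = 22). Binning is by *class* for frontier records
and by score otherwise.

Density stability accumulates bins in descending frequency order — ties
broken toward the higher-RTE bin, then lower index — until the running
sum first strictly exceeds `prob` (default 0.8). The published log
anchors minln = 1.2909, maxln = 4.6051 are the defaults; they are
four-decimal prints of ln(100·prob/inttot) = 1.2910 and ln(100) = 4.6052,
and `derive_log_bounds=True` switches to the closed forms for other
(prob, inttot). Because the printed anchors are rounded, the raw score
can overshoot the [0, 100] range by a few thousandths (all mass in one
bin gives ln(100) vs maxln = 4.6051); the indicator is clipped to
[0, 100] so the boundary semantics ("completely stable" = 100) hold
exactly.

Evaluating density stability with the *rounded* worked-example inputs
(acprob = 0.88, nintprob = 3) gives 63.00, not the published 63.13; an
unrounded acprob ≈ 0.884 reproduces 63.13. The implementation reports
full precision and makes no attempt to match the rounded print.

The "efficiency error" estimator appears in published tables at a
constant ≈1.243 × the standard deviation with no printed definition; we
expose `error = factor · sd` with factor 1 by default and make no claim
to reproduce that column.

Entropy is base-2 Shannon entropy over the 22 bins with 0·log 0 = 0,
plus its percentage of the maximum log₂(inttot).

## Scenarios and interventions

The shipped catalogue holds the 11 scenarios whose variable lists are
published in full (S4, S6–S15); S1–S3 and S5 are named but never
enumerated, so they are deliberately absent rather than invented.
Scenario files are plain YAML and user-extensible.

Intervention edits are absolute increments by default; when a per-area
population mapping is supplied, amounts are read as raw counts (FTEs)
and converted to rates per 100,000. Secondary "causal-effect" edits
(e.g. a day hospital serving several areas) are never inferred — the
catchment structure is data, so every affected cell must be listed
explicitly. Pre/post pools are compared with a two-sample t test
(Welch's form when Levene rejects equal variances at the stricter alpha),
Levene's test and the two-sample Kolmogorov–Smirnov test, at
alpha ∈ {0.05, 0.01}, alongside variation percentages
100·(post − pre)/pre (flagged NaN when the pre value is 0).

## Synthetic generator

The generator emulates structure, not magnitudes: 19 areas × 57
indicators (43 provision inputs, 14 utilization outputs) under the same
naming taxonomy, with all names used in published scenario and
intervention tables present verbatim and the remainder synthetic fill.
Each area draws a latent log-normal "care level" per care group
(sigma = 0.4); indicators multiply the group level by a measure-typical
scale (availability ≈ 1, places ≈ 25, workforce ≈ 15, utilization ≈ 300
per 100,000) and log-normal noise (sigma = 0.25); outputs use the same
group level, which induces the positive provision-utilization
correlation a non-degenerate frontier needs. What passing tests on this
fixture show is that the *machinery* is correct — shapes, invariants,
determinism, statistical properties — not that any real province's
efficiency tables are reproduced: those require the original dataset and
the unpublished expert fuzzy ranges, and no attempt is made to match
them. Synthetic pools (`fig2_style_pool`) place scores at bin midpoints
so a requested histogram is recovered exactly.

## Problem sizes and defaults

Default pipeline configuration is 500 simulations per scenario×area, the
published production scale (19 × 15 × 500 = 142,500 pool records per
orientation). The test suite and the acceptance script run the same code
paths at reduced scale (hundreds to a few thousand LP solves, seconds),
which is sufficient because every per-record computation is identical at
any scale and the cardinality invariant is exact. Monte-Carlo oracle
tests use 10⁵ draws and 3-standard-error bands; fuzzy scans use 10⁴
points at 1e-12.

## Known limitations

* The fuzzy default configuration derives ranges from data quantiles; it
  is a stand-in for expert elicitation, not a care model.
* D↔O causal interdependencies are not modelled (matching the prototype
  scope); only R depends on D and O.
* Degenerate LP alternate optima: peer weights (λ) are whatever HiGHS
  returns among optima; only the objective and slack totals are
  disambiguated (lexicographic two-phase).
* The 22-bin scheme is fixed for pool binning; indicator formulas accept
  other inttot values but the binning of real pools does not.
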