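# stochdea

Stochastic efficiency analysis for small health areas: variable-returns-
to-scale DEA under Monte-Carlo uncertainty, with a fuzzy inference layer
for expert interpretation of indicator values and bespoke stability and
entropy indicators for the resulting efficiency distributions.

## Who this is for

Health-services researchers and regional planners who need to compare the
relative technical efficiency (RTE) of small health areas — catchment
areas of community mental-health centres, each described by dozens of
availability, placement-capacity, workforce and utilization indicators
(rates per 100,000 inhabitants, DESDE-LTC-style names such as `TD1`,
`PR4-R7`, `ProfTotO8+O10`, `UFrecO8+O10`) — and to ask *what would change*
if staff or places were shifted between services and areas.

## The model

Each area is a decision-making unit (DMU). For a *scenario* — a named
subset of input variables (provision) and output variables (utilization) —
the RTE of DMU *k* is the optimum of the BCC envelopment program
(input orientation):

    min θ   s.t.   Xᵀλ ≤ θ·x_k,   Yᵀλ ≥ y_k,   1ᵀλ = 1,   λ ≥ 0

with a second phase maximizing total slack at the optimal θ, so frontier
units with residual slacks are classified *weakly efficient* rather than
*efficient*. Output orientation maximizes φ analogously and reports
RTE = 1/φ, keeping both orientations on the same [0, 1] scale.

Because small-area rates are uncertain, every observed value x becomes a
distribution — triangular T[0.9x, x, 1.1x] by default, uniform
U[x, 1.1x] for expert-selected cells — and the whole analysis is
repeated over Monte-Carlo realizations. Before each DEA solve, a fuzzy
inference engine can reinterpret values through expert appropriateness
ranges: day-care (D) and outpatient (O) provision scores in [0, 100] fire
"IF D is *little* AND O is *very little* THEN the residential floor is
*much*" rules that displace the appropriateness range of residential
variables (width preserved exactly), and a monotone piecewise-linear
profile maps each sampled value through its range.

Each simulated RTE distribution is binned into 22 intervals
([0, 0.05), …, [0.95, 1), weakly efficient, efficient) and summarized by

* interval stability `intstab = 100 − 100·(nint − 1)/(inttot − 1)`,
* density stability `denstab = 100·(ln(acprob·100/nintprob) − minln)/(maxln − minln)`,
* their weighted sum `stab = w_int·intstab + w_den·denstab`, and
* Shannon entropy `−Σ freq_h·log₂ freq_h` (bits, and % of log₂ 22).

Management interventions are lists of cell edits (e.g. a paired
decrease/increase reassigning one FTE between areas); pre/post pools are
compared with variation percentages and t, Levene and Kolmogorov–Smirnov
tests.

## Worked example

```python
import stochdea as sd

ds = sd.generate_ecosystem(sd.FixtureConfig(seed=7))   # synthetic 19x57
scenarios = [s for s in sd.default_scenarios(ds) if s.id in ("S4", "S6")]
cfg = sd.PipelineConfig(n_sim=50, orientations=("input",), seed=1)
pool, manifest = sd.run_pipeline(cfg, ds, scenarios)

rep = sd.estimators(pool)
print(f"P(efficient) = {rep.p_efficient:.4f}")
print(f"mean RTE     = {rep.mean:.4f}")
print(f"P(RTE>0.75)  = {rep.p_above(0.75):.4f}")

stab = sd.stability_report(sd.bin_pool(pool.filter(dmu="SHA-15", scenario="S6")))
print(f"SHA-15/S6: intstab={stab.intstab:.2f} denstab={stab.denstab:.2f} "
      f"stab={stab.stab:.2f} entropy={stab.entropy:.2f}")
```

prints

```
P(efficient) = 0.7689
mean RTE     = 0.9757
P(RTE>0.75)  = 0.9853
SHA-15/S6: intstab=76.19 denstab=63.00 stab=69.59 entropy=2.02
```

The pool holds 1,900 records (19 DMUs × 2 scenarios × 50 simulations).
Across it, 77% of simulated scores sit on the frontier with zero slack
and the average RTE is 0.976 — the synthetic generator couples
utilization to provision, so most areas are near-efficient by
construction. For area SHA-15 under the outpatient-care scenario, the
simulated scores spread over 6 of the 22 intervals (interval stability
76.19); the top 3 intervals accumulate the 0.8 probability threshold
(density stability 63.00), giving a final stability of 69.59 and an
entropy of 2.02 bits — a moderately stable area whose score would move
noticeably under small data changes.

A CLI wraps the same pipeline: `stochdea simulate-data`, `stochdea run`,
`stochdea intervene`, `stochdea stability`, `stochdea compare` (see
`stochdea --help`).

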