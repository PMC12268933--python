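# Methods

## Growth data model

Tumor area is caliper length × width in cm², converted to mm² by
multiplication by 100. Undetectable tumors are recorded as 0 cm² and floored
at 1 mm², so log10(area) is defined and non-negative everywhere; all
modelling is on the log10 mm² scale. Days are integer days post injection;
non-integer days are accepted with a flag. Missing intermediate
measurements are dropped with a warning — an explicit package choice, since
no imputation rule is obviously right for irregular caliper schedules and
the downstream rules operate on observed points only.

## Pseudo-control selection

Each animal's growth AUC is the trapezoid area under its (day, mm²) curve
on the raw scale; it needs ≥ 2 measurements. Animals at or above the 75th
percentile of AUC (linear-interpolation / type-7 quantile) form the
pseudo-control set — for distinct AUC values this is exactly the top
⌈n/4⌉ animals, which we verify against a sort-and-cut oracle in the tests.
Ties are broken deterministically (descending AUC, then animal id).
Pseudo-control animals are *not* removed from subsequent classification:
cohort proportions are reported over every classifiable animal.

## Control band

The band is a two-stage fit on pooled pseudo-control points up to the day
cutoff (default 17):

1. **Mean curve.** A Gompertz-form curve on the log scale,
   `mean_log(t) = a − b·exp(−c·t)` (b ≥ 0, 10⁻⁴ ≤ c ≤ 2), fitted by
   Levenberg–Marquardt least squares. This saturating form covers both
   near-exponential early growth (small c, large b) and plateauing growth.
   If the fit fails to converge the stage falls back to a quadratic in day,
   which is always well-posed with ≥ 3 distinct days.
2. **Bounds.** Lower/upper offsets are the empirical 12.5th/87.5th
   percentiles (for 75% coverage) of the pooled residuals, added to the
   mean curve. A minimum half-width ε = 0.01 log10 units prevents
   zero-width bands on noiseless input.

The band is defined on the distinct observed control days; between grid
days it interpolates linearly, beyond the last day it extends flat, and it
refuses to extrapolate backward before the first control day. Achieved
in-sample coverage is recorded in the fit diagnostics and warned about if
it falls more than 0.05 below target. Because the bounds are residual
quantiles, in-sample coverage is close to nominal by construction; the
meaningful calibration check (in the tests) is on freshly simulated
control-only cohorts. Pooled points are put in canonical order before
fitting so the result is exactly permutation-invariant. The band-fitting
stage is deterministic by design; a Bayesian posterior-predictive variant
could be slotted in behind the same `ControlBand` contract.

"Two-stage" here means mean-fit-then-bounds. An alternative reading — a
growth-phase changepoint model — would alter the mean curve but not the
band contract or the downstream rules.

## Classification rules

A point is a *responder point* iff its log area is **strictly below** the
band's lower bound at its day; a point exactly on the bound is not. Only
the low side counts: the pseudo-control is the fastest-growing quartile,
and "response" means a smaller tumor than control growth. Per animal, with
day threshold 10 (inclusive):

- fewer than 3 measurements on/after day 10 → **unclassifiable** (reported,
  never silently dropped);
- *responder* ⇔ ≥ 2 responder points among days ≥ 10 **and** the final
  measurement is itself a responder point (the final point counts within
  the two, not in addition — the stricter conjunctive reading);
- non-responder → **non-responsive**;
- responder → OLS slope of log10 area on day over the day ≥ 10 points,
  two-sided t-test with n − 2 df against zero slope (the package tests
  against zero, not against the control growth rate): slope < 0 and
  p < 0.05 → **regressing**, otherwise **exhausted**. A perfectly flat
  series gets p = 1 (no evidence of decline → exhausted); a non-zero slope
  with zero residual variance gets p = 0.

## Synthetic cohorts

Latent trajectories are piecewise log-linear per archetype:
`log10 area(t) = base + r₁·min(t, t₀) + r₂·max(t − t₀, 0)` with i.i.d.
Gaussian noise on the log scale. Piecewise-linear truth (rather than a
mechanistic Gompertz simulation) keeps every expected value
hand-computable. Defaults, chosen once as a realistic untreated
immunogenic-tumor cohort:

| parameter | value | meaning |
|---|---|---|
| schedule | days 7, 10, 12, 14, 17 | twice-weekly caliper measurements |
| base | 0.7 log10 mm² | ≈ 5 mm² at first palpation |
| r₁ | 0.13 log10/day | ≈ 1.35×/day early growth |
| t₀ | day 10 | response onset |
| r₂ (regressing) | −0.18 log10/day | sustained regression |
| r₂ (exhausted) | 0.0 | plateau below control growth |
| noise σ | 0.05 log10 | caliper + biological noise |
| mixture | 0.478 / 0.257 / 0.265 | regressing / exhausted / non-responsive |
| size cap | 1500 mm² | humane-endpoint stand-in; later points censored |

Archetype counts come from largest-remainder rounding of the mixture
weights, so cohort composition is exact and the only stochastic element is
the measurement noise; everything is reproducible from a single seed. What
the generator does **not** emulate: between-animal growth-rate
heterogeneity within an archetype, irregular measurement schedules,
experiment/batch effects across pooled experiments, or measurement error
correlated in time. Passing label-recovery tests therefore show the
decision rules are implemented correctly and are robust to log-additive
noise — not that real cohorts are this separable.

DE-table generation plants up/down blocks that pass FDR ≤ 0.01 and
|log2FC| ≥ effect (default 3) in their designated contrasts, while every
background gene fails at least one threshold per contrast; ortholog maps
use upper-cased symbols with configurable unmapped and one-to-many
fractions. The planted-truth bundle nests a 259-gene exhausted signature
(180 up, 79 down) and 25 upregulated TFs inside larger shared blocks, with
decoy human genes and TFs that must not leak through.

## Signatures

Thresholds are inclusive (FDR ≤ 0.01, |log2FC| ≥ 2), with the fold-change
sign giving direction; intersections are direction-concordant and
discordant genes are counted in provenance. Mouse symbols are Title-cased
and human symbols upper-cased before joins to prevent silent misses.
One-to-many orthologs expand rather than collapse (reported), unmapped
genes are dropped (reported), and a human symbol mapped into both
directions is removed as conflicting. The human exhausted-cluster list is
treated direction-agnostically by default (its clusters do not come with
per-gene directions); direction-concordant matching is available via
`human_up`/`human_down`.

## Over-representation

The statistic is the over-representation upper tail P(X ≥ k) of the
hypergeometric distribution — not the weighted running-sum enrichment
statistic — with a fixed universe size (default 42 739, the MSigDB mouse
total). When an explicit universe gene list is supplied, memberships and
the query are intersected with it and N is its cardinality. The tail is
computed via the log survival function for stability and matches exact
rational enumeration to ≤ 10⁻¹² relative error on all universes N ≤ 20.
BH adjustment runs over all tested sets; results passing FDR 0.01 are
ranked by fold enrichment with a fully specified tie-break (fold ↓, p ↑,
name ↑). The tail convention includes k (P(X ≥ k), no midpoint
correction).

## Morphometry

Circularity = 4π·area/perimeter², dimensionless, scale-invariant, exactly
1 for a circle and < 1 for every other simple shape (isoperimetric
inequality). Discretised perimeter estimates from segmented images can
overshoot slightly, so values above 1 + 10⁻⁶ are clipped to 1 with a
warning rather than rejected.

## Problem sizes and numerical choices

The test suite uses cohorts of 50–300 animals, 1000 random curves for the
rule-equivalence check, 1000 random p-vectors for the BH check, and
exhaustive hypergeometric enumeration up to N = 20; the whole suite runs in
well under a minute. Quantiles are type-7 throughout. Band evaluation at
non-grid days is linear in day. Seeds are fixed in every stochastic test.

## Limitations

- The band is an empirical coverage band, not a credible or confidence
  interval; its guarantee is in-sample coverage of control points.
- The slope t-test assumes i.i.d. Gaussian residuals on the log scale over
  as few as 3 points; with exactly 3 points it has 1 degree of freedom and
  low power, so borderline regressors will be called exhausted.
- No mixed-effects pooling across experiments: experiments are pooled
  flatly, matching the classification workflow rather than the
  treatment-effect analyses around it.
- DE tables are consumed, not produced; the differential-expression model
  itself is out of scope.
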