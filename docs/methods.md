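# Methods

## Model and assumptions

Observations of `k` real-valued risk factors come from two groups: `n`
samples with the outcome (`D = 1`) and `m` without (`D = 0`). For one
factor with diseased values `u_1..u_n ~ F₁` and healthy values `v_1..v_m ~
F₀`, the population ROC curve is `R(t) = 1 − F₁(F₀⁻¹(1 − t))` under the
convention that values at or above a threshold are called positive. If
larger factor values raise disease incidence (stochastic dominance of `F₁`
over `F₀`), `R(t) ≥ t` everywhere; independence of factor and outcome
gives `R(t) = t`. The method tests that independence null per factor and
needs no model for the dose–response relation — only the dominance
direction is informative, so factors whose effect is non-monotone in the
observed value can be missed.

## Screening statistic and its null

The empirical ROC curve is the piecewise-linear curve through the
staircase vertices `(FPR(f), TPR(f))` for the pooled distinct observed
values `f` in descending order, prefixed by (0,0). Values shared across
groups produce diagonal segments, so the trapezoidal area equals the
Mann–Whitney statistic with half-weight ties exactly (asserted to 1e−12 in
the tests). The screening statistic is

    S_A = √n · |AUC − ½| = | ∫₀¹ √n (R̂(t) − t) dt |.

The absolute value makes the test two-sided: protective factors
(AUC < ½) score identically to their mirror image.

Under the null, `√n (R̂(t) − t) ⇒ B₁(t) + √λ B₂(t)` with independent
Brownian bridges and `λ = n/m`. The null of `S_A` is simulated by drawing
bridges as `B(t_g) = W(t_g) − t_g W(1)` on a uniform grid of `G` steps and
integrating by the trapezoid rule; since `∫₀¹ B(t) dt ~ N(0, 1/12)`, the
exact null is half-normal with scale `√((1+λ)/12)`, which the simulator
matches to KS distance < 0.015 at 20,000 draws — the closed form serves as
an independent oracle, never as the implementation path.

P-values are raw exceedance fractions `#{draws ≥ S_A}/n_sim`, so a
statistic beyond every draw reports exactly 0.000; the positively biased
`(1 + count)/(1 + n_sim)` variant is available behind the `add_one` flag.
All factors in one dataset share `λ`, so a single null sample is simulated
once and reused — identical, by construction, to per-factor nulls at the
same seed.

## Pairwise correlation and the network

For factors `i, j` the distance `d_ij` is the exact L1 distance between
their piecewise-linear ROC curves, computed on the merged breakpoint set
with segments split at interior sign changes (one-sided limits are used at
vertical jumps, which carry no measure). `l2`, `sup` and `|ΔAUC|` are
alternatives behind the `metric` option; L1 is the default because the
construction is about the *difference of the curves*, of which `|ΔAUC|`
is only a lower bound. The weight `r_ij = 1/(1 + d_ij)` (option:
`exp(−d_ij)`) is strictly decreasing in distance, confined to (0, 1] and
equals 1 iff the curves coincide.

Under the pair null "both factors share one population ROC curve", each
empirical curve deviates from the common curve by an independent copy of
the limit process over `√n`; the simulated null of `r̂_ij` therefore draws
`δ(t) = (B_a(t) + √λ B_b(t))/√n` twice from four independent bridges and
measures the distance between the two deviation curves. The common curve
is fixed at the diagonal — an approximation, since the limit process's
covariance depends weakly on the common curve's shape; with unequal group
sizes per factor each factor would use its own `n`, but the package's
datasets share sizes across factors, so one null serves all pairs.

### Threshold direction

The pruning level `β` picks a quantile of the simulated `r_ij` null;
entries below the threshold become 0 and the pruned matrix is the
adjacency matrix (diagonal zeroed, no self-loops). Two readings coexist
and both are provided:

- `tail="upper"` (default): threshold = `(1−β)` quantile. Smaller `β`
  always prunes harder, giving the nested edge sets
  (`β = 0.01 ⊆ β = 0.02`) and the "fewer nodes for smaller β" behaviour.
- `tail="lower"`: threshold = `β` quantile. This is the goodness-of-fit
  retention reading: a pair whose curves are truly equal is kept with
  probability `1 − β`.

The two differ sharply in what survives. Because pairs with equal
population curves have `r̂_ij` distributed *as* the null, the upper tail
retains any such pair with probability only ≈ `β`; it is a deliberately
aggressive filter that keeps just the closest-of-the-close. The
block-recovery study below therefore runs with `tail="lower"`, where truly
co-acting factors are retained at rate `1 − β` and unrelated pairs fall
far below the threshold.

## Synthetic data generator

The generator emulates a two-group survey: a Gaussian copula with
within-block latent correlation `ρ` (blocks model groups of co-varying
factors, e.g. pollutants from a shared source), marginals `normal`
(standard), `lognormal` (log-sd 1, skewed concentrations) or `t3` (heavy
tails), a per-factor location shift `δ_j` added to the diseased group
(`δ = 0` marks a null factor), and optionally a fraction of cells replaced
by draws at 10× the marginal scale (gross outliers). `population_auc`
supplies the matching oracle `P(U > V)` — `Φ(δ/√2)` in closed form for the
normal marginal, numeric integration otherwise.

What it does not emulate: real pollutant concentration distributions,
measurement censoring/detection limits, or non-monotone dose–response.
Passing tests demonstrate calibration and power under location-shift
alternatives with copula dependence, not performance on arbitrary real
surveys.

## Numerical and design choices

- **Defaults**: `n_sim = 1000` null draws (10,000 recommended for final
  reports), grid `G = 1000`, screening level `α = 0.05` with no
  multiple-testing correction by default (Benjamini–Hochberg behind
  `bh_correction`), network level `β = 0.01`.
- **Ties**: half-weight convention throughout; a zero MAD in the display
  transform falls back to scale 1 with a warning; the logistic squashing
  `z = 1/(1 + exp(−(f − median)/MAD))` is strictly monotone, so it never
  changes any ROC-based quantity.
- **Determinism**: every Monte-Carlo routine is reproducible from
  `(seed, n_sim, G)`; the pipeline logs its full configuration and writes
  byte-identical artifacts on rerun.
- **Study sizes** used by the validation suite and `scripts/acceptance.py`:
  type-I error from 2,000 null factors at `n = m = 50` against a shared
  2,000-draw null; power and mean-AUC from 500 replicates (`n = m = 50`
  and `200`); block recovery from 50 replicates of a `k = 10`,
  `n = m = 200` two-block design (shifts 1 and 0, `ρ = 0.5`, `β = 0.01`,
  `tail="lower"`); null calibration from 20,000 draws at `G = 1000`.

## Known limitations

- The asymptotic null is used at finite `n`; at `n = m = 50` its scale
  differs from the exact finite-sample AUC variance by under 1%, and the
  measured type-I error stays within [0.035, 0.065] of nominal 0.05.
- The pair null's diagonal baseline slightly misstates the deviation
  covariance when the common curve is far from the diagonal.
- Factors with equal population shifts are connected by the network even
  if causally unrelated; components group factors by similarity of their
  relation to the outcome, not by mechanism.
- The screen has no power against alternatives whose ROC curve crosses the
  diagonal with `AUC = ½` exactly.
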