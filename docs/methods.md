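# Methods

## Respirometry reduction

Intermittent-flow respirometry alternates sealed "measure" phases, in which
the fish depletes chamber oxygen, with "flush" phases that re-equilibrate
the chamber with an aerated basin. The pipeline takes the flush-pump state
as an explicit logged channel (`pump_on`), because in the emulated protocol
switching was manual; measurement phases are maximal runs of `pump_on == 0`
and are never inferred from oxygen inflections.

Each sealed phase is trimmed of its first `lead_trim_s` and last
`tail_trim_s` seconds (both default 60 s): the lead still mixes flush
water and handling disturbance, the tail may catch the reopening. The DO
decline over the trimmed window is fitted by ordinary least squares —
rolling-window minima and other SMR estimators are deliberately out of
scope — and converted to an absolute rate by Eq. MO₂ = |slope|·V_eff·60
with V_eff the system volume minus fish mass / 1 kg l⁻¹. The slope's sign
is preserved until this conversion so that physically impossible rising
traces stay visible to QC. An r² below `r2_threshold` (default 0.90) sets a
`low_r2` flag but never auto-rejects: no r² rejection rule is part of the
emulated protocol, so rejection remains an explicit analyst choice.

**Background.** Microbial respiration of the empty system is reduced from
one long blank run before and after each trial. When the post rate exceeds
the pre rate the background is modelled as linear in time through the two
anchors (microbial growth during the trial); when it decreased, the
difference is treated as measurement scatter and the model is constant at
the mean — the decrease case is not specified by the emulated protocol, and
this choice is logged in the model's `mode`. Background is evaluated at the
trimmed segment midpoint, the unbiased location under a linear drift.
Corrected rates below zero are clamped to 0 and flagged.

**RMR fixed point.** The 25%-of-RMR background filter is circular as
usually stated (the threshold depends on RMR; RMR averages the surviving
records). It is resolved as a fixed-point iteration: compute a provisional
RMR from the usable set, drop records whose background exceeds
`bg_frac_threshold` × provisional RMR, recompute; records never re-enter,
so the set shrinks monotonically and the iteration terminates. The unit
suite checks the result against an exhaustive oracle.

**MMR.** The single highest post-chase measurement, tie-broken to the
earliest segment (the maximum is expected immediately after the chase). An
MMR that does not exceed the fish's own maximal rate during chamber
acclimation is excluded — it cannot be a maximum — with the rule skipped
(and a warningless summary) when no acclimation record exists. Aerobic
scope is computed per fish before any group averaging; group-table row
arithmetic (mean MMR − mean RMR) is therefore not expected to equal the
mean scope column.

## Scaling, mass adjustment, Q₁₀

The scaling exponent b is the OLS slope of log₁₀ absolute rate (mg min⁻¹)
on log₁₀ mass (kg), fitted per rate type over the fish entering that
analysis; "mean mass" in the adjustment equation is the arithmetic mean of
that same cohort's masses. The adjustment
MO₂,adj = m̄^(b−1)·m^(1−b)·MO₂,obs is exact under the power law: it is the
identity at m = m̄ and at b = 1, and removes the mass–rate relationship of
a cohort generated with that exponent (both asserted in tests).

Q₁₀ uses the van't Hoff exponential form (r₂/r₁)^(10/(T₂−T₁)). A "literal
printed" product form (r₂/r₁)·(10/(T₂−T₁)) is available behind an explicit
flag for audit only: the product is not a temperature coefficient (it is
not 1 for equal rates unless the interval is exactly 10 °C) and cannot
reproduce any published Q₁₀ over a non-10 °C interval. Q₁₀ group means are
computed per temperature treatment pooling habitats (one coefficient per
interval), after mass adjustment to the cohort mean mass.

## CTmax

CTmax is the tank temperature at the operator-recorded loss-of-equilibrium
time, linearly interpolated between the bracketing log samples (at a 90 s
cadence and ~0.33 °C min⁻¹ ramp the interpolation ambiguity is < 0.01 °C;
whether the "true" endpoint is the interpolated or the last-logged
temperature is a documented choice). The realized heating rate is the OLS
slope of temperature on time over the ramp window only, excluding the
pre-ramp recovery hold. Loss of equilibrium is a behavioral, observed
endpoint; it is never inferred from the trace. The ramp log must not
decrease on average; a flat log is representable (rate 0) so degenerate
trials remain analyzable.

## Comparison layer

ANCOVA/ANOVA are fitted by OLS (statsmodels) on log₁₀-transformed rates
with log₁₀ mass as covariate. The reduction protocol fits the full declared
model, then removes non-significant interactions one at a time — highest
order first, then largest p — refitting until all retained interactions
have p < α (0.05). Main effects and the mass covariate are never removed by
this loop. Term tests use Type II sums of squares; with no retained
interaction in a balanced design this coincides with Types I/III, and the
choice is recorded on the results object. Ancillary covariates
(acclimation time) are screened by a three-part check: term and interaction
significance, AIC on removal (drop supported when removal improves or
changes AIC by ≤ 2), and a regression of final-model residuals on the
candidate.

Adjusted means are model predictions per factor-level combination at a
common covariate value (default: common log₁₀ mean mass), with model-based
SEs; back-transformed (10^x) means are reported alongside, SEs staying on
the log scale to avoid asymmetric-interval ambiguity. Tukey contrasts are
computed on the model scale from LS-mean contrast vectors with
studentized-range p-values and a compact letter display. A zero-variance
covariate is aliased with the intercept and is dropped with a note, which
also makes "covariate identical for all fish ⇒ adjusted means = raw means"
hold exactly. Rank-deficient designs (e.g. one observation per cell under
the interaction model) raise an estimation error naming the aliased terms;
the report layer falls back to the additive model in that case.

## Synthetic generators

`simulate_trace` integrates dDO/dt = −(MO₂ + bg(t))/60/V_eff, plus a
first-order washout k·(DO_basin − DO) during flushes, by explicit Euler at
≤ 1 s steps (the dynamics are first-order and slow; halving the step
changes noiseless recovered rates at the 1e-12 level), subsampled to the
logging cadence with Gaussian sensor noise added to the readings, not the
state. Oxygen mass balance is asserted to 1e-9 in tests. Default schedule:
four 10-min sealed phases separated by 15-min flushes.

`simulate_cohort` draws masses log-uniform on 2.4–53.7 g (even leverage in
log–log space across the order-of-magnitude size range), assigns
habitat × treatment cells round-robin before a joint permutation (so the
design stays as balanced as n allows), and generates
RMR = a·m^b·Q₁₀^((T−25.5)/10)·h·ε with a = 2.0 mg min⁻¹ at 1 kg (placing a
17 g fish near 3.7 mg min⁻¹ kg⁻¹), b = 0.85, Q₁₀ = 1.6, a ×0.9 offset for
the low-oxygen wetland habitat, and unit-median lognormal individual
variation with CV 0.15. By default MMR = 2.2 × the fish's realized RMR with
further lognormal noise (sharing RMR's thermal response); setting
`q10_mmr` decouples MMR onto its own deterministic kernel with independent
noise, which is how a thermally flat MMR is expressed. CTmax trials use
intercept 30.3 °C, slope 0.30 per °C acclimation, residual SD 0.8 °C, a
0.333 °C min⁻¹ ramp and 90 s logging. All generators are deterministic
given (config, seed); the PRNG (numpy PCG64) is recorded in truth-table
metadata.

What the generators do *not* emulate: spontaneous activity inside the
chamber, within-trial temperature drift, serial correlation of sensor
noise, diel metabolic cycles, or operator variability in phase switching.
Passing recovery tests therefore shows the reduction arithmetic and
statistics are correct under the stated noise model, not that field data
meet that model.

## Pattern-recovery power

One end-to-end check asks a study-sized simulation (n = 34, CV 0.15,
RMR Q₁₀ 1.6, thermally flat MMR) to reproduce the qualitative effect
pattern "mass significant for every response; temperature significant for
RMR only" in ≥ 80% of seeds. Measured jointly, the pattern holds in ~60% of
seeds: with RMR rising at Q₁₀ 1.6 while MMR stays flat, absolute aerobic
scope genuinely contracts ~27% across 25.5→31.5 °C, and the temperature
F-test detects that real effect in roughly a quarter of cohorts (the
remaining shortfall is RMR detection power ~0.87 and MMR type-I error).
A flat-scope *and* flat-MMR world is internally inconsistent at these
effect sizes, so the 80% target is not attainable under the stated
conditions; the test asserts it anyway rather than weakening the check, and
this note documents the power analysis. (Scope stays flat only when MMR
warms at an intermediate Q₁₀ ≈ 1.3, which instead makes the MMR temperature
term fire in half the cohorts.)

## Problem sizes

Default verification sizes: 200 seeds for noisy-trace RMR recovery and
scaling recovery, 500 replicates for the CTmax slope/coverage check, 5000
replicates for type-I calibration at n = 24, 100 seeds for the pattern
check — chosen so each simulation estimates its rate to comfortably better
than the asserted margin while the whole suite runs in about a minute and a
half.

## Known limitations

- Background blanks are reduced to a single rate each; within-blank drift
  is not modelled.
- The chamber washout constant is fixed, not estimated from flush-phase
  recovery curves.
- No mixed-effects structure (chamber or holding-tank random effects) in
  the comparison layer; the emulated analysis used fixed effects only.
- Closed (non-intermittent) respirometry, swim-tunnel MMR protocols,
  P_crit estimation, CTmin and agitation-temperature metrics are out of
  scope.
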