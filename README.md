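# aeroscope

A metabolic-phenotyping pipeline for fish ecophysiology: intermittent-flow
respirometry reduction (oxygen slopes → MO₂ → background-corrected RMR, MMR
and aerobic scope), allometric mass adjustment and Q₁₀ temperature
coefficients, critical-thermal-maximum (CTmax) trial analysis, and an
ANCOVA comparison layer with covariate-adjusted group means. A
synthetic-trial generator with embedded ground truth makes every stage
verifiable by parameter recovery, so the whole pipeline can be exercised
without any instrument data.

Written for comparative physiologists who run chamber respirometry and
thermal-ramp trials on fishes (the defaults emulate juvenile Nile perch
acclimated to 25.5–31.5 °C), and for anyone who wants a tested, scriptable
version of the standard reduction arithmetic instead of a spreadsheet.

## The core quantities

For each sealed measurement phase, oxygen consumption is

    MO₂ = |ΔDO/Δt| · V_eff · 60        [mg O₂ min⁻¹]

where ΔDO/Δt is the OLS slope of dissolved oxygen (mg l⁻¹) on time (s) over
the phase trimmed of its first and last minute, and V_eff is the
closed-system volume minus the fish's displacement (density 1 kg l⁻¹).
Microbial background respiration, measured in the empty system before and
after each trial, is subtracted (a linear-in-time model when it grew during
the trial). RMR is the mean of the usable sealed-phase measurements after
an iterative filter that rejects records whose background exceeds 25% of
the provisional RMR; MMR is the single highest post-chase measurement,
excluded when it fails to beat the fish's own acclimation-period maximum.
Aerobic scope is MMR − RMR (absolute) and MMR/RMR (factorial).

Across fish, absolute rate scales allometrically, rate = a·mass^b, with b
estimated as the slope of log₁₀ rate on log₁₀ mass; mass-specific rates are
brought to a common body mass via

    MO₂,adj = m̄^(b−1) · m^(1−b) · MO₂,obs

and thermal sensitivity is the van't Hoff coefficient
Q₁₀ = (MO₂,₂/MO₂,₁)^(10/(T₂−T₁)). CTmax is the tank temperature at loss of
equilibrium, interpolated between ramp-log samples; its response to
acclimation temperature is an OLS slope with treatment means ± SEM. Group
comparisons use ANCOVA on log₁₀-transformed rates with log₁₀ mass as
covariate, sequential removal of non-significant interactions, Type II term
tests, adjusted means at a common body mass, and Tukey pairwise contrasts.

## Worked example

Simulate a 16-fish cohort (traces with 0.02 mg l⁻¹ sensor noise and a
0.002 mg min⁻¹ chamber background), reduce it, and build the report tables:

```python
from aeroscope import CohortSimConfig, simulate_cohort, run_reduce, run_report

cfg = CohortSimConfig(n_fish=16, trace_noise_sd_mgl=0.02,
                      bg_rate_mg_min=0.002, seed=42)
sim = simulate_cohort(cfg, make_traces=True)
records, summaries, manifest = run_reduce(sim.trials)
tables = run_report(summaries)
```

`summaries` holds one row per fish (rates in mg min⁻¹ kg⁻¹):

```
fish_id       habitat  acclim_temp_c  mass_g   rmr    mmr  as_abs   fas
   f000 miscanthidium           25.5  26.599 3.214  8.216   5.002 2.556
   f001 miscanthidium           31.5   9.388 4.841  8.548   3.706 1.766
   f002        forest           31.5  34.603 4.529  9.515   4.986 2.101
   f003        forest           27.5  20.965 4.476 10.124   5.648 2.262
```

`tables["scaling"]` gives the allometric fits — b ≈ 0.90 ± 0.04 for RMR
here against a generating exponent of 0.85 at n = 16 — and `tables["q10"]`
the mass-adjusted temperature coefficients over each treatment interval:

```
rate_type      b   se_b  intercept  n     r2
      rmr 0.8990 0.0446     0.4322 16 0.9667
      mmr 0.8799 0.0499     0.7363 16 0.9568

rate_type  t1_c  t2_c   q10
      rmr  25.5  31.5 1.663
      mmr  25.5  31.5 1.276
```

The RMR Q₁₀ of 1.66 recovers the generating value of 1.6; the manifest
records every filtered record and excluded fish with exactly one reason
code. The same flow is available from the shell:

```sh
aeroscope --seed 42 simulate --out data/ --n-fish 16
aeroscope reduce --inputs data/ --out results/
aeroscope report --summaries results/summaries.csv --out results/
```

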