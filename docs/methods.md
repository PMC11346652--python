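# Methods

## The targeted-yield calibration model

The inductive soil-test crop response (STCR) approach assumes that a crop's
total uptake of each nutrient decomposes additively into a soil term, a
fertilizer term and (in the integrated mode) a manure term:

```
uptake_x = cs_x · STV_x + cf_x · dose_x + (com_x / 100) · (FYM t/ha · 1000)
```

where `cs_x`, `cf_x` are the fractional contributions from the soil test
value and the applied dose, and `com_x` is the manure contribution on a
**manure-mass percent** basis — i.e. the denominator is kilograms of manure
applied, not kilograms of nutrient in the manure.  That mass-basis
convention is how COM is defined and reported in STCR practice; it makes
COM numerically small (0.1–1%) and, importantly, makes the manure credit
per tonne of FYM large relative to the nutrients FYM physically contains.
The consequences of that are handled explicitly (see *Self-consistency of
the FYM mode* below).

Yield enters through the nutrient requirement `NR_x` (kg uptake per tonne
of fresh cob).  Nitrogen is treated as the yield-defining nutrient — cob
yield is `uptake_N / NR_N` — because the N uptake–yield correlation is the
strongest of the three in this system (r² ≈ 0.87 vs 0.86/0.83 for K/P).

### Estimators and plot-selection policy

Each parameter is an unweighted arithmetic mean of a per-plot ratio (a
yield-weighted mean is available).  Which plots enter which average is not
fully standardised in the field, so the policy is an explicit, configurable
object with these defaults:

| parameter | plots used |
|---|---|
| CS | the zero-NPK, zero-FYM controls, pooled across strips (strip-wise first averaging is an option) |
| NR | fertilised plots of the mode: `npk_only` for NPK-alone; `npk_only` + `npk_plus_fym` for NPK+FYM |
| CF (NPK-alone) | `npk_only` plots, after the soil credit |
| CF (NPK+FYM) | `npk_plus_fym` plots, after soil **and** manure credits (manure credit = COM% · FYM mass / 100) |
| COM | `fym_only` plots (zero NPK, FYM > 0), after the soil credit |

Negative per-plot CF/COM values (noise-driven) are retained in the average
by default so the estimator stays unbiased under symmetric noise;
truncation at zero is an option.  CF above 100% — routinely observed for K
because applied K primes release of native soil K — is preserved, never
clipped.

## Prescription equations

`derive_equation` turns the parameter set into the linear dose equations
`F_x = (NR_x/CF_x)·100·T − (CS_x/CF_x)·STV_x − c_om·OM`.  Two conventions
are deliberately explicit because published STCR equation sets are
internally ambiguous about them:

- **Slope basis.**  Published equation sets for this system reconcile with
  their own parameter tables only if the slope term for P and K is divided
  by 2.29 / 1.205 (oxide→elemental) while the STV coefficients are left
  unconverted.  That mixed convention is the default
  (`slope_oxide_conversion=True`), is recorded in the equation's
  provenance notes, and can be switched off for a fully elemental,
  internally consistent derivation (`slope_oxide_conversion=False`) —
  which is what the round-trip simulation tests use.
- **OM coefficient.**  Three choices: `printed` (default) uses the COM%
  value verbatim per t/ha of manure, matching published integrated
  equations; `formula` uses COM/CF, the literal general formula; and
  `self_consistent` uses 1000·COM/CF, which is the unique coefficient that
  exactly inverts the mass-basis manure credit in the uptake model.

Conversion constants are 2.29 (P↔P₂O₅) and 1.205 (K↔K₂O); the
higher-precision stoichiometric ratios (2.2914/1.2046) change results by
under 0.1% and are configurable in `stcr.units`.

Negative raw doses are clamped to zero with a per-nutrient flag rather than
raising: a high-testing soil can legitimately meet a modest target alone.

### Self-consistency of the FYM mode

Feeding an NPK-alone prescription back through the uptake model returns the
target yield exactly: the soil terms cancel and `cf · (NR·T/cf) / NR = T`.
The integrated mode does **not** close under either published OM
convention, because inverting the mass-basis manure credit requires the
`self_consistent` coefficient (≈ 20.6 kg N per t FYM at the reference
parameters) while published equations subtract only COM% (≈ 0.87).  This is
a property of the conventions themselves, not of the implementation; the
round-trip simulation tests therefore exercise the NPK-alone mode, and the
three OM conventions are exposed so the discrepancy can be examined
directly.

## Verification metrics

Percent deviation, response yardstick (RYS), value-cost ratio (VCR),
recovery efficiency (RE), partial factor productivity (PFP) and reciprocal
internal utilization efficiency (RIUE) follow the standard formulas, with
two unit conventions fixed by reconciliation against published trial
tables:

- RYS denominator: fertilizer nutrients only (manure excluded), summed on
  the oxide basis N + P₂O₅ + K₂O.  The elemental alternative and manure
  inclusion are flags.
- PFP: (fresh cob + dry stover) in quintals (t × 10) per kg of
  N / P₂O₅ / K₂O.  The literal variant (fresh cob t/ha per elemental kg)
  is a flag.
- RE uses elemental doses throughout.

`evaluate_trial` reports a metric as missing (NaN) — never zero — when its
inputs are absent (no cost model, no cob-only uptake, zero dose, the
control row itself).  Deviation for non-targeted comparator treatments
(general recommended dose, soil-fertility rating) requires an explicit
`reference_target`; the package does not guess one.

## The synthetic-trial generator

`simulate_main_experiment` inverts the calibration arithmetic so every
estimator can be tested against known truth:

1. per-plot soil tests are strip means × multiplicative spread noise
   (lognormal, CV `stv_spread_cv`, default 10%), strips ordered low→high N
   to emulate a deliberately created fertility gradient;
2. clean uptakes follow the contribution decomposition above;
3. cob yield = clean N uptake / NR_N;
4. observed uptakes get multiplicative measurement noise (lognormal,
   mean 1, CV `uptake_noise_cv`); observed yield gets independent
   biological noise (CV `yield_noise_cv`).  Both CVs default to 5%, a
   within-treatment variability typical of small-plot yield trials; a
   clipped-Gaussian additive mode is available.

The default design is 3 strips × FYM blocks (0/10/20 t/ha) × 8 subplots
(seven NPK combinations drawn from the grids N 0/75/150/225,
P₂O₅ 0/37.5/75/112.5, K₂O 0/18.75/37.5/56.25 kg/ha, plus an absolute
control) = 72 plots.  Every nonzero combination carries nonzero N, which
keeps the consistency back-solve (next paragraph) feasible under the
NPK-alone truth.

**Per-nutrient consistency.**  Because yield is driven by N, the per-plot
ratios uptake_P/yield and uptake_K/yield vary across plots and their means
do not equal the configured NR_P/NR_K.  With
`per_nutrient_consistency=True` the generator rescales P and K uptakes to
`NR_x · yield` and back-solves each plot's soil-test P/K so the
decomposition still holds exactly — then *all* parameters, NR included, are
exactly recoverable from a noiseless table.  Under the integrated-mode
reference truth the large mass-basis COM_P/COM_K credits exceed the
`NR_x · yield` headroom on manured plots, leaving no non-negative soil test
to solve for; the generator raises an error rather than emitting an
internally contradictory table.  Exact recovery is therefore demonstrated
as: all nine NPK-alone parameters (consistency on), and NR_N + CS + CF +
COM in the integrated mode (consistency off).

The verification simulator draws doses from `prescribe` for targeted
treatments and pushes every treatment through the same uptake model; with
noise, percent deviation from target is driven by the yield noise alone
(≈ 95% of replicates inside ±10% at CV 5%).

What the generator does **not** emulate: diminishing returns (the response
surface is linear, so high-FYM synthetic plots can out-yield anything a
real field would do), nutrient interactions, spatial autocorrelation
between plots, weather/phenology, and season-to-season carry-over.  Passing
recovery tests therefore show the estimators are correct *given the model*,
not that the model captures real fields.

## Numerical choices and degenerate inputs

- Strip summaries: sample (n−1) standard deviation; linear-interpolation
  quartiles; adjusted Fisher–Pearson skewness; CV% reported missing when
  the mean is zero; skewness reported 0 for effectively constant data
  (sd ≤ 1e-12 × |mean|), where the third moment is pure round-off.
- Correlations require ≥ 3 plots; a constant regressor yields NaN r², not
  an exception.
- Equation coefficients are carried at full precision everywhere; the
  3-decimal rendering in `summary()` is formatting only.
- All generators take explicit integer seeds (`numpy.random.default_rng`);
  there is no hidden global random state, and identical inputs produce
  byte-identical tables.
- Bootstrap standard errors resample plots within role classes, so each
  resampled table retains controls, manured and fertilised plots; resamples
  that still fail calibration (e.g. a degenerate draw) are skipped.

## Known limitations

- The calibrated parameters are means of ratios; no variance model links
  them, so the bootstrap is the only uncertainty quantification offered.
- The FYM-mode prescription inherits the field's convention ambiguity
  described above; users comparing against published equation sets should
  check which OM convention those sets used.
- Economic evaluation stops at the value-cost ratio; no price database or
  profit optimisation is included.
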