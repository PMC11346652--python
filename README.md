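# stcr — soil-test crop response fertilizer prescription

`stcr` implements the inductive (targeted-yield) soil-test crop response
workflow used to turn a multi-strip field calibration trial into fertilizer
prescription equations, and to judge those equations in a verification
trial.  It is written for agronomists and soil scientists who work with
STCR-style data: plot tables with fertility strips, manure blocks, graded
NPK doses, pre-sowing soil tests, yields and nutrient uptakes.

## The model

A calibration trial is summarised by four *basic parameters* per nutrient
(N, P, K):

- **NR** — nutrient requirement, kg of total uptake per tonne of economic
  produce (here fresh sweet-corn cob):  `NR = uptake / cob yield`;
- **CS%** — contribution from soil:  `CS = 100 · uptake_control / STV`;
- **CF%** — contribution from fertilizer:
  `CF = 100 · (uptake − STV·CS/100 [− manure credit]) / dose`;
- **COM%** — contribution from organic manure, on a manure **mass** basis:
  `COM = 100 · (uptake − STV·CS/100) / (FYM t/ha · 1000)`.

STV is the pre-sowing soil test value (available N/P/K, kg/ha).  CF for
potassium routinely exceeds 100% (applied K primes the release of native
soil K); it is reported as estimated.  From these, the dose equation for a
yield target `T` (t/ha) is

```
F_x = (NR_x / CF_x)·100 · T  −  (CS_x / CF_x) · STV_x  [−  c_om · OM]
```

with `OM` the manure rate in t/ha.  Negative doses (target met by soil
supply alone) are clamped to zero and flagged.  Verification trials are
scored with percent deviation from target, the response yardstick (kg yield
response per kg nutrients applied), the value-cost ratio, and the
efficiency triple RE / PFP / RIUE.

P and K circulate both as elements and as oxides (P₂O₅ = 2.29 × P,
K₂O = 1.205 × K); every quantity in the package carries an explicit basis
and the metric/equation conventions that published STCR tables follow
(oxide response-yardstick denominators, quintal-per-oxide PFP, oxide→
elemental slope division) are defaults with the literal alternatives behind
flags.  See `docs/methods.md` for the details and their rationale.

## Worked example

Simulate a 72-plot calibration trial (3 fertility strips × 3 FYM blocks ×
8 NPK subplots) from the bundled reference truth, fit the model, and
prescribe a dose:

```python
from stcr import (TargetedYieldModel, SoilTest, default_truth,
                  default_design, simulate_main_experiment, MODE_NPK_FYM)

truth = default_truth("npk_fym", uptake_noise_cv=2.0, yield_noise_cv=2.0)
table = simulate_main_experiment(truth, default_design(), seed=42)
res = TargetedYieldModel(table, MODE_NPK_FYM).fit(bootstrap=200, seed=0)
print(res.summary())
```

```
mode: npk_fym    plots: 72
plots per estimate: {'cs': 3, 'nr': 63, 'cf': 42, 'com': 6}

                  N       P       K
NR_kg_per_t   6.054   1.080   3.636
CS_pct       29.689   7.631  43.940
CF_pct       41.656  25.298  92.702
COM_pct       0.874   0.351   0.646
...
Prescription equations (npk_fym), doses kg/ha elemental:
  FN = 14.532 T - 0.713 SN - 0.874 OM
  ...
```

With 2% noise the fit lands close to the generating truth
(CS_N = 29.53%, CF_N = 42.25%, COM_N = 0.871%); the bootstrap column gives
a standard error per parameter.  Prescribing for a 22 t/ha target on a soil
testing 238/26/133 kg/ha N/P/K with 10 t/ha FYM:

```python
rec = res.prescribe(22.0, SoilTest(sn=238, sp=26, sk=133), fym_rate=10.0)
# dose N/P/K kg/ha: 141.3 29.7 2.1
```

The same pipeline is scriptable from the shell:

```sh
stcr simulate --preset npk_fym --seed 42 --out main.csv
stcr calibrate --in main.csv --mode npk_fym --out bp.csv --equations-out eq.csv
stcr prescribe --equations eq.csv --target 22 --sn 238 --sp 26 --sk 133 --fym 10
stcr evaluate --in verification.csv --control T7 --out metrics.csv
```

Verification metrics for the bundled reference trial:

```python
from stcr import evaluate_trial
from stcr.datasets import verification_trial
print(evaluate_trial(verification_trial(), "T7", reference_target=22.0)
      [["pct_deviation", "rys", "re_n", "pfp_k"]].round(3))
```

```
           pct_deviation     rys   re_n   pfp_k
treatment
T1                -7.160  61.403  0.535  28.849
T2                -6.480  72.622  0.618  46.506
T3                -2.455  79.839  0.675  37.351
T4                 1.545  93.455  0.772  71.747
T5                -2.182  55.201  0.662  13.448
T6                 3.136  54.496  0.578  14.178
T7               -68.818     NaN    NaN    NaN
```

A deviation within ±10% of target is the usual validity criterion for a
prescription equation; the STCR treatments (T1–T4) all satisfy it.

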