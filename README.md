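# permkin

Data-reduction toolkit for two questions that come up together in intranasal
(nose-to-brain) drug-delivery development:

1. **How fast does the drug cross the nasal mucosa?**
   Franz-diffusion-cell experiments sample the receptor chamber over time;
   `permkin` corrects those samples for withdrawal-with-replacement dilution,
   fits the single-membrane non-steady-state diffusion model (time-lag
   method), and reports the steady-state flux *J*<sub>ss</sub>, apparent
   permeability *P*<sub>app</sub>, diffusion coefficient *D*, partition
   coefficient *K* and lag time *t*<sub>lag</sub>.

2. **Does intranasal dosing actually target the brain?**
   From blood and brain concentration–time profiles after intranasal and
   intravenous dosing, `permkin` computes trapezoidal AUCs and the standard
   targeting ratios: drug targeting efficiency (DTE%), direct transport
   percentage (DTP%) and nasal bioavailability.

A synthetic-data generator with known ground truth (forward diffusion model
plus sampling/dilution bookkeeping; Bateman/mono-exponential PK profiles
with a controllable direct-transport component) makes every pipeline stage
testable end to end.

## The models

**Membrane permeation.** For a homogeneous membrane of thickness *L* between
an infinite donor (concentration *C*<sub>d</sub>, membrane/donor partition
coefficient *K*) and a perfect-sink receptor, the cumulative amount permeated
per unit area is

```
Q(t) = Cd·K·L·[ D·t/L² − 1/6 − (2/π²) Σₙ ((−1)ⁿ/n²)·exp(−D·n²π²·t/L²) ]
```

whose large-time asymptote `(D·K·Cd/L)·(t − L²/(6D))` defines the
steady-state flux `J_ss = D·K·Cd/L`, the lag time `t_lag = L²/(6D)`, and the
derived coefficients `P_app = J_ss/Cd` and `D = P_app·L/K`.  The fit
estimates (*D*, *K*) in log space by Levenberg least squares with
model-weighted residuals (the maximum-likelihood choice for assay error
proportional to the signal).

**Brain targeting.** Writing `Bin/Pin` for the brain/blood AUC₀₋ₜ after
intranasal dosing and `Biv/Piv` after IV dosing,

```
DTE% = [(Bin/Pin)/(Biv/Piv)]·100
Bx   = (Biv/Piv)·Pin                  # brain AUC explained by systemic exposure
DTP% = (Bin − Bx)/Bin·100
F%   = AUC_in/AUC_iv·100              # per matrix
```

DTE% > 100 (equivalently DTP% > 0) indicates preferential nose-to-brain
delivery beyond what systemic circulation provides.

## Worked example

Simulate a Franz-cell run at the default study conditions (0.12 cm mucosa,
3.14 cm², 12.5 mL receptor, 0.25 mL aliquots every 30 min for 6 h, 5% assay
CV; true D = 0.0024 cm²/h, K = 0.5) and fit it back:

```bash
permkin simulate-permeation --seed 7 --out demo/sim
permkin fit-permeation --input demo/sim/permeation_samples.csv --out demo/fit
cat demo/fit/fit_report.json
```

```json
{
  "D_cm2_per_h": 0.0024006800998923883,
  "K": 0.49751321134935084,
  "J_ss_ug_per_cm2_h": 9.953083882666187,
  "P_app_cm_per_h": 0.009953083882666186,
  "t_lag_h": 0.9997167053234545,
  "D_from_Papp_cm2_per_h": 0.0024006800998923883,
  "window_start": 0,
  "window_stop": 12,
  "r_squared": 0.992175520154282,
  "residual_sse": 8.967604899290077,
  "converged": true,
  "weak_identifiability": false
}
```

The fit recovers the generating parameters to a fraction of a percent: a
lag time of ~1.0 h and a flux of ~10 µg/(cm²·h) across this barrier.

Targeting metrics from the library, using four profiles whose AUC₀₋₆ values
are 1183 (blood) / 1892 (brain) ng·h per unit after intranasal dosing and
2184 / 617 after IV dosing:

```python
import numpy as np
import permkin as pk

sched = np.array([0.5, 1, 1.5, 2, 4, 6])
def prof(auc, matrix, route):      # flat profile with that trapezoidal AUC
    return pk.PKProfile(matrix, route, sched, np.full(6, auc / 5.5))

m = pk.targeting_report([prof(1183, "blood", "in"), prof(1892, "brain", "in"),
                         prof(2184, "blood", "iv"), prof(617, "brain", "iv")])
print(f"DTE = {m.dte_pct:.2f}%  DTP = {m.dtp_pct:.1f}%  "
      f"Bx = {m.Bx:.1f}  F_brain = {m.nasal_bioavailability_pct:.1f}%")
```

```
DTE = 566.11%  DTP = 82.3%  Bx = 334.2  F_brain = 306.6%
```

Read: after intranasal dosing the brain-to-blood exposure ratio is 5.66×
the IV ratio; 82.3% of the intranasal brain AUC is not explained by
recirculation from blood (only 334 of 1892 ng·h/g is, the `Bx` term); brain
exposure is 3.07× the IV brain exposure at the same dose.

## Command-line interface

| command | what it does |
| --- | --- |
| `permkin simulate-permeation` | synthetic Franz-cell record + noiseless truth |
| `permkin simulate-pk` | the four blood/brain × intranasal/IV profiles |
| `permkin fit-permeation` | reduce a record and fit the diffusion model |
| `permkin pk-metrics` | NCA + targeting report from four profile CSVs |

All commands accept `--config file.yaml` (key/value defaults), write CSV +
JSON artifacts plus a `run_info.json` (version, parameters, seed), and exit
non-zero with partial outputs removed on any error.  See
`docs/methods.md` for the modeling assumptions and numerical choices.
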