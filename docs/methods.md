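# Methods

## Membrane permeation model

The forward model is the non-steady-state solution of the one-dimensional
diffusion equation for a single homogeneous membrane (thickness *L*,
diffusivity *D*) between an infinite well-stirred donor and a perfect-sink
receptor, with partitioning *K* at the donor face:

    Q(t) = Cd·K·L·[ D·t/L² − 1/6 − (2/π²) Σ_{n≥1} ((−1)ⁿ/n²)·e^{−D n²π² t/L²} ]

Assumptions: constant donor concentration (infinite dose), sink receptor
(zero concentration boundary), instantaneous partitioning equilibrium at the
donor face, homogeneous isotropic barrier, no binding or metabolism in the
membrane.  `Q` is per unit area (µg/cm²); multiplying by the exposed area
gives total mass, which keeps the cumulative-curve slope and the flux
definition `J_ss = ΔQ/(Δt·S)` dimensionally coherent.

Derived quantities and their identities:

- lag time `t_lag = L²/(6D)` — t-intercept of the late-time asymptote;
- steady-state flux `J_ss = D·K·Cd/L` — slope of that asymptote;
- apparent permeability `P_app = J_ss/Cd` (cm/h);
- diffusivity back-out `D = P_app·L/K`, the algebraic inverse of
  `P_app = D·K/L`.  *K* (and the donor concentration) are explicit user
  inputs to these conversions; the package never assumes a value.

### Series evaluation

The eigenfunction series alternates, so terms are accumulated in (+,−)
pairs; summation stops when the next term's magnitude falls below
`tol·max(|partial sum|, 1/6)` (default `tol = 1e-10`), with a hard cap of
1e5 terms (exceeding it raises a convergence error naming the offending
times).  At `t = 0` the series cancels the −1/6 term exactly and `Q(0) = 0`
is returned without summation.  Truncation/rounding residues in
`(−1e-9, 0)` (scaled by `Cd·K·L`) are clamped to zero — the model is
physically non-negative.  In double precision the evaluation stays accurate
even at `0.1·t_lag`, where `Q` is ~9 orders of magnitude below the curve
scale and the bracket cancels to ~1e-9 of its leading terms.

### Steady-state ("linear portion") regression

"Linear portion" is operationalized as a suffix window, because linearity
sets in late: among all suffix windows with ≥ 4 points, the longest one with
r² ≥ 0.99 is used; if none qualifies, the best-r² suffix is returned with a
`warn_nonlinear` flag.  A caller may always pass an explicit window.  A
zero-variance (constant) series is treated as a perfect flat line with zero
flux.

### Inverse fit

`fit_diffusion_model` estimates (*D*, *K*) with `Cd` and `L` fixed, by
Levenberg least squares in (log D, log K) — the log parameterization
enforces positivity.  Residuals are model-weighted, `(model − data)/model`:
this is the maximum-likelihood weighting for multiplicative
(signal-proportional) assay noise and prevents the large late samples from
swamping the small early ones that carry all the lag information.
Initialization comes from the steady-state regression (t-intercept →
`D₀ = L²/(6·t₀)`; slope → `K₀ = slope·L/(D₀·Cd)`).

Identifiability: at late times only the asymptote's slope `D·K·Cd/L` and
intercept `−Cd·K·L/6` are observable, which still separates *D* and *K* —
but a series that is linear through the origin (no measurable intercept)
pins down only the product.  The fit flags this (`weak_identifiability`)
when the regression intercept is indistinguishable from zero or the fitted
lag exceeds the sampling span, and falls back to a heuristic start point
(`t₀ = 5%` of the span) so the optimizer still returns the best-so-far
parameters.

## Franz-cell reduction

Withdrawal with replacement dilutes the receptor at every sample.  Under
instantaneous mixing and constant receptor volume the unique consistent
correction is the ledger

    A_n = V_r·C_n + V_s·Σ_{i<n} C_i

(mass in the chamber now plus mass carried away by earlier aliquots),
divided by the membrane area for the per-area series.  No back-diffusion
correction is applied: the model already assumes sink conditions.  The mass
balance closes by construction (`unaccounted = dose − permeated −
recovered`); a deficit worse than 5% of the dose is flagged rather than
silently truncated.

## Non-compartmental targeting metrics

AUCs are linear-trapezoidal over the observed points, from the first sample
to `t_end`, with no extrapolation to `t = 0` or beyond the data (a `t_end`
between samples is cut by linear interpolation).  `c_max`/`t_max` take the
earliest maximum.  Metrics:

    DTE% = [(Bin/Pin)/(Biv/Piv)]·100
    Bx   = (Biv/Piv)·Pin,   DTP% = (Bin − Bx)/Bin·100
    F%   = AUC_in/AUC_iv·100

Identities that hold by construction and are property-tested: DTP% plus the
systemic share `(Bx/Bin)·100` equals 100; DTE% and DTP% are invariant under
common rescaling of all four AUCs; DTE > 100 ⇔ Bin/Pin > Biv/Piv ⇔ DTP > 0.
Blood (ng/mL·h) and brain (ng/g·h) AUCs are combined as plain numeric
ratios, the field convention for these indices; the bioavailability ratio
is computed per matrix and the report labels which one (default brain).
Reports render `t_max` in minutes while all internal times are hours.

## Synthetic data generator

The generator's role is to produce records whose ground truth is known, not
to model any particular drug's disposition.

**Permeation:** the forward model is evaluated on the sampling schedule
(default every 0.5 h to 6 h), converted to receptor concentrations by
inverting the replacement ledger step by step, then corrupted with
multiplicative Gaussian noise `c·(1+ε)`, `ε ~ N(0, CV)`, truncated at zero
(assay SDs in such experiments grow with the mean).  At zero noise,
reduction inverts simulation exactly (adjointness, tested to 1e-9).

Default conditions: 0.12 cm membrane, 3.14 cm², Cd = 1000 µg/mL, 12.5 mL
receptor, 0.25 mL aliquots, CV = 5%.  Default membrane parameters are
D = 0.0024 cm²/h and K = 0.5, chosen so the lag time is 1.0 h — inside the
sampling window, as a time-lag experiment requires for identifiability —
giving J_ss = 10 µg/(cm²·h) and P_app = 1e-2 cm/h, the order measured for
drugs crossing this kind of mucosal barrier.  (With a lag much shorter than
the first sample, D is informed only by the regression intercept and cannot
be recovered reliably at 5% noise; the generator deliberately avoids that
degenerate design.)

**PK:** intranasal blood follows the one-compartment Bateman form
`scale·ka/(ka−ke)·(e^{−ke·t} − e^{−ka·t})`; IV blood is `scale·e^{−ke·t}`.
Brain is `brain_partition ×` blood plus, for the intranasal route, a direct
nose-to-brain term with a faster Bateman shape (absorption 3·ka, the
quicker olfactory pathway) whose amplitude is solved against the
trapezoidal AUC on the schedule so the recomputed DTP% equals `dtp_target`
exactly at zero noise — a closed-loop test of the whole NCA pipeline.
Defaults: ka = 1.2/h, ke = 0.4/h (Tmax ≈ 1.4 h, within the 0.5–6 h
schedule), brain_partition = 0.3, sampling at 0.5, 1, 1.5, 2, 4, 6 h.
All outputs are reproducible from (config, seed); the seed touches only the
noise.

What the generator does *not* emulate: inter-animal variability structure,
mucociliary clearance and deposition physics, donor depletion, membrane
heterogeneity, and assay limits of quantification.  Tests passing on
synthetic data therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to those real-world effects.

## Verification strategy and problem sizes

- The series evaluation is checked against an independent discretization of
  the underlying PDE: second-order finite differences in space with exact
  modal integration of the semi-discrete system in time, Richardson-
  extrapolated over grid doublings (128/256/512 intervals) until
  self-converged.  Agreement is required to 1e-3 relative error across
  `[0.1·t_lag, 10·t_lag]` for 20 random parameter sets; the extrapolated
  oracle is accurate to ~1e-7 relative even where Q is ~1e-9 of curve
  scale, which a plain time-stepping scheme cannot reach there.
- Monte-Carlo parameter recovery runs 200 seeded replicates of the default
  design (12 samples, 5% CV) and requires median relative error ≤ 10% for
  both D and K (observed: ~1–2%).
- Metric identities are exercised on 1000 random AUC quadruples plus
  hypothesis-driven property tests; "exact" identities are asserted to a
  tolerance scaled by the magnitudes involved, since shares can cancel
  across many orders of magnitude.
- The whole suite runs in a few seconds; the problem sizes above were
  chosen as the smallest that make the statistical assertions stable across
  seeds.

## Known limitations

- Infinite-dose, single-layer, sink-condition model only; no finite-dose or
  multi-layer variants.
- The diffusion fit assumes the provided `Cd` and `L` are exact; their
  uncertainty is not propagated.
- AUC is not extrapolated to t = 0 or infinity; profiles sampled first at
  0.5 h therefore slightly undercount early exposure, consistently across
  routes (the targeting ratios are unaffected by any common undercount).
- The PK generator is a calibration device, not a disposition model.
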