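# delamod

Modelling and measurement of **corrosion-triggered delamination** at
metal–polymer interfaces, for reliability assessment of
polymer-encapsulated implant electronics.

When an encapsulated device sits in an ionic fluid, corroding species
creep along the metal–polymer interface from the edge inward, corrode the
metal, and detach the polymer.  On an accelerated copper/PDMS bench
system the corrosion front is directly visible in time-lapse photographs:
the exposed copper blackens immediately, while the film under the polymer
droplet stays bright and is eaten inward.  `delamod` provides the whole
analysis chain for such experiments:

- **`delamod.stefan`** — the phase-I physics: Fick diffusion with a
  Stefan moving boundary (every arriving ion is immobilized at the front,
  consuming `S` per unit advance).  Goodman's heat-balance-integral
  method gives the closed form `X(t) = α√t` with `α` the root of
  `C0 α²/6 + S α⁴/(12D) + S α² = 2 D C0`; an explicit finite-volume
  solver with an auditable discrete mass balance serves as the
  independent numerical oracle, and `fit_alpha` fits `α` to measured
  traces.
- **`delamod.imaging`** — front tracking from images: fixed-margin
  grayscale thresholding (level ≤ 90 counts as corroded), black-pixel
  counting inside a circular ROI, `r = √(A/π)`, `s(t) = r(t₀) − r(t)`.
- **`delamod.phases`** — segmentation of a trace into the three observed
  phases (`α√t` → linear → artifact jump) by exhaustive changepoint
  search; the constant-lag delamination front `d(t) = max(0, X − Δ)`; the
  steady-state membrane rate `v2 = D C0/(S Δ)` behind the linear phase;
  and the interface-vs-bulk failure-route competition (`predict_merge`).
- **`delamod.bulk`** — bulk diffusivity from the tilted-plate cuvette:
  `h(y) = offset + y·tan(tilt)`, `D = h²/(2(t − lag))`
  (Einstein–Smoluchowski), averaged over the linear onset interval.
- **`delamod.synthetic`** — forward simulation of both experiments with
  known ground truth (rendered droplet time-lapse, cuvette onset tables),
  so the entire pipeline is testable end to end without lab data.

The fitting stages follow the statsmodels convention: build a model from
data, `fit()` returns a results object with estimates, uncertainties and
a `summary()` table (`FrontKineticsModel` → `PhaseSegmentation`,
`BulkDiffusionModel` → `BulkDiffusionResults`).

## Worked example

```python
import numpy as np
from delamod import (CompositeFrontLaw, FrontKineticsModel, PlateGeometry,
                     BulkDiffusionModel, StefanParams, fd_solve,
                     goodman_alpha, simulate_cuvette, simulate_front_trace)

# a three-phase front trace: sqrt-growth, delamination-assisted linear
# segment from t1 = 420 min, artifact jump at t2 = 600 min
law = CompositeFrontLaw(alpha=1.0, t1=420.0, v2=0.05, t2=600.0, jump=30.0)
trace = simulate_front_trace(law, duration=700.0, step=5.0)
print(FrontKineticsModel(trace).fit().summary())

# bulk diffusivity from a simulated tilted-plate cuvette
geom = PlateGeometry(offset=1.0, tilt_deg=30.0, plate_length=40.0)
onsets = simulate_cuvette(1.676e-6, geom, n_positions=20, lag_min=120.0)
print(BulkDiffusionModel(onsets, geom).fit(lag="fit").summary())

# closed-form vs numerical front coefficient
p = StefanParams(D=1e-6, C0=1.0, S=10.0)
fd = fd_solve(p, t_end=2e5)
print(f"alpha (HBI) = {goodman_alpha(p).alpha:.4e}  "
      f"alpha (FD) = {fd.alpha_fit():.4e}  balance = {fd.mass_balance_rel:.1e}")
```

Output:

```
Front-kinetics segmentation
=============================================
points per phase:  I: 85   II: 36   III: 20
alpha (phase I):   1 ± 2.1e-17 [len/sqrt(min)]
t1 (I → II):       420 min
v2 (phase II):     0.05 [len/min]
t2 (II → III):     600 min (jump artifact)
SSE (phases I+II): 1.16929e-27

Bulk diffusion (tilted-plate) fit
=============================================
positions:            20
linear interval:      rows 6..19 (y = 12.63..40.00 mm, R² = 0.9823)
lag (fit):        120.00 min
D̄ (mean over interval): 1.6760e-06 cm²/s
per-position D range:  1.676e-06 .. 1.676e-06 cm²/s

alpha (HBI) = 4.4005e-04  alpha (FD) = 4.4004e-04  balance = 3.4e-14
```

The segmentation recovers the generating changepoints exactly on
noise-free data; the bulk fit recovers both the diffusivity and the
120-minute uptake lag; and the analytic front coefficient matches the
finite-volume solver to four significant figures with a machine-precision
mass balance.

## Command line

```bash
delamod simulate -c config.yaml -o bundle/        # frames + truth sidecars
delamod track    -f bundle/frames -o trace.csv    # images -> front trace
delamod fit      -t trace.csv -o fit.json         # phases + alpha
delamod bulk     --onsets bundle/cuvette_onsets.csv -o bulk.json
delamod analyze  -i bundle/ -o report.json        # full pipeline
delamod report   -r report.json
```

All files use minutes and millimetres (physics runs internally in
cm/s); every report embeds the config hash, seed and version, and
identical configs reproduce byte-identical outputs.

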