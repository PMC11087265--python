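# trxmap

Time-resolved crystallography difference-map analysis: difference
electron-density (DED) maps, SVD kinetic decomposition, IRF-convolved
global fitting, species-associated difference maps (SADED) and
extrapolated structure factors.

## The problem

In a pump–probe (e.g. serial femtosecond) crystallography experiment a
laser pulse converts a small fraction of unit cells into photoproduct
structures, and X-ray snapshots at delays t record structure-factor
amplitudes |F(hkl, t)|.  The science lives in few-percent amplitude
changes: which transient structures form, with what kinetics, and what do
they look like at full occupancy?  This package implements the standard
analysis chain for that question, exercised end to end on a synthetic toy
crystal that emulates photoinduced CO dissociation from an iron-porphyrin
site, Fe out-of-plane doming, Zr positional disorder and lattice heating
in a porphyrinic metal–organic framework.

The chain:

- Δ|F|(hkl, t) = |F(hkl, t)| − |F(hkl, ref)|, referenced to the average
  over negative delays; DED maps Δρ(x, t) by Fourier synthesis with
  ground-state phases (difference-Fourier approximation),
- SVD of masked regional map series into spatial features × time
  profiles, screened by singular value and lag-1 autocorrelation,
- global fit of the meaningful time profiles with a Gaussian IRF
  (200 fs FWHM) convolved with [instantaneous rise + exponential decay +
  damped cosine], time constants shared across traces,
- a three-species kinetic model (oscillatory / transient / vibrationally
  hot) whose profiles decompose the whole-cell DED series into SADED
  maps, plus heat-free maps with the thermal component removed,
- extrapolated amplitudes |F|_extr(hkl) = |F|_ground(hkl) +
  (1/p) Δ|F|_SA(hkl), with the photoconversion yield p chosen as the
  smallest value that digs no spurious negative density into occupied
  atom sites,
- geometry metrics (Fe doming = distance of Fe from the least-squares
  plane of the four pyrrole-bridging atoms; minimum-image Zr–Zr
  distance).

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Fit two synthetic time traces built from the kinetic model on the
33-point delay grid, sharing the decay, period and damping constants,
from deliberately wrong starting values:

```python
import numpy as np
from trxmap import KineticParams, rsv_model, global_fit, period_to_frequency
from trxmap.toy_crystal import DEFAULT_DELAYS_PS

t = np.array(DEFAULT_DELAYS_PS)                    # 33 delays, -3.9 ps .. 3 ns
truth = KineticParams()                          # 47.1 / 5.55 / 2.68 ps
traces = [(t, rsv_model(t, truth, (0.2, 1.0, 0.5))),
          (t, rsv_model(t, truth, (0.1, 0.8, 0.15)))]
init = KineticParams(tau_decay=61.2, period=3.9, tau_damp=3.5)
fit = global_fit(traces, init=init)
p = fit.params
print(f"decay {p.tau_decay:.4f}  period {p.period:.4f}  damp {p.tau_damp:.4f}"
      f"  rms {fit.residual_rms:.2e}")
thz, cm1 = period_to_frequency(p.period)
print(f"{thz:.4f} THz  {cm1:.4f} cm-1")
```

prints

```
decay 47.1000  period 5.5500  damp 2.6800  rms 3.50e-16
0.1802 THz  6.0102 cm-1
```

— the shared constants are recovered exactly from the noiseless traces
(residual at machine precision), and the 5.55 ps oscillation corresponds
to a 0.18 THz / 6.01 cm⁻¹ lattice mode.

The same works from the shell, driving the whole pipeline on the toy
crystal (simulate → scale → difference maps → SVD → fit → SADED →
extrapolation; ~2 s):

```sh
trxmap run --seed 7 --out-dir run7        # hkl/, maps/, svd/, saded/,
                                          # extrapolated/, fit.json, report.md
trxmap recover --seed 7                   # blind recovery: true vs refitted
```

`trxmap recover` simulates a series with known constants, re-analyses it
from ±30%-perturbed initial guesses, and reports the relative error on
every constant (all below 0.1% in the noiseless default configuration)
plus the recovered transient photoconversion yield (0.20 ± one 0.05 grid
step).

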