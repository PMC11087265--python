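# Methods

## The analysis problem

A pump–probe crystallography experiment measures structure-factor
amplitudes |F(hkl, t)| at a series of delays t after optical excitation.
Small population transfers into photoproduct structures change those
amplitudes by a few percent.  The analysis chain implemented here turns the
amplitude series into kinetic constants and per-species structural
information:

1. scale the observed amplitudes to the calculated ground-state amplitudes,
2. form difference amplitudes Δ|F|(hkl, t) = |F(t)| − |F(reference)|,
   with the reference averaged over pre-excitation (negative) delays,
3. synthesize difference electron-density (DED) maps
   Δρ(x, t) = (1/V) Σ Δ|F| e^{iφ_ground} e^{−2πi h·x} (difference-Fourier
   approximation; the (000) term is omitted, so DED maps are zero-mean),
4. decompose masked regional map series by SVD into spatial features
   (LSVs), weights (singular values) and time profiles (RSVs), and screen
   components by relative singular value and lag-1 autocorrelation,
5. fit the meaningful RSVs globally with an IRF-convolved kinetic model
   sharing time constants across traces,
6. decompose the whole-cell DED series into species-associated DED (SADED)
   maps with the fitted model, and subtract the thermal component to obtain
   heat-free maps,
7. convert a SADED map into signed species difference amplitudes and
   extrapolate, |F|_extr = |F|_ground + (1/p)·Δ|F|_SA, scanning the
   photoconversion yield p against the criterion that no spurious negative
   density appears at occupied atom sites.

## Kinetic model

Three species with fixed spatial signatures and analytic time profiles,
all convolved with a Gaussian instrument response function (IRF) of
full width at half maximum 0.2 ps (σ = FWHM / 2√(2 ln 2)):

- **Oscillatory species** — damped cosine, period T = 5.55 ps, damping
  τ_d = 2.68 ps, phase 0 at t₀ (the phase is not an observable of the
  packaged experiments and defaults to zero; it can be freed).  Its
  profile is signed: the map it multiplies is the half-difference of the
  two turning-point structures.
- **Transient species** — forms within the IRF (modelled as a 20 fs
  exponential rise where a rise term is needed) and decays exponentially
  with τ = 47.1 ps.
- **Vibrationally hot species** — rises to a unit plateau with two
  exponential time constants, 1.143 ps and 11.32 ps; the weight w of the
  fast branch is not separately published and defaults to 0.5
  (configurable, and freed in the recovery fits).

Closed forms are used for the convolutions.  Gaussian ⊗ causal
exponential:

    ½ exp(σ²/2τ² − u/τ) erfc((σ/τ − u/σ)/√2),  u = t − t₀,

evaluated through the scaled complementary error function erfcx on the
side where the plain form overflows.  The damped cosine uses the same
form with the complex rate a = 1/τ_d − 2πi/T (complex erfcx), taking the
real part; both branches are finite for all delays between −∞ and 3 ns.
The closed forms are verified in the test suite against adaptive
quadrature of the defining integral to ≤ 1e-8.

## Global fitting

`global_fit` shares any subset of {τ_decay, T, τ_damp, t₀, τ_rise1,
τ_rise2, w, phase} across traces while giving each trace its own
(a_rise, a_decay, a_osc) amplitudes.  The amplitudes are eliminated by
variable projection — at each trial of the shared constants every trace's
amplitudes are the exact linear least-squares solution — so the
trust-region optimizer (scipy `least_squares`, box bounds, iteration cap
2000) searches only the low-dimensional constant space.  This converges
from ±30% perturbed starting values where the joint parameterization has
degenerate local minima.  t₀ is bounded to ±0.3 ps.  1σ uncertainties
come from the Jacobian-based covariance.

When traces were referenced to an average over negative delays, the model
can subtract its own mean over those delays (`baseline_delays`): the
−0.2 ps reference point lies only 2.4 IRF widths before t₀ and retains
≈0.9% of the peak signal, a small but systematic offset.

## Synthetic toy crystal

A 20 Å cubic P1 cell containing a minimal mimic of an iron-porphyrin /
hexazirconium MOF: Fe domed 0.597 Å below a square of four nitrogens
(pyrrole-plane proxy), an axial C–O ligand, and a half-occupied Zr pair
0.841 Å apart along the x ("d") axis.  The photoproducts differ by:
CO occupancy 0, doming 0.716 Å and Zr–Zr 0.907 Å (transient); all B + 5 Å²
and Zr–Zr 0.891 Å (hot; doming stays at the ground value — the hot
structure is ground-like apart from thermal broadening); Fe displaced
+0.443 / −0.312 Å along the doming axis with Zr–Zr 1.057 / 0.625 Å
(oscillation turning points).

Every site has an inversion-related copy, so the arrangement is
centrosymmetric (all phases 0 or π) while the code treats the cell as
plain P1.  This matters: in an acentric arrangement the
difference-Fourier approximation recovers only about half of the true
difference density, and yield scans then select p ≈ p_true/2.  The
centrosymmetric toy matches the symmetric character of the real material
and makes the approximation quantitative.

Structure factors are computed by direct summation,
F(hkl) = Σ_j o_j f_j exp(−B_j s²/4) exp(2πi h·x_j), s = 1/d, with
constant form factors f = Z by default so that Friedel symmetry, the
F(000) electron count and the shift theorem are exact test oracles
(a single-Gaussian falloff is available behind a flag).

The simulated series mixes complex structure factors coherently:

    F(t) = (1 − e(t)) F_ground + c_tr(t) F_tr + c_hot(t) F_hot
           + c_osc(t) (F_osc+ − F_osc−)/2,   e(t) = c_tr + c_hot.

Peak populations default to the per-species photoconversion yields
(0.25, 0.20, 1.00) normalized to unit sum — (0.172, 0.138, 0.690) — since
the mixture model requires the total excited population to stay ≤ 1.
Amplitude noise is multiplicative Gaussian (relative sd `noise_sd`),
a proxy for merged-intensity error, reproducible from a mandatory seed.

What the generator does **not** emulate: partiality and merging
statistics of serial data, resolution-dependent noise, space-group
symmetry beyond the explicit inversion pair, anisotropic displacement,
solvent contribution, and per-delay scale drifts.  Passing tests
therefore demonstrate the correctness and internal consistency of the
analysis chain in its small-signal regime, not robustness to every
artefact of real serial crystallography data.

## Numerical choices

- Map grids: spacing ≤ dmin/3 per axis, rounded up to fast FFT lengths;
  reciprocal-space grids are Hermitian-completed so maps are exactly real.
  Below-Nyquist shapes warn and proceed.  Missing reflections contribute 0.
- Default toy problem size: hmax = 12, dmin = 1.6 Å (≈8 200 reflections,
  40³ maps, 33 delays); a full pipeline run takes ~2 s on one CPU.
- SVD sign convention: the largest-magnitude element of each LSV is made
  positive; autocorrelation is the lag-1 Pearson correlation of each RSV
  in delay order (non-uniform spacing ignored, the field's usual
  sequence-order statistic).  Component screening thresholds default to
  sv/sv₁ ≥ 0.05 and autocorr ≥ 0.5.
- The pipeline's SVD uses post-excitation delays only: maps at the
  reference delays share their noise with the reference itself and
  otherwise produce a spurious self-correlated component in null data.
  The pipeline also keeps only the leading contiguous run of selected
  ranks — an isolated deep-rank component passing both thresholds is a
  chance fluctuation.
- Scaling: the module-level Wilson fit (ln of binned intensity ratios vs
  s², slope −ΔB/2) reports k and ΔB and by default applies both.  The
  pipeline applies only a single common k derived from the pre-excitation
  reference: a per-delay ΔB correction would subtract the thermal
  overall-B signal, and even a per-delay k reacts to the signal itself.
  The per-delay (k, ΔB) fits are kept as diagnostics — the ΔB(t) trace is
  the Wilson-plot counterpart of the thermal RSV.
- Species decomposition is voxel-wise linear least squares against the
  profile design matrix (whole-cell maps); collinear profile pairs are
  rejected by Gram-matrix inspection.  Profiles are unit-peak (transient,
  oscillatory) or unit-plateau (hot) normalized; peak location is found on
  a dense grid.
- Yield scan: p ∈ {0.05, …, 1.00} in steps of 0.05; the acceptance
  threshold defaults to 1σ (rms) of each candidate extrapolated map; the
  chosen p is the smallest whose minimum probe-site density ≥ −threshold.
- Extrapolated amplitudes below zero are clamped at 0 and counted.
  Reflections whose structure factor changes sign between ground and
  photoproduct cannot be recovered by amplitude extrapolation (~6% of the
  toy transient case); this is an inherent limitation of the method, not
  of the implementation.

## Recovery experiment

`run_recovery` simulates a series with the model constants, analyses it
blind (SVD → global fit from ±30% perturbed initial guesses) and
tabulates true vs recovered {T, τ_damp, τ_decay, τ_rise1, τ_rise2}, plus
the transient yield from a dedicated single-species simulation at 20%
conversion followed by the p scan.  It runs at 5% excitation by default —
the small-signal regime the difference-Fourier approximation assumes —
where all constants recover to better than 0.1% noiselessly; at full
excitation the modulus nonlinearity limits recovery to ~1%.  With 1%
amplitude noise at full excitation the median period error across seeds
is ≈0.1%.

## Known limitations

- Amplitude extrapolation cannot restore sign-crossing reflections (see
  above); refinement against extrapolated intensities is out of scope.
- The difference-Fourier approximation degrades quadratically with
  excited fraction; quantitative SADED recovery assumes the small-signal
  regime.
- The toy's kinetic and geometric ground truth is self-consistent by
  construction; agreement of recovered constants demonstrates the
  analysis, not the photophysics of any real material.
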