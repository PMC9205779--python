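# Methods

## Photoactivation decay (FDAP)

**Model.** Photoactivation marks the protein inside a segment of length
`window_length` (default 6 µm) of a thin neurite, treated as a 1-D domain.
The marked total concentration starts as a top-hat. Two forward models are
used:

* *Pure diffusion.* One species with diffusion constant D. The
  window-averaged survival on an infinite line is
  `F(t) = erf(w) − (1 − e^{−w²})/(w√π)`, `w = a/√(Dt)`, `a = window/2`,
  continuous at t = 0 where F = 1. The implementation is validated against
  direct numerical quadrature of the heat-kernel convolution.
* *Reaction–diffusion.* Free protein (diffusing, constant `d_free`)
  exchanges with an immobile bound state: `f_t = D f_xx − k*_on f + k_off b`,
  `b_t = k*_on f − k_off b`. `k*_on` is pseudo-first-order (it absorbs the
  free binding-site concentration). Before activation the system is at
  steady state, so the activated top-hat is split between free and bound at
  the equilibrium bound fraction `φ_b = k*_on/(k*_on + k_off)`.

**Numerics.** The linear two-species system is solved on a long reflecting
domain by cosine-mode (Neumann) expansion: each mode obeys a 2×2 linear ODE
solved in closed form via its eigendecomposition, so the scheme is exact in
time, spectrally accurate in space and unconditionally stable — important
because each two-parameter fit evaluates the forward model ~10³ times.
Spectral truncation is corrected analytically: the unresolved high modes
carry the sharp top-hat edges, whose free component decays essentially
instantly while the bound component relaxes as `φ_b e^{−k_off t}`; adding
this tail in closed form leaves the pure-diffusion solution accurate to
machine precision against the infinite-line closed form. The domain is
enlarged automatically to keep reflections at least four diffusion lengths
away from the window. Total marked mass is conserved identically (the
reaction terms cancel in mode 0); the test suite verifies conservation by
integrating the reconstructed spatial profile and cross-checks the whole
solver against an independent finite-difference Crank–Nicolson integrator.

**Fitting.** `DiffusionDecayModel` fits log₁₀D by multi-start nonlinear
least squares (7 starts over 10⁻²–10² µm²/s). `ReactionDiffusionDecayModel`
fits (log₁₀k*_on, log₁₀k_off) with a start grid over 10⁻²–10² s⁻¹ (5×5 by
default; replicate studies use 3×3, verified to return identical optima) and
`d_free` fixed — fitting D together with both rates is degenerate on
window-averaged data. Goodness of fit χ² is the unweighted sum of squared
residuals: single normalized curves carry no per-point variance estimate, so
χ² is meaningful only for comparisons on the same curve (each reaction fit
also records the χ² of the pure-diffusion fit and flags a possible
mis-specification when it is worse by more than a configurable factor).
Tie-breaks: lowest χ², then smallest parameter-vector norm. A fit whose
optimum pins the search bound is flagged non-converged.

**Identifiability.** With a 6 µm window, `d_free` ≈ 10 µm²/s and 112 frames
at 1 frame/s, individual rates are resolvable only when exchange is slow on
the acquisition timescale: at (k*_on, k_off) = (7, 3) s⁻¹ the curve differs
from its doubled-rate twin by < 0.015 — below a σ = 0.02 noise floor — so
only the ratio (through D_eff = d_free/(1 + k*_on/k_off)) is measurable; at
a 2 s dissociation time the rates separate cleanly. The synthetic default
(k*_on, k_off) = (7/6, 1/2) s⁻¹ therefore keeps the tubulin-like 70% bound
fraction while remaining identifiable; recovery at σ = 0.02 then reaches
~16% relative RMSE over 100 replicates. `d_free` has no universal value and
must be supplied per protein (10 µm²/s is a typical free-cytosolic-protein
placeholder used in examples).

## Single-molecule residence time

An immobility event opens at an anchor localization and extends while each
*consecutive* frame (no gaps) stays within `radius` (default 50 nm) of the
anchor. Anchoring to the first localization is the plainest reading of
"stays within a radius"; a rolling-centroid variant was deliberately not
made the default. Gaps terminate events; events touching the end of a track
are kept, a censoring bias that is negligible while tracks are much longer
than the dwell (the default study: 160 frames vs 3-frame dwells). Events
need ≥ 2 frames — one frame cannot evidence dwelling.

The duration histogram (integer frame bins, zero bins inside the observed
range included) is fitted with `counts(n) = A e^{−nΔt/τ}` on raw counts by
least squares, initialized from a log-linear regression. For exponential
dwells sampled with random camera phase the observed frame counts are
geometric with ratio `e^{−Δt/τ}`, so the fit is unbiased; at 2000+ events
τ is recovered within a few percent. Localization noise interacts with the
fixed radius: at σ = 16.7 nm (the reported precision) a bound molecule
wanders out of a 50 nm radius with ~10% probability per frame, truncating
long events and biasing τ low by tens of percent — an intrinsic property of
the counting rule, not of the fit; recovery studies therefore use σ = 5 nm
to isolate estimator behavior. The camera interval is an acquisition
setting with no canonical value and is a required parameter everywhere
(studies here use 20 ms, typical of high-speed HILO imaging).

## Mitochondria classification

Because the apparent diameter fluctuates frame to frame (z-motion,
rotation, fusion/fission), "moved further than its own size" is posed
statistically: the per-track diameter sample is tested against the track's
net start-to-end displacement with a one-sample t-test
(`t = (mean diameter − displacement)/(sd/√n)`, two-sided p, confidence
1 − p). Mobile: confidence > 0.95 and t < 0; stationary: confidence > 0.95
and t ≥ 0; otherwise undefined and excluded from kinematics. Net
displacement is the default reading of "displacement of the track"; maximal
excursion from the start is available as an option. Tracks with fewer than
3 diameter observations are undefined; zero diameter variance degenerates
to a sign comparison with confidence 1 (logged). Per-cell summaries report
fractions over all tracks and over defined tracks, and mobile-pool
velocity/speed (missing, never zero, when a cell has no mobile tracks).

## Vesicle transport

Pipeline per track: (1) drop tracks spanning < 15 frames (3 s at
5 frames/s); (2) orient arclength s away from an axon-hillock reference so
anterograde is positive; (3) gate mobility at net |Δs| strictly greater
than 0.75 µm; (4) for each pair of successive observations ≤ 3 frames
apart, compute ds/frame = Δs/Δframes (this is how 1–2 frame tracking gaps
are accounted for) and assign anterograde (> +0.02 µm/frame), retrograde
(< −0.02) or stall (within ±0.02, boundary inclusive — equality is the
conservative stall call); (5) metrics: signed velocity (net Δs/duration),
speed and max speed (mean/max |ds/frame|·fps), processivity and state
changes. Gaps longer than the linkable maximum split a track; runs and
state changes never bridge a split.

Processivity is the mean length (µm) of maximal uninterrupted
anterograde/retrograde runs — the standard motor-transport meaning, chosen
because it can fall while speed is nearly unchanged, which is the behavior
the metric exists to capture; the fraction of time in motion is available
behind `processivity_mode="time_fraction"`. Per-cell summaries are
unweighted means over that cell's mobile tracks; state changes are emitted
both as per-track mean and per-cell sum, since "cumulative" admits both
readings.

## Synthetic data

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`, and return truth records sufficient to score
every downstream estimator.

* **FDAP**: the spectral forward model plus additive Gaussian noise
  (default σ = 0.02), renormalized at the first frame exactly as measured
  curves are; acquisition defaults are 6 µm window, 1 frame/s, 112 frames.
* **Kiss-and-hop**: continuous-time alternation of exponential bound
  episodes (default mean 60 ms) at fixed anchors and instantaneous
  fixed-length hops (default 300 nm, random direction), sampled with random
  camera phase; isotropic Gaussian localization noise per frame. Not
  modeled: photophysics (blinking/bleaching), free-diffusion excursions
  between sites, 3-D geometry.
* **Organelle tracks**: a 3-state (anterograde/retrograde/stall)
  continuous-time Markov chain, advanced per frame through the matrix
  exponential of its generator and initialized at stationarity; ±speed/fps
  increments plus localization noise; i.i.d. frame drops capped at the
  2-frame linkable maximum so gap handling is exercised while tracks stay
  linkable. Vesicle defaults: 5 frames/s, 60 s, speeds 1.0/0.9 µm/s,
  10 nm noise (sub-pixel centroid precision after deconvolution; half the
  stall threshold), starts 60–120 µm from the hillock so no track can reach
  the reference within the window. Mitochondria defaults: 0.5 frames/s,
  8 min, speeds 0.5/0.4 µm/s, lognormal per-frame diameters (mean 0.6 µm,
  CV 0.15), 30 nm jitter, mobile fraction 0.2.

Passing recovery tests on these populations shows the estimators implement
their definitions correctly under realistic noise; it does not certify
performance on real microscopy, where localization error is non-Gaussian,
organelles leave the focal plane, neurites curve in 3-D, and tracker
linking errors correlate across frames.

## Problem sizes and numerical settings

Recovery studies use 100 noisy FDAP replicates (acceptance script; 15 in
the routine test suite), 250 molecules × 160 frames (~8000 events) for
residence times, 200 mitochondria tracks and 150 vesicle tracks; stall-step
misclassification under noise (ds noise σ√2 = 14 nm vs the 20 nm/frame
threshold) bounds segmentation accuracy near 98%, and state-change
recovery is measured on an anterograde↔retrograde switching population
(mean 2 switches/track) where noise-induced stall flips cannot inflate the
count. Spectral solver: 2000 modes, domain ≥ 20 windows (auto-enlarged with
√(4 D t_max)). All tolerances asserted in tests are stated inline with the
property they check.

## Known limitations

* Infinite-line geometry: no sealed neurite ends (activation is
  mid-process and 112 s is short relative to process length).
* χ² is unweighted; no per-point variance model.
* The immobility criterion's τ depends on the radius/noise ratio (above).
* Imaris' autoregressive-motion linking is proprietary: its declared
  parameters are only validated and echoed, tracks are consumed as given.
* No raw-image processing, spot detection or track linking; no
  group-comparison statistics beyond per-cell summaries.
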