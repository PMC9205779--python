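# neurokin

Quantitative live-cell analysis of microtubule-binding kinetics and axonal
transport in neurons, built for experiments of three kinds:

1. **Photoactivation kinetics (FDAP).** A 6 µm segment of a neurite
   expressing a photoactivatable-GFP fusion (tau, tubulin) is activated and
   the window-averaged fluorescence F(t) is followed at 1 frame/s. For a
   freely diffusing species the decay has the closed form
   F(t) = erf(w) − (1 − e^(−w²))/(w√π) with w = a/√(Dt) (a = half the window
   length), from which an effective diffusion constant D_eff is fitted. For
   a species exchanging with an immobile scaffold (the microtubule lattice)
   the package fits the two-species reaction–diffusion system
   ∂f/∂t = D∂²f/∂x² − k*_on f + k_off b, ∂b/∂t = k*_on f − k_off b for the
   pseudo-first-order association rate k\*\_on and dissociation rate k_off,
   with the free-diffusion constant D held fixed. The equilibrium bound
   fraction k\*\_on/(k\*\_on + k_off) gives the fraction of protein on the
   lattice — for tubulin, the percent of polymerized tubulin. In fast
   exchange D_eff = D/(1 + k\*\_on/k_off).
2. **Single-molecule residence times.** Sub-stoichiometrically labeled
   molecules interacting with axonal microtubules by kiss-and-hop are
   temporally immobile while bound: their localizations stay within a 50 nm
   radius over consecutive frames, then hop hundreds of nm. Counting
   consecutive in-radius frames yields dwell durations whose frequency
   histogram is fitted with a single exponential A·e^(−nΔt/τ); τ is the
   residence time.
3. **Organelle transport.** From tracker exports (TrackMate/Imaris-style
   CSV): mitochondria are classified mobile/stationary/undefined by a
   one-sample t-test of each track's recorded diameters against its
   displacement (mobile: confidence > 0.95 and t < 0); vesicles are gated
   mobile when net displacement exceeds 0.75 µm per 60 s, then every step of
   a mobile track is labeled anterograde/retrograde/stall against a
   0.02 µm/frame (0.1 µm/s at 5 frames/s) threshold, with 1–2 frame
   tracking gaps normalized by elapsed frames. Derived metrics: velocity,
   speed, max speed, processivity (mean uninterrupted run length) and the
   number of state changes.

No microscopy data are required: `neurokin.simulate` generates curves,
kiss-and-hop localization series and organelle tracks from the same models
with full ground truth, so every estimator is verifiable by parameter
recovery.

## Worked example

Simulate three FDAP curves of a tubulin-like species (70% bound,
k\*\_on = 1.17 s⁻¹, k_off = 0.5 s⁻¹, noise σ = 0.02) and fit the
reaction–diffusion model:

```bash
$ nk simulate fdap --n-cells 3 --seed 7 --out sim
wrote 3 curves to sim
$ nk fit fdap sim/curves.csv --model reaction --d-free 10 --out fit
fitted 3 curves -> fit/fits.csv
```

`fit/fits.csv` then holds, per cell:

```
cell_id  k_on_star    k_off  bound_fraction     chi2  converged
cell000   1.077476 0.492640        0.686240 0.033641       True
cell001   1.099008 0.470569        0.700194 0.039420       True
cell002   1.266554 0.547139        0.698329 0.039641       True
```

Each row recovers the generative rates within the noise-limited scatter;
`bound_fraction` is the polymer fraction (truth 0.70) and `chi2` the
unweighted sum of squared residuals of the fit. The same pattern applies to
the other stages: `nk simulate {smt,mito,vesicle}` writes data plus
`truth.csv`, and `nk smt dwell`, `nk transport mito`, `nk transport vesicle`
analyze them. Python entry points (`DiffusionDecayModel`,
`ReactionDiffusionDecayModel`, `ResidenceTimeFitter`, `MitoTrackClassifier`,
`VesicleTransportAnalyzer`) follow scikit-learn conventions (`fit`,
`get_params`, fitted attributes with trailing underscores).

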