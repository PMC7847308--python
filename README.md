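# gietkit

**Graphene-induced energy transfer (GIET) as a computational axial ruler
for membrane-bound fluorophores.**

A single sheet of graphene quenches the fluorescence of a nearby dye by
near-field energy transfer with a steep (~d⁻⁴) distance dependence.  On a
graphene-supported lipid monolayer this turns relative fluorescence
lifetimes or intensities — measured on graphene versus a quenching-free
reference substrate — into nanometer-scale heights of proteins, DNA and
protein complexes above the membrane, over a 3–25 nm working range that
bridges the gap between FRET and localization microscopy.

`gietkit` is for biophysicists who make such measurements.  It provides:

- **First-principles distance curves.**  The power dissipated by an
  oscillating electric dipole above the stratified
  glass | graphene | lipid | water system is computed with the classical
  plane-wave (CPS) formalism — generalized Fresnel reflection of each
  plane/evanescent wave component by the layer stack, integrated over the
  in-plane wavenumber.  The orientation-averaged relative emission power
  S(d)/S₀ gives the relative lifetime

  τ_G/τ₀ = S₀ / [(1 − ϕ)·S₀ + ϕ·S(d)],

  with ϕ the quantum yield; the intensity ratio I_G/I₀ follows the same
  relation.  Curves for FAM, EGFP, mNeonGreen and Dy647P1 on the
  calibrated 520/670 nm stacks are built in.
- **Ratio → distance inversion** with asymmetric uncertainty brackets
  (invert ratio ∓ s.d. on the strictly monotone curve).
- **DNA-nanoruler tilt calibration**: a statsmodels-style
  `TiltCalibration` model fits a single global tilt angle α to measured
  ratios via d = l_DNA·sin α + l_ML, with bootstrap standard errors.
- **Single-molecule GIET (smGIET) analysis**: spot localization by
  iterative Gaussian-mask centroiding, trace linking with crowding
  exclusion, STaSI change-point segmentation, Gaussian-emission HMM
  (Baum–Welch + Viterbi), state occupancies, dwell-time transition
  kinetics, transition-density plots, per-state heights and axial
  precision.
- **Synthetic data generators** for every stage (Markov intensity traces
  with GIET-modulated means, TIRF image stacks with Poisson noise,
  nanoruler datasets), all seeded and returning ground truth.

## Worked example

```python
import numpy as np
import gietkit as gk

# 1. distance curve and inversion
fam = gk.build_curve("FAM")                      # 2.5-30 nm, 0.05 nm grid
est = gk.invert_ratio(fam, 0.080, 0.006)         # measured tau_G/tau_0 +- sd
print(f"d = {est.d_nm:.2f} nm ({est.d_low_nm:.2f}-{est.d_high_nm:.2f})")

# 2. nanoruler tilt calibration on synthetic data
meas = gk.simulate_ruler_dataset(
    43.0, (0.0, 1.7, 5.1, 6.8, 8.5, 10.2, 11.9, 17.0), fam,
    noise_cv=0.03, seed=11)
print(gk.TiltCalibration(meas, fam).fit(seed=0).summary())

# 3. single-molecule state analysis on synthetic 3-state traces
dy = gk.build_curve("Dy647P1")
Q = np.array([[-0.6, 0.5, 0.1], [0.4, -0.8, 0.4], [0.1, 0.5, -0.6]])  # 1/s
spec = gk.TraceSimSpec(heights_nm=(4.7, 6.8, 11.2), curve=dy,
                       rate_matrix_per_s=Q, n_traces=60, n_frames=600)
traces, _ = gk.simulate_traces(spec, seed=7)
res = gk.SmGietModel(traces, 3, curve=dy,
                     reference_mean_on_glass=1000.0).fit(seed=1)
print(res.summary())
```

This prints:

```
d = 4.47 nm (4.32-4.62)

Tilt calibration (global least squares vs simulated GIET curve)
---------------------------------------------------------------
n measurements      : 8
tilt angle alpha    :  42.99 deg
bootstrap s.e.      :   0.26 deg (200 replicates)
residual sum sq.    : 1.596e-04

Single-molecule GIET state analysis
===================================
traces: 60   frames: 36000   states: 3   logL: -178567.8

state   mean(a.u.)   sd(a.u.)   occupancy        dwell(s)   exit rate(1/s)
    L        252.9       18.9    31.9 +- 2.1%      1.601      0.630
    M        414.3       31.2    40.2 +- 2.1%      1.248      0.793
    H        694.2       51.8    27.9 +- 2.1%      1.447      0.681

state   h (nm)   bracket (nm)
    L      4.7   (4.4-5.0)
    M      6.8   (6.4-7.2)
    H     11.2   (10.2-12.4)
```

The inverted distance (4.47 nm from graphene) is the height of a FAM
label whose lifetime drops to 8% of its on-glass value; the tilt fit
recovers the 43° angle used to generate the noisy ruler ratios; and the
state analysis resolves the three simulated conformational heights
(4.7 / 6.8 / 11.2 nm above the membrane) with their occupancies and
second-scale exchange kinetics.

A `giet` command-line tool wraps the same functionality
(`giet curve`, `invert`, `calibrate`, `simulate`, `localize`,
`analyze`; see `giet --help`).

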