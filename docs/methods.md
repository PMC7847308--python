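# Methods

## Electromagnetic model

An excited fluorophore is treated as an ideal electric dipole at height
z above a planar stratified medium.  Its total dissipated power
(radiative plus non-radiative) follows from the classical plane-wave
(CPS) expansion: each plane or evanescent wave component, labelled by
the normalized in-plane wavenumber u = k∥/k₁ (k₁ the wavenumber in the
emitter's medium), is reflected by the stack with a generalized Fresnel
coefficient r_s(u), r_p(u), and the interference of the reflected field
with the source current is integrated:

    S⊥/S₀ = 1 + (3/2) Re ∫₀^∞ (u³/l₁) r_p e^{2 i k₁ l₁ z} du
    S∥/S₀ = 1 + (3/4) Re ∫₀^∞ (u/l₁) [r_s − l₁² r_p] e^{2 i k₁ l₁ z} du

with l₁ = √(1 − u²), branch Im ≥ 0.  A freely rotating label is modelled
by the isotropic orientation average (S⊥ + 2 S∥)/3.  For u > 1 the
components are evanescent; absorption in the graphene sheet enters
through Im r and constitutes the distance-dependent energy-transfer
channel.  Sanity limits are enforced by tests: a homogeneous medium
gives S/S₀ = 1 to 1e−9, and S/S₀ → 1 at z = 1000 nm.

The stack reflection coefficients are computed by the standard recursion
over interfaces with complex indices (equivalent to the transfer-matrix
method), validated against an independently coded recursion to 1e−10.

**Reference geometry** (refractive indices at the emission wavelength):
glass half-space n = 1.52; graphene slab, thickness 0.34 nm, n =
2.68 + 1.21i for green emitters (FAM 518 nm, EGFP 507 nm, mNeonGreen
517 nm) and n = 2.76 + 1.40i for red emission (Dy647P1 667 nm); lipid
monolayer n = 1.44, thickness 2.5 nm; water half-space n = 1.33.  The
graphene index is tabulated at these two bands only; other wavelengths
require a user-supplied index — no silent interpolation.  Emission is
treated as monochromatic at the emission maximum.

**Quadrature.**  The u-integral is split at the branch point u = 1.  The
propagating range uses u = sin θ (removing the 1/l₁ endpoint
singularity); the evanescent tail uses u = √(1 + x²), which exposes the
explicit damping factor e^{−2 k₁ z x}.  The transparent substrate's
critical wavenumber imprints a square-root branch point on r(u) at
u_c = n_glass/n_water; the tail is split there and a t² substitution
applied on both sides, restoring spectral convergence of the composite
Gauss–Legendre rule.  Panels are doubled until successive estimates
agree to 1e−8 relative (default; the contract is 1e−6).  The tail is
truncated where the integrand is damped below ~1e−19, using the fact
that beyond u_c the only loss channel is the absorber, reached through
z nm of water plus the finite transparent layers.  Agreement with a
10⁶-node brute-force trapezoid oracle is tested at 1e−5 relative.

## Lifetime-ratio curve and distance convention

With quantum yield ϕ and free-space lifetime τ₀, only the radiative
channel is fixed while the total decay rate scales with S/S₀, giving

    τ_G/τ₀ = 1 / (1 − ϕ + ϕ·S(d)/S₀).

Of the two readings of this relation the implemented one is the only one
with the correct physical limit τ_G/τ₀ → 1 as S → S₀ (d → ∞).  In the
absence of static quenching the intensity ratio I_G/I₀ obeys the same
relation, so one curve serves both readouts.

**Distance coordinate.**  The curve's distance axis d follows the
convention of the published nanoruler calibration that this model
reproduces: the dipole sits at height d above the top surface of the
lipid monolayer, and heights above the membrane follow as
h = d − 2.5 nm.  Under this convention the model reproduces all
calibrated ratio↔distance anchor pairs for FAM, EGFP and Dy647P1 to
within 0.1 nm (tests assert ±0.3 nm, the experimental uncertainty).
The alternative, strictly geometric reading — emitter at d − 2.5 nm
above the monolayer so that d counts from the graphene surface through
the lipid — shifts the axis by exactly the monolayer thickness and is
inconsistent with every published anchor pair; it was therefore
rejected.  Users who need the geometric distance to the graphene sheet
under the alternative reading can add the monolayer thickness
themselves; `relative_emission_power` takes the unambiguous emitter
height above the stack directly.

Curves are tabulated on a ≤ 0.1 nm grid (default 0.05 nm over
2.5–30 nm), checked for strict monotonicity at build time, and
interpolated shape-preservingly (monotone piecewise cubic), which keeps
off-grid errors below 0.5% and guarantees invertibility.  Inversion uses
root bracketing to 1e−3 nm.  Measurement uncertainty propagates by
endpoint inversion of ratio ∓ s.d. (asymmetric bracket), not a
linearized delta method, matching the convention used for reported
heights; endpoints are clipped to the curve's valid range.

## Nanoruler tilt calibration

Membrane-anchored DNA duplexes place a dye at contour length l_DNA from
the anchor; with a global tilt angle α between duplex and surface the
dye sits at d = l_DNA·sin α + l_ML (l_ML = 2.5 nm).  `TiltCalibration`
minimizes Σᵢ wᵢ [rᵢ − C(lᵢ sin α + l_ML)]² over α ∈ (0°, 90°] by bounded
scalar minimization (xatol 1e−4°).  One α is shared by all lengths and
both label ends; intensity- and lifetime-mode data are pooled by default
(separate fits via `mode=`).  The default loss is unweighted; 1/s.d.²
weighting is available.  Uncertainty comes from a seeded case-resampling
bootstrap (≥ 200 replicates); degenerate resamples with fewer than two
distinct nonzero lengths carry no tilt information and are redrawn.
Convergence at a bound sets a warning flag.  The calibration's standard
noise proxy is 3% multiplicative Gaussian ratio noise, under which the
recovered angle stays within ±1° of truth and the bootstrap s.e. below
2° (tested).

## Single-molecule pipeline

**Localization.**  Candidate spots are local maxima of the PSF-smoothed
frame rising `threshold` (default 5) robust noise s.d. above background;
duplicates closer than 2σ_PSF keep the brighter peak.  Positions are
refined by iterative Gaussian-mask centroiding (tolerance 0.01 px, max
50 iterations); the intensity is the background-subtracted, mask-
weighted flux (least-squares Gaussian amplitude × 2πσ²), with local
background from the ROI border median.  Saturated frames are flagged,
not fatal.  Defaults mirror the reference instrument: 107 nm pixels,
32 ms frames.

**Trace linking.**  Frame by frame, localizations are matched to the
nearest running-mean anchor within 150 nm, globally greedily by
distance, so the result is invariant to input order within a frame
(tested).  Traces shorter than 100 frames are dropped; surviving pairs
with anchors closer than 500 nm are both removed (crosstalk exclusion).

**STaSI segmentation.**  The noise scale is estimated as
median(|Δy|)/(√2·0.6745).  Change points are found by recursive
bisection on the Student-t statistic of the mean difference, accepted
against a Bonferroni-corrected two-sided critical value (family level
0.01 across the n candidate positions) — conservative, so pure noise
yields no splits.  Segment means are merged agglomeratively
(closest-pair, count-weighted) into nested state sets, and the state
count is chosen by minimum description length: Gaussian residual code
length ssr/(2 ln 2 σ²) plus a model cost of ½ log₂N bits per state mean
and log₂N bits per change point.  This is our MDL variant; it recovers
noise-free steps exactly and labels ≥ 95% of frames correctly at ≥ 4σ
state separation (tested).

**HMM.**  The best-fitting third of traces — ranked by normalized
residual variance of the piecewise-constant fit, a scale-invariant score
chosen because the selection metric is otherwise unspecified — seeds a
K-state Gaussian-emission HMM: state means by 1-D k-means on the
framewise STaSI levels, a common noise s.d., and a pseudo-counted
transition matrix from nearest-level label sequences.  Baum–Welch runs
on the pooled traces (each an independent sequence) one sweep at a time,
recording the exact log-likelihood after every sweep, until the relative
change drops below 1e−6 (cap 1000).  A variance floor of 1e−6·var(data)
guards against collapse (flagged when hit).  K is user-set, default 3;
there is no automatic model selection beyond the STaSI initialization,
mirroring the two-stage design of the reference analysis.  States are
re-sorted ascending by mean (L/M/H convention).  Decoding is Viterbi;
ties resolve to the lower state index.

**Kinetics.**  Occupancies pool all decoded frames; the s.e.m. is a
seeded bootstrap over whole traces (frames within a trace are
correlated).  Dwell times are maximal constant runs with the first and
last run of each trace censored and excluded.  The exit rate is the
slope of the mono-exponential fit to the empirical log-survival
function, evaluated at the unique observed dwell times and weighted by
the inverse variance of ln Ŝ (≈ (1−S)/(nS)) so the noisy deep tail does
not dominate; an exponential-MLE alternative (1/mean) is available.
States with fewer than 5 complete dwells report NaN plus the count.
Pairwise rates split the exit rate by observed branching fractions, so
they sum to the exit rate by construction.  Two sources of small bias
are documented and bounded by tests rather than corrected: frame
discretization (slope estimates −ln(1−p)/Δt rather than p/Δt) and
length-biased censoring in finite traces (~mean dwell / trace length);
both stay within the 10–15% test tolerances at the simulated sizes.

**Heights and precision.**  Per-state ratios are state mean / on-glass
reference mean, inverted on the (lifetime-ratio) curve with the state
s.d. propagated as an asymmetric bracket — intensity and lifetime ratios
are interchangeable under the lifetime-ratio relation above, and this
equivalence is applied deliberately.  Axial precision: per-trace
RMSD/mean of on-glass intensities, pooled by averaging; the intensity
ratio divides two such intensities, so its relative error is √2 larger
(7.5% per intensity → 10.6% on the ratio — the quadrature reading, which
matches the propagated value, rather than a plain product).

## Synthetic data

`simulate_traces` samples a continuous-time Markov chain (generator Q,
rows sum to 0) at the 32 ms frame interval via the matrix exponential,
starting from the stationary distribution; per-frame intensities are
Gaussian with mean on_glass_mean·curve(h + l_ML) and constant
coefficient of variation (default 7.5%, the measured single-molecule
relative intensity error — the per-frame experimental cv is only
indirectly constrained, so this proxy is used as-is).  The Gaussian
constant-cv choice matches the RMSD/mean framing of the precision
analysis; the image simulator, by contrast, is Poisson-based, covering
the photon-counting regime.  Photobleaching, when enabled, is a single
irreversible step to background at an exponential time (single-step
bleachers are what trace screening selects for), with bleached frames
marked −1 in the ground truth.  Reference simulation conditions for the
3-state analyses: heights 4.7/6.8/11.2 nm on the Dy647P1 curve (state
means ≈ 0.25/0.41/0.69 of the on-glass mean), exchange rates of order
0.5–1 s⁻¹ dominated by L↔M and M↔H, 100 traces × 500–1000 frames
(~10⁵ frames, comparable to the pooled reference datasets).

`simulate_image_stack` renders static Gaussian spots (uniform positions
with configurable minimum separation; count from a Poisson draw at
0.5 µm⁻² by default, the sparse single-molecule regime) over a constant
background, applies Poisson photon noise and Gaussian read noise, and
returns a 16-bit stack plus ground truth.  It omits diffusing emitters,
z-dependent PSF shape and EM-gain statistics.

`simulate_ruler_dataset` evaluates the curve at d = l sin α + l_ML for
the calibrated contour lengths (plus l = 0 for a lipid-conjugated dye)
and applies multiplicative Gaussian noise.

**What passing tests show — and don't.**  The generators realize exactly
the statistical assumptions of the analysis (Gaussian emissions,
Markovian switching, static emitters, single-step bleaching).  Recovery
tests therefore validate correctness of the implementation and
identifiability at realistic sizes, not robustness to model violations
in real data (non-Gaussian photon noise at low counts, spectral
dynamics, drift, blinking, diffusing backgrounds).

## Numerical and design notes

- All randomness flows from explicit seeds; one top-level seed derives
  per-stage sub-seeds via a CRC-keyed SeedSequence.
- Units: nm for lengths, ns for lifetimes, s for kinetics; tables are
  UTF-8, tab-delimited, '.' decimal, units encoded in column names.
- Emitters are restricted to the water half-space above the stack
  (height > 0); dipoles inside a layer are out of scope.
- The tilt fit clips trial distances to the curve's valid range so
  extreme trial angles stay finite during optimization.
- `normalize_intensity` ((m₀/m_G)·(I_G,raw/I₀,raw)) and `frap_normalize`
  ((I_in − I_BG)/(I_out − I_BG)) are exact closed forms with validation
  only; degenerate FRAP references (denominator ≤ 0) are rejected.
- The known 20–5´ label/lipid-proximity failure mode is handled by
  dataset construction (that ruler is excluded from calibration sets;
  the lipid-conjugated dye enters with l_DNA = 0).
- Known limitations: no spectral averaging over the emission band, no
  NA-dependent detection corrections, no dipole-inside-layer theory, no
  drift correction or diffusion analysis, photobleaching-step counting
  replaced by an optional single-step filter flagged experimental.

## Problem sizes

Defaults were chosen so the whole test suite runs in well under a
minute on one core: curves at 551 grid points each (~1.5 s), tilt
bootstraps at 200 replicates, HMM recovery at 100 traces × 500–1000
frames, kinetics consistency at 150–500 traces × 1500–2000 frames.
These sizes are comfortably identifiable for the tested tolerances;
larger ensembles tighten the stochastic checks but do not change any
conclusion.
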