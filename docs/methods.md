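# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Acquisition model and phantoms

The synthetic acquisition emulates a multi-shell HARDI protocol: shells at
b = 1000/2000/3000 s/mm² with 90 directions each plus 6 b = 0 volumes, at
1.25 mm isotropic resolution. Direction sets are spherical Fibonacci
lattices with one seeded random rotation per shell: deterministic,
near-uniform (minimum pairwise angle ≈ 18.7° at 90 directions), and free
of pole clustering.

Phantoms are tubes: a centerline polyline with a radius, rasterized onto
the voxel grid by nearest-centerline distance. In-tube voxels carry the
bundle's anisotropic ground truth (axially symmetric tensor with
d∥ = 1.7×10⁻³, d⊥ = 0.3×10⁻³ mm²/s by default, and neurite-model
parameters ν_ic, ν_iso, κ); the background is isotropic with
ADC 0.9×10⁻³ mm²/s (tissue-like). Signals come from either the tensor law
or the full three-compartment model, per `PhantomSpec.signal_model`.
Voxels shared by two tubes are crossing voxels (equal-fraction mean of the
two single-fiber signals, both orientations recorded) and are an error
unless explicitly enabled — a single-compartment truth cannot represent a
crossing. Noise is Rician by default (magnitude MRI), with a Gaussian
option for analytic tests. The phantom's default noise level is a
configuration choice: the source protocol's SNR is not published, so tests
state their own sigma (SNR 30 where a noisy condition is needed).

What the phantoms deliberately do not emulate: anatomy (no T1 contrast, no
gyral geometry), susceptibility/eddy artifacts (the emulated protocol is
already corrected), partial-volume mixtures at tissue interfaces, and
spatially varying microstructure within a bundle. Passing tests therefore
demonstrate the correctness and calibration of the computational chain,
not robustness to real-data confounds.

## Watson orientation integrals

The dispersed-stick compartment averages the stick signal over a Watson
distribution W(n; μ, κ) ∝ exp(κ(μ·n)²). This average is computed by
quadrature on a 3072-point Fibonacci sphere with numerically normalized
weights, rather than by hypergeometric series: the quadrature is a few
lines, vectorizes, and is testable against both limits (κ → 0 gives the
isotropic average; κ = 64 leaves the perpendicular signal within 2% of
S₀). Inside the NODDI refinement loop the same integral is read from a
per-shell interpolation table over (|cos ψ|, log κ) (51 × 25 nodes, built
once per gradient table), which reproduces the quadrature to ~10⁻⁴.

## Local model fitting

**DTI** — weighted linear least squares on the log signal (one IRLS pass
with predicted-signal weights), restricted to b ∈ {0, 1000}: the
quantitative tensor metrics are defined on the b = 1000 shell only, and a
test asserts that corrupting the higher shells cannot change the fit. At
zero noise the estimator inverts the generator to machine precision.
Negative eigenvalues are clamped to zero before scalar computation and
counted; FA of an all-zero tensor is defined as 0.

**CSA q-ball** — per shell, E = S/S₀ is clamped to [δ, 1−δ] with δ = 10⁻³
(the double log is otherwise unbounded), expanded in even-order real
spherical harmonics (default order 8; 45 coefficients, supported by 90
directions/shell; configurable 2–8 and automatically validated against
the per-shell direction count) with Laplace–Beltrami regularization
λ = 0.006. The ODF follows by scaling degree-l coefficients with
−l(l+1)·2πP_l(0)/(16π²) and pinning the l = 0 term to 1/(2√π). The three
shells are combined by averaging the per-shell ODF coefficients with
equal weights — the source protocol does not define the fusion, and
averaging is simple and testable. Sampled ODFs are clamped at zero and
normalized to unit sum over the direction set. GFA uses the population
std/rms of the sampled ODF, so a one-hot profile on N directions gives
√((N−1)/N), not exactly 1.

**NODDI** — dense grid search (ν_ic, ν_iso ∈ {0, 0.1, …, 1}, κ ∈ {0.25,
0.5, 1, 2, 4, 8, 16, 32, 64}, 30 hemisphere orientations; ~33k candidate
signals scored by vectorized SSD) followed by bounded nonlinear least
squares per voxel over (ν_ic, ν_iso, κ, θ, φ). If refinement fails or
does not improve on the grid point, the voxel falls back to the grid
solution and is flagged in a QC mask. Requires ≥ 2 nonzero shells. A
coarse grid (6 × 6 × 4 × 12, no refinement) exists for throughput-bound
runs such as the demo.

## Tractography

The propagation domain is the WM mask dilated by one voxel
(6-connectivity); in the phantom world there is no T1 image to derive it
from, so the dilation stands in for the anatomically defined domain.
Seeds are uniformly jittered inside every domain voxel (8 per voxel by
default). Growth is bidirectional with 0.3 mm steps; total lengths
outside 1.25–300 mm are discarded.

The step-direction law is a Gibbs draw over a 724-direction tessellation
restricted to the aperture cone, with energy

  E(v) = −γ·ln ψ̃(v) + λ·(1 − v·v_prev),  p(v) ∝ exp(−E(v)/T)

where ψ̃ is the ODF after per-voxel baseline (minimum) subtraction,
γ = 12 is a sharpening exponent and λ = 50 a straightness prior. Three
readings fixed here because the cited sampler's exact functional is not
published: (1) the 30° "aperture angle" is taken as the full cone apex
angle, so candidates lie within 15° of the previous direction — this is
the reading under which the engine's angular-coherence invariant (mean
deviation below half the aperture on a straight tube) is natural;
(2) the isotropic ODF baseline is removed before sampling, since the raw
CSA ODF of even a coherent single-fiber voxel carries a large uniform
component that would otherwise dominate the draw; (3) the sharpening
exponent and the curvature term provide the regularization the method's
name promises — with γ = 1, λ = 0 the direction performs an almost
unrestored random walk inside the broad CSA lobe and even a straight
3 mm-radius tube is not followed. T = 1 keeps the published temperature
semantics: T scales the whole energy.

ODF values on the tessellation are precomputed per voxel and trilinearly
interpolated at off-grid positions; since SH evaluation is linear, this
equals interpolating the SH coefficients and evaluating them. GFA along
streamlines is stored for downstream use but low-GFA stopping is *not*
applied — propagation stops on domain exit or an empty candidate set
only. Tracking is bit-reproducible for a fixed RNG seed.

## Bundle labeling and tractometry

Streamline-to-centroid distance: both curves are resampled to 21
equidistant points and compared by the maximum corresponding-point
distance, minimized over the two orientations (flip-symmetric). The two
published phrasings — a "maximum pairwise distance threshold" and the
"minimum pairwise distance" assignment — are read consistently as:
max-over-points defines the distance (strict, Guevara-style), min-over-
tracts defines the assignment among tracts whose threshold is met; ties
cannot split a streamline across tracts. The packaged toy atlas uses a
10 mm threshold; real atlases carry their own per-tract thresholds, which
are data, never hard-coded.

Density masks count *distinct* streamlines per voxel, so the 0.1 mm
metric resampling cannot inflate counts. Tract volumes are voxel counts
times voxel volume (cm³), normalized to TBV and WMV (mask voxel counts)
as percentages. Tract metric means pool the trilinearly interpolated map
values at every 0.1 mm-resampled streamline point — point-weighted, so
longer streamlines weigh more, which is the literal "mean over all fiber
points". A Shapiro–Wilk p-value over the pooled values can be recorded as
QC; it never gates the mean.

## Cohort statistics

Student's t (pooled variance, two-sided) is always the reported test;
Shapiro–Wilk and Levene (center = mean) are recorded as QC columns and do
not trigger a Welch or nonparametric fallback (none is published).
Cohen's d uses the df-weighted pooled SD; boundary |d| values go to the
higher bin (the published inequalities are open at 0.2/0.5/0.8). The
relative difference uses the men-mean denominator — the convention that
reproduces the printed TBV (+12.6%) and genu (−7.3%) values; the printed
WMV relative difference (13.6%) is reproduced by no denominator
convention on the rounded summaries and was evidently computed on
unrounded means, as were one or two small-tract rows. The comparison
family is computed from the atlas — 10 measures per tract (2 normalized
volumes + 8 metric means) plus TBV and WMV, i.e. 772 for 77 tracts — and
the threshold is α/m. The ANCOVA is an OLS of normalized volume on
TBV × sex; the interaction F is the squared t of the single-df
interaction term.

## The demo study

`run_demo` builds the fixed study conditions of the end-to-end check:
10 + 10 subjects on an 18×12×12 grid (1.25 mm), three slightly oblique
non-overlapping tubes as both phantom bundles and atlas centroids
(oblique because an exactly axis-aligned tube makes the rasterized volume
a coarse step function of radius), a reduced acquisition (30
directions/shell + 3 b0, SH order 6, coarse NODDI grid without
refinement, 2 seeds/voxel on the undilated WM domain, 0.5 mm metric
resampling) chosen so a full cohort runs in ~10 s, and Rician noise at
sigma 0.02.

The planted effect is defined on the generating distribution of one
tract's volume scale: group means shifted by ±d/2 pooled SD with
d = −0.56 (women larger) and between-subject CV 0.35. Subject deviates
are quantile-stratified (seed-permuted normal quantiles), pinning each
group's sample moments near the generating values. This is deliberate:
at n = 10 + 10, i.i.d. sampling would make the *sample* d swing by ±0.45
and the demo would mostly measure sampling noise; with stratified
deviates the cohort realizes the planted effect by construction and what
the check exercises is the pipeline's measurement chain (tracking,
labeling, density volumetry, normalization, the t/d machinery). The
between-subject CV (0.35) was set, by a back-of-envelope error budget
against the ~2% measurement CV of the density volume, so that residual
measurement noise cannot move the recovered d across a bin boundary.
The demo's brain mask is the whole grid, so TBV is constant across
subjects and %TBV inherits the raw-volume effect exactly; the
volume-vs-TBV regression is therefore demonstrated on a separate
synthetic cohort with TBV variation (analysis/05).

## Numerical choices and degenerate inputs

- Signal floor 10⁻¹⁰ before logs (DTI); CSA clamp δ = 10⁻³.
- All-zero ODFs and tensors define GFA = FA = 0 rather than NaN.
- Identical constant samples in `group_compare` report t = 0, p = 1.
- Equal-mean groups with zero pooled SD report d = 0; unequal means with
  zero SD are an error (undefined effect).
- Shell detection clusters b-values with ±50 s/mm² tolerance (real bval
  files jitter); anything below 50 s/mm² is b = 0.
- Streamline files are float32 (TCK native); round-trips are exact to
  1e-5 mm.

## Problem sizes

Defaults in tests and the acceptance script: 20³ voxels for model
recovery (≈ 740-voxel tube), a 22×14×14 tube for tracking (≈ 6500 seeds),
200 replicates for the FWER and labeling checks, 200–400 for the ANCOVA
calibrations, 20 demo seeds. These sizes were chosen so the full suite
and the acceptance script each complete in minutes on one CPU while
keeping every Monte-Carlo bound several standard errors away from its
threshold.

## Limitations

- The atlas construction itself (the 77-tract centroid set) is out of
  scope; only a toy atlas ships, and real atlases are inputs.
- Registration is rigid/affine (a 4×4 matrix applied to the atlas);
  diffeomorphic warping is out of scope, so phantoms live in atlas space.
- No deterministic tracking, no anatomically-constrained tractography,
  no CSD/multi-tensor models, no along-tract profiling (whole-tract
  means only), no FDR alternatives to Bonferroni.
- The Gibbs-sampler reading (sharpening + curvature prior) is one
  defensible implementation of an under-specified algorithm; its γ and λ
  defaults are engine calibration constants validated on straight and
  crossing phantoms, not published values.
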