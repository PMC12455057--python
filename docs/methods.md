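# Methods

## Response models

All convolved kernels are sampled on a microtime grid of step
dt = TR/50, capped at 0.01 s. TR/50 keeps the mid-volume frame times
exactly on the grid, which makes the Box model's two equivalent
implementations (discrete convolution with a unit impulse vs direct
boxcar evaluation at the frame times) bit-identical. Kernels are
peak-normalized (max = 1) so that task parameter estimates — and hence z
scores — are on the same amplitude scale under every model; the task
column of the design matrix is likewise rescaled to unit peak after
convolution and frame sampling.

**Peak-span (rat).** The model is defined only by two measured constants:
time to peak 1.92 s and full width at half maximum 2.18 s. We realise it
as a single gamma-variate density — the minimal unimodal form uniquely
determined by those two constraints — with no undershoot term (whether the
original implementation carried one is not documented; the single-gamma
choice is recorded here as the package definition). Because the gamma
family is a scale family, FWHM/TTP depends on the shape parameter alone
and decreases monotonically in it, so the shape is found by Brent root
finding on that ratio (bracket 1.1–5000) and the scale follows as
TTP/(shape−1). Each solve is verified by a sample-and-measure round trip
at 1 ms and fails loudly if the kernel misses the constraints by more
than one grid step. Solving the defaults gives shape ≈ 5.378,
scale ≈ 0.4386 s.

**Human canonical models.** SPM: gamma pdfs with shapes 6 and 16, unit
scales, undershoot ratio 1/6 (density mode 5 s). Glover: shapes 6/0.9 and
16/0.9 with scale 0.9, ratio 0.35 (mode ≈ 5.1 s). The constants live in
`ratbold.hrf` as named specs and are cross-checked in the test suite
against nilearn's reference implementation (shape correlation > 0.999).

**2-Gammas (rat).** The defining study's exact constants are not bundled
with this package; the shipped defaults (peak gamma shape 4, scale 0.93 —
mode ≈ 2.8 s; undershoot shape 8, scale 1.3, ratio 0.2) approximate the
published rat cortical double-gamma and are flagged as externally sourced
in the code. Users with the authoritative values pass their own
`DoubleGammaSpec`. Both rat models peak well before the human presets,
which is the property the analyses depend on.

**Box.** A unit impulse; the task regressor is the unconvolved boxcar,
whose frame values are exactly {0, amplitude}.

**Kernel measurement.** TTP = grid argmax refined by 3-point parabolic
interpolation; FWHM = distance between the two linear-interpolated
half-maximum crossings flanking the peak. Tolerances in tests are two
grid steps.

## Design matrix

Frame times use the mid-volume convention (i + 0.5)·TR; onsets are
interpreted relative to the first retained volume (dummy volumes are
assumed removed upstream). Blocks are half-open intervals
[onset, onset+duration), which also resolves ties at frame boundaries.
Columns are ordered [task, 6 motion, poly_0..poly_3]. Motion columns are
demeaned but not orthogonalized against the task; identically-zero motion
columns are dropped with a warning. Drift columns are Legendre
polynomials of degrees 0..3 on the frame times rescaled to [−1, 1],
then Gram-Schmidt-orthogonalized on the discrete frame grid (continuous
Legendre orthogonality does not survive discretisation; two GS passes
bring the off-diagonal Gram entries below 1e-12). poly_0 is the constant
and doubles as the intercept. Assembly refuses rank-deficient matrices,
naming the collinear columns.

## First level

Spatial smoothing (default 0.45 mm FWHM, read as isotropic; the squared
unit in the protocol listing is taken as typographical) is applied to the
data before fitting, per-axis σ = FWHM/(voxel·2√(2 ln 2)), with
nearest-neighbour edge handling; FWHM = 0 is the identity. The GLM is
voxelwise OLS through a single shared pseudoinverse; no prewhitening, by
design — the reference analysis uses plain OLS, and the synthetic noise
is white (an AR option was considered and deliberately left out rather
than shipped untested). Residual variance uses dof = T − rank(X).
Exact-fit voxels (round-off-level RSS, threshold 1e-24 × mean squared
signal) are clamped to zero variance, given z = 0, and flagged invalid —
never NaN. t→z conversion matches CDFs through `t.logsf` and
`ndtri_exp`, so it is sign-symmetric and accurate beyond |t| ≈ 40 where
naive sf/isf saturates.

## Group level and overlap

One-sample t across subject beta maps with sample (n−1) sd; dof = n−1;
the same t→z conversion. Zero-between-subject-variance voxels mirror the
first-level policy (t = 0, flagged). The default threshold z > 1.93
(strict inequality, positive tail) corresponds to a one-sided Gaussian
tail of ≈ 0.0268; the package keeps 1.93 as the literal default rather
than re-deriving a threshold from p = 0.05. Signed thresholding
(±1 masks) is available for deactivation clusters. Overlap maps are the
per-voxel fraction of datasets active, computed on positive-tail masks by
default.

## ROI reporting and model comparison

ROI summaries average z over the ROI per subject, then report mean and
sample sd over those per-subject means (not pooled voxels — the recorded
reading of "mean ± sd across scans"). The best model per dataset
maximizes |group mean ROI z|; ties break on the canonical order
(2gammas, peakspan, glover, spm, box) with a tie flag. Fit panels show
the task regressor scaled by the group-mean ROI task beta plus the
group-mean drift fit, against the subject-averaged ROI series and
residual; scans entering a panel must share the paradigm (motion
confounds may differ).

## Synthetic cohorts

The generator emulates the structure of a multi-center rat somatosensory
block-design session: cohorts of 10 subjects, 24×24×12 voxels at 0.3 mm,
TR 2 s, 150 volumes, three 20 s blocks at onsets 40/100/160 s (a
long-block preset uses 30 s blocks), baseline 100, 2% peak signal change,
white Gaussian noise sd 2 (voxel CNR 1), drift amplitudes (0, 1, 0.5,
0.25) on the orthogonalized polynomial basis, and a motion-leak term
coupling six smooth random-walk motion traces into the signal with
strength 0.1. Per-subject effects are lognormal around the cohort effect
(log-sd 0.2, median preserved); an outlier flag zeroes the last subject's
effect. An optional early-onset transient — a gamma bump with TTP 0.5 s,
FWHM 0.5 s at each block onset, amplitude in percent of baseline, ROI
only — emulates the fast initial rise convolved models cannot capture; it
is a phenomenological stand-in, not a physiological claim. Everything is
deterministic per (seed, subject index) via `SeedSequence((seed, i))`.

What the generator does **not** emulate: temporally autocorrelated or
physiological noise, registration error, partial-volume and
draining-vein geometry, scanner drift nonlinearity, or
anesthesia-dependent neurovascular coupling. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-data violations of it.

## Problem sizes and numerics

Tests and the acceptance checks run at deliberately small scales chosen
as the smallest sizes at which the statistical properties are
unambiguous: calibration uses 200,000 independent null voxels (Monte
Carlo sd ≈ 4e-4 against a ±0.003 band); recovery and model-direction
checks use 10 seeds × 10 subjects on the default grid; the
law-of-large-numbers check uses 200 seeds with a Bonferroni-style
4.5-sigma family bound over 60 time points. Solver tolerances: Brent
xtol 1e-12; round-trip tolerance one microtime step; design rank checks
via `matrix_rank` with QR-based diagnosis.

## Known limitations

* The Peak-span undershoot question (above) and the 2-Gammas constants
  are configuration points, not settled facts.
* Whole-image analysis only; an explicit brain mask is supported but no
  masking heuristic is shipped.
* No multiple-comparison correction, cluster inference, or mixed-effects
  group model — uncorrected maps are the stated scope.
* Event-related designs, parametric modulation and slice timing are out
  of scope; the paradigm model is strictly block-based.
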