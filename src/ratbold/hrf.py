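"""Hemodynamic response function (HRF) models for rat task-fMRI analysis.

Five response models are supported, addressable by string key:

``"peakspan"``
    A rat somatosensory HRF specified only by its time to peak (1.92 s) and
    full width at half maximum (2.18 s).  It is realised as a single
    gamma-variate density whose (shape, scale) are solved numerically so
    that the sampled kernel reproduces those two constraints.
``"2gammas"``
    A rat double-gamma (peak minus undershoot) HRF.  The exact constants of
    the published rat cortical double-gamma are not restated here; the
    shipped defaults (peak near 2.8 s, mild undershoot) approximate that
    reference and are user-overridable — see :data:`RAT_2GAMMA_DEFAULTS`.
``"glover"`` and ``"spm"``
    The two canonical human double-gamma models, with their standard
    published constants (:data:`GLOVER_DEFAULTS`, :data:`SPM_DEFAULTS`).
``"box"``
    No hemodynamic convolution at all: a unit impulse, so the task
    regressor is the raw block-design boxcar.

All convolved-model kernels are peak-normalized (max = 1) so that GLM
parameter estimates are on a comparable amplitude scale across models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy import stats

__all__ = [
    "GammaSpec",
    "DoubleGammaSpec",
    "SampledKernel",
    "MODEL_ORDER",
    "SPM_DEFAULTS",
    "GLOVER_DEFAULTS",
    "RAT_2GAMMA_DEFAULTS",
    "solve_gamma_from_peak_fwhm",
    "sample_peak_span",
    "sample_double_gamma",
    "box_kernel",
    "measure_kernel",
    "get_kernel",
]

#: Canonical model-key order, used for tie-breaking in model comparison.
MODEL_ORDER = ("2gammas", "peakspan", "glover", "spm", "box")

#: Default Peak-span rat HRF constraints (seconds).
PEAKSPAN_TTP = 1.92
PEAKSPAN_FWHM = 2.18


@dataclass(frozen=True)
class GammaSpec:
    """A gamma-variate density: shape (dimensionless), scale and onset delay (s).

    The density is ``t ** (shape - 1) * exp(-t / scale)`` normalized to unit
    area, shifted right by ``onset_delay``.  ``shape > 1`` is required so the
    density has an interior peak at ``(shape - 1) * scale + onset_delay``.
    """

    shape: float
    scale: float
    onset_delay: float = 0.0

    def __post_init__(self) -> None:
        if not self.shape > 1:
            raise ValueError(f"gamma shape must be > 1, got {self.shape}")
        if not self.scale > 0:
            raise ValueError(f"gamma scale must be > 0, got {self.scale}")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")

    @property
    def peak_time(self) -> float:
        """Mode of the density, in seconds."""
        return (self.shape - 1.0) * self.scale + self.onset_delay

    def density(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the (unit-area) density at times ``t`` (seconds)."""
        return stats.gamma.pdf(t, self.shape, loc=self.onset_delay, scale=self.scale)


@dataclass(frozen=True)
class DoubleGammaSpec:
    """Difference of two gamma densities: peak minus scaled undershoot."""

    peak: GammaSpec
    undershoot: GammaSpec
    undershoot_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")
        if self.undershoot_ratio >= 1:
            raise ValueError("undershoot_ratio must be < 1")
        if self.undershoot.peak_time <= self.peak.peak_time:
            raise ValueError("undershoot must peak later than the main response")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.peak.density(t) - self.undershoot_ratio * self.undershoot.density(t)


#: SPM canonical double gamma: peak delay 6 s, undershoot delay 16 s,
#: unit dispersions, undershoot ratio 1/6 (density mode at 5 s).
SPM_DEFAULTS = DoubleGammaSpec(
    peak=GammaSpec(shape=6.0, scale=1.0),
    undershoot=GammaSpec(shape=16.0, scale=1.0),
    undershoot_ratio=1.0 / 6.0,
)

#: Glover (1999) auditory-response double gamma as commonly parameterized:
#: peak delay 6 s / dispersion 0.9 (mode ~5.1 s), undershoot delay 16 s /
#: dispersion 0.9, undershoot ratio 0.35.
GLOVER_DEFAULTS = DoubleGammaSpec(
    peak=GammaSpec(shape=6.0 / 0.9, scale=0.9),
    undershoot=GammaSpec(shape=16.0 / 0.9, scale=0.9),
    undershoot_ratio=0.35,
)

#: Rat cortical double-gamma defaults.  Externally sourced approximation
#: (source: published rat cortical HRF literature; the defining study is not
#: bundled with this package): fast peak near 2.8 s with a mild, late
#: undershoot.  Override via :func:`get_kernel` / :func:`sample_double_gamma`
#: when exact study constants are available.
RAT_2GAMMA_DEFAULTS = DoubleGammaSpec(
    peak=GammaSpec(shape=4.0, scale=0.93),
    undershoot=GammaSpec(shape=8.0, scale=1.30),
    undershoot_ratio=0.20,
)

_PRESETS = {
    "spm": SPM_DEFAULTS,
    "glover": GLOVER_DEFAULTS,
    "2gammas": RAT_2GAMMA_DEFAULTS,
}


@dataclass(frozen=True)
class SampledKernel:
    """An HRF sampled on a fine regular time grid starting at t = 0.

    ``values[i]`` is the amplitude at ``t = i * dt``.  Convolved-model
    kernels are peak-normalized (max = 1).  ``is_impulse`` marks the Box
    identity kernel, for which downstream convolution is a no-op.
    """

    values: np.ndarray
    dt: float
    is_impulse: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if v.ndim != 1 or v.size == 0:
            raise ValueError("kernel values must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("kernel values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def area(self) -> float:
        """Riemann integral of the kernel, in seconds (amplitude-weighted)."""
        if self.is_impulse:
            return float(np.sum(self.values))
        return float(np.sum(self.values) * self.dt)

    def to_tsv(self, path) -> None:
        """Write a 2-column (time_s, amplitude) TSV, for plots and audits."""
        arr = np.column_stack([self.times, self.values])
        np.savetxt(path, arr, delimiter="\t", header="time_s\tamplitude", comments="")

    @classmethod
    def from_tsv(cls, path) -> "SampledKernel":
        arr = np.loadtxt(path, delimiter="\t", skiprows=1)
        t, v = arr[:, 0], arr[:, 1]
        dt = float(t[1] - t[0])
        if not np.allclose(np.diff(t), dt, rtol=0, atol=1e-9):
            raise ValueError("kernel TSV time grid is not regular")
        return cls(values=v, dt=dt)


def _normalize_peak(values: np.ndarray) -> np.ndarray:
    m = values.max()
    if m <= 0:
        raise ValueError("kernel has no positive peak to normalize")
    return values / m


def _gamma_fwhm_over_mode(shape: float) -> float:
    """FWHM of the standard (scale=1) gamma density divided by its mode.

    Dimensionless; depends on shape only, and decreases monotonically with
    shape (the density tends to a Gaussian of relative width ~ 1/sqrt(shape)).
    """
    mode = shape - 1.0
    # log density up to a constant: (shape-1) log t - t
    def logf(t: float) -> float:
        return (shape - 1.0) * math.log(t) - t

    target = logf(mode) - math.log(2.0)
    lo = mode * 0.5
    while logf(lo) > target:
        lo *= 0.5
        if lo < 1e-300:
            raise ValueError(f"no half-maximum crossing below the mode (shape={shape})")
    left = optimize.brentq(lambda t: logf(t) - target, lo, mode, xtol=1e-12)
    hi = mode + 1.0
    while logf(hi) > target:
        hi *= 2.0
    right = optimize.brentq(lambda t: logf(t) - target, mode, hi, xtol=1e-12)
    return (right - left) / mode


def solve_gamma_from_peak_fwhm(ttp: float, fwhm: float, dt: float = 0.001) -> GammaSpec:
    """Solve gamma (shape, scale) so the density has the given TTP and FWHM.

    The gamma family is a scale family, so the ratio FWHM/TTP determines the
    shape alone; the shape is found by 1-D root finding on that ratio and the
    scale then follows as ``ttp / (shape - 1)``.  The solution is verified by
    sampling and measuring the kernel; ``dt`` is the verification grid step
    and tolerance.

    Raises
    ------
    ValueError
        If the requested geometry is infeasible (``fwhm >= 4 * ttp`` or
        non-positive inputs, or ``dt > 0.01``).
    RuntimeError
        If the solver fails to converge or the round-trip check fails.
    """
    if ttp <= 0 or fwhm <= 0:
        raise ValueError("ttp and fwhm must be positive")
    if fwhm >= 4.0 * ttp:
        raise ValueError(
            f"infeasible gamma geometry: fwhm={fwhm} >= 4*ttp={4.0 * ttp}"
        )
    if dt > 0.01:
        raise ValueError("verification grid dt must be <= 0.01 s")

    ratio = fwhm / ttp

    def mismatch(shape: float) -> float:
        return _gamma_fwhm_over_mode(shape) - ratio

    try:
        shape = optimize.brentq(mismatch, 1.1, 5000.0, xtol=1e-12, maxiter=200)
    except ValueError as exc:  # bracket failure
        raise RuntimeError(
            f"gamma solver failed for (ttp={ttp}, fwhm={fwhm}): {exc}"
        ) from exc
    spec = GammaSpec(shape=shape, scale=ttp / (shape - 1.0))

    duration = ttp + 4.0 * fwhm
    t = np.arange(int(round(duration / dt))) * dt
    kern = SampledKernel(values=_normalize_peak(spec.density(t)), dt=dt)
    got_ttp, got_fwhm = measure_kernel(kern)
    if abs(got_ttp - ttp) > dt or abs(got_fwhm - fwhm) > dt:
        raise RuntimeError(
            f"gamma solver round-trip check failed for (ttp={ttp}, fwhm={fwhm}): "
            f"measured ({got_ttp:.6g}, {got_fwhm:.6g})"
        )
    return spec


def sample_peak_span(
    dt: float,
    duration: float,
    ttp: float = PEAKSPAN_TTP,
    fwhm: float = PEAKSPAN_FWHM,
) -> SampledKernel:
    """Sample the Peak-span rat HRF: a single gamma variate with the given
    time to peak and full width at half maximum, peak-normalized."""
    if duration < ttp + 3.0 * fwhm:
        raise ValueError(
            f"duration {duration} s too short: need >= ttp + 3*fwhm = "
            f"{ttp + 3.0 * fwhm} s"
        )
    spec = solve_gamma_from_peak_fwhm(ttp, fwhm, dt=min(dt, 0.001))
    t = np.arange(int(round(duration / dt))) * dt
    return SampledKernel(values=_normalize_peak(spec.density(t)), dt=dt)


def sample_double_gamma(
    spec: DoubleGammaSpec, dt: float, duration: float
) -> SampledKernel:
    """Sample a double-gamma HRF (peak minus undershoot), peak-normalized."""
    if duration < 32.0 and spec in (SPM_DEFAULTS, GLOVER_DEFAULTS):
        raise ValueError("human canonical presets need duration >= 32 s")
    t = np.arange(int(round(duration / dt))) * dt
    values = spec.evaluate(t)
    if values.min() < -values.max():
        raise ValueError("undershoot dominates the response; check the spec")
    return SampledKernel(values=_normalize_peak(values), dt=dt)


def box_kernel(dt: float = 0.01) -> SampledKernel:
    """The Box-model identity kernel: a unit impulse at t = 0.

    Discrete convolution with this kernel leaves the block-design boxcar
    unchanged, so the Box task regressor is the raw (unconvolved) boxcar.
    """
    return SampledKernel(values=np.array([1.0]), dt=dt, is_impulse=True)


def measure_kernel(kernel: SampledKernel) -> tuple[float, float]:
    """Measure (time-to-peak, FWHM) of a sampled kernel, in seconds.

    TTP is the grid argmax refined by 3-point parabolic interpolation; FWHM
    is the distance between the two linear-interpolated half-maximum
    crossings flanking the peak.

    Raises ``ValueError`` for kernels without an interior positive maximum.
    """
    v = kernel.values
    i = int(np.argmax(v))
    if i == 0 or i == v.size - 1 or v[i] <= 0:
        raise ValueError("kernel has no interior positive maximum")

    # parabolic refinement of the peak location
    denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
    offset = 0.0 if denom == 0 else 0.5 * (v[i - 1] - v[i + 1]) / denom
    ttp = (i + offset) * kernel.dt

    half = v[i] / 2.0
    below_left = np.nonzero(v[:i] < half)[0]
    below_right = np.nonzero(v[i:] < half)[0]
    if below_left.size == 0 or below_right.size == 0:
        raise ValueError("kernel does not fall below half maximum on both sides")

    jl = below_left[-1]  # last sample below half before the peak
    t_left = (jl + (half - v[jl]) / (v[jl + 1] - v[jl])) * kernel.dt
    jr = i + below_right[0]  # first sample below half after the peak
    t_right = (jr - 1 + (v[jr - 1] - half) / (v[jr - 1] - v[jr])) * kernel.dt
    return float(ttp), float(t_right - t_left)


def get_kernel(
    model: str,
    dt: float,
    duration: float = 32.0,
    spec: DoubleGammaSpec | None = None,
) -> SampledKernel:
    """Build the sampled kernel for a model key.

    ``spec`` overrides the shipped double-gamma constants for the
    "2gammas"/"glover"/"spm" models (e.g. exact study-specific values).
    """
    if model == "box":
        return box_kernel(dt)
    if model == "peakspan":
        return sample_peak_span(dt, duration)
    if model in _PRESETS:
        return sample_double_gamma(spec or _PRESETS[model], dt, duration)
    raise KeyError(
        f"unknown HRF model {model!r}; choose from {', '.join(MODEL_ORDER)}"
    )
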