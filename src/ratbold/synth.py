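"""Synthetic rat BOLD cohorts with known ground truth.

Each synthetic subject is a 4-D volume on a 0.3 mm isotropic grid whose
voxel signal is

    baseline * (1 + effect/100 * x(t) * roi(v))          task response
    + sum_k drift_k * P_k(t)                             low-frequency drift
    + motion_leak * (motion(t) @ w)                      nuisance leakage
    + early-peak transient (optional, ROI only)
    + N(0, noise_sd^2)                                   white noise

where ``x(t)`` is the unit-peak expected response (boxcar convolved with the
chosen true HRF, as built by :mod:`ratbold.design`), ``roi(v)`` indicates the
active region, ``P_k`` are the orthogonalized drift polynomials, and the
motion traces are smooth random walks that are also written to the
confounds table.  A disjoint "null" region carries no task effect, so false
and true positives can be scored on the same volume.

The default scene mirrors a typical multi-center block-design session:
~10 subjects per cohort, three 20 s stimulation blocks separated by 40 s of
rest, TR 2 s, 150 volumes, 2% peak signal change on a 24x24x12 grid.
Everything is deterministic given (seed, subject index).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from . import hrf
from .design import MOTION_COLUMNS, Block, Paradigm, ScanMeta
from .firstlevel import Volume4D

__all__ = [
    "SynthConfig",
    "SynthSubject",
    "SynthDataset",
    "ACTIVE_LABEL",
    "NULL_LABEL",
    "default_paradigm",
    "long_block_paradigm",
    "make_atlas",
    "true_regressor",
    "generate_subject",
    "generate_cohort",
    "write_bids",
]

ACTIVE_LABEL = 1   # somatosensory-cortex-like active region
NULL_LABEL = 2     # disjoint control region with no task effect


def default_paradigm() -> Paradigm:
    """Three 20 s stimulation blocks separated by 40 s rest (onset 40 s)."""
    return Paradigm(blocks=tuple(Block(o, 20.0) for o in (40.0, 100.0, 160.0)))


def long_block_paradigm() -> Paradigm:
    """Long-block preset: three 30 s stimulation blocks, 40 s rest."""
    return Paradigm(blocks=tuple(Block(o, 30.0) for o in (40.0, 110.0, 180.0)))


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth scene description for one synthetic cohort."""

    n_subjects: int = 10
    grid: tuple[int, int, int] = (24, 24, 12)
    voxel_size: float = 0.3              # mm, isotropic common-space grid
    tr: float = 2.0                      # seconds
    n_vols: int = 150
    paradigm: Paradigm = field(default_factory=default_paradigm)
    true_hrf: str = "peakspan"
    effect: float = 2.0                  # peak % signal change in the ROI
    baseline: float = 100.0              # signal units
    noise_sd: float = 2.0                # signal units (CNR 1 at defaults)
    drift_coeffs: tuple[float, ...] = (0.0, 1.0, 0.5, 0.25)  # signal units
    motion_leak: float = 0.1             # nuisance coupling strength
    effect_log_sd: float = 0.2           # between-subject lognormal spread
    outlier: bool = False                # zero one subject's true effect
    early_peak: tuple[float, float, float] | None = None
    # early_peak = (amplitude %, ttp s, fwhm s); a brief gamma bump at each
    # block onset inside the ROI, emulating an early-onset fast rise.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0 or self.noise_sd < 0:
            raise ValueError("effect and noise_sd must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.paradigm.end > self.n_vols * self.tr:
            raise ValueError("paradigm extends beyond the scan")

    @property
    def meta(self) -> ScanMeta:
        return ScanMeta(tr=self.tr, n_vols=self.n_vols)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


@dataclass(frozen=True)
class SynthSubject:
    vol: Volume4D
    events: pd.DataFrame
    confounds: pd.DataFrame
    truth: dict


@dataclass(frozen=True)
class SynthDataset:
    subjects: tuple[SynthSubject, ...]
    atlas: np.ndarray
    affine: np.ndarray
    truth: dict
    config: SynthConfig


def make_atlas(cfg: SynthConfig) -> np.ndarray:
    """Integer-label atlas: a central active box and a disjoint corner null box."""
    nx, ny, nz = cfg.grid
    atlas = np.zeros(cfg.grid, dtype=np.int16)
    atlas[nx // 3 : 2 * nx // 3, ny // 3 : 2 * ny // 3, nz // 3 : 2 * nz // 3] = (
        ACTIVE_LABEL
    )
    atlas[: max(nx // 6, 2), : max(ny // 6, 2), : max(nz // 4, 2)] = NULL_LABEL
    return atlas


def true_regressor(cfg: SynthConfig) -> np.ndarray:
    """Unit-peak expected response at the frame times for the true HRF."""
    kernel = hrf.get_kernel(cfg.true_hrf, dt=cfg.meta.microtime_dt)
    x = design_mod.task_regressor(cfg.paradigm, kernel, cfg.meta)
    peak = np.abs(x).max()
    return x / peak if (not kernel.is_impulse and peak > 0) else x


def _early_peak_series(cfg: SynthConfig) -> np.ndarray:
    """Transient bump (unit peak) at each block onset, at the frame times."""
    amp, ttp, fwhm = cfg.early_peak
    spec = hrf.solve_gamma_from_peak_fwhm(ttp, fwhm, dt=0.001)
    t = design_mod.frame_times(cfg.meta)
    out = np.zeros_like(t)
    for b in cfg.paradigm.blocks:
        dtv = t - b.onset
        bump = np.where(dtv > 0, spec.density(np.maximum(dtv, 1e-12)), 0.0)
        out += bump
    peak_density = spec.density(np.array([spec.peak_time]))[0]
    return amp / 100.0 * cfg.baseline * out / peak_density


def _motion_traces(rng: np.random.Generator, n_vols: int) -> np.ndarray:
    """Six smooth random-walk motion traces (3 translations mm, 3 rotations rad)."""
    steps = rng.normal(size=(n_vols, 6)) * np.array([0.01] * 3 + [0.002] * 3)
    walk = np.cumsum(steps, axis=0)
    # light smoothing so traces look like slow drifts rather than jitter
    kern = np.ones(5) / 5.0
    return np.column_stack(
        [np.convolve(walk[:, j], kern, mode="same") for j in range(6)]
    )


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, subject_index)))


def generate_subject(
    cfg: SynthConfig, subject_index: int, effect: float | None = None
) -> SynthSubject:
    """Generate one subject's volume, events and confounds.

    ``effect`` overrides the cohort-level per-subject true effect (percent
    signal change); by default the config value is used unmodified.
    Deterministic per (cfg.seed, subject_index).
    """
    rng = _subject_rng(cfg.seed, subject_index)
    meta = cfg.meta
    t = design_mod.frame_times(meta)
    true_effect = cfg.effect if effect is None else effect

    x = true_regressor(cfg)
    atlas = make_atlas(cfg)
    roi = atlas == ACTIVE_LABEL

    motion = _motion_traces(rng, meta.n_vols)
    w = rng.normal(size=6)
    leak = cfg.motion_leak * (motion @ w)

    drift_basis = design_mod.drift_columns(meta, order=len(cfg.drift_coeffs) - 1)
    drift = drift_basis @ np.asarray(cfg.drift_coeffs)

    task_amp = cfg.baseline * true_effect / 100.0
    series_bg = cfg.baseline + drift + leak                  # background voxels
    series_roi = series_bg + task_amp * x                    # active voxels
    if cfg.early_peak is not None:
        series_roi = series_roi + _early_peak_series(cfg)

    data = np.empty((*cfg.grid, meta.n_vols))
    data[...] = series_bg
    data[roi] = series_roi
    if cfg.noise_sd > 0:
        data += rng.normal(scale=cfg.noise_sd, size=data.shape)

    confounds = pd.DataFrame(motion, columns=list(MOTION_COLUMNS))
    truth = {
        "subject_index": subject_index,
        "true_effect_percent": true_effect,
        "true_task_beta": task_amp,
        "true_hrf": cfg.true_hrf,
        "motion_weights": w.tolist(),
        "drift_coeffs": list(cfg.drift_coeffs),
        "motion_leak": cfg.motion_leak,
        "baseline": cfg.baseline,
        "noise_sd": cfg.noise_sd,
        "early_peak": list(cfg.early_peak) if cfg.early_peak else None,
        "seed": cfg.seed,
    }
    return SynthSubject(
        vol=Volume4D(data=data, affine=cfg.affine),
        events=cfg.paradigm.to_events(),
        confounds=confounds,
        truth=truth,
    )


def generate_cohort(cfg: SynthConfig) -> SynthDataset:
    """Generate a cohort with lognormal between-subject effect variability.

    Per-subject true effects are ``cfg.effect * exp(N(0, effect_log_sd^2))``
    (median = cfg.effect).  With ``outlier=True`` the last subject's effect
    is set to zero, emulating a non-responding scan.
    """
    effect_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 10**6)))
    mult = np.exp(effect_rng.normal(0.0, cfg.effect_log_sd, size=cfg.n_subjects))
    effects = cfg.effect * mult
    if cfg.outlier:
        effects[-1] = 0.0
    subjects = tuple(
        generate_subject(cfg, i, effect=float(effects[i]))
        for i in range(cfg.n_subjects)
    )
    truth = {
        "config": _config_dict(cfg),
        "true_effects_percent": effects.tolist(),
        "active_label": ACTIVE_LABEL,
        "null_label": NULL_LABEL,
        "subjects": [s.truth for s in subjects],
    }
    return SynthDataset(
        subjects=subjects,
        atlas=make_atlas(cfg),
        affine=cfg.affine,
        truth=truth,
        config=cfg,
    )


def _config_dict(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["paradigm"] = [
        [b.onset, b.duration, b.amplitude] for b in cfg.paradigm.blocks
    ]
    return d


def write_bids(dataset: SynthDataset, outdir) -> Path:
    """Write a BIDS-like tree: per-subject bold/events/confounds + atlas + truth."""
    import nibabel as nib

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sub in enumerate(dataset.subjects, start=1):
        func = out / f"sub-{i:02d}" / "func"
        func.mkdir(parents=True, exist_ok=True)
        sub.vol.save(func / f"sub-{i:02d}_task-stim_bold.nii.gz")
        sub.events.to_csv(
            func / f"sub-{i:02d}_task-stim_events.tsv", sep="\t", index=False
        )
        sub.confounds.to_csv(
            func / f"sub-{i:02d}_task-stim_confounds.tsv", sep="\t", index=False
        )
    nib.save(
        nib.Nifti1Image(dataset.atlas.astype(np.int16), dataset.affine),
        str(out / "atlas.nii.gz"),
    )
    (out / "truth.json").write_text(json.dumps(dataset.truth, indent=2))
    return out
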