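"""First-level design matrices for block-design task fMRI.

A design matrix has one task column (the block-design boxcar convolved with
the chosen HRF, peak-normalized), six motion-parameter confound columns
(demeaned), and third-order polynomial drift columns built from Legendre
polynomials orthogonalized on the actual frame-time grid.

Conventions
-----------
* Frame times use the mid-volume convention ``t_i = (i + 0.5) * TR``; no
  slice-timing correction is modelled.
* Event onsets are interpreted relative to the first retained volume
  (dummy scans are assumed already removed upstream).
* Stimulation blocks are half-open intervals ``[onset, onset + duration)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hrf
from .hrf import SampledKernel

__all__ = [
    "Block",
    "Paradigm",
    "ScanMeta",
    "MOTION_COLUMNS",
    "DesignMatrix",
    "frame_times",
    "build_boxcar",
    "task_regressor",
    "drift_columns",
    "assemble_design",
    "load_events",
    "load_confounds",
]

#: BIDS-style motion-parameter column names expected in confounds TSVs.
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class Block:
    onset: float
    duration: float
    amplitude: float = 1.0


@dataclass(frozen=True)
class Paradigm:
    """An ordered set of non-overlapping stimulation blocks, in seconds."""

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        blocks = tuple(
            b if isinstance(b, Block) else Block(*b) for b in self.blocks
        )
        for b in blocks:
            if b.duration <= 0:
                raise ValueError(f"block duration must be > 0, got {b.duration}")
        onsets = [b.onset for b in blocks]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("block onsets must be strictly increasing")
        for a, b in zip(blocks, blocks[1:]):
            if a.onset + a.duration > b.onset:
                raise ValueError(
                    f"blocks overlap: [{a.onset}, {a.onset + a.duration}) and "
                    f"[{b.onset}, ...)"
                )
        object.__setattr__(self, "blocks", blocks)

    @property
    def end(self) -> float:
        if not self.blocks:
            return 0.0
        last = self.blocks[-1]
        return last.onset + last.duration

    def to_events(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [b.onset for b in self.blocks],
                "duration": [b.duration for b in self.blocks],
                "trial_type": "stim",
            }
        )

    @classmethod
    def from_events(cls, events: pd.DataFrame) -> "Paradigm":
        """Build from a BIDS events table (single trial_type supported)."""
        if "trial_type" in events.columns and events["trial_type"].nunique() > 1:
            raise ValueError("only a single trial_type is supported")
        rows = events.sort_values("onset")
        return cls(
            blocks=tuple(
                Block(float(r.onset), float(r.duration)) for r in rows.itertuples()
            )
        )


@dataclass(frozen=True)
class ScanMeta:
    """Timing of the retained volumes of one scan."""

    tr: float
    n_vols: int
    n_dummy: int = 0  # volumes already removed before analysis (bookkeeping)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.n_vols <= 0:
            raise ValueError("n_vols must be > 0")
        if self.n_dummy < 0:
            raise ValueError("n_dummy must be >= 0")

    @property
    def duration(self) -> float:
        return self.n_vols * self.tr

    @property
    def microtime_dt(self) -> float:
        """Microtime grid step: TR/50, capped at 0.01 s.

        TR/50 keeps the mid-volume frame times exactly on the microtime grid.
        """
        return min(self.tr / 50.0, 0.01)


def frame_times(meta: ScanMeta) -> np.ndarray:
    """Mid-volume acquisition times ``(i + 0.5) * TR`` of retained volumes."""
    return (np.arange(meta.n_vols) + 0.5) * meta.tr


def build_boxcar(paradigm: Paradigm, t_end: float, dt: float) -> np.ndarray:
    """Piecewise-constant stimulation indicator on the microtime grid.

    Samples at ``t = i * dt``; a sample is inside a block iff
    ``onset <= t < onset + duration`` (half-open rule).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if paradigm.end > t_end:
        raise ValueError(
            f"paradigm extends to {paradigm.end} s beyond scan end {t_end} s"
        )
    n = int(round(t_end / dt))
    t = np.arange(n) * dt
    box = np.zeros(n)
    for b in paradigm.blocks:
        box[(t >= b.onset) & (t < b.onset + b.duration)] = b.amplitude
    return box


def _sample_boxcar_at(paradigm: Paradigm, times: np.ndarray) -> np.ndarray:
    """Evaluate the block indicator exactly at arbitrary times (half-open)."""
    out = np.zeros_like(times, dtype=float)
    for b in paradigm.blocks:
        out[(times >= b.onset) & (times < b.onset + b.duration)] = b.amplitude
    return out


def task_regressor(
    paradigm: Paradigm, kernel: SampledKernel, meta: ScanMeta
) -> np.ndarray:
    """Expected BOLD regressor at the frame times.

    The boxcar is convolved with ``kernel * dt`` on the microtime grid,
    truncated to the scan, then sampled at the frame times by linear
    interpolation.  For the Box (impulse) kernel the convolution is the
    identity, so the boxcar is evaluated at the frame times directly; on a
    TR/50-aligned grid both routes agree bit-for-bit.
    """
    if kernel.is_impulse:
        return _sample_boxcar_at(paradigm, frame_times(meta))
    dt = kernel.dt
    expected = meta.microtime_dt
    if not np.isclose(dt, expected, rtol=1e-9, atol=0):
        raise ValueError(
            f"kernel dt {dt} does not match the scan microtime grid {expected}"
        )
    box = build_boxcar(paradigm, meta.duration, dt)
    conv = np.convolve(box, kernel.values)[: box.size] * dt
    micro_t = np.arange(box.size) * dt
    return np.interp(frame_times(meta), micro_t, conv)


def drift_columns(meta: ScanMeta, order: int = 3) -> np.ndarray:
    """Polynomial drift basis: degrees 0..order, orthogonal on the frame grid.

    Legendre polynomials are evaluated on the frame times rescaled to
    [-1, 1] and then Gram-Schmidt-orthogonalized on the discrete grid
    (Legendre orthogonality is exact only for the continuous inner product).
    Column 0 is the constant; higher columns are scaled to unit max-abs.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if meta.n_vols <= order + 1:
        raise ValueError("n_vols must exceed order + 1")
    t = frame_times(meta)
    x = 2.0 * (t - t[0]) / (t[-1] - t[0]) - 1.0 if meta.n_vols > 1 else np.zeros(1)
    cols = np.polynomial.legendre.legvander(x, order).astype(float)
    for j in range(1, order + 1):
        for _ in range(2):  # two passes for numerical orthogonality
            for k in range(j):
                cols[:, j] -= (cols[:, j] @ cols[:, k]) / (
                    cols[:, k] @ cols[:, k]
                ) * cols[:, k]
        cols[:, j] /= np.abs(cols[:, j]).max()
    return cols


@dataclass(frozen=True)
class DesignMatrix:
    """Named first-level regressors sampled at the frame times.

    Column order: ``task``, six motion parameters, ``poly_0..poly_k``.  The
    task column is peak-normalized (max 1) so that task betas are comparable
    across HRF models.
    """

    frame_times: np.ndarray
    matrix: pd.DataFrame
    model: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def task_index(self) -> int:
        return self.columns.index("task")

    def to_tsv(self, path) -> None:
        self.matrix.assign(frame_time=self.frame_times).to_csv(
            path, sep="\t", index=False
        )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify near-dependent columns from the R diagonal of a QR
        _, r = np.linalg.qr(X / np.linalg.norm(X, axis=0, keepdims=True))
        bad = [names[i] for i in np.nonzero(np.abs(np.diag(r)) < 1e-10)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def assemble_design(
    paradigm: Paradigm,
    model_key: str,
    meta: ScanMeta,
    confounds: pd.DataFrame,
    drift_order: int = 3,
    kernel: SampledKernel | None = None,
) -> DesignMatrix:
    """Build the full first-level design: [task, motion x6, poly_0..poly_k].

    Motion columns are demeaned (not orthogonalized against the task).
    All-zero motion columns are dropped with a warning.  The convolved task
    column is rescaled to unit peak.
    """
    if len(confounds) != meta.n_vols:
        raise ValueError(
            f"confound rows ({len(confounds)}) != n_vols ({meta.n_vols})"
        )
    if kernel is None:
        kernel = hrf.get_kernel(model_key, dt=meta.microtime_dt)
    task = task_regressor(paradigm, kernel, meta)
    if not kernel.is_impulse:
        peak = np.abs(task).max()
        if peak > 0:
            task = task / peak

    data: dict[str, np.ndarray] = {"task": task}
    for name in MOTION_COLUMNS:
        if name not in confounds.columns:
            raise ValueError(f"confounds table is missing column {name!r}")
        col = confounds[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"non-finite values in confound column {name!r}")
        if np.all(col == 0):
            warnings.warn(
                f"motion column {name!r} is identically zero; dropping it",
                stacklevel=2,
            )
            continue
        data[name] = col - col.mean()

    drift = drift_columns(meta, drift_order)
    for d in range(drift_order + 1):
        data[f"poly_{d}"] = drift[:, d]

    frame = pd.DataFrame(data)
    _check_full_rank(frame.to_numpy(), list(frame.columns))
    return DesignMatrix(frame_times=frame_times(meta), matrix=frame, model=model_key)


def load_events(path) -> Paradigm:
    """Read a BIDS events.tsv (onset, duration[, trial_type]) into a Paradigm."""
    return Paradigm.from_events(pd.read_csv(path, sep="\t"))


def load_confounds(path, n_vols: int | None = None) -> pd.DataFrame:
    """Read a motion-confound TSV; optionally validate the row count."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"confounds file {path} missing columns: {missing}")
    if n_vols is not None and len(table) != n_vols:
        raise ValueError(f"confounds rows ({len(table)}) != n_vols ({n_vols})")
    return table
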