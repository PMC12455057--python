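"""Group-level mapping: one-sample t-test across subjects, thresholding,
and cross-dataset activation-overlap maps."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .firstlevel import t_to_z

__all__ = [
    "DEFAULT_Z_THRESHOLD",
    "GroupResult",
    "OverlapMap",
    "one_sample_t",
    "threshold_map",
    "overlap",
]

#: Default z threshold for suprathreshold masks (one-sided Gaussian tail
#: probability ~0.0268, i.e. p < 0.05 uncorrected).
DEFAULT_Z_THRESHOLD = 1.93


@dataclass(frozen=True)
class GroupResult:
    """One-sample t-test over per-subject parameter-estimate maps."""

    t_map: np.ndarray
    z_map: np.ndarray
    n_subjects: int
    dof: int
    threshold: float
    mask: np.ndarray        # z_map > threshold (positive tail)
    valid: np.ndarray       # False where the between-subject sd is zero


@dataclass(frozen=True)
class OverlapMap:
    """Per-voxel fraction of datasets whose group mask is active."""

    fraction: np.ndarray
    n_datasets: int


def one_sample_t(
    beta_maps: Sequence[np.ndarray], threshold: float = DEFAULT_Z_THRESHOLD
) -> GroupResult:
    """Voxelwise one-sample t-test: t = mean / (sd / sqrt(n)), dof = n - 1.

    The sample standard deviation uses the n-1 denominator.  Voxels where
    all subjects agree exactly (sd = 0) get t = z = 0 and are flagged
    invalid, mirroring the first-level zero-variance policy.
    """
    if len(beta_maps) < 2:
        raise ValueError("need at least 2 subject maps for a one-sample t-test")
    shapes = {m.shape for m in beta_maps}
    if len(shapes) != 1:
        raise ValueError(f"subject maps are on different grids: {sorted(shapes)}")
    stack = np.stack(beta_maps)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=valid)
    z = np.where(valid, t_to_z(t, n - 1), 0.0)
    return GroupResult(
        t_map=t,
        z_map=z,
        n_subjects=n,
        dof=n - 1,
        threshold=threshold,
        mask=threshold_map(z, threshold),
        valid=valid,
    )


def threshold_map(
    z_map: np.ndarray, threshold: float = DEFAULT_Z_THRESHOLD, signed: bool = False
) -> np.ndarray:
    """Suprathreshold mask with strict inequality, positive tail by default.

    ``signed=True`` returns {-1, 0, +1}: +1 where z > threshold, -1 where
    z < -threshold.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if not np.all(np.isfinite(z_map)):
        raise ValueError("z map contains non-finite values")
    if signed:
        return (z_map > threshold).astype(np.int8) - (z_map < -threshold).astype(
            np.int8
        )
    return z_map > threshold


def overlap(masks: Sequence[np.ndarray]) -> OverlapMap:
    """Per-voxel fraction of datasets with an active (True/1) voxel."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to compute overlap")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks are on different grids: {sorted(shapes)}")
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    return OverlapMap(
        fraction=stack.mean(axis=0), n_datasets=stack.shape[0]
    )
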