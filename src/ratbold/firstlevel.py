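"""Per-scan voxelwise GLM: smoothing, OLS fit, task contrast, t-to-z maps.

The model is plain ordinary least squares per voxel (no prewhitening),
matching a block-design analysis with motion and polynomial-drift
co-regressors.  Statistic maps are converted from Student-t to
standard-normal z units by CDF matching, computed sign-symmetrically with
survival functions so the far tails do not saturate.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage, special, stats

from .design import DesignMatrix

__all__ = [
    "Volume4D",
    "FirstLevelResult",
    "GAUSS_FWHM_TO_SIGMA",
    "smooth_gaussian",
    "fit_glm",
    "task_zmap",
    "t_to_z",
    "roi_timeseries",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
GAUSS_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Volume4D:
    """A 4-D functional image: X*Y*Z voxels by T frames, with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume4D":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.get_fdata(), dtype=float), affine=img.affine)


@dataclass(frozen=True)
class FirstLevelResult:
    """Voxelwise OLS output for one scan and one HRF model."""

    beta: np.ndarray        # X*Y*Z*p coefficients, design column order
    sigma2: np.ndarray      # X*Y*Z residual variance (RSS / dof)
    dof: int                # T - rank(design)
    residual: np.ndarray    # X*Y*Z*T residual time courses
    task_beta: np.ndarray   # X*Y*Z task parameter-estimate map
    task_z: np.ndarray      # X*Y*Z z-statistic map (0 where variance is 0)
    valid: np.ndarray       # X*Y*Z bool; False where sigma2 == 0
    design: DesignMatrix


def smooth_gaussian(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Smooth each frame with an isotropic Gaussian of the given FWHM (mm).

    Sigma per axis is ``fwhm_mm / (voxel_size * 2*sqrt(2 ln 2))`` voxels;
    ``fwhm_mm = 0`` is the identity.  Edges use nearest-neighbour padding.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol
    sigma_vox = fwhm_mm / (vol.voxel_size * GAUSS_FWHM_TO_SIGMA)
    smoothed = ndimage.gaussian_filter(
        vol.data, sigma=(*sigma_vox, 0.0), mode="nearest"
    )
    return Volume4D(data=smoothed, affine=vol.affine)


def fit_glm(vol: Volume4D, design: DesignMatrix) -> FirstLevelResult:
    """Per-voxel ordinary least squares fit of the design to the signal."""
    X = design.values
    T, p = X.shape
    if vol.n_vols != T:
        raise ValueError(f"volume has {vol.n_vols} frames but design has {T} rows")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient; refusing to fit")

    shape3 = vol.data.shape[:3]
    Y = vol.data.reshape(-1, T).T                     # T x V
    beta = np.linalg.pinv(X) @ Y                      # p x V
    resid = Y - X @ beta                              # T x V
    dof = int(T - rank)
    sigma2 = np.einsum("tv,tv->v", resid, resid) / dof
    # exact-fit voxels leave O(eps^2) round-off in the RSS; clamp them to 0
    # so they are flagged invalid instead of yielding meaningless t values
    signal_scale = np.einsum("tv,tv->v", Y, Y) / T
    sigma2[sigma2 <= 1e-24 * np.maximum(signal_scale, 1e-300)] = 0.0

    result = FirstLevelResult(
        beta=beta.T.reshape(*shape3, p),
        sigma2=sigma2.reshape(shape3),
        dof=dof,
        residual=resid.T.reshape(*shape3, T),
        task_beta=beta[design.task_index].reshape(shape3),
        task_z=np.zeros(shape3),
        valid=np.ones(shape3, dtype=bool),
        design=design,
    )
    task_z, valid = task_zmap(result, design)
    object.__setattr__(result, "task_z", task_z)
    object.__setattr__(result, "valid", valid)
    return result


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Convert Student-t values to standard-normal z by CDF matching.

    Sign-symmetric and tail-stable: the conversion is done on |t| through
    the survival functions, then the sign is restored, so z does not
    saturate for large |t|.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    t = np.asarray(t, dtype=float)
    log_p_tail = stats.t.logsf(np.abs(t), dof)
    z = -special.ndtri_exp(log_p_tail)  # Phi^-1(1 - p) computed in log space
    return np.sign(t) * z


def task_zmap(
    result: FirstLevelResult, design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Task-effect z map and validity mask from a fitted GLM.

    t = beta_task / se, with se^2 = sigma2 * [(X'X)^-1]_task,task; z by CDF
    matching.  Voxels with zero residual variance get z = 0 and are flagged
    invalid rather than emitting NaN.
    """
    if result.dof < 1:
        raise ValueError("dof must be >= 1 to form a t statistic")
    X = design.values
    c = np.linalg.inv(X.T @ X)[design.task_index, design.task_index]
    se = np.sqrt(result.sigma2 * c)
    valid = se > 0
    t = np.zeros_like(result.task_beta)
    np.divide(result.task_beta, se, out=t, where=valid)
    z = np.where(valid, t_to_z(t, result.dof), 0.0)
    return z, valid


def roi_timeseries(
    vol: Volume4D, atlas: np.ndarray, label: int
) -> np.ndarray:
    """Unweighted per-frame mean signal over the voxels carrying ``label``."""
    if atlas.shape != vol.data.shape[:3]:
        raise ValueError(
            f"atlas grid {atlas.shape} does not match volume grid "
            f"{vol.data.shape[:3]}"
        )
    mask = atlas == label
    if not mask.any():
        available = sorted(int(v) for v in np.unique(atlas))
        raise KeyError(f"label {label} not in atlas; available labels: {available}")
    return vol.data[mask].mean(axis=0)
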