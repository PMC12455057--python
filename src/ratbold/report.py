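"""ROI summaries, per-dataset HRF model comparison, and model-fit panels.

The model-comparison statistic is the group mean of per-subject ROI-mean
z scores; the winning model per dataset is the one with the highest
*absolute* group mean ROI z (signed responses count), with ties broken by
the canonical model-key order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .firstlevel import FirstLevelResult, Volume4D, roi_timeseries
from .hrf import MODEL_ORDER

__all__ = [
    "ROISummary",
    "ModelComparison",
    "roi_zscore_summary",
    "select_best_model",
    "comparison_table",
    "fit_panel",
    "save_panel_png",
]


@dataclass(frozen=True)
class ROISummary:
    """Per-dataset ROI z summary: subject means, group mean and sample sd."""

    per_subject_mean_z: np.ndarray
    group_mean_z: float
    group_sd_z: float
    n_subjects: int
    single_subject: bool  # sd reported as 0 when only one subject


@dataclass(frozen=True)
class ModelComparison:
    """Winner of the per-dataset model comparison."""

    dataset: str
    mean_z_by_model: dict[str, float]
    best_model: str
    tie: bool


def _roi_mask(atlas: np.ndarray, label: int) -> np.ndarray:
    mask = atlas == label
    if not mask.any():
        available = sorted(int(v) for v in np.unique(atlas))
        raise KeyError(f"label {label} not in atlas; available labels: {available}")
    return mask


def roi_zscore_summary(
    z_maps: Sequence[np.ndarray], atlas: np.ndarray, label: int
) -> ROISummary:
    """Average z over the ROI per subject; group mean and sample (n-1) sd."""
    if len(z_maps) < 1:
        raise ValueError("need at least one subject z map")
    mask = _roi_mask(atlas, label)
    per_subject = np.array([float(z[mask].mean()) for z in z_maps])
    single = per_subject.size == 1
    sd = 0.0 if single else float(per_subject.std(ddof=1))
    return ROISummary(
        per_subject_mean_z=per_subject,
        group_mean_z=float(per_subject.mean()),
        group_sd_z=sd,
        n_subjects=per_subject.size,
        single_subject=single,
    )


def select_best_model(
    dataset: str, mean_z_by_model: Mapping[str, float]
) -> ModelComparison:
    """Pick the model with the highest |group mean ROI z| for a dataset.

    Ties (equal absolute z) are broken by the canonical model-key order and
    flagged.
    """
    if len(mean_z_by_model) < 2:
        raise ValueError("need at least 2 models to compare")
    ordered = sorted(
        mean_z_by_model,
        key=lambda k: MODEL_ORDER.index(k) if k in MODEL_ORDER else len(MODEL_ORDER),
    )
    best = max(ordered, key=lambda k: abs(mean_z_by_model[k]))
    tie = (
        sum(
            abs(mean_z_by_model[k]) == abs(mean_z_by_model[best])
            for k in ordered
        )
        > 1
    )
    return ModelComparison(
        dataset=dataset,
        mean_z_by_model=dict(mean_z_by_model),
        best_model=best,
        tie=tie,
    )


def comparison_table(comparisons: Sequence[ModelComparison]) -> pd.DataFrame:
    """Long-form (dataset, model, mean_z, best) table for export."""
    rows = []
    for c in comparisons:
        for model, z in c.mean_z_by_model.items():
            rows.append(
                {
                    "dataset": c.dataset,
                    "model": model,
                    "mean_z": z,
                    "best": model == c.best_model,
                    "tie": c.tie,
                }
            )
    return pd.DataFrame(rows)


def fit_panel(
    vols: Sequence[Volume4D],
    results: Sequence[FirstLevelResult],
    design: DesignMatrix,
    atlas: np.ndarray,
    label: int,
) -> pd.DataFrame:
    """Model-fit panel series for one dataset and one model.

    Columns: ``time`` (s), ``modeled`` (task regressor scaled by the group
    mean ROI task beta, plus the group mean drift fit), ``observed`` (ROI
    mean signal averaged over subjects) and ``residual`` (ROI mean residual
    averaged over subjects).  All scans must share the design (same
    paradigm/timing), else the averages are meaningless.
    """
    if len(vols) != len(results) or not vols:
        raise ValueError("need matching, non-empty volumes and results")
    # motion confounds legitimately differ per subject; the paradigm (task
    # column) and frame timing must not
    for r in results:
        if not np.array_equal(
            r.design.matrix["task"].to_numpy(), design.matrix["task"].to_numpy()
        ) or not np.array_equal(r.design.frame_times, design.frame_times):
            raise ValueError("heterogeneous paradigms across scans")
    mask = _roi_mask(atlas, label)

    observed = np.mean([roi_timeseries(v, atlas, label) for v in vols], axis=0)
    residual = np.mean([r.residual[mask].mean(axis=0) for r in results], axis=0)

    X = design.values
    names = design.columns
    drift_idx = [i for i, n in enumerate(names) if n.startswith("poly_")]
    mean_betas = np.mean(
        [r.beta[mask].mean(axis=0) for r in results], axis=0
    )
    modeled = X[:, design.task_index] * mean_betas[design.task_index]
    modeled = modeled + X[:, drift_idx] @ mean_betas[drift_idx]
    return pd.DataFrame(
        {
            "time": design.frame_times,
            "modeled": modeled,
            "observed": observed,
            "residual": residual,
        }
    )


def save_panel_png(panel: pd.DataFrame, path, title: str = "") -> None:
    """Render a fit panel (modeled vs observed, plus residual) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax1.plot(panel["time"], panel["observed"], "k-", label="observed (ROI mean)")
    ax1.plot(panel["time"], panel["modeled"], "r-", label="modeled response")
    ax1.legend(loc="best", fontsize=8)
    ax1.set_ylabel("signal")
    if title:
        ax1.set_title(title)
    ax2.plot(panel["time"], panel["residual"], "b-")
    ax2.axhline(0.0, color="0.6", lw=0.5)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("residual")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
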