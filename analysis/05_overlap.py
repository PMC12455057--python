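#!/usr/bin/env python
"""Cross-dataset activation overlap per HRF model.

Simulates 12 independent cohorts (different seeds, same paradigm), computes
each cohort's thresholded group map under each model, and the per-voxel
fraction of cohorts active.  Reports, per model, how many voxels reach 100%
overlap and how many of them fall inside the true active region.
"""

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ratbold import grouplevel, pipeline, synth
from ratbold.hrf import MODEL_ORDER

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

N_DATASETS = 12


def main() -> None:
    masks = {m: [] for m in MODEL_ORDER}
    atlas = affine = None
    for seed in range(N_DATASETS):
        cfg = synth.SynthConfig(seed=seed)
        ds = synth.generate_cohort(cfg)
        atlas, affine = ds.atlas, ds.affine
        for m in MODEL_ORDER:
            masks[m].append(pipeline.fit_cohort(ds, m).group.mask)
    active = atlas == synth.ACTIVE_LABEL

    (SCRATCH / "overlap").mkdir(parents=True, exist_ok=True)
    rows = []
    for m in MODEL_ORDER:
        out = grouplevel.overlap(masks[m])
        full = out.fraction == 1.0
        rows.append(
            {
                "model": m,
                "n_full_overlap_voxels": int(full.sum()),
                "full_overlap_in_active_roi": int((full & active).sum()),
                "active_roi_size": int(active.sum()),
            }
        )
        nib.save(
            nib.Nifti1Image(out.fraction.astype(np.float32), affine),
            str(SCRATCH / "overlap" / f"overlap_{m}.nii.gz"),
        )
        print(
            f"{m:>9}: {int(full.sum()):4d} voxels active in "
            f"{N_DATASETS}/{N_DATASETS} cohorts "
            f"({int((full & active).sum())} inside the true ROI of {int(active.sum())})"
        )
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "overlap.tsv", sep="\t", index=False)
    print("wrote overlap table -> results/overlap.tsv")


if __name__ == "__main__":
    main()
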