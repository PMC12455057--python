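#!/usr/bin/env python
"""First-level fits: every subject of the short-block cohort under each of
the five HRF models (2-Gammas, Peak-span, Glover, SPM, Box).

Smoothing 0.45 mm FWHM, motion + third-order drift co-regressors.  Writes
the per-subject ROI-mean z table to results/ — the raw material for the
group maps and the model comparison.
"""

from pathlib import Path

import pandas as pd

from ratbold import pipeline, synth
from ratbold.hrf import MODEL_ORDER

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = synth.SynthConfig(seed=1)
    ds = synth.generate_cohort(cfg)
    rows = []
    for model in MODEL_ORDER:
        fit = pipeline.fit_cohort(ds, model)
        for i, z in enumerate(fit.roi_summary.per_subject_mean_z):
            rows.append({"model": model, "subject": i, "roi_mean_z": round(z, 4)})
        print(
            f"{model:>9}: ROI z = {fit.roi_summary.group_mean_z:5.2f} "
            f"± {fit.roi_summary.group_sd_z:4.2f} across {cfg.n_subjects} subjects"
        )
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "first_level_roi_z.tsv", sep="\t", index=False)
    print("wrote per-subject ROI z table -> results/first_level_roi_z.tsv")


if __name__ == "__main__":
    main()
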