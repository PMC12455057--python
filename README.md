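# ratbold

Activation mapping for rat sensory-evoked BOLD fMRI.

Task-evoked rodent fMRI is usually analysed with human-derived hemodynamic
response functions (HRFs), even though the rat BOLD response has markedly
faster temporal kinetics. `ratbold` implements the standard block-design
mass-univariate analysis — first-level GLM, group one-sample t-test,
thresholded z maps — with **five interchangeable HRF models**, so that the
effect of model choice on rat activation maps can be measured rather than
assumed:

| key        | model |
|------------|-------|
| `peakspan` | rat single gamma-variate, solved from time-to-peak 1.92 s and FWHM 2.18 s |
| `2gammas`  | rat double gamma (fast peak, mild undershoot; constants configurable) |
| `glover`   | canonical Glover human double gamma |
| `spm`      | canonical SPM human double gamma |
| `box`      | no convolution: the raw block-design boxcar |

It is aimed at preclinical imaging groups who need a transparent,
dependency-light reference pipeline for multi-center rat data, and ships a
synthetic 4-D BOLD cohort generator with exact ground truth so every stage
is testable without downloading any data.

## The model

For each voxel \(v\) with signal \(y_v(t)\) sampled at frame times
\(t_i=(i+\tfrac12)\,\mathrm{TR}\):

\[ y_v = \beta_{task} x + M\gamma_v + P\delta_v + \varepsilon_v,\qquad
   \varepsilon_v \sim N(0, \sigma_v^2 I) \]

where \(x\) is the stimulation boxcar convolved with the chosen HRF
(peak-normalized so \(\beta\) is comparable across models), \(M\) are six
demeaned motion parameters, and \(P\) are polynomial drift regressors of
degree 0–3 (Legendre, orthogonalized on the frame grid). The fit is plain
OLS; the task statistic is

\[ t_v = \hat\beta_{task}/\widehat{se}, \qquad
   z_v = \Phi^{-1}\!\big(F_{t,\nu}(t_v)\big) \]

with the t→z conversion done sign-symmetrically through log survival
functions (no tail saturation). Group maps are voxelwise one-sample
t-tests over subject \(\hat\beta_{task}\) maps, thresholded at z > 1.93
(one-sided Gaussian tail ≈ 0.027, i.e. p < 0.05 uncorrected). Per-dataset
model comparison scores each HRF by the group mean ROI z; cross-dataset
consistency is the per-voxel fraction of datasets whose thresholded group
map is active.

The Peak-span rat HRF is the package's scientific centrepiece: a gamma
density \(t^{k-1}e^{-t/\theta}\) whose \((k,\theta)\) are solved by 1-D
root finding so that the *sampled kernel* reproduces the defining
constraints TTP = 1.92 s, FWHM = 2.18 s (the FWHM/TTP ratio fixes the
shape; the gamma scale family fixes the rest).

## Worked example

```python
from ratbold import synth, pipeline, report

cfg = synth.SynthConfig(seed=1)          # 10 subjects, 20 s blocks, CNR 1
ds = synth.generate_cohort(cfg)
for model in ("peakspan", "spm", "box"):
    fit = pipeline.fit_cohort(ds, model) # smooth 0.45 mm, fit, group map
    s = fit.roi_summary
    print(f"{model:>9}: ROI z = {s.group_mean_z:5.2f} ± {s.group_sd_z:4.2f}, "
          f"{int(fit.group.mask.sum())} voxels above z=1.93")
```

prints

```
 peakspan: ROI z =  8.93 ± 1.35, 722 voxels above z=1.93
      spm: ROI z =  7.35 ± 1.24, 724 voxels above z=1.93
      box: ROI z =  7.04 ± 1.26, 680 voxels above z=1.93
```

The cohort was generated with the Peak-span HRF, and the matched model
indeed yields the highest group mean ROI z (8.93); the mis-specified human
SPM model loses about 18% of the ROI statistic, and the unconvolved Box
regressor a little more. The ± value is the between-subject standard
deviation of per-subject ROI-mean z.

The same stages are exposed as a CLI
(`ratbold simulate|fit-subject|fit-group|report|overlap|run`) and as the
numbered drivers under `analysis/` (simulation → first level → group maps →
model comparison → cross-cohort overlap), which write their tables to
`results/`.

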