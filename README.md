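# gliodki

Quantitative-MRI biomarkers of the glioma invasion border.

High-grade gliomas infiltrate white matter far beyond the
contrast-enhancing tumour mass, and the infiltrated zones look normal on
conventional MRI. Diffusion kurtosis imaging (DKI) measures the
non-Gaussianity of water diffusion and is sensitive to exactly this kind of
microstructural disruption; arterial-spin-labeling cerebral blood flow
(CBF) marks the most malignant, hyper-perfused tumour core. `gliodki`
implements the full analysis chain a neuroimaging group needs to evaluate
these biomarkers across four tissue zones — enhancing core (ROI1),
perifocal infiltrative edema (ROI2), ipsilateral normal-appearing white
matter (ROI3), contralateral white matter (ROI4) — together with a
synthetic phantom generator that emulates the acquisition and cohort
structure, so every stage is testable against ground truth.

## What it computes

**Model.** Voxel-wise least-squares DKI: the log-signal of a multi-shell
acquisition (b = 0, 1000, 2500 s/mm², 60 directions per shell) is fitted by

    ln S(b,n) = ln S0 − b·Σ nᵢnⱼDᵢⱼ + (b²/6)·Σ nᵢnⱼnₖnₗVᵢⱼₖₗ,  V = MD²·W,

a linear model in 22 unknowns (two-pass signal-weighted by default). From
the tensor pair (D, W) the package derives

* scalar maps — MD, FA, MK, AK, RK, KA, with the QC rule deleting voxels
  whose MK falls strictly outside [0, 3] from all kurtosis maps;
* white-matter tract-integrity (WMTI) maps — AWF (axonal water fraction,
  f = K_max/(K_max+3)), AxEAD/RadEAD, AxIAD/RadIAD, TORT = AxEAD/RadEAD;
* per-ROI means (the only statistics input) joined with a CBF map;
* the statistics battery — Mann-Whitney zone comparisons (α = 0.001),
  ROC curves with Youden cutoffs and bootstrap CIs ranking the biomarkers
  per ROI pair, and Spearman correlations with immunohistochemical markers
  (Ki-67 LI, Bcl-2 EA; α = 0.05).

The core objects follow the statsmodels idiom: `DiffusionKurtosisModel`
is built from data and a scheme, `fit()` returns a
`DiffusionKurtosisResults` carrying the tensor field, derived maps and a
`summary()`. See `docs/methods.md` for the model, the phantom calibration
and the numerical choices.

## Worked example

Simulate a 50-case cohort table (the calibrated phantom conditions) and
rank the biomarkers for the hardest contrast — normal-appearing peritumoral
white matter (ROI3) vs contralateral white matter (ROI4):

```python
from gliodki import (CohortSpec, simulate_cohort, roc_analysis,
                     compare_rois, marker_correlations)

table = simulate_cohort(CohortSpec(n_cases=50, seed=7))
for r in roc_analysis(table, 3, 4, n_boot=2000, seed=7)[:5]:
    print(f"{r.parameter:7s} AUC={r.auc:.2f}  cutoff={r.cutoff:.2f}  "
          f"spec={r.specificity:.2f}  sens={r.sensitivity:.2f}  "
          f"CI=[{r.ci_low:.2f}, {r.ci_high:.2f}]")
```

```
RK      AUC=0.99  cutoff=1.92  spec=0.98  sens=0.94  CI=[0.97, 1.00]
MK      AUC=0.97  cutoff=1.09  spec=0.90  sens=0.96  CI=[0.94, 0.99]
AWF     AUC=0.96  cutoff=0.40  spec=0.88  sens=0.92  CI=[0.92, 0.98]
AK      AUC=0.89  cutoff=0.40  spec=0.86  sens=0.82  CI=[0.82, 0.95]
FA      AUC=0.86  cutoff=0.63  spec=0.90  sens=0.68  CI=[0.78, 0.93]
```

Kurtosis-family parameters (RK, MK, AWF) lead the ranking: their
generating distributions separate the outer zones most reliably, which is
the calibrated structure of the phantom. A cutoff of e.g. MK = 1.09
classifies a ROI-3-like mean below it with 96 % sensitivity at 90 %
specificity. The comparison and correlation layers read the same table:

```python
comp = {c.parameter: c for c in compare_rois(table, 3, 4)}
print(comp["MK"].p_value < 0.001)        # True — MK separates ROI3/ROI4
corr = marker_correlations(table, 1, markers=["Ki67_LI"],
                           params=["CBF"], seed=7)[0]
print(f"rho={corr.rho:.3f}  p={corr.p_value:.3g}")
# rho=0.207  p=0.149
```

The last line is a deliberate caution: the generator's true core-CBF/Ki-67
rank correlation is 0.363, but a single n = 50 cohort estimates it with a
standard error of ~0.14 — at this sample size a real effect of that
magnitude sits near the detection limit (at n = 500 the estimate lands
within a few hundredths of the target).

Image-level work uses the same objects end to end:

```bash
gliodki simulate image --seed 1 --out case0/      # DWI + CBF + ROIs + truth
gliodki fit  --dwi case0/phantom_dwi.nii.gz --bval case0/phantom.bval \
             --bvec case0/phantom.bvec --mask case0/phantom_labels.nii.gz \
             --out case0/tensors
gliodki maps --tensors case0/tensors --out case0/maps
gliodki wmti --tensors case0/tensors --out case0/maps
gliodki roistats --table cohort.csv --seed 0 --out stats/
gliodki run --config pipeline.yaml                # all stages, one config
```

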