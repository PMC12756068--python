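# frocdwi

Quantitative analysis of multi-b diffusion-weighted MRI (DWI) of breast
lesions: voxel-wise fitting of the fractional-order-calculus (FROC)
diffusion model and the mono-exponential ADC, fuzzy C-means whole-lesion
segmentation from a 2D seed ROI, whole-lesion first-order histogram
features, and the cohort statistics used to evaluate the resulting metrics
as diagnostic and prognostic biomarkers.

## The problem

Conventional DWI summarizes water mobility with the apparent diffusion
coefficient (ADC) of a mono-exponential decay, `S(b) = S0·exp(−b·ADC)`,
which assumes Gaussian diffusion.  Tumor tissue is heterogeneous at the
voxel scale, and at strong diffusion weighting (b up to 2000 s/mm²) the
signal departs from mono-exponential decay.  The FROC model describes this
non-Gaussian decay with three parameters:

    S = S0 · exp[ −D · μ^{2(β−1)} · (γ·G_d·δ)^{2β} · (Δ − (2β−1)/(2β+1)·δ) ]

where `D` (mm²/s) is a diffusivity, `β ∈ (0, 1]` the spatial fractional
order (lower β ⇒ more intravoxel heterogeneity; β = 1 recovers
`S0·exp(−b·D)` exactly), `μ` (mm) a spatial constant, `G_d` the diffusion
gradient amplitude, `δ`/`Δ` the gradient pulse width and lobe separation,
and `γ` the proton gyromagnetic ratio.  `G_d` and the b-value are linked by
the rectangular-pulse Stejskal–Tanner relation `b = (γ·G_d·δ)²·(Δ − δ/3)`.

The package is aimed at researchers evaluating non-Gaussian diffusion
metrics as lesion biomarkers: it provides the forward models, per-voxel
estimators, lesion segmentation, histogram radiomics, the full statistical
battery (Mann–Whitney U with exact small-sample p-values, Kruskal–Wallis +
Bonferroni, Spearman, ICC(2,1), ROC/Youden, DeLong, multivariable logistic
AUC), and synthetic phantom/cohort generators so that the entire pipeline
is testable without patient data.

An identifiability caveat that any user of this model family should know:
with a single diffusion timing (one δ, Δ) the FROC signal is a stretched
exponential in b, so `D` and `μ` are identified only jointly through the
composite `D·μ^{2(β−1)}`; fitted `D`/`μ` maps are deterministic ridge
selections (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from frocdwi import (FrocParams, froc_signal, fit_froc, rician_noise,
                     default_protocol, make_cohort, CohortSpec,
                     roc_analysis, mann_whitney_u)

# fit one voxel's multi-b decay (8 b-values, 0–2000 s/mm², δ=19.3 ms, Δ=40 ms)
protocol = default_protocol()
truth = FrocParams(S0=1000.0, D=0.93e-3, beta=0.78, mu=6.5e-3)
signal = rician_noise(froc_signal(truth, protocol), sigma=3.0, seed=0)
fit = fit_froc(signal, protocol)
print(f"beta_hat = {fit.params.beta:.3f}   (truth 0.780)")

# simulate a 50 benign / 109 malignant cohort and evaluate ADC-median
cohort = make_cohort(CohortSpec(seed=1))
labels = cohort["malignant"].to_numpy(bool)
roc = roc_analysis(cohort["ADC-median"].to_numpy(), labels)
test = mann_whitney_u(cohort.loc[~labels, "ADC-median"],
                      cohort.loc[labels, "ADC-median"])
print(f"ADC-median AUC = {roc.auc:.3f} (95% CI {roc.ci[0]:.3f}-{roc.ci[1]:.3f})")
print(f"cutoff = {roc.cutoff:.1f}, sens = {roc.sensitivity:.1f}%, "
      f"spec = {roc.specificity:.1f}%")
```

prints

```
beta_hat = 0.775   (truth 0.780)
ADC-median AUC = 0.979 (95% CI 0.954-1.000)
cutoff = 1040.2, sens = 96.3%, spec = 94.0%
```

The fitted β recovers the simulated heterogeneity index to within noise;
the cohort block shows that an ADC-median threshold of ~1040 (in 10⁻⁶
mm²/s) separates benign from malignant lesions with an AUC near 0.98 —
malignant lesions score *low*, which `roc_analysis` detects and reports via
its `positive_low` flag.

## Command line

```sh
frocdwi simulate phantom --seed 1 --out phantom/      # 4D NIfTI + .bval + truth
frocdwi simulate cohort  --seed 1 --readers --out cohort.csv
frocdwi fit --dwi phantom/dwi.nii --bval phantom/dwi.bval \
            --mask phantom/lesion_mask.nii --model froc --out maps/
frocdwi stats --table cohort.csv --out report/
frocdwi pipeline --seed 1 --out run/                  # full synthetic pipeline
```

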