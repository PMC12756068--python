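# Methods

## Signal models and units

All internal computation uses seconds, s/mm², T/mm, mm and mm²/s, which
makes every model exponent dimensionless by construction.  Reporting-scale
conversion (diffusivities ×10⁶ to "10⁻⁶ mm²/s" units; β and μ ×10³ / ×10⁶
to "10⁻³" units) happens only at feature/CSV emission, never internally.

The mono-exponential model is `S(b) = S0·exp(−b·ADC)`.  The
fractional-order-calculus (FROC) model is

    S = S0 · exp[ −D · μ^{2(β−1)} · (γ G_d δ)^{2β} · (Δ − (2β−1)/(2β+1) δ) ]

with β restricted to (0, 1]: values above 1 make the equation degenerate
and reported tissue values are all below 1.  The b↔G_d mapping is the
rectangular-pulse Stejskal–Tanner relation `b = (γ G_d δ)² (Δ − δ/3)` —
the convention under which the β = 1 limit collapses *exactly* to
`exp(−b·D)` (verified to machine precision in the tests).  The default
timing is δ = 19.3 ms, Δ = 40.0 ms with b ∈ {0, 50, 100, 200, 400, 800,
1200, 2000} s/mm², the emulated breast protocol; γ defaults to the proton
value 2.675222×10⁸ rad s⁻¹ T⁻¹.

### Identifiability of D and μ

With a single diffusion timing, substituting the b↔G_d relation gives

    S(b) = S0 · exp(−C · b^β),
    C = D · μ^{2(β−1)} · (Δ − δ/3)^{−β} · (Δ − (2β−1)/(2β+1) δ).

Only S0, β and the composite C are identifiable; D and μ are *exactly*
coupled along the ridge `D ∝ μ^{2−2β}` (at β = 1 the μ exponent vanishes
and D becomes identifiable on its own, equal to the ADC).  This is a
property of the acquisition, not of the estimator — separating D from μ
would require data at several diffusion times.

The fitter nevertheless reports all four parameters, as the field's
software does: with fixed, deterministic start values the optimizer's
ridge selection is a reproducible function of the identifiable quantities
(C, β), so D and μ maps still carry real contrast — but their *absolute*
values should not be interpreted as unbiased estimates of the generating
D and μ.  Tests of estimator accuracy therefore assert β, S0 and C;
voxels with β > 0.98 are additionally flagged `mu_unidentifiable` (the
data carry no μ information at all there) and are excluded from μ
histogram features.

## Voxel fitting

* **ADC** (b ≤ 800 s/mm² by default): weighted log-linear least squares of
  ln S on b with weights S², the variance-stabilizing choice that makes the
  log-domain fit first-order equivalent to untransformed least squares.
  ADC is clamped at ≥ 0; at least 3 positive signals are required.  Whether
  to use all b ≤ 800 or only {0, 800} is an open choice for this kind of
  protocol; all b ≤ 800 is used as the more robust option in the same model
  class.
* **FROC** (b ≤ 2000 s/mm²): bounded trust-region nonlinear least squares
  (`scipy.optimize.least_squares`, TRF) on the untransformed signal.
  Bounds: D ∈ [10⁻⁵, 5×10⁻³] mm²/s, β ∈ [0.2, 1.0], μ ∈ [5×10⁻⁴, 2×10⁻²]
  mm, S0 ∈ (0, 10·max signal].  Multi-start (3 by default): one
  deterministic start seeded from the mono fit (β = 0.9, μ = 5×10⁻³ mm)
  plus seeded log-uniform jitters; lowest converged residual wins, exact
  ties break toward smaller β (the non-degenerate solution).  S0 is free
  rather than pinned to the measured b = 0 signal, which is itself noisy.
  Residuals are Gaussian least squares, not a Rician likelihood: at the
  SNR levels this pipeline targets (≥ ~20 at b = 2000) the magnitude bias
  is small against fit residuals, and this matches common practice.
* **Volume fitting** uses the *same* start set for every voxel, so
  identical signals give identical parameters and the run is fully
  deterministic under the config seed.  Per-voxel failures and flags
  (`not_converged`, `mu_unidentifiable`, `signal_increase`) are recorded as
  boolean maps; non-fitted voxels are NaN, never zero-filled.  Voxels whose
  signal rises with b beyond twice the local noise spread are fit anyway
  and flagged — region-level exclusions (cysts, hemorrhage) are the seed
  ROI's responsibility.

## Lesion segmentation

A 2D seed ROI on the b = 800 s/mm² volume is grown into a whole-lesion 3D
mask by plain intensity fuzzy C-means (c = 2 clusters, fuzzifier m = 2,
standard alternating membership/centroid updates).  The clustering domain
is the seed's bounding box dilated 10 voxels in-plane with full z extent —
a per-lesion domain, because a whole-breast two-class split would be
dominated by air/fat rather than lesion/parenchyma contrast.  Details
fixed here because no published convention exists:

* deterministic initialization at the 10th/90th intensity percentiles of
  the search region, falling back to min/max when a small lesion fraction
  makes those percentiles coincide;
* convergence when the largest centroid shift falls below `tol·range(x)`
  (relative, so clustering is equivariant under affine intensity rescaling
  — property-tested);
* the cluster with the highest mean membership over the seed is binarized
  at membership ≥ 0.5, and the 26-connected component overlapping the seed
  is kept; the result must cover ≥ 50 % of the seed or segmentation fails
  loudly with diagnostics.

## Histogram features

Seven first-order statistics per parameter map over the lesion ROI: 10th
and 90th percentiles and median (linear interpolation), mean, entropy,
kurtosis, skewness.  Conventions, fixed for reproducibility because vendor
conventions are unpublished:

* skewness `m₃/m₂^1.5` and kurtosis `m₄/m₂²` with *population* central
  moments; kurtosis is non-excess (Gaussian = 3) — consistent with
  benign-lesion reference values sitting at ≈ 3.5;
* entropy `−Σ pᵢ log₂ pᵢ` over 100 equal-width bins spanning the ROI's own
  [min, max] (bits, bounded by log₂ 100 ≈ 6.64, consistent with reference
  entropy magnitudes of ~3.3–6.1); equal-width bins over the data range
  make entropy affine-invariant; bin count is configurable;
* constant input: skewness = kurtosis = entropy = 0 by convention;
* absolute entropy values are therefore comparable *within* this package
  but not bit-exact against software with different bin counts or bases.

## Cohort statistics

* Mann–Whitney U: exact two-sided p by exhaustive enumeration of group
  assignments for pooled n ≤ 10 (valid under ties), otherwise the normal
  approximation with tie and continuity corrections (scipy).  Reported
  statistic is min(Uₓ, U_y).
* Kruskal–Wallis: tie-corrected H with χ² reference; pairwise follow-up by
  Mann–Whitney with Bonferroni adjustment (p × number of pairs, capped).
* Spearman ρ with midrank ties and t-approximation p; strength bands
  0.75–1.00 good / 0.50–0.74 moderate / 0.25–0.49 mild / below poor.
* ICC(2,1): two-way random effects, absolute agreement, single measure,
  with F-based 95 % CI (pingouin; cross-checked against a hand ANOVA
  decomposition in the tests); bands ≤ 0.40 poor / 0.40–0.59 fair /
  0.60–0.74 good / 0.75–1.00 excellent.
* ROC: empirical AUC via the rank (Mann–Whitney) formulation, equal to
  U/(n₁n₂) by identity (property-tested against scikit-learn).  For
  diffusion metrics low values typically indicate malignancy, so
  orientation is auto-detected and reported explicitly (`positive_low`)
  instead of silently flipping.  The cutoff maximizes the Youden index,
  reported as the midpoint between adjacent observed scores; J ties break
  toward higher specificity.  CIs use the DeLong placement-value variance.
* DeLong test: paired placement-value covariance, two-sided z test.
* Multivariable combination: columns standardized, additive logistic model
  by IRLS (statsmodels GLM), ROC on the linear predictor.  Deliberately
  *in-sample* — mirroring how such models are usually reported at this
  cohort size — and flagged as optimistic in the output; perfect
  separation is flagged and the AUC computed from the diverging linear
  predictor's ordering, which remains well defined.

## Synthetic data

**Phantoms** emulate a breast DWI study: an ellipsoidal lesion (low D ≈
0.93×10⁻³ mm²/s, low β ≈ 0.78, μ ≈ 6.5 μm — malignant-like central
values) in a looser background (D 1.5×10⁻³, β 0.90, μ 7.3 μm), per-voxel
parameters mean + SD × a unit-variance Gaussian random field smoothed to a
2-voxel correlation length, clipped to the model bounds with clip counts
warned.  Forward signals use the FROC equation; Rician magnitude noise
`sqrt((S+ε₁)² + ε₂²)` is calibrated so mean lesion signal at b = 2000
divided by the channel σ equals the target SNR (default 119.56, the
malignant-lesion level of the reference study; benign 56.53 and
fibroglandular 22.53 are available as presets).  Phantoms do *not* emulate
anatomy, partial volume, motion, EPI distortion, fat suppression, or
susceptibility gradients — passing tests demonstrate estimator and
pipeline correctness under the stated noise model, not robustness to those
real-data effects.

**Cohorts** are simulated directly at lesion level: the reference study
publishes per-metric group means ± SDs only, so correlated Gaussian
marginals (single exchangeable inter-metric ρ = 0.5) are the minimal
faithful choice — with the known caveat that real metric distributions are
right-skewed.  Defaults: 50 benign / 109 malignant; the 28 reference
benign/malignant means ± SDs; prognostic-label prevalences (ER 60.6 %, PR
63.3 %, HER2 29.4 %, high Ki-67 80.7 %, nodal metastasis 34.9 %; subtype
mixture 68.8/11.9/19.3 %) assigned independently per label;
estrogen-receptor-conditional mean shifts for the D/β/μ metric families
(the reference ADC rows for that breakdown contain typesetting errors and
are omitted from defaults); optional duplicate-reader columns `value +
N(0, 0.3 × group SD)`, which lands ICC(2,1) in the excellent band.

## Problem sizes and determinism

Default analysis sizes are chosen for a single CPU: the end-to-end
synthetic pipeline uses a 64×64×16 grid (≈1700 lesion voxels, ~1 minute),
estimator calibration uses 200-voxel replicates, statistical calibration
1000 null replicates, and the headline-AUC reproduction 500 replicate
cohorts.  Every stochastic component consumes an explicit seed; identical
seeds give bit-identical volumes, tables and reports.

## Known limitations

* D and μ are reported on the identifiability ridge (above); multi-timing
  acquisitions would be needed to separate them.
* No Rician-likelihood fitting; biased at SNR well below ~20.
* FCM is plain intensity clustering (no spatial regularization, no
  bias-field correction); seeds must avoid cystic/hemorrhagic components.
* The multivariable AUC is in-sample and optimistic by construction.
* Lesion-level cohort simulation reproduces first and second moments and a
  single exchangeable correlation, not the full joint distribution of real
  histogram metrics.
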