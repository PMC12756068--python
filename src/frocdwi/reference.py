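"""Reference cohort distributions used as simulation defaults.

Group means and standard deviations of whole-lesion histogram metrics for
benign vs. malignant breast lesions, on the reporting scale (diffusivities
in 1e-6 mm^2/s; beta and mu in 1e-3 units), together with prognostic-label
prevalences among the malignant lesions and estrogen-receptor-conditional
group means.  These describe a clinical breast-DWI cohort (50 benign / 109
malignant mass lesions at 3 T) and drive the cohort generator's defaults.
"""

from __future__ import annotations

#: metric -> (benign mean, benign SD, malignant mean, malignant SD),
#: reporting scale.
GROUP_STATS: dict[str, tuple[float, float, float, float]] = {
    "ADC-p10":       (1182.070, 336.607, 656.414, 126.826),
    "ADC-p90":       (1668.982, 297.146, 1068.590, 171.082),
    "ADC-entropy":   (4.165, 0.585, 4.376, 0.491),
    "ADC-kurtosis":  (3.560, 2.483, 4.667, 2.433),
    "ADC-mean":      (1431.755, 272.719, 843.832, 122.565),
    "ADC-median":    (1439.880, 285.282, 816.936, 121.969),
    "ADC-skewness":  (0.114, 0.818, 0.880, 0.704),
    "D-p10":         (1255.080, 333.550, 712.878, 148.349),
    "D-p90":         (1747.994, 282.887, 1181.537, 180.711),
    "D-entropy":     (4.189, 0.562, 4.540, 0.489),
    "D-kurtosis":    (3.538, 2.341, 4.330, 1.960),
    "D-mean":        (1508.486, 256.272, 927.381, 132.942),
    "D-median":      (1516.810, 269.924, 901.665, 133.399),
    "D-skewness":    (0.117, 0.794, 0.785, 0.669),
    "beta-p10":      (719.868, 176.372, 657.139, 116.150),
    "beta-p90":      (960.416, 37.259, 895.620, 57.903),
    "beta-entropy":  (3.275, 0.473, 3.592, 0.433),
    "beta-kurtosis": (17.212, 24.568, 14.520, 13.469),
    "beta-mean":     (849.692, 54.255, 772.093, 35.107),
    "beta-median":   (868.740, 54.812, 783.211, 38.641),
    "beta-skewness": (-2.153, 2.345, -1.929, 1.675),
    "mu-p10":        (6035.350, 1591.250, 5435.192, 1191.744),
    "mu-p90":        (9333.234, 1662.342, 8187.907, 1491.670),
    "mu-entropy":    (5.525, 0.851, 6.066, 0.533),
    "mu-kurtosis":   (26.555, 22.290, 57.157, 67.352),
    "mu-mean":       (7866.594, 782.448, 6996.922, 702.785),
    "mu-median":     (7329.720, 433.453, 6507.206, 353.028),
    "mu-skewness":   (3.052, 3.051, 5.236, 3.801),
}

#: prevalence of positive status among malignant lesions.
LABEL_PREVALENCE: dict[str, float] = {
    "ER": 0.606,
    "PR": 0.633,
    "HER2": 0.294,
    "Ki67": 0.807,
    "ALN": 0.349,
}

#: molecular-subtype mixture among malignant lesions.
SUBTYPE_PREVALENCE: dict[str, float] = {
    "luminal": 0.688,
    "HER2-positive": 0.119,
    "triple-negative": 0.193,
}

#: estrogen-receptor-conditional group means among malignant lesions:
#: metric -> (ER-negative mean, ER-positive mean), reporting scale.  Only
#: the fractional-order metric families are covered.
ER_GROUP_MEANS: dict[str, tuple[float, float]] = {
    "D-p10":         (747.947, 690.030),
    "D-p90":         (1204.351, 1166.673),
    "D-mean":        (955.875, 908.818),
    "D-median":      (926.802, 885.288),
    "D-entropy":     (4.531, 4.545),
    "D-kurtosis":    (4.306, 4.346),
    "D-skewness":    (0.855, 0.739),
    "beta-p10":      (679.472, 642.588),
    "beta-p90":      (892.574, 897.605),
    "beta-mean":     (779.515, 767.258),
    "beta-median":   (788.058, 780.053),
    "beta-entropy":  (3.519, 3.639),
    "beta-kurtosis": (15.078, 14.155),
    "beta-skewness": (-1.871, -1.968),
    "mu-p10":        (5549.998, 5360.394),
    "mu-p90":        (8033.509, 8288.500),
    "mu-mean":       (6943.614, 7031.652),
    "mu-median":     (6538.012, 6487.136),
    "mu-entropy":    (6.115, 6.035),
    "mu-kurtosis":   (62.524, 53.660),
    "mu-skewness":   (5.568, 5.019),
}

#: signal-to-noise ratios at b = 2000 s/mm^2 (mean over lesions) for
#: fibroglandular tissue, benign, and malignant lesions.
SNR_B2000 = {"fgt": 22.53, "benign": 56.53, "malignant": 119.56}
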