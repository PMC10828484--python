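"""Published study inputs used to parameterise analyses and simulations.

The contingency tables below are the sex × category counts printed for
the 40-participant feasibility cohort (24 men, 16 women); they are the
inputs to the chi-squared reproduction.  The marginal specifications are
the printed per-sex medians and IQRs of the participant characteristics
and the per-biopsy senescence/morphology variables; together with a
plausible rank-correlation structure assembled from the reported
correlation coefficients, they parameterise the Gaussian-copula synthetic
cohort generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import MarginalSpec, nearest_psd

# sex × category counts (rows: men, women)
TABLE1_CONTINGENCY = {
    "education": [[16, 8], [12, 4]],                # no / yes higher education
    "occupation": [[6, 3, 15], [3, 5, 8]],          # routine / intermediate / managerial
    "bmi_category": [[7, 13, 4], [4, 10, 2]],       # normal / overweight / obese
    "ewgsop2": [[23, 1], [13, 3]],                  # none / probable
    "smoking": [[14, 10, 0], [9, 6, 1]],            # never / previous / current
    "sarcf": [[22, 2], [14, 2]],                    # 0 / >= 1
}

# two-decimal p-values printed alongside the tables above
TABLE1_PRINTED_P = {
    "education": 0.83,
    "occupation": 0.35,
    "bmi_category": 0.87,
    "ewgsop2": 0.33,
    "smoking": 0.46,
    "sarcf": 1.0,
}


def _pct(median, q1, q3, family="lognormal"):
    if family == "lognormal" and q1 <= 0:
        family = "normal"
    return MarginalSpec(median, q1, q3, family, lower=0.0, upper=100.0)


# per-sex marginals: participant characteristics (medians / IQRs)
DEFAULT_MARGINALS = {
    "M": {
        "age_years": MarginalSpec(69.09, 60.51, 74.91, "normal", lower=45, upper=85),
        "grip_kg": MarginalSpec(42.0, 37.5, 45.25, "normal", lower=5),
        "chair_stands_s": MarginalSpec(10.98, 9.49, 12.91, "lognormal"),
        "gait_speed_ms": MarginalSpec(1.27, 1.15, 1.32, "normal", lower=0.2),
        "alm_kg": MarginalSpec(25.17, 23.02, 27.18, "normal", lower=5),
        "almi_kgm2": MarginalSpec(8.0, 7.49, 8.88, "normal", lower=2),
        "bmi_kgm2": MarginalSpec(26.55, 24.56, 28.24, "normal", lower=15),
        "mvpa_min": MarginalSpec(23.23, 8.64, 38.51, "lognormal"),
        "sf36_general": MarginalSpec(59, 52, 70, "normal", lower=0, upper=100),
        "pct_p16_nuclei_2plus": _pct(4.6, 2.3, 8.5),
        "pct_p16_fibre_2plus": _pct(2.35, 1.0, 6.8),
        "pct_p16_any_2plus": _pct(12.6, 8.3, 16.0),
        "pct_taf_2plus": _pct(5.0, 1.8, 7.3),
        "pct_taf_3plus": _pct(0.0, 0.0, 1.0),
        "pct_hmgb1_pos": _pct(27.5, 12.8, 37.8),
        "pct_laminb1_pos": _pct(24.5, 19.8, 33.3),
        "taf_pct_of_gh2ax": _pct(33.1, 18.8, 43.5),
        "min_feret_mean": MarginalSpec(56.14, 50.14, 63.57, "normal", lower=10),
        "fibre_number": MarginalSpec(99, 80.5, 111, "normal", lower=10),
        "fibrotic_area_pct": _pct(12.85, 10.09, 17.54),
        "cnf_pct": _pct(0.33, 0.0033, 0.83, family="normal"),
    },
    "F": {
        "age_years": MarginalSpec(58.26, 51.59, 63.28, "normal", lower=45, upper=85),
        "grip_kg": MarginalSpec(26.0, 24.21, 32.0, "normal", lower=5),
        "chair_stands_s": MarginalSpec(10.78, 8.24, 12.31, "lognormal"),
        "gait_speed_ms": MarginalSpec(1.11, 0.96, 1.23, "normal", lower=0.2),
        "alm_kg": MarginalSpec(16.31, 14.88, 19.41, "normal", lower=5),
        "almi_kgm2": MarginalSpec(6.31, 5.83, 7.11, "normal", lower=2),
        "bmi_kgm2": MarginalSpec(27.02, 24.88, 28.29, "normal", lower=15),
        "mvpa_min": MarginalSpec(21.9, 16.65, 38.25, "lognormal"),
        "sf36_general": MarginalSpec(70, 64.5, 75, "normal", lower=0, upper=100),
        "pct_p16_nuclei_2plus": _pct(5.67, 1.47, 10.74),
        "pct_p16_fibre_2plus": _pct(0.51, 0.0, 1.6),
        "pct_p16_any_2plus": _pct(8.56, 5.9, 14.9),
        "pct_taf_2plus": _pct(4.0, 0.0, 7.5),
        "pct_taf_3plus": _pct(1.0, 0.0, 1.0),
        "pct_hmgb1_pos": _pct(25.5, 13.3, 30.0),
        "pct_laminb1_pos": _pct(23.5, 20.0, 27.0),
        "taf_pct_of_gh2ax": _pct(39.7, 22.3, 44.2),
        "min_feret_mean": MarginalSpec(45.61, 39.19, 53.13, "normal", lower=10),
        "fibre_number": MarginalSpec(140, 100.5, 212, "lognormal", lower=10),
        "fibrotic_area_pct": _pct(14.26, 10.55, 16.21),
        "cnf_pct": _pct(0.33, 0.0017, 0.83, family="normal"),
    },
}

# reported rank correlations assembled into per-sex target matrices;
# unreported pairs default to 0 and the result is repaired to the nearest
# positive semi-definite correlation matrix
_CORR_PAIRS = {
    "M": [
        ("age_years", "grip_kg", -0.50),
        ("age_years", "alm_kg", -0.50),
        ("age_years", "pct_p16_nuclei_2plus", 0.15),
        ("age_years", "pct_taf_3plus", -0.50),
        ("age_years", "min_feret_mean", -0.27),
        ("age_years", "cnf_pct", -0.27),
        ("age_years", "fibrotic_area_pct", 0.13),
        ("grip_kg", "min_feret_mean", 0.09),
        ("grip_kg", "fibrotic_area_pct", -0.09),
        ("almi_kgm2", "min_feret_mean", 0.36),
        ("almi_kgm2", "fibrotic_area_pct", -0.36),
        ("pct_taf_2plus", "fibrotic_area_pct", 0.45),
        ("pct_p16_nuclei_2plus", "cnf_pct", 0.45),
    ],
    "F": [
        ("age_years", "grip_kg", -0.50),
        ("age_years", "alm_kg", -0.50),
        ("age_years", "pct_p16_nuclei_2plus", -0.58),
        ("age_years", "pct_p16_fibre_2plus", -0.27),
        ("age_years", "pct_hmgb1_pos", -0.44),
        ("age_years", "pct_laminb1_pos", 0.15),
        ("age_years", "pct_taf_3plus", -0.30),
        ("age_years", "min_feret_mean", -0.41),
        ("age_years", "cnf_pct", -0.35),
        ("age_years", "fibrotic_area_pct", 0.36),
        ("grip_kg", "min_feret_mean", 0.24),
        ("grip_kg", "pct_hmgb1_pos", 0.52),
        ("almi_kgm2", "min_feret_mean", 0.36),
        ("almi_kgm2", "fibrotic_area_pct", -0.29),
        ("almi_kgm2", "pct_taf_2plus", 0.55),
        ("gait_speed_ms", "pct_taf_2plus", -0.36),
        ("fibrotic_area_pct", "pct_laminb1_pos", -0.50),
    ],
}


def default_rank_corr() -> dict:
    """Per-sex target Spearman matrices over the default marginal variables.

    Repaired (and, if needed, slightly shrunk toward independence) so the
    matrix remains positive semi-definite after the copula's
    Spearman-to-Pearson conversion."""
    from .cohort import spearman_to_pearson
    out = {}
    for sex, specs in DEFAULT_MARGINALS.items():
        names = list(specs)
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a, b, r in _CORR_PAIRS[sex]:
            mat.loc[a, b] = mat.loc[b, a] = r
        vals = nearest_psd(mat.values)
        for _ in range(20):
            pearson = spearman_to_pearson(vals)
            np.fill_diagonal(pearson, 1.0)
            if np.linalg.eigvalsh(pearson).min() > 1e-8:
                break
            off = ~np.eye(len(vals), dtype=bool)
            vals[off] *= 0.98
        out[sex] = pd.DataFrame(vals, index=names, columns=names)
    return out
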