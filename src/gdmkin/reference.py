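"""Published group summary statistics for the HD wrist-sensor cohort.

Per-feature group means and standard deviations (daily values averaged
over seven monitoring days) reported for a cohort of 16 manifest-HD, 7
prodromal-HD and 16 control participants, together with the effect sizes
the publication prints. These summaries serve as inputs: the package
recomputes pooled-SD Cohen's d (and pooled-t p-values) from them, which
both cross-checks the effect-size implementation against printed values
and regenerates the published effect-size table from first principles.

Velocity rows carry the source's device-specific velocity scale; only
effect sizes are comparable across devices, not raw magnitudes.
"""

from __future__ import annotations

import pandas as pd

from .stats import cohens_d_from_summary, summary_t_p

GROUP_N = {"HD": 16, "pHD": 7, "CTR": 16}

# feature -> (HD mean, HD sd, pHD mean, pHD sd, CTR mean, CTR sd,
#             printed d HD_vs_pHD, printed d HD_vs_CTR, printed d pHD_vs_CTR)
PUBLISHED_SUMMARY = {
    "gdm_count": (1110.6, 427.1, 1046.6, 348.0, 1217.36, 499.9, 0.16, -0.23, 0.37),
    "gdm_count_gt_4_5": (805.92, 303.3, 736.31, 226.5, 796.04, 271.11, 0.25, 0.03, 0.23),
    "gdm_count_gt_7_5": (98.98, 46.99, 102.53, 51.76, 286.9, 304.19, -0.07, -0.86, 0.71),
    "gdm_count_gt_10_5": (35.59, 18.87, 37.46, 22.59, 121.94, 136.17, -0.09, -0.89, 0.73),
    "gdm_count_gt_13_5": (13.77, 7.95, 15.28, 10.56, 56.17, 66.85, -0.17, -0.89, 0.72),
    "gdm_count_gt_16_5": (5.1, 2.99, 5.96, 4.38, 26.86, 34.4, -0.25, -0.89, 0.72),
    "velocity_min": (18.46, 4.53, 20.8, 3.11, 19.21, 4.49, -0.56, -0.17, -0.38),
    "velocity_median": (59.03, 14.41, 69.97, 7.85, 69.77, 9.28, -0.85, -0.89, -0.02),
    "velocity_max": (109.95, 27.45, 132.13, 11.3, 132.09, 14.23, -0.93, -1.01, 0.0),
    "velocity_rms": (67.42, 16.57, 80.51, 8.19, 80.4, 9.69, -0.89, -0.96, -0.01),
    "velocity_entropy": (4.26, 0.01, 4.26, 0.0, 4.26, 0.01, 0.45, 0.18, 0.04),
    "velocity_zc_count": (4.48, 0.68, 4.53, 0.39, 4.47, 0.39, -0.08, 0.03, -0.16),
    "velocity_zc_duration_entropy": (0.94, 0.03, 0.96, 0.01, 0.98, 0.02, -0.98, -1.67, 0.96),
    "velocity_zc_mean_duration": (38.02, 2.58, 39.25, 1.22, 40.38, 2.94, -0.54, -0.85, 0.44),
    "acceleration_min": (0.73, 0.23, 0.92, 0.16, 0.89, 0.18, -0.86, -0.77, -0.15),
    "acceleration_median": (3.46, 1.0, 4.1, 0.53, 3.92, 0.64, -0.71, -0.55, -0.29),
    "acceleration_max": (10.32, 2.98, 11.09, 0.89, 10.64, 1.38, -0.3, -0.14, -0.36),
    "acceleration_rms": (4.37, 1.21, 5.0, 0.51, 4.86, 0.64, -0.6, -0.52, -0.23),
    "acceleration_entropy": (4.23, 0.02, 4.24, 0.0, 4.24, 0.04, -0.77, -0.37, 0.0),
    "acceleration_zc_count": (35.47, 6.46, 32.71, 3.43, 31.07, 3.39, 0.48, 0.85, -0.48),
    "acceleration_zc_duration_entropy": (1.04, 0.02, 1.03, 0.01, 1.02, 0.01, 0.51, 0.99, -0.65),
    "acceleration_zc_mean_duration": (7.15, 1.49, 7.88, 0.85, 9.11, 2.36, -0.55, -0.99, 0.6),
}

_CONTRASTS = (("HD", "pHD"), ("HD", "CTR"), ("pHD", "CTR"))
_COL = {"HD": 0, "pHD": 2, "CTR": 4}


def published_summary_frame() -> pd.DataFrame:
    """The published summaries as a tidy frame (one row per feature)."""
    rows = []
    for feat, vals in PUBLISHED_SUMMARY.items():
        rows.append(
            {
                "feature": feat,
                "hd_mean": vals[0],
                "hd_sd": vals[1],
                "phd_mean": vals[2],
                "phd_sd": vals[3],
                "ctr_mean": vals[4],
                "ctr_sd": vals[5],
                "printed_d_HD_vs_pHD": vals[6],
                "printed_d_HD_vs_CTR": vals[7],
                "printed_d_pHD_vs_CTR": vals[8],
            }
        )
    return pd.DataFrame(rows)


def recompute_effect_sizes() -> pd.DataFrame:
    """Recompute pooled-SD Cohen's d and pooled-t p for every published row.

    Effects are always first-listed minus second-listed group. One row per
    (feature, contrast) with the recomputed values next to the printed d.
    """
    rows = []
    printed_idx = {"HD_vs_pHD": 6, "HD_vs_CTR": 7, "pHD_vs_CTR": 8}
    for feat, vals in PUBLISHED_SUMMARY.items():
        for ga, gb in _CONTRASTS:
            ma, sa = vals[_COL[ga]], vals[_COL[ga] + 1]
            mb, sb = vals[_COL[gb]], vals[_COL[gb] + 1]
            na, nb = GROUP_N[ga], GROUP_N[gb]
            if sa == 0 and sb == 0:
                continue
            d = cohens_d_from_summary(ma, sa, na, mb, sb, nb)
            t, p = summary_t_p(ma, sa, na, mb, sb, nb)
            rows.append(
                {
                    "feature": feat,
                    "contrast": f"{ga}_vs_{gb}",
                    "cohens_d": d,
                    "t_stat": t,
                    "p_value": p,
                    "printed_d": vals[printed_idx[f"{ga}_vs_{gb}"]],
                }
            )
    return pd.DataFrame(rows)
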