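"""Published summary statistics of the three-cohort study behind the LDL window.

The LDL-window rule was developed on three Japanese cohorts measured
2006-2008: healthy working adults (n=1665), patients with type 2 diabetes
(n=201), and patients with angiographically confirmed coronary artery
disease (n=528, of whom 174 also had diabetes).  Subject-level data were
never deposited; what survives are the printed cohort summaries collected
here.  They serve two roles in this package:

1. inputs for the worked-example reconstructions (derived means, group
   shares, quartile enrichment, fold differences recomputed from printed
   counts and means), and
2. calibration targets for the synthetic-cohort simulator presets.

All concentrations are mg/dL, LDL size in nm, values as printed (1 dp).
``(mean, sd)`` tuples throughout.
"""

from __future__ import annotations

COHORTS = ("healthy", "diabetes", "cad")

#: Per-cohort demographics and lipid panel summaries (mean, sd).
COHORT_STATS: dict[str, dict] = {
    "healthy": {
        "n": 1665,
        "male": 954,
        "female": 711,
        "age": (41.0, 12.0),
        "diabetes_n": 0,
        "total_c": (195.5, 33.5),
        "hdl_c": (62.0, 15.3),
        "tg": (95.0, 65.2),
        "ldl_c": (113.9, 31.6),
        "sdldl_c": (25.0, 13.0),
        "lbldl_c": (88.9, 24.9),
        "non_hdl_c": (133.4, 33.7),
        "sdldl_fraction": (21.6, 8.3),
        "apob": (88.3, 23.4),
        "ldl_apob_ratio": (1.29, 0.12),
        "ldl_size": (26.1, 0.51),
    },
    "cad": {
        "n": 528,
        "male": 414,
        "female": 114,
        "age": (67.0, 11.0),
        "diabetes_n": 174,
        "total_c": (197.1, 36.4),
        "hdl_c": (47.2, 13.5),
        "tg": (131.5, 76.1),
        "ldl_c": (119.6, 32.4),
        "sdldl_c": (35.3, 20.5),
        "lbldl_c": (84.3, 29.1),
        "non_hdl_c": (149.9, 35.5),
        "sdldl_fraction": (29.6, 15.0),
        "apob": (98.0, 23.6),
        "ldl_apob_ratio": (1.22, 0.17),
        "ldl_size": (25.6, 0.41),
    },
    "diabetes": {
        "n": 201,
        "male": 125,
        "female": 76,
        "age": (61.0, 12.0),
        "diabetes_n": 201,
        "total_c": (205.3, 49.6),
        "hdl_c": (48.2, 13.3),
        "tg": (142.0, 85.1),
        "ldl_c": (129.2, 40.4),
        "sdldl_c": (40.3, 24.9),
        "lbldl_c": (88.9, 31.7),
        "non_hdl_c": (157.1, 47.4),
        "sdldl_fraction": (30.5, 14.5),
        "apob": (105.3, 31.4),
        "ldl_apob_ratio": (1.23, 0.12),
        "ldl_size": (25.8, 0.50),
    },
}

#: Ordinary least squares of non-HDL-C (y) on apoB (x) in the healthy
#: cohort: Y = 1.404 X + 9.48, R^2 = 0.94.  Inverting at the consensus
#: high non-HDL-C threshold of 170 mg/dL motivated the apoB cutoff.
NONHDL_ON_APOB = {"slope": 1.404, "intercept": 9.48, "r_squared": 0.94, "n": 1665}

#: Pearson correlations of LDL size with its two candidate surrogates in
#: the healthy cohort; TG won on |r| and was adopted as the size axis.
SIZE_SURROGATE_R = {"tg": -0.52, "ldl_apob_ratio": 0.44}

#: sdLDL-C quartile edges of the healthy cohort as printed at 0.1 mg/dL
#: resolution: Q1 <15.4, Q2 15.4-21.9, Q3 22.0-31.7, Q4 >31.7.
QUARTILE_EDGES_PRINTED = (15.4, 21.9, 22.0, 31.7)

#: Healthy-cohort lipid summaries per sdLDL-C quartile (Q1..Q4).
QUARTILE_STATS = {
    "n": (415, 416, 417, 417),
    "sdldl_c_mean": (11.7, 18.7, 26.2, 43.3),
    "ldl_c_mean": (88.1, 104.2, 120.6, 142.6),
    "pattern_b_n": (10, 20, 59, 154),
}

WINDOW_GROUPS = ("normal", "hyper_tg", "hyper_b", "hyper_tg_b")

#: Printed LDL-window tables (apoB x TG axes) for the three cohorts:
#: group sizes, pattern-B counts, sdLDL-C quartile counts (Q1..Q4 against
#: the healthy-cohort scheme) and group mean (sd) sdLDL-C.
WINDOW_TABLES: dict[str, dict] = {
    "healthy": {
        "group_n": {"normal": 1261, "hyper_tg": 100, "hyper_b": 196, "hyper_tg_b": 108},
        "pattern_b_n": {"normal": 81, "hyper_tg": 46, "hyper_b": 55, "hyper_tg_b": 61},
        "quartile_n": {
            "normal": (407, 391, 328, 135),
            "hyper_tg": (6, 14, 27, 53),
            "hyper_b": (1, 8, 56, 131),
            "hyper_tg_b": (1, 3, 6, 98),
        },
        "sdldl_c": {
            "normal": (20.4, 8.9),
            "hyper_tg": (31.2, 10.8),
            "hyper_b": (37.2, 11.1),
            "hyper_tg_b": (49.2, 14.6),
        },
    },
    "diabetes": {
        "group_n": {"normal": 105, "hyper_tg": 19, "hyper_b": 38, "hyper_tg_b": 39},
        "pattern_b_n": {"normal": 18, "hyper_tg": 6, "hyper_b": 11, "hyper_tg_b": 24},
        "quartile_n": {
            "normal": (19, 21, 33, 32),
            "hyper_tg": (1, 1, 6, 11),
            "hyper_b": (1, 3, 7, 27),
            "hyper_tg_b": (0, 0, 3, 36),
        },
        "sdldl_c": {
            "normal": (26.4, 11.8),
            "hyper_tg": (38.2, 17.2),
            "hyper_b": (45.7, 18.9),
            "hyper_tg_b": (73.0, 27.1),
        },
    },
    "cad": {
        "group_n": {"normal": 312, "hyper_tg": 76, "hyper_b": 63, "hyper_tg_b": 77},
        "pattern_b_n": {"normal": 111, "hyper_tg": 59, "hyper_b": 25, "hyper_tg_b": 62},
        "quartile_n": {
            "normal": (61, 75, 81, 95),
            "hyper_tg": (3, 5, 23, 45),
            "hyper_b": (3, 5, 13, 42),
            "hyper_tg_b": (0, 0, 3, 74),
        },
        "sdldl_c": {
            "normal": (26.6, 13.9),
            "hyper_tg": (37.6, 14.6),
            "hyper_b": (44.1, 24.6),
            "hyper_tg_b": (60.8, 19.0),
        },
    },
}
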