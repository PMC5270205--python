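"""Worked-example reconstructions from the published summary tables.

Subject-level data for the original three cohorts were never released,
but many headline numbers are recomputable from what was printed: the
subtraction-defined means (non-HDL-C, lbLDL-C) from the cohort mean
table, group shares and quartile-enrichment percentages from the
printed counts, pattern-B prevalences, and the fold differences between
group mean sdLDL-C levels.  These reconstructions exercise the same
package operations used on subject-level data and double as regression
anchors: if a formula or a bracketing convention drifts, the
reconstructed numbers stop matching the published ones.

All percentages are returned on the printed scale (e.g. 75.7 for
75.7 %), at full precision — callers round for display.
"""

from __future__ import annotations

import numpy as np

from .panels import derive_lbldl, derive_non_hdl
from .reference import COHORT_STATS, QUARTILE_STATS, WINDOW_TABLES


def derived_cohort_means() -> dict[str, float]:
    """Non-HDL-C and lbLDL-C cohort means reconstructed from the printed
    total-C/HDL-C and LDL-C/sdLDL-C means by their defining subtractions."""
    out = {}
    for label, s in COHORT_STATS.items():
        out[f"non_hdl_mean_{label}"] = float(
            derive_non_hdl(s["total_c"][0], s["hdl_c"][0]))
        out[f"lbldl_mean_{label}"] = float(
            derive_lbldl(s["ldl_c"][0], s["sdldl_c"][0]))
    return out


def group_share_pct(cohort: str, group: str) -> float:
    """A window group's share of its cohort, from printed group counts."""
    counts = WINDOW_TABLES[cohort]["group_n"]
    return 100.0 * counts[group] / sum(counts.values())


def quartile_pct(cohort: str, group: str, quartile: str) -> float:
    """Share of a window group falling in an sdLDL-C quartile, from the
    printed quartile count rows."""
    idx = {"Q1": 0, "Q2": 1, "Q3": 2, "Q4": 3}[quartile]
    row = WINDOW_TABLES[cohort]["quartile_n"][group]
    return 100.0 * row[idx] / sum(row)


def pattern_b_group_pct(cohort: str, group: str) -> float:
    """Pattern-B prevalence within a window group, from printed counts."""
    t = WINDOW_TABLES[cohort]
    return 100.0 * t["pattern_b_n"][group] / t["group_n"][group]


def pattern_b_quartile_pct(quartile: str) -> float:
    """Pattern-B prevalence within a healthy-cohort sdLDL-C quartile."""
    idx = {"Q1": 0, "Q2": 1, "Q3": 2, "Q4": 3}[quartile]
    return 100.0 * (QUARTILE_STATS["pattern_b_n"][idx]
                    / QUARTILE_STATS["n"][idx])


def sdldl_fold_vs_normal(cohort: str) -> float:
    """Fold difference of mean sdLDL-C, hyper-TG/-apoB group over the
    normal group, from the printed group means."""
    means = WINDOW_TABLES[cohort]["sdldl_c"]
    return means["hyper_tg_b"][0] / means["normal"][0]


def headline_numbers() -> dict[str, float]:
    """Every printed-table reconstruction reported by the analysis."""
    out = derived_cohort_means()
    out["healthy_normal_share_pct"] = group_share_pct("healthy", "normal")
    out["healthy_hyper_tg_apob_share_pct"] = group_share_pct("healthy", "hyper_tg_b")
    out["diabetes_hyper_tg_apob_share_pct"] = group_share_pct("diabetes", "hyper_tg_b")
    for cohort in ("healthy", "diabetes", "cad"):
        out[f"{cohort}_hyper_tg_apob_q4_pct"] = quartile_pct(cohort, "hyper_tg_b", "Q4")
    out["healthy_hyper_tg_apob_pattern_b_pct"] = pattern_b_group_pct(
        "healthy", "hyper_tg_b")
    out["healthy_q4_pattern_b_pct"] = pattern_b_quartile_pct("Q4")
    out["diabetes_sdldl_fold_vs_normal"] = sdldl_fold_vs_normal("diabetes")
    out["cad_sdldl_fold_vs_normal"] = sdldl_fold_vs_normal("cad")
    return out
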