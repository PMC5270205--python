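"""sdLDL-C quartile stratification and window-group enrichment tables.

Quartile boundaries come from a *reference* cohort (the healthy cohort
in the original analysis) and are applied unchanged to patient cohorts,
so a Q4 subject in any cohort means "sdLDL-C above the healthy 75th
percentile".  Assignment is half-open upward:

    Q1: v < q25,  Q2: q25 ≤ v < q50,  Q3: q50 ≤ v < q75,  Q4: v ≥ q75.

The published reference edges were printed at 0.1 mg/dL resolution with
gaps (Q2 ends 21.9, Q3 starts 22.0; Q4 is ">31.7"), so the effective
boundaries of the printed scheme sit at the half-resolution points
(15.4, 21.95, 31.75): printed edge cases land exactly as the source
tables bracket them (15.4→Q2, 21.9→Q2, 31.7→Q3, 31.8→Q4).

Percentiles use linear interpolation between order statistics (the
numpy default); nearest-rank or other conventions are deliberately not
offered so schemes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .window import GROUP_ORDER

QUARTILE_LABELS = ["Q1", "Q2", "Q3", "Q4"]

#: Default measures summarised per window group in enrichment tables.
DEFAULT_MEASURES = [
    "total_c", "hdl_c", "tg", "ldl_c", "sdldl_c", "lbldl_c",
    "non_hdl_c", "sdldl_fraction", "apob", "ldl_apob_ratio", "ldl_size",
]


@dataclass(frozen=True)
class QuartileScheme:
    """The three sdLDL-C boundaries (mg/dL) defining Q1..Q4."""

    q25: float
    q50: float
    q75: float
    source: str = "computed"  # "computed" | "reference"

    def __post_init__(self):
        if not (self.q25 < self.q50 < self.q75):
            raise ValueError("quartile boundaries must be strictly increasing")

    @property
    def boundaries(self) -> tuple[float, float, float]:
        return (self.q25, self.q50, self.q75)


def reference_scheme() -> QuartileScheme:
    """The published healthy-cohort scheme with effective boundaries at
    the half-resolution points of the printed 0.1 mg/dL edges."""
    return QuartileScheme(15.4, 21.95, 31.75, source="reference")


def compute_quartiles(sdldl_values, source: str = "computed") -> QuartileScheme:
    """Quartile boundaries of a reference cohort's sdLDL-C values.

    Uses the 25th/50th/75th percentiles under linear interpolation
    between closest order statistics.  Requires at least 8 distinct
    values and distinct resulting boundaries.
    """
    values = np.asarray(sdldl_values, dtype=float)
    if values.ndim != 1:
        values = values.ravel()
    if np.unique(values).size < 8:
        raise ValueError("need at least 8 distinct sdLDL-C values to form quartiles")
    q25, q50, q75 = np.percentile(values, [25, 50, 75], method="linear")
    if not (q25 < q50 < q75):
        raise ValueError("degenerate collection: quartile boundaries not distinct")
    return QuartileScheme(float(q25), float(q50), float(q75), source=source)


def assign_quartile(sdldl_c, scheme: QuartileScheme):
    """Map sdLDL-C values to 'Q1'..'Q4' (vectorised; scalars allowed)."""
    values = np.asarray(sdldl_c, dtype=float)
    idx = np.searchsorted(np.asarray(scheme.boundaries), values, side="right")
    if np.ndim(sdldl_c) == 0:
        return QUARTILE_LABELS[int(idx)]
    return np.asarray(QUARTILE_LABELS)[idx]


@dataclass
class WindowTable:
    """Machine form of an LDL-window summary table for one cohort.

    Attributes
    ----------
    group_n : per-group subject counts (index: window groups)
    sex_n : per-group male/female counts
    share_pct : per-group share of the cohort, percent
    measure_stats : MultiIndex (measure, {mean, sd}) by group
    pattern_b : per-group pattern-B n and percent (NaN when no sizes)
    quartile_n / quartile_pct : per-group sdLDL-C quartile counts / %
    empty_groups : groups with zero subjects, flagged for the renderer
    """

    group_n: pd.Series
    sex_n: pd.DataFrame
    share_pct: pd.Series
    measure_stats: pd.DataFrame
    pattern_b: pd.DataFrame
    quartile_n: pd.DataFrame
    quartile_pct: pd.DataFrame
    empty_groups: list[str]

    def check(self) -> "WindowTable":
        """Re-assert the count-conservation invariants."""
        n = int(self.group_n.sum())
        if int(self.quartile_n.to_numpy().sum()) != n:
            raise ValueError("quartile counts do not sum to cohort n")
        for g in self.group_n.index:
            if int(self.quartile_n.loc[g].sum()) != int(self.group_n[g]):
                raise ValueError(f"quartile counts for group {g} do not sum to group n")
        return self


def enrichment_table(assignments: pd.DataFrame,
                     scheme: QuartileScheme,
                     measures: list[str] | None = None) -> WindowTable:
    """Cross-tabulate window groups against sdLDL-C quartiles.

    ``assignments`` is a classified, derived cohort frame (must carry
    ``window_group``, ``sdldl_c``, ``sex``; ``pattern_b`` optional).
    Percentages are carried at full precision; 1-dp rounding is the
    renderer's job.
    """
    for col in ("window_group", "sdldl_c", "sex"):
        if col not in assignments.columns:
            raise ValueError(f"assignments frame lacks required column {col!r}")
    frame = assignments.copy()
    frame["quartile"] = assign_quartile(frame["sdldl_c"].to_numpy(), scheme)

    groups = [g.value for g in GROUP_ORDER]
    group_n = (frame["window_group"].value_counts()
               .reindex(groups, fill_value=0).astype(int))
    total = int(group_n.sum())
    share_pct = 100.0 * group_n / total

    sex_n = (frame.pivot_table(index="window_group", columns="sex",
                               values="subject_id", aggfunc="count", observed=False)
             .reindex(groups).reindex(columns=["M", "F"]).fillna(0).astype(int))

    measures = [m for m in (measures or DEFAULT_MEASURES) if m in frame.columns]
    stats = frame.groupby("window_group", observed=False)[measures].agg(["mean", "std"])
    stats = stats.reindex(groups)
    stats.columns = pd.MultiIndex.from_tuples(
        [(m, {"mean": "mean", "std": "sd"}[s]) for m, s in stats.columns])

    if "pattern_b" in frame.columns and frame["pattern_b"].notna().any():
        pb_n = (frame.groupby("window_group", observed=False)["pattern_b"]
                .apply(lambda s: int(s.fillna(False).sum())).reindex(groups, fill_value=0))
        pb_pct = 100.0 * pb_n / group_n.replace(0, np.nan)
    else:
        pb_n = pd.Series(np.nan, index=groups)
        pb_pct = pd.Series(np.nan, index=groups)
    pattern_b = pd.DataFrame({"n": pb_n, "pct": pb_pct})

    quartile_n = (frame.pivot_table(index="window_group", columns="quartile",
                                    values="subject_id", aggfunc="count", observed=False)
                  .reindex(groups).reindex(columns=QUARTILE_LABELS)
                  .fillna(0).astype(int))
    quartile_pct = 100.0 * quartile_n.div(group_n.replace(0, np.nan), axis=0)
    quartile_pct = quartile_pct.fillna(0.0)

    empty = [g for g in groups if group_n[g] == 0]
    return WindowTable(group_n=group_n, sex_n=sex_n, share_pct=share_pct,
                       measure_stats=stats, pattern_b=pattern_b,
                       quartile_n=quartile_n, quartile_pct=quartile_pct,
                       empty_groups=empty).check()
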