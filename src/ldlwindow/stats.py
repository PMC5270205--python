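"""Statistical procedures behind the LDL-window analysis.

Three pieces: ordinary least squares with inversion (how the apoB
cutoff of 110 mg/dL was read off the non-HDL-C ~ apoB regression at the
consensus non-HDL-C threshold of 170 mg/dL), Pearson correlations
ranking TG against the LDL-C/apoB ratio as surrogates of LDL particle
size, and one-way ANOVA with Bonferroni-corrected pairwise post-hoc
tests for group comparisons.

The post-hoc convention ("Bonferroni-Dunn") is pooled-within-variance
pairwise t tests with p values multiplied by the number of pairs and
capped at 1 — the standard reading of Dunn's procedure.  Software using
a different convention (e.g. Tukey HSD) will differ; the raw p values
are retained alongside the adjusted ones for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit y = slope·x + intercept with R² = squared Pearson r."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x) + self.intercept


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares of y on x (n ≥ 3, non-constant x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), n=int(x.size))


def invert_regression_at(fit: RegressionFit, y_threshold: float) -> float:
    """The x at which the fitted line reaches ``y_threshold``:
    (y − intercept)/slope.  Exact left-inverse of ``fit.predict``."""
    if fit.slope == 0:
        raise ValueError("zero slope; cannot invert regression")
    return (y_threshold - fit.intercept) / fit.slope


def propose_cutoff(inverted: float, granularity: float = 10.0) -> float:
    """Round an inverted threshold down to a clinically usable cutoff
    (nearest lower multiple of ``granularity``, e.g. 113 → 110)."""
    if inverted <= 0:
        raise ValueError("inverted threshold must be positive")
    if granularity not in (5, 10):
        raise ValueError("granularity must be 5 or 10 mg/dL")
    return math.floor(inverted / granularity) * granularity


# ---------------------------------------------------------------------------
# LDL-size surrogate comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateComparison:
    """Pearson correlations of candidate surrogates with LDL size,
    ranked by |r|; ``winner`` is the strongest candidate."""

    correlations: dict
    ranking: list
    winner: str


def compare_size_surrogates(panels: pd.DataFrame, log_tg: bool = False,
                            include_tg_hdl: bool = False) -> SurrogateComparison:
    """Rank TG and the LDL-C/apoB ratio as correlates of LDL size.

    ``log_tg=True`` correlates log TG instead of raw TG; raw TG is the
    default.  ``include_tg_hdl=True`` adds TG/HDL-C as a third
    candidate.  Requires LDL size for all subjects and n ≥ 10.
    """
    if "ldl_size" not in panels.columns or panels["ldl_size"].isna().any():
        raise ValueError("LDL size must be present for every subject")
    if len(panels) < 10:
        raise ValueError("need at least 10 subjects")
    size = panels["ldl_size"].to_numpy(dtype=float)
    tg = panels["tg"].to_numpy(dtype=float)
    if "ldl_apob_ratio" in panels.columns:
        ratio = panels["ldl_apob_ratio"].to_numpy(dtype=float)
    else:
        ratio = panels["ldl_c"].to_numpy(dtype=float) / panels["apob"].to_numpy(dtype=float)
    candidates = {"tg": np.log(tg) if log_tg else tg, "ldl_apob_ratio": ratio}
    if include_tg_hdl:
        candidates["tg_hdl_ratio"] = tg / panels["hdl_c"].to_numpy(dtype=float)
    corr = {name: float(sps.pearsonr(vals, size).statistic)
            for name, vals in candidates.items()}
    ranking = sorted(corr, key=lambda k: abs(corr[k]), reverse=True)
    return SurrogateComparison(correlations=corr, ranking=ranking, winner=ranking[0])


# ---------------------------------------------------------------------------
# one-way ANOVA with Bonferroni pairwise post-hoc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    t_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    anova_p: float
    df_between: int
    df_within: int
    pairwise: list[PairwiseResult] = field(default_factory=list)


def one_way_anova(groups: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across ≥2 groups plus Bonferroni pairwise t tests.

    ``groups`` maps label → 1-d values (each n ≥ 2).  Pairwise t tests
    use the pooled within-group variance (ANOVA mean-square error) on
    its full within degrees of freedom; adjusted p = raw p × number of
    pairs, capped at 1.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")

    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_within = ss_within / df_w
    if ms_within == 0:
        f_stat = 0.0 if ss_between == 0 else float("inf")
        anova_p = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = (ss_between / df_b) / ms_within
        anova_p = float(sps.f.sf(f_stat, df_b, df_w))

    n_pairs = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            diff = a.mean() - b.mean()
            if ms_within == 0:
                p_raw = 1.0 if diff == 0 else 0.0
                t_stat = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
            else:
                se = math.sqrt(ms_within * (1 / a.size + 1 / b.size))
                t_stat = diff / se
                p_raw = float(2 * sps.t.sf(abs(t_stat), df_w))
            p_adj = min(1.0, p_raw * n_pairs)
            pairwise.append(PairwiseResult(
                group_a=labels[i], group_b=labels[j], mean_diff=float(diff),
                t_statistic=float(t_stat), p_raw=p_raw, p_adjusted=p_adj,
                significant=p_adj < alpha))
    return GroupComparison(f_statistic=float(f_stat), anova_p=anova_p,
                           df_between=df_b, df_within=df_w, pairwise=pairwise)
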