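"""Human-readable summary tables and the end-to-end pipeline.

The renderers turn cohort frames and :class:`~ldlwindow.quartiles.WindowTable`
objects into the familiar publication layout: cohorts or window groups
as columns, "mean ± SD" rows at one decimal, pattern B as "n (x.x)",
quartile count rows paired with percentage rows.  The renderer itself
does no arithmetic beyond rounding — every percentage is recomputed
from its count row and half-up rounded at render time, so rendered
tables cannot drift from their counts.

:func:`run_full_pipeline` chains simulate/read → validate → derive →
classify (both marker modes) → quartiles → enrichment → statistics →
rendered reports, logs each stage (name, n, seed), and writes a flat
run manifest (command line, config snapshot, input/output checksums,
seed, package version, timestamp) alongside the artifacts so any output
can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .panels import derive_panels, read_panels, validate_panels, write_panels
from .quartiles import (DEFAULT_MEASURES, QUARTILE_LABELS, WindowTable,
                        compute_quartiles, enrichment_table, reference_scheme)
from .stats import (compare_size_surrogates, fit_linear, invert_regression_at,
                    one_way_anova, propose_cutoff)
from .simulate import cohort_preset, generate_cohort
from .window import GROUP_ORDER, WindowConfig, classify_cohort

logger = logging.getLogger("ldlwindow")

_MEASURE_LABELS = {
    "total_c": "Total cholesterol, mg/dl", "hdl_c": "HDL-C, mg/dl",
    "tg": "TG, mg/dl", "ldl_c": "LDL-C, mg/dl", "sdldl_c": "sdLDL-C, mg/dl",
    "lbldl_c": "lbLDL-C, mg/dl", "non_hdl_c": "Non-HDL-C, mg/dl",
    "sdldl_fraction": "sdLDL-C/LDL-C, %", "apob": "ApoB, mg/dl",
    "ldl_apob_ratio": "LDL-C/apoB", "ldl_size": "LDL size, nm",
}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (publication style: 0.05 → 0.1)."""
    if value != value:  # NaN
        return float("nan")
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(value: float, ndigits: int = 1) -> str:
    if value != value:
        return "-"
    rounded = round_half_up(value, ndigits)
    return f"{rounded:.{ndigits}f}"


def _fmt_mean_sd(mean: float, sd: float) -> str:
    if mean != mean:
        return "-"
    return f"{_fmt(mean)} ± {_fmt(sd)}"


def render_cohort_summary(cohorts: dict[str, pd.DataFrame],
                          measures: list[str] | None = None,
                          mark_significance: bool = True) -> pd.DataFrame:
    """Cohort characteristics table: one column per cohort, "mean ± SD"
    rows per measure, with a ``*`` marker when one-way ANOVA across the
    cohorts is significant at 0.05 (only computed for ≥2 cohorts)."""
    if not cohorts or any(len(f) == 0 for f in cohorts.values()):
        raise ValueError("every cohort must be non-empty")
    measures = measures or [m for m in DEFAULT_MEASURES
                            if all(m in f.columns for f in cohorts.values())]
    rows: dict[str, dict[str, str]] = {}
    for label, frame in cohorts.items():
        col = {"Number": str(len(frame))}
        if "sex" in frame.columns:
            m = int((frame["sex"] == "M").sum())
            col["Sex, M/F"] = f"{m}/{len(frame) - m}"
        for meas in measures:
            vals = frame[meas].dropna()
            col[_MEASURE_LABELS.get(meas, meas)] = _fmt_mean_sd(
                vals.mean(), vals.std())
        rows[label] = col
    table = pd.DataFrame(rows)
    if mark_significance and len(cohorts) >= 2:
        for meas in measures:
            groups = {lab: f[meas].dropna().to_numpy() for lab, f in cohorts.items()}
            if any(v.size < 2 for v in groups.values()):
                continue
            cmp = one_way_anova(groups)
            if cmp.anova_p < 0.05:
                key = _MEASURE_LABELS.get(meas, meas)
                table.loc[key] += "  *"
    return table


def render_window_report(table: WindowTable) -> pd.DataFrame:
    """Render a WindowTable as the group-column layout: counts with
    their recomputed %-rows, pattern B as "n (x.x)", and the sdLDL-C
    quartile count and percentage rows.  Count invariants are
    re-checked before rendering; empty groups render as flagged zero
    columns."""
    table.check()
    groups = [g.value for g in GROUP_ORDER]
    out: dict[str, dict[str, str]] = {}
    total = int(table.group_n.sum())
    for g in groups:
        n = int(table.group_n[g])
        col = {}
        m, f = int(table.sex_n.loc[g, "M"]), int(table.sex_n.loc[g, "F"])
        col["Number (M/F)"] = f"{n} ({m}/{f})" + (" [empty]" if n == 0 else "")
        col["%N/total N"] = _fmt(100.0 * n / total)
        for meas in table.measure_stats.columns.get_level_values(0).unique():
            col[_MEASURE_LABELS.get(meas, meas)] = _fmt_mean_sd(
                table.measure_stats.loc[g, (meas, "mean")],
                table.measure_stats.loc[g, (meas, "sd")])
        pb_n = table.pattern_b.loc[g, "n"]
        if pb_n == pb_n and n > 0:
            col["Pattern B, n (%)"] = f"{int(pb_n)} ({_fmt(100.0 * pb_n / n)})"
        else:
            col["Pattern B, n (%)"] = "-"
        qn = [int(table.quartile_n.loc[g, q]) for q in QUARTILE_LABELS]
        col["sdLDL-C Q1, Q2, Q3, Q4, n"] = ", ".join(str(v) for v in qn)
        if n > 0:
            col["sdLDL-C Q1, Q2, Q3, Q4, %"] = ", ".join(
                _fmt(100.0 * v / n) for v in qn)
        else:
            col["sdLDL-C Q1, Q2, Q3, Q4, %"] = "-"
        out[g] = col
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Inputs for one end-to-end run: either a panel file or a simulate
    directive (cohort presets and sizes), plus cutoffs and scheme."""

    input_path: str | None = None
    simulate_cohorts: dict[str, int] | None = None  # label -> n (None = preset n)
    seed: int = 0
    window: WindowConfig = field(default_factory=WindowConfig)
    scheme: str = "reference"  # "reference" | "computed" (from healthy subjects)
    output_dir: str = "results"


@dataclass
class RunManifest:
    command_line: str
    config: str
    seed: int
    version: str
    timestamp: str
    checksums: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        lines = [f"command_line: {self.command_line}",
                 f"config: {self.config}",
                 f"seed: {self.seed}",
                 f"package_version: {self.version}",
                 f"timestamp: {self.timestamp}"]
        lines += [f"sha256 {name}: {digest}"
                  for name, digest in sorted(self.checksums.items())]
        path.write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Derive → classify (both modes) → quartiles → enrichment → stats →
    reports, writing every artifact plus a manifest under
    ``config.output_dir``.  Returns the in-memory artifacts."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest = RunManifest(
        command_line=" ".join(sys.argv),
        config=repr(dataclasses.asdict(config)),
        seed=config.seed, version=_pkg_version, timestamp=t0)

    # stage: input
    if config.input_path is not None:
        panels = read_panels(config.input_path)
        manifest.checksums["input"] = _sha256(Path(config.input_path))
        logger.info("stage=read n=%d path=%s", len(panels), config.input_path)
    else:
        sim = config.simulate_cohorts or {c: None for c in ("healthy", "diabetes", "cad")}
        frames = []
        for i, (label, n) in enumerate(sim.items()):
            model = cohort_preset(label)
            frames.append(generate_cohort(model, n=n, seed=config.seed + i))
        panels = pd.concat(frames, ignore_index=True)
        logger.info("stage=simulate n=%d seed=%d", len(panels), config.seed)
    validate_panels(panels)

    # stage: derive
    derived = derive_panels(panels)
    logger.info("stage=derive n=%d", len(derived))

    # stage: quartile scheme from the healthy/reference standard
    if config.scheme == "reference":
        scheme = reference_scheme()
    else:
        healthy = derived[derived["cohort"] == "healthy"]
        source = healthy if len(healthy) >= 8 else derived
        scheme = compute_quartiles(source["sdldl_c"].to_numpy())
    logger.info("stage=quartiles scheme=%s boundaries=%s", config.scheme,
                tuple(round(b, 2) for b in scheme.boundaries))

    artifacts: dict = {"panels": panels, "derived": derived, "scheme": scheme,
                       "assignments": {}, "tables": {}, "reports": {}, "stats": {}}

    # stage: classify in both marker modes and tabulate per cohort
    for mode in ("apob", "non_hdl"):
        cfg = config.window.with_mode(mode)
        assigned = classify_cohort(derived, cfg)
        artifacts["assignments"][mode] = assigned
        path = out_dir / f"assignments_{mode}.csv"
        write_panels(assigned, path)
        manifest.checksums[path.name] = _sha256(path)
        for label, sub in assigned.groupby("cohort", observed=False):
            if len(sub) == 0:
                continue
            table = enrichment_table(sub, scheme)
            artifacts["tables"][(mode, label)] = table
            report = render_window_report(table)
            artifacts["reports"][(mode, label)] = report
            path = out_dir / f"window_{mode}_{label}.csv"
            report.to_csv(path)
            manifest.checksums[path.name] = _sha256(path)
        logger.info("stage=classify mode=%s n=%d", mode, len(assigned))

    # stage: cohort summary
    cohorts = {lab: sub for lab, sub in derived.groupby("cohort", observed=False)
               if len(sub) > 0}
    summary = render_cohort_summary(cohorts)
    artifacts["reports"]["cohort_summary"] = summary
    path = out_dir / "cohort_summary.csv"
    summary.to_csv(path)
    manifest.checksums[path.name] = _sha256(path)

    # stage: statistics on the healthy standard (cutoff derivation and
    # LDL-size surrogate ranking need the reference population)
    healthy = derived[derived["cohort"] == "healthy"]
    stats_pop = healthy if len(healthy) >= 10 else derived
    fit = fit_linear(stats_pop["apob"], stats_pop["non_hdl_c"])
    inverted = invert_regression_at(fit, config.window.non_hdl_cutoff)
    artifacts["stats"]["nonhdl_on_apob"] = fit
    artifacts["stats"]["apob_at_nonhdl_cutoff"] = inverted
    artifacts["stats"]["proposed_apob_cutoff"] = propose_cutoff(inverted)
    if stats_pop["ldl_size"].notna().all():
        artifacts["stats"]["size_surrogates"] = compare_size_surrogates(stats_pop)
    group_values = {
        str(g): sub["sdldl_c"].to_numpy() for g, sub in
        artifacts["assignments"]["apob"].groupby("window_group", observed=False)
        if len(sub) >= 2}
    if len(group_values) >= 2:
        artifacts["stats"]["sdldl_by_group"] = one_way_anova(group_values)
    logger.info("stage=stats fit_slope=%.4f inverted=%.2f cutoff=%g",
                fit.slope, inverted, artifacts["stats"]["proposed_apob_cutoff"])

    manifest.write(out_dir / "manifest.txt")
    artifacts["manifest"] = manifest
    return artifacts
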