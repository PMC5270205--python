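"""Rendering (half-up rounding, count/percent consistency), the
end-to-end pipeline, and the command-line surface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ldlwindow import (WindowConfig, classify_cohort, derive_panels,
                       enrichment_table, reference_scheme)
from ldlwindow.cli import main as cli_main
from ldlwindow.reporting import (PipelineConfig, render_cohort_summary,
                                 render_window_report, round_half_up,
                                 run_full_pipeline)

from conftest import make_panels


class TestRounding:
    @pytest.mark.parametrize("value, expected", [
        (75.735, 75.7),   # 1261/1665 as a percentage
        (6.486, 6.5),
        (0.05, 0.1),      # half rounds up, not to even
        (2.25, 2.3),
        (90.74, 90.7),
    ])
    def test_half_up_one_decimal(self, value, expected):
        assert round_half_up(value) == expected

    def test_nan_passthrough(self):
        assert np.isnan(round_half_up(float("nan")))


@pytest.fixture(scope="module")
def window_table():
    frame = derive_panels(make_panels(n=150, seed=13))
    assigned = classify_cohort(frame, WindowConfig())
    return enrichment_table(assigned, reference_scheme())


class TestWindowReport:
    def test_percent_rows_recompute_from_count_rows(self, window_table):
        report = render_window_report(window_table)
        total = int(window_table.group_n.sum())
        for g in window_table.group_n.index:
            n = int(window_table.group_n[g])
            assert report.loc["%N/total N", g] == f"{round_half_up(100 * n / total):.1f}"
            counts = [int(v) for v in
                      report.loc["sdLDL-C Q1, Q2, Q3, Q4, n", g].split(", ")]
            assert sum(counts) == n
            if n:
                pcts = report.loc["sdLDL-C Q1, Q2, Q3, Q4, %", g].split(", ")
                assert pcts == [f"{round_half_up(100 * c / n):.1f}" for c in counts]

    def test_pattern_b_rendered_as_n_percent(self, window_table):
        report = render_window_report(window_table)
        for g in window_table.group_n.index:
            n = window_table.group_n[g]
            cell = report.loc["Pattern B, n (%)", g]
            if n == 0:
                continue
            pb = int(window_table.pattern_b.loc[g, "n"])
            assert cell == f"{pb} ({round_half_up(100 * pb / n):.1f})"

    def test_corrupted_counts_rejected_at_render(self, window_table):
        import copy
        broken = copy.deepcopy(window_table)
        broken.quartile_n.iloc[0, 0] += 1
        with pytest.raises(ValueError):
            render_window_report(broken)


class TestCohortSummary:
    def test_identical_groups_get_no_markers(self):
        frame = derive_panels(make_panels(n=30, seed=17))
        table = render_cohort_summary({"a": frame, "b": frame.copy()})
        assert not table.map(lambda s: "*" in str(s)).any().any()

    def test_healthy_preset_ldl_row(self, healthy_sim_derived):
        table = render_cohort_summary({"healthy": healthy_sim_derived},
                                      mark_significance=False)
        cell = table.loc["LDL-C, mg/dl", "healthy"]
        mean, sd = (float(tok) for tok in cell.split(" ± "))
        assert mean == pytest.approx(113.9, rel=0.02)
        assert sd == pytest.approx(31.6, rel=0.10)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            render_cohort_summary({"a": pd.DataFrame()})


SMALL_STUDY = {"healthy": 400, "diabetes": 120, "cad": 150}


class TestPipeline:
    def test_end_to_end_smoke(self, tmp_path):
        cfg = PipelineConfig(simulate_cohorts=SMALL_STUDY, seed=7,
                             scheme="computed", output_dir=str(tmp_path / "out"))
        artifacts = run_full_pipeline(cfg)
        assert len(artifacts["panels"]) == sum(SMALL_STUDY.values())
        assert set(artifacts["assignments"]) == {"apob", "non_hdl"}
        for mode in ("apob", "non_hdl"):
            for label in SMALL_STUDY:
                assert (mode, label) in artifacts["tables"]
        assert (tmp_path / "out" / "manifest.txt").exists()
        assert (tmp_path / "out" / "window_apob_healthy.csv").exists()
        assert artifacts["stats"]["proposed_apob_cutoff"] % 10 == 0

    def test_rerun_is_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            run_full_pipeline(PipelineConfig(
                simulate_cohorts={"healthy": 250}, seed=3,
                scheme="computed", output_dir=str(tmp_path / sub)))
        files_a = sorted((tmp_path / "a").glob("*"))
        for fa in files_a:
            if fa.name == "manifest.txt":  # carries a timestamp
                continue
            assert fa.read_bytes() == (tmp_path / "b" / fa.name).read_bytes()


class TestCli:
    def test_simulate_classify_roundtrip(self, tmp_path):
        runner = CliRunner()
        panels_path = tmp_path / "panels.csv"
        res = runner.invoke(cli_main, ["simulate", "--cohort", "healthy",
                                       "--n", "200", "--seed", "1",
                                       "--output", str(panels_path)])
        assert res.exit_code == 0, res.output
        assigned_path = tmp_path / "assigned.csv"
        res = runner.invoke(cli_main, ["classify", "--input", str(panels_path),
                                       "--output", str(assigned_path)])
        assert res.exit_code == 0, res.output
        assigned = pd.read_csv(assigned_path)
        assert "window_group" in assigned.columns
        assert len(assigned) == 200

        res = runner.invoke(cli_main, ["window-table", "--input",
                                       str(assigned_path), "--scheme", "reference"])
        assert res.exit_code == 0, res.output
        assert "Pattern B" in res.output

        res = runner.invoke(cli_main, ["derive-cutoff", "--input", str(panels_path)])
        assert res.exit_code == 0, res.output
        assert "proposed cutoff" in res.output

        res = runner.invoke(cli_main, ["group-stats", "--input", str(assigned_path)])
        assert res.exit_code == 0, res.output
        assert "ANOVA" in res.output

    def test_config_file_overrides_cutoffs(self, tmp_path):
        runner = CliRunner()
        panels_path = tmp_path / "panels.csv"
        runner.invoke(cli_main, ["simulate", "--cohort", "healthy", "--n", "100",
                                 "--seed", "2", "--output", str(panels_path)])
        config = tmp_path / "window.cfg"
        config.write_text("apob_cutoff = 90\ntg_cutoff = 100\n")
        out = tmp_path / "assigned.csv"
        res = runner.invoke(cli_main, ["classify", "--input", str(panels_path),
                                       "--config", str(config),
                                       "--output", str(out)])
        assert res.exit_code == 0, res.output
        loose = pd.read_csv(out)["window_group"].value_counts()
        assert loose.get("normal", 0) < 100  # lower cutoffs shrink normal

    def test_unknown_config_key_rejected(self, tmp_path):
        config = tmp_path / "bad.cfg"
        config.write_text("volume = 11\n")
        panels_path = tmp_path / "p.csv"
        CliRunner().invoke(cli_main, ["simulate", "--cohort", "cad", "--n", "20",
                                      "--seed", "0", "--output", str(panels_path)])
        res = CliRunner().invoke(cli_main, ["classify", "--input", str(panels_path),
                                            "--config", str(config),
                                            "--output", str(tmp_path / "o.csv")])
        assert res.exit_code != 0
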