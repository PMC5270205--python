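"""Synthetic-cohort generator: validity, determinism, moment and
dependence recovery, calibration behaviour, degenerate limits."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from ldlwindow import (CohortModel, SdldlCoupling, assign_quartile,
                       classify_cohort, cohort_preset, compute_quartiles,
                       fit_linear, generate_cohort, validate_panels)
from ldlwindow.reference import COHORT_STATS
from ldlwindow.simulate import calibrate_sdldl_coupling, lognormal_params


def _zeroed_correlations(model: CohortModel, **extra) -> CohortModel:
    zero = {name: 0.0 for name in (
        "apob_tg_corr", "hdl_tg_corr", "apob_hdl_corr", "apob_ratio_corr",
        "apob_size_corr", "tg_ratio_corr", "hdl_ratio_corr", "hdl_size_corr",
        "size_tg_corr", "ratio_size_corr")}
    return replace(model, **zero, **extra)


class TestGeneration:
    def test_every_panel_passes_validation(self, healthy_sim):
        validate_panels(healthy_sim)
        assert (healthy_sim["sdldl_c"] < healthy_sim["ldl_c"]).all()
        assert (healthy_sim["ldl_c"]
                <= healthy_sim["total_c"] - healthy_sim["hdl_c"] + 1e-9).all()

    def test_single_panel(self):
        panels = generate_cohort(cohort_preset("cad"), n=1, seed=99)
        assert len(panels) == 1
        validate_panels(panels)

    def test_deterministic_byte_for_byte(self):
        model = cohort_preset("diabetes")
        a = generate_cohort(model, n=500, seed=21).to_csv()
        b = generate_cohort(model, n=500, seed=21).to_csv()
        c = generate_cohort(model, n=500, seed=22).to_csv()
        assert a == b
        assert a != c

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(cohort_preset("healthy"), n=0)

    def test_demographics(self):
        panels = generate_cohort(cohort_preset("diabetes"), n=300, seed=4)
        assert panels["diabetes"].all()
        assert panels["hba1c_jds"].between(4, 15).all()
        healthy = generate_cohort(cohort_preset("healthy"), n=300, seed=4)
        assert not healthy["diabetes"].any()
        assert healthy["hba1c_jds"].isna().all()


class TestModelConstruction:
    def test_non_positive_definite_correlations_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            replace(cohort_preset("healthy"), apob_tg_corr=0.9,
                    apob_hdl_corr=0.9, hdl_tg_corr=-0.9)

    def test_infeasible_size_tg_target_rejected(self):
        # at this TG skew the latent correlation would exceed 1
        with pytest.raises(ValueError):
            replace(cohort_preset("healthy"), tg_sd=300.0)

    def test_lognormal_moment_matching(self):
        mu, sigma = lognormal_params(95.0, 65.2)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(95.0)
        assert (np.exp(sigma**2) - 1) * 95.0**2 == pytest.approx(65.2**2)


class TestNoiselessLimit:
    def test_all_subjects_at_configured_means(self):
        model = _zeroed_correlations(
            cohort_preset("healthy"),
            apob_sd=0.0, tg_sd=0.0, hdl_sd=0.0, size_sd=0.0,
            ldl_apob_ratio_mean=1.29, ldl_apob_ratio_sd=0.0,
            sdldl_coupling=SdldlCoupling(-1.29, 0.0, 0.0, 0.0))
        panels = generate_cohort(model, n=25, seed=1)
        non_hdl = panels["total_c"] - panels["hdl_c"]
        expected = 1.404 * 88.3 + 9.48  # 133.45 at the printed precision
        assert non_hdl.to_numpy() == pytest.approx(expected)
        assert panels["apob"].to_numpy() == pytest.approx(88.3)
        assert panels["tg"].to_numpy() == pytest.approx(95.0)
        assert panels["ldl_c"].to_numpy() == pytest.approx(88.3 * 1.29)


@pytest.fixture(scope="module")
def big_healthy():
    return generate_cohort(cohort_preset("healthy"), n=100_000, seed=1)


class TestRecovery:
    """Published-summary recovery at n = 100000 (healthy preset)."""

    def test_regression_recovery(self, big_healthy):
        fit = fit_linear(big_healthy["apob"],
                         big_healthy["total_c"] - big_healthy["hdl_c"])
        assert fit.slope == pytest.approx(1.404, abs=0.02)
        assert fit.intercept == pytest.approx(9.48, abs=2.0)
        assert fit.r_squared == pytest.approx(0.94, abs=0.02)

    def test_tg_size_correlation_recovery(self, big_healthy):
        r = sps.pearsonr(big_healthy["tg"], big_healthy["ldl_size"]).statistic
        assert r == pytest.approx(-0.52, abs=0.03)

    def test_ratio_size_correlation_recovery(self, big_healthy):
        ratio = big_healthy["ldl_c"] / big_healthy["apob"]
        r = sps.pearsonr(ratio, big_healthy["ldl_size"]).statistic
        assert r == pytest.approx(0.44, abs=0.05)

    @pytest.mark.parametrize("label", ["healthy", "diabetes", "cad"])
    def test_preset_moment_fidelity(self, label):
        """Every published cohort mean within 2 % and SD within 10 %."""
        panels = generate_cohort(cohort_preset(label), n=100_000, seed=2)
        derived = {
            **{c: panels[c] for c in ("total_c", "hdl_c", "tg", "ldl_c",
                                      "sdldl_c", "apob", "ldl_size")},
            "lbldl_c": panels["ldl_c"] - panels["sdldl_c"],
            "non_hdl_c": panels["total_c"] - panels["hdl_c"],
            "sdldl_fraction": 100 * panels["sdldl_c"] / panels["ldl_c"],
            "ldl_apob_ratio": panels["ldl_c"] / panels["apob"],
        }
        for measure, values in derived.items():
            mean, sd = COHORT_STATS[label][measure]
            assert values.mean() == pytest.approx(mean, rel=0.02), measure
            assert values.std() == pytest.approx(sd, rel=0.10), measure


class TestCalibration:
    def test_trivial_band_returns_current_coefficients(self):
        model = cohort_preset("healthy")
        result = calibrate_sdldl_coupling(
            model, target_sdldl_mean=25.0, q4_share_min=0.0,
            n=4000, seed=5)
        cp = result.model.sdldl_coupling
        assert (cp.b_apob, cp.b_tg) == (model.sdldl_coupling.b_apob,
                                        model.sdldl_coupling.b_tg)
        assert result.achieved_sdldl_mean == pytest.approx(25.0, rel=0.05)

    def test_preset_coupling_reaches_enrichment_band(self):
        result = calibrate_sdldl_coupling(
            cohort_preset("healthy"), target_sdldl_mean=25.0,
            q4_share_min=0.85, n=20_000, seed=5)
        assert result.achieved_q4_share >= 0.85
        assert sum(result.quartile_shares) == pytest.approx(1.0)

    def test_independence_limit_has_no_enrichment(self):
        """With the sdLDL coupling and every latent correlation switched
        off (and a degenerate particle-number axis so LDL-C cannot leak
        TG information), quartile shares inside the hyper-TG group match
        the cohort-wide quarter shares."""
        model = _zeroed_correlations(
            cohort_preset("healthy"), apob_sd=0.0,
            sdldl_coupling=SdldlCoupling(-1.29, 0.0, 0.0, 0.3))
        panels = generate_cohort(model, n=20_000, seed=6)
        scheme = compute_quartiles(panels["sdldl_c"].to_numpy())
        assigned = classify_cohort(panels)
        hyper_tg = assigned[assigned["window_group"] == "hyper_tg"]
        labels = assign_quartile(hyper_tg["sdldl_c"].to_numpy(), scheme)
        for lab in ("Q1", "Q2", "Q3", "Q4"):
            assert (labels == lab).mean() == pytest.approx(0.25, abs=0.03)

    def test_infeasible_band_reports_best_found(self):
        model = cohort_preset("healthy")
        with pytest.raises(ValueError, match="best found"):
            calibrate_sdldl_coupling(
                model, target_sdldl_mean=25.0, q4_share_min=1.01,
                candidates=[(0.1, 0.35, 0.34)], n=4000, seed=5)
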