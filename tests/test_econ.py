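"""Cost-effectiveness summarisation, PSA, CEAC and CE plane."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qmcea
from qmcea import ModelConfig, ceac, ce_plane, icer, inhb, inmb, qaly_auc
from qmcea.econ import PSADraws, deterministic_totals, psa_run
from qmcea.params import ConfigurationError


class TestQalyAUC:
    def test_perfect_health(self):
        assert qaly_auc([1, 1, 1, 1]) == pytest.approx(1.5)

    def test_constant_utility(self):
        assert qaly_auc([0.8, 0.8, 0.8, 0.8]) == pytest.approx(1.2)

    def test_trapezoid_on_observed_means(self):
        # independent trapezoid arithmetic: 0.5*(0.7536) + 0.5*means of pairs
        u = (0.7536, 0.7536, 0.7835, 0.8097)
        expected = 0.5 * (0.7536 + (0.7536 + 0.7835) / 2 + (0.7835 + 0.8097) / 2)
        assert expected == pytest.approx(1.159375)
        assert qaly_auc(u) == pytest.approx(expected, abs=1e-12)

    def test_missing_value_rejected(self):
        with pytest.raises(ConfigurationError):
            qaly_auc([0.8, np.nan, 0.8, 0.8])


class TestICER:
    @pytest.mark.parametrize("dc,dq,label,value", [
        (1693.0, -0.010, "dominated", None),
        (-100.0, 0.01, "dominant", None),
        (1000.0, 0.05, "ratio", 20000.0),
        (500.0, 0.0, "+inf", None),
        (-500.0, 0.0, "-inf", None),
        (0.0, 0.0, "ratio", 0.0),
    ])
    def test_labels_and_ratios(self, dc, dq, label, value):
        got_label, got_value = icer(dc, dq)
        assert got_label == label
        if value is None:
            assert got_value is None
        else:
            assert got_value == pytest.approx(value)


class TestNetBenefit:
    def test_zero_increments(self):
        assert inhb(0.0, 0.0, 30000.0) == 0.0

    def test_headline_arithmetic(self):
        assert inhb(1693.0, -0.010, 30000.0) == pytest.approx(-0.0664, abs=5e-5)

    def test_nice_values_row(self):
        assert inhb(1349.68, -0.002, 30000.0) == pytest.approx(-0.0470, abs=5e-5)

    def test_invalid_threshold(self):
        with pytest.raises(ConfigurationError):
            inhb(1.0, 1.0, 0.0)

    @given(st.floats(-1e5, 1e5), st.floats(-1, 1), st.floats(1, 1e5))
    def test_inmb_is_wtp_times_inhb(self, dc, dq, lam):
        assert inmb(dc, dq, lam) == pytest.approx(lam * inhb(dc, dq, lam), rel=1e-9, abs=1e-9)


def _draws(pairs):
    dc = np.array([p[0] for p in pairs], dtype=float)
    dq = np.array([p[1] for p in pairs], dtype=float)
    df = pd.DataFrame({"dc_18m": dc, "dq_18m": dq, "dc_60m": dc, "dq_60m": dq})
    return PSADraws(draws=df, n_sims=len(pairs), seed=0, source="test")


class TestCEAC:
    def test_all_dominant_draws_probability_one(self):
        cc = ceac(_draws([(-10, 0.1), (-5, 0.2)]), [0, 10000, 50000])
        assert (cc["p_cost_effective"] == 1.0).all()

    def test_split_draws_half(self):
        cc = ceac(_draws([(1000, 0.1), (1000, -0.1)]), [30000])
        assert cc["p_cost_effective"].iloc[0] == 0.5

    def test_single_dominated_draw_zero_throughout(self):
        cc = ceac(_draws([(1693, -0.010)]), np.arange(0, 50001, 500))
        assert (cc["p_cost_effective"] == 0.0).all()

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(3)
        pairs = list(zip(rng.normal(500, 800, 400), rng.normal(0, 0.05, 400)))
        grid = np.arange(0, 50001, 500)
        cc = ceac(_draws(pairs), grid)
        for i, lam in enumerate(grid):
            count = sum(1 for dc, dq in pairs
                        if (lam * dq - dc > 0 if lam > 0 else -dc > 0))
            assert cc["p_cost_effective"].iloc[i] == count / len(pairs)


class TestCEPlane:
    def test_all_north_west(self):
        out = ce_plane(_draws([(100, -0.01), (50, -0.02)]))
        assert out["proportions"]["north_west"] == 1.0

    def test_symmetric_cloud_quarters(self):
        rng = np.random.default_rng(4)
        pairs = list(zip(rng.normal(0, 1, 4000), rng.normal(0, 1, 4000)))
        out = ce_plane(_draws(pairs))
        for q, p in out["proportions"].items():
            assert abs(p - 0.25) < 0.03, q

    def test_plot_and_csv_export(self, tmp_path):
        out = ce_plane(_draws([(100, -0.01)] * 5), path_prefix=str(tmp_path / "plane"))
        assert (tmp_path / "plane.csv").exists() and (tmp_path / "plane.png").exists()
        assert out["n"] == 5


class TestPSA:
    def test_degenerate_psa_equals_deterministic(self, small_suite):
        import copy
        suite = copy.deepcopy(small_suite)
        for fit in suite.fits.values():
            fit.cov.loc[:, :] = 0.0
        cfg = ModelConfig()
        det = deterministic_totals(suite, cfg)["totals"]
        draws = psa_run(suite, cfg, n_sims=64, seed=9)
        for h in ("18m", "60m"):
            dc_det = det[h]["FT"]["cost"] - det[h]["TAU"]["cost"]
            dq_det = det[h]["FT"]["qaly"] - det[h]["TAU"]["qaly"]
            np.testing.assert_allclose(draws.draws[f"dc_{h}"], dc_det, atol=1e-8)
            np.testing.assert_allclose(draws.draws[f"dq_{h}"], dq_det, atol=1e-10)

    def test_draws_reproducible_and_prefix_stable(self, small_suite):
        cfg = ModelConfig()
        d1 = psa_run(small_suite, cfg, n_sims=100, seed=5)
        d2 = psa_run(small_suite, cfg, n_sims=100, seed=5)
        pd.testing.assert_frame_equal(d1.draws, d2.draws)
        d3 = psa_run(small_suite, cfg, n_sims=200, seed=5)
        pd.testing.assert_frame_equal(d3.draws.iloc[:100], d1.draws)

    def test_nice_mode_draw_means_match_parametric_means(self, small_suite):
        cfg = ModelConfig(value_source="nice")
        draws = psa_run(small_suite, cfg, n_sims=4000, seed=6)
        assert draws.source == "NICE-parametric"
        # the parametric state values have means 0.93 / 0.68 / ~2134
        from qmcea.econ import _nice_value_draws
        vals = _nice_value_draws(4000, 6)
        for key, mean, sd in (("utility_nonrsh", 0.93, 0.006),
                              ("utility_rsh", 0.68, 0.01),
                              ("excess_cost_rsh", 2133.5, 1070.0)):
            assert abs(vals[key].mean() - mean) <= 3 * sd / np.sqrt(4000) + 1e-3


def test_econ_result_dominance_consistency():
    totals = {"60m": {"FT": {"cost": 100.0, "qaly": 1.0}, "TAU": {"cost": 50.0, "qaly": 1.2}}}
    res = qmcea.econ_result(totals, "60m")
    assert res.icer_label == "dominated"
    assert res.inmb_30k == pytest.approx(30000 * res.inhb_30k)
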