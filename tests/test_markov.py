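"""Quasi-Markov engine: occupancy, payoffs and discounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qmcea import ModelConfig, build_occupancy, cycle_payoffs, discount_and_sum
from qmcea.markov import discount_weights, run_model
from qmcea.params import ARMS


def flat_preds(p_event=0.43, u_sh=0.674, u_nosh=0.792, cost_sh=1000.0,
               cost_nonsh=500.0, cost_any=1000.0, p_nonsh=0.2, p_nh=0.9,
               c_nh_sh=933.35, c_nh_nosh=705.03, n=10):
    """Cycle-constant predictions, identical across arms."""
    mk = lambda v: {a: np.full(n, v) for a in ARMS}
    return {
        "p_sh": mk(p_event), "p_any": mk(p_event),
        "p_nonsh_given_sh": mk(p_nonsh), "p_nonsh_given_nosh": mk(p_nonsh),
        "cost_sh": mk(cost_sh), "cost_any": mk(cost_any), "cost_nonsh": mk(cost_nonsh),
        "p_nonhosp_given_sh": mk(p_nh), "p_nonhosp_given_nosh": mk(p_nh),
        "cost_nonhosp_given_sh": mk(c_nh_sh), "cost_nonhosp_given_nosh": mk(c_nh_nosh),
        "u_sh": mk(u_sh), "u_nosh": mk(u_nosh),
    }


def no_deaths(n=10):
    return {a: np.zeros(n) for a in ARMS}


class TestOccupancy:
    def test_alive_split_without_mortality(self):
        cfg = ModelConfig(include_mortality=False)
        occ = build_occupancy(flat_preds(p_event=0.43), no_deaths(), cfg)
        row = occ[(occ["arm"] == "FT") & (occ["cycle"] == 0)].iloc[0]
        assert row["pi_rsh"] == pytest.approx(0.43)
        assert row["pi_nonrsh"] == pytest.approx(0.57)
        assert row["pi_death"] == 0.0

    def test_zero_event_probability_everyone_non_rsh(self):
        occ = build_occupancy(flat_preds(p_event=0.0), no_deaths(), ModelConfig())
        assert (occ["pi_nonrsh"] == 1.0).all()

    def test_mortality_curve_enters_and_rows_still_sum(self):
        km = {a: np.r_[np.zeros(7), np.full(3, 0.00625)] for a in ARMS}
        occ = build_occupancy(flat_preds(), km, ModelConfig())
        row = occ[(occ["arm"] == "FT") & (occ["cycle"] == 7)].iloc[0]
        assert row["pi_death"] == pytest.approx(0.00625)
        sums = occ["pi_rsh"] + occ["pi_nonrsh"] + occ["pi_death"]
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=10, max_size=10),
           st.lists(st.floats(0, 0.1), min_size=10, max_size=10))
    def test_conservation_and_monotone_mortality(self, p_event, hazards):
        death = np.minimum(np.cumsum(hazards), 1.0)
        preds = flat_preds()
        preds["p_sh"] = {a: np.array(p_event) for a in ARMS}
        occ = build_occupancy(preds, {a: death for a in ARMS}, ModelConfig())
        total = (occ["pi_rsh"] + occ["pi_nonrsh"] + occ["pi_death"]).to_numpy()
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        for arm in ARMS:
            d = occ.loc[occ["arm"] == arm, "pi_death"].to_numpy()
            assert np.all(np.diff(d) >= -1e-12)
        assert ((occ[["pi_rsh", "pi_nonrsh", "pi_death"]] >= -1e-12).all().all()
                and (occ[["pi_rsh", "pi_nonrsh", "pi_death"]] <= 1 + 1e-12).all().all())


class TestCyclePayoffs:
    def test_nice_values_full_rsh_occupancy(self):
        cfg = ModelConfig(value_source="nice", include_mortality=False,
                          intervention_cost={"FT": 0.0, "TAU": 0.0})
        occ = build_occupancy(flat_preds(p_event=1.0), no_deaths(), cfg)
        pay = cycle_payoffs(flat_preds(p_event=1.0), occ, cfg)
        row = pay[(pay["arm"] == "FT") & (pay["cycle"] == 5)].iloc[0]
        assert row["qaly"] == pytest.approx(0.68 * 0.5)
        assert row["total_cost"] == pytest.approx(2134.0)

    def test_all_dead_zero_costs_and_qalys(self):
        km = {a: np.ones(10) for a in ARMS}
        cfg = ModelConfig(intervention_cost={"FT": 0.0, "TAU": 0.0})
        occ = build_occupancy(flat_preds(), km, cfg)
        pay = cycle_payoffs(flat_preds(), occ, cfg)
        assert (pay["total_cost"] == 0).all() and (pay["qaly"] == 0).all()

    def test_state_utility_mixture(self):
        cfg = ModelConfig(include_mortality=False)
        preds = flat_preds(p_event=0.5)
        occ = build_occupancy(preds, no_deaths(), cfg)
        pay = cycle_payoffs(preds, occ, cfg)
        assert pay["utility"].iloc[0] == pytest.approx(0.5 * 0.674 + 0.5 * 0.792)

    def test_post_trial_nonhospital_toggle(self):
        cfg_on = ModelConfig(include_mortality=False)
        cfg_off = ModelConfig(include_mortality=False, include_post_trial_nonhosp=False)
        preds = flat_preds()
        occ = build_occupancy(preds, no_deaths(), cfg_on)
        pay_on = cycle_payoffs(preds, occ, cfg_on)
        pay_off = cycle_payoffs(preds, occ, cfg_off)
        assert (pay_off.loc[pay_off["cycle"] >= 3, "nonhosp_cost"] == 0).all()
        assert (pay_off.loc[pay_off["cycle"] < 3, "nonhosp_cost"]
                == pay_on.loc[pay_on["cycle"] < 3, "nonhosp_cost"]).all()


class TestDiscounting:
    def test_zero_rate_weights_are_one(self):
        cfg = ModelConfig(discount_rate=0.0)
        np.testing.assert_allclose(discount_weights(cfg), 1.0)

    def test_cycle_two_weight_closed_form(self):
        w = discount_weights(ModelConfig())
        assert w[2] == pytest.approx(1.035 ** -1, abs=1e-9)
        assert w[2] == pytest.approx(0.96618, abs=5e-6)

    def test_perfect_health_bound(self):
        cfg = ModelConfig(discount_rate=0.0, include_mortality=False,
                          intervention_cost={"FT": 0.0, "TAU": 0.0})
        preds = flat_preds(u_sh=1.0, u_nosh=1.0)
        res = run_model(preds, no_deaths(), cfg)
        q = res["totals"]["60m"]["TAU"]["qaly"]
        assert q == pytest.approx(5.0)
        assert 3.68 < 5.0  # the reported 60-month QALY total is below this bound

    def test_discounted_below_undiscounted_iff_positive_rate(self):
        preds = flat_preds()
        r0 = run_model(preds, no_deaths(), ModelConfig(discount_rate=0.0))
        r35 = run_model(preds, no_deaths(), ModelConfig(discount_rate=0.035))
        for arm in ARMS:
            assert r35["totals"]["60m"][arm]["qaly"] < r0["totals"]["60m"][arm]["qaly"]
            assert r35["totals"]["60m"][arm]["cost"] < r0["totals"]["60m"][arm]["cost"]

    def test_intervention_cost_lands_in_both_horizons(self):
        cfg = ModelConfig(intervention_cost={"FT": 1800.0, "TAU": 300.0})
        preds = flat_preds()
        res = run_model(preds, no_deaths(), cfg)
        cfg0 = ModelConfig(intervention_cost={"FT": 0.0, "TAU": 0.0})
        res0 = run_model(preds, no_deaths(), cfg0)
        for h in ("18m", "60m"):
            assert res["totals"][h]["FT"]["cost"] - res0["totals"][h]["FT"]["cost"] \
                == pytest.approx(1800.0)


def test_state_definition_switch_is_pure_relabelling():
    """When SH and any-hospitalisation indicators coincide, both definitions
    must produce identical occupancy and totals."""
    preds = flat_preds(p_event=0.3, cost_sh=800.0, cost_any=800.0, p_nonsh=0.0)
    km = no_deaths()
    res_sh = run_model(preds, km, ModelConfig(rsh_definition="sh"))
    res_any = run_model(preds, km, ModelConfig(rsh_definition="any"))
    pd.testing.assert_frame_equal(res_sh["occupancy"], res_any["occupancy"])
    for h in ("18m", "60m"):
        for arm in ARMS:
            assert res_sh["totals"][h][arm]["cost"] == pytest.approx(
                res_any["totals"][h][arm]["cost"])
            assert res_sh["totals"][h][arm]["qaly"] == res_any["totals"][h][arm]["qaly"]
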