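"""GEE fitting, pruning, prediction and the Kaplan-Meier death curve."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import qmcea
from qmcea import ModelSpec
from qmcea.estimation import build_design, fit_gee, km_death, predict_suite
from qmcea.params import ConfigurationError

from conftest import minimal_frame


class TestFitGEE:
    def test_intercept_only_logistic_closed_form(self):
        y = np.r_[np.ones(43), np.zeros(57)]
        df = minimal_frame(100, "sh_hosp", y)
        fit = fit_gee(df, ModelSpec("p", "sh_hosp", "binomial"), n_cycles=1)
        assert fit.params["const"] == pytest.approx(logit(0.43), abs=1e-6)

    def test_intercept_only_gamma_log_constant(self):
        df = minimal_frame(50, "cost", np.full(50, 123.4))
        fit = fit_gee(df, ModelSpec("c", "cost", "gamma"), n_cycles=1)
        assert fit.params["const"] == pytest.approx(np.log(123.4), abs=1e-6)

    def test_gaussian_independence_equals_ols(self, observed_trial):
        spec = ModelSpec("utility", "utility", "gaussian", extra_covariates=("sh_hosp",))
        fit = fit_gee(observed_trial, spec)
        df = observed_trial.merged()
        df = df[df["utility"].notna() & df["sh_hosp"].notna()]
        x = build_design(df, 10, ("sh_hosp",))[fit.columns].to_numpy()
        beta, *_ = np.linalg.lstsq(x, df["utility"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-6)

    def test_sandwich_invariant_to_cluster_order(self, observed_trial):
        spec = ModelSpec("p_sh", "sh_hosp", "binomial")
        fit1 = fit_gee(observed_trial, spec)
        shuffled = observed_trial.copy()
        rng = np.random.default_rng(0)
        shuffled.patients = shuffled.patients.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled.cycles = shuffled.cycles.sample(frac=1, random_state=2).reset_index(drop=True)
        fit2 = fit_gee(shuffled, spec)
        np.testing.assert_allclose(fit1.params[fit1.columns], fit2.params[fit1.columns], atol=1e-8)
        np.testing.assert_allclose(fit1.cov.loc[fit1.columns, fit1.columns],
                                   fit2.cov.loc[fit1.columns, fit1.columns], atol=1e-8)

    def test_separation_raises(self):
        # outcome perfectly determined by a covariate
        df = minimal_frame(40, "sh_hosp", np.r_[np.ones(20), np.zeros(20)])
        df["hospital_referred"] = np.r_[np.ones(20), np.zeros(20)].astype(int)
        with pytest.raises(qmcea.EstimationError, match="separation"):
            fit_gee(df, ModelSpec("p", "sh_hosp", "binomial"), n_cycles=1)

    def test_fitted_score_identity_for_logit(self, observed_trial):
        # with a canonical link the average fitted probability per cycle must
        # equal the observed per-cycle event rate (saturated time structure)
        fit = fit_gee(observed_trial, ModelSpec("p_sh", "sh_hosp", "binomial"))
        df = observed_trial.merged()
        df = df[df["sh_hosp"].notna()]
        x = build_design(df, 10)[fit.columns].to_numpy()
        p = 1 / (1 + np.exp(-(x @ fit.params.to_numpy())))
        for c in (0, 5, 9):
            sel = df["cycle"].to_numpy() == c
            assert p[sel].mean() == pytest.approx(df.loc[sel, "sh_hosp"].mean(), abs=1e-4)


def _two_arm_frame(p_ft, p_tau, n_per_arm=400, n_cycles=3, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for arm, probs, offset in (("FT", p_ft, 0), ("TAU", p_tau, n_per_arm)):
        for c in range(n_cycles):
            y = (rng.random(n_per_arm) < probs[c]).astype(float)
            f = minimal_frame(n_per_arm, "sh_hosp", y, arm=arm, cycle=c)
            f["patient_id"] += offset
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


class TestPruneInteractions:
    def test_identical_arms_lose_all_interactions(self):
        # both arms share the exact same outcome vectors, so every
        # interaction coefficient is 0 and must be pruned
        rng = np.random.default_rng(1)
        frames = []
        for c, p in enumerate([0.4, 0.3, 0.2]):
            y = (rng.random(400) < p).astype(float)
            for arm, offset in (("FT", 0), ("TAU", 400)):
                f = minimal_frame(400, "sh_hosp", y, arm=arm, cycle=c)
                f["patient_id"] += offset
                frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        spec = ModelSpec("p_sh", "sh_hosp", "binomial")
        fit = fit_gee(df, spec, n_cycles=3)
        reduced = qmcea.prune_interactions(fit, df, alpha=0.05, n_cycles=3)
        assert not any(c.startswith("ft_x_") for c in reduced.columns)

    def test_single_cycle_effect_retained(self):
        df = _two_arm_frame([0.15, 0.3, 0.2], [0.55, 0.3, 0.2], seed=2)
        spec = ModelSpec("p_sh", "sh_hosp", "binomial")
        fit = fit_gee(df, spec, n_cycles=3)
        reduced = qmcea.prune_interactions(fit, df, alpha=0.05, n_cycles=3)
        kept = [c for c in reduced.columns if c.startswith("ft_x_")]
        assert kept == ["ft_x_cyc_0"]

    def test_cost_models_keep_interactions(self, small_suite):
        for name in ("cost_sh", "cost_any", "cost_nonsh"):
            fit = small_suite[name]
            assert any(c.startswith("ft_x_") for c in fit.columns)

    def test_state_only_utility_prunes_to_two_means(self, small_suite):
        fit = small_suite["utility"]
        assert not any(c.startswith("ft_x_") or c.startswith("cyc_") for c in fit.columns)
        u_sh = {(a, c): predict_suite(small_suite, a, c)["u_sh"] for a in ("FT", "TAU")
                for c in (0, 5)}
        assert len({round(v, 9) for v in u_sh.values()}) == 1


class TestPredictSuite:
    def test_probabilities_and_costs_in_range(self, small_suite):
        for arm in ("FT", "TAU"):
            for c in (0, 4, 9):
                pred = predict_suite(small_suite, arm, c)
                for k, v in pred.items():
                    if k.startswith("p_"):
                        assert 0.0 < v < 1.0, k
                    elif k.startswith("cost_"):
                        assert v > 0.0, k

    def test_cycle_out_of_horizon_rejected(self, small_suite):
        with pytest.raises(ConfigurationError):
            predict_suite(small_suite, "FT", 10)

    def test_declining_hospitalisation_recovered(self, small_suite):
        p0 = predict_suite(small_suite, "TAU", 0)["p_sh"]
        p9 = predict_suite(small_suite, "TAU", 9)["p_sh"]
        assert p0 > 0.3 and p9 < 0.2 and p0 > p9


class TestKMDeath:
    @staticmethod
    def _patients(n, death_cycles, censor_before=()):
        pats = pd.DataFrame({"patient_id": np.arange(n), "arm": "FT",
                             "death_cycle": np.nan, "censor_cycle": 10})
        for i, c in enumerate(death_cycles):
            pats.loc[i, "death_cycle"] = c
        for j, (idx, cyc) in enumerate(censor_before):
            pats.loc[idx, "censor_cycle"] = cyc
        tau = pd.DataFrame({"patient_id": np.arange(n, n + 50), "arm": "TAU",
                            "death_cycle": np.nan, "censor_cycle": 10})
        return pd.concat([pats, tau], ignore_index=True)

    def test_no_deaths_zero_curve(self):
        curves, _ = km_death(self._patients(50, []))
        assert np.all(curves["FT"] == 0) and np.all(curves["TAU"] == 0)

    def test_single_death_product_limit(self):
        # 398 patients, 52 censored before the cycle-6 death: risk set 346
        censored = [(i, 3) for i in range(300, 352)]
        pats = self._patients(398, [], censor_before=censored)
        pats.loc[0, "death_cycle"] = 6
        curves, _ = km_death(pats)
        assert curves["FT"][7] == pytest.approx(1 / 346, abs=1e-6)

    def test_two_deaths_product_limit(self):
        # risk sets 346 then 297: 1 - (345/346)(296/297) = 0.00625
        censored = [(i, 3) for i in range(300, 352)] + [(i, 7) for i in range(252, 300)]
        pats = self._patients(398, [], censor_before=censored)
        pats.loc[0, "death_cycle"] = 6
        pats.loc[1, "death_cycle"] = 7
        curves, _ = km_death(pats)
        assert curves["FT"][8] == pytest.approx(1 - (345 / 346) * (296 / 297), abs=1e-6)
        assert curves["FT"][8] == pytest.approx(0.00625, abs=5e-5)
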