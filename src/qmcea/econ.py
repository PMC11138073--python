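"""Cost-effectiveness summarisation and probabilistic sensitivity analysis.

Implements the within-trial QALY area-under-the-curve, the incremental
cost-effectiveness ratio with dominance handling, incremental net health and
monetary benefit, Monte-Carlo parameter uncertainty (multivariate-normal
coefficient draws on the link scale, or the NICE Beta/Gamma parametric
distributions), cost-effectiveness acceptability curves and the
cost-effectiveness plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as P
from .params import ConfigurationError, substream
from .estimation import PREDICTION_MAP, ModelSuite, _inv_link, design_row
from .markov import ModelConfig, run_model, totals_vectorised

DOMINATED = "dominated"
DOMINANT = "dominant"


def qaly_auc(utilities, months=(0, 6, 12, 18)) -> float:
    """Trapezoidal QALYs (in years) from utilities at the trial follow-ups."""
    u = np.asarray(utilities, dtype=float)
    if u.shape != (len(months),):
        raise ConfigurationError(f"expected {len(months)} utility values, got {u.shape}")
    if np.isnan(u).any():
        raise ConfigurationError("utilities contain missing values; impute before the AUC")
    return float(np.trapezoid(u, np.asarray(months, dtype=float))) / 12.0


def icer(dc: float, dq: float) -> tuple[str, float | None]:
    """Dominance label or the cost-per-QALY ratio.

    Returns ('dominated', None) when the new strategy costs more and yields
    fewer QALYs, ('dominant', None) when it costs less and yields more, and
    ('ratio', dc/dq) otherwise.  A zero QALY difference with a non-zero cost
    difference yields a signed-infinity ratio label.
    """
    if dc > 0 and dq < 0:
        return DOMINATED, None
    if dc < 0 and dq > 0:
        return DOMINANT, None
    if dq == 0:
        if dc == 0:
            return "ratio", 0.0
        return ("+inf" if dc > 0 else "-inf"), None
    return "ratio", float(dc / dq)


def inhb(dc: float, dq: float, wtp: float) -> float:
    """Incremental net health benefit (QALYs) at willingness-to-pay ``wtp``."""
    if wtp <= 0:
        raise ConfigurationError("willingness-to-pay must be > 0")
    return float(dq - dc / wtp)


def inmb(dc: float, dq: float, wtp: float) -> float:
    """Incremental net monetary benefit (GBP): wtp * dQ - dC = wtp * INHB."""
    if wtp <= 0:
        raise ConfigurationError("willingness-to-pay must be > 0")
    return float(wtp * dq - dc)


@dataclass
class EconResult:
    """Deterministic cost-effectiveness summary for one horizon."""

    horizon: str
    cost: dict                      # arm -> discounted GBP
    qaly: dict                      # arm -> discounted QALYs
    dc: float
    dq: float
    icer_label: str
    icer_value: float | None
    inhb_30k: float
    inmb_30k: float

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon, "cost": self.cost, "qaly": self.qaly,
            "incremental_cost": self.dc, "incremental_qaly": self.dq,
            "icer_label": self.icer_label, "icer_value": self.icer_value,
            "inhb_30k": self.inhb_30k, "inmb_30k": self.inmb_30k,
        }


def econ_result(totals: dict, horizon: str, wtp: float = 30000.0) -> EconResult:
    """Summarise per-arm discounted totals (FT vs TAU) at one horizon."""
    t = totals[horizon]
    dc = float(t["FT"]["cost"] - t["TAU"]["cost"])
    dq = float(t["FT"]["qaly"] - t["TAU"]["qaly"])
    label, value = icer(dc, dq)
    return EconResult(horizon=horizon,
                      cost={a: float(t[a]["cost"]) for a in P.ARMS},
                      qaly={a: float(t[a]["qaly"]) for a in P.ARMS},
                      dc=dc, dq=dq, icer_label=label, icer_value=value,
                      inhb_30k=inhb(dc, dq, wtp), inmb_30k=inmb(dc, dq, wtp))


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSADraws:
    """Monte-Carlo (dC, dQ) pairs per horizon."""

    draws: pd.DataFrame             # columns dc_18m, dq_18m, dc_60m, dq_60m
    n_sims: int
    seed: int
    source: str                     # 'coefficient-MVN' | 'NICE-parametric'

    def pairs(self, horizon: str = "60m") -> tuple[np.ndarray, np.ndarray]:
        return self.draws[f"dc_{horizon}"].to_numpy(), self.draws[f"dq_{horizon}"].to_numpy()


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def _draw_coefficients(fit, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """(n_sims, p) multivariate-normal coefficient draws on the link scale."""
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if vals.min() < -1e-8 * max(1.0, vals.max()):
        warnings.warn(f"model '{fit.spec.name}': covariance not positive semi-definite; "
                      "using nearest-PSD repair", stacklevel=2)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n_sims, len(beta)))
    return beta[None, :] + z @ root.T


def _prediction_draws(suite: ModelSuite, n_sims: int, seed: int) -> dict:
    """Quantity -> {arm: array(n_sims, n_cycles)} from coefficient draws.

    One substream per model, filled row-major, so earlier draws are unchanged
    when n_sims grows.  Drawn utilities are truncated to <= 1.
    """
    betas = {}
    for idx, (name, fit) in enumerate(sorted(suite.fits.items())):
        rng = substream(seed, 5, idx)
        betas[name] = _draw_coefficients(fit, n_sims, rng)
    grid = {}
    for key, (model, sh) in PREDICTION_MAP.items():
        fit = suite[model]
        grid[key] = {}
        for arm in P.ARMS:
            x = np.stack([design_row(fit, arm, c, suite.covariate_means, sh, suite.n_cycles)
                          for c in range(suite.n_cycles)], axis=1)  # (p, n_cycles)
            eta = betas[model] @ x                                   # (n_sims, n_cycles)
            pred = _inv_link(fit.spec.family, eta)
            if model == "utility":
                pred = np.minimum(pred, P.UTILITY_MAX)
            grid[key][arm] = pred
    return grid


def _nice_value_draws(n_sims: int, seed: int) -> dict:
    dists = P.nice_value_distributions()
    rng = substream(seed, 6)
    return {
        "utility_nonrsh": dists["utility_nonrsh"].rvs(n_sims, random_state=rng),
        "utility_rsh": dists["utility_rsh"].rvs(n_sims, random_state=rng),
        "excess_cost_rsh": dists["excess_cost_rsh"].rvs(n_sims, random_state=rng),
    }


def psa_run(suite: ModelSuite, config: ModelConfig, n_sims: int = 10000,
            seed: int = 0) -> PSADraws:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    In empirical mode every regression's coefficient vector is drawn from a
    multivariate normal (pooled mean and robust covariance) on the link
    scale.  In NICE mode the state utilities are Beta draws and the RSH
    excess cost a Gamma draw, while the state-probability model still uses
    coefficient draws.  Each draw re-runs the Markov engine.
    """
    config.validate()
    grid = _prediction_draws(suite, n_sims, seed)
    cfg = config
    if config.value_source == "nice":
        vals = _nice_value_draws(n_sims, seed)
        totals = {}
        # re-run per unique NICE parameter triple via the vectorised engine:
        # overriding the scalar config values with per-draw arrays
        totals = _nice_totals(grid, suite.km, config, vals)
    else:
        totals = totals_vectorised(grid, suite.km, cfg)
    draws = pd.DataFrame({
        f"{q}_{h}": totals[h]["FT"][k] - totals[h]["TAU"][k]
        for h, q, k in (("18m", "dc", "cost"), ("18m", "dq", "qaly"),
                        ("60m", "dc", "cost"), ("60m", "dq", "qaly"))
    })
    draws.columns = ["dc_18m", "dq_18m", "dc_60m", "dq_60m"]
    if not np.all(np.isfinite(draws.to_numpy())):
        raise ConfigurationError("non-finite PSA draws")
    source = "NICE-parametric" if config.value_source == "nice" else "coefficient-MVN"
    return PSADraws(draws=draws, n_sims=n_sims, seed=seed, source=source)


def _nice_totals(grid: dict, km: dict, config: ModelConfig, vals: dict) -> dict:
    """Vectorised NICE-mode totals with per-draw Beta/Gamma state values."""
    from .markov import HORIZONS, discount_weights, occupancy_arrays
    w = discount_weights(config)
    out = {}
    for label, n in HORIZONS.items():
        n = min(n, config.horizon_cycles)
        out[label] = {}
        for arm in P.ARMS:
            death = np.asarray(km[arm], dtype=float)[: config.horizon_cycles]
            if not config.include_mortality:
                death = np.zeros_like(death)
            key = "p_sh" if config.rsh_definition == "sh" else "p_any"
            p_event = np.asarray(grid[key][arm], dtype=float)[..., : config.horizon_cycles]
            occ = occupancy_arrays(p_event, death)
            cost_c = occ["rsh"] * vals["excess_cost_rsh"][:, None]
            util_c = (occ["rsh"] * vals["utility_rsh"][:, None]
                      + occ["nonrsh"] * vals["utility_nonrsh"][:, None])
            interv = np.zeros(config.horizon_cycles)
            interv[: min(2, config.horizon_cycles)] = config.intervention_cost.get(arm, 0.0) / 2.0
            cost = (cost_c[..., :n] * w[:n]).sum(axis=-1) + interv[:n].sum()
            qaly = (util_c[..., :n] * P.CYCLE_YEARS * w[:n]).sum(axis=-1)
            out[label][arm] = {"cost": cost, "qaly": qaly}
    return out


def deterministic_totals(suite: ModelSuite, config: ModelConfig) -> dict:
    """Totals from the point estimates (the zero-covariance limit of the PSA)."""
    from .estimation import predict_grid
    grid = predict_grid(suite)
    return run_model(grid, suite.km, config)


# ---------------------------------------------------------------------------
# CEAC and CE plane
# ---------------------------------------------------------------------------

def ceac(draws: PSADraws, wtp_grid=None, horizon: str = "60m") -> pd.DataFrame:
    """P(FT cost-effective) = fraction of draws with INMB > 0, per threshold."""
    grid = np.asarray(P.WTP_GRID if wtp_grid is None else wtp_grid, dtype=float)
    dc, dq = draws.pairs(horizon)
    if dc.size < 1:
        raise ConfigurationError("CEAC requires at least one draw")
    prob = [(float(np.mean(lam * dq - dc > 0)) if lam > 0 else float(np.mean(-dc > 0)))
            for lam in grid]
    return pd.DataFrame({"wtp": grid, "p_cost_effective": prob})


def ce_plane(draws: PSADraws, horizon: str = "60m", path_prefix=None) -> dict:
    """Quadrant counts/proportions of the (dQ, dC) cloud; optional plot + CSV.

    Quadrants are named compass-style with incremental QALYs on the x axis
    and incremental cost on the y axis (north-west = costlier and less
    effective).
    """
    dc, dq = draws.pairs(horizon)
    if dc.size < 1:
        raise ConfigurationError("CE plane requires at least one draw")
    quads = {
        "north_east": int(np.sum((dq > 0) & (dc > 0))),
        "north_west": int(np.sum((dq <= 0) & (dc > 0))),
        "south_west": int(np.sum((dq <= 0) & (dc <= 0))),
        "south_east": int(np.sum((dq > 0) & (dc <= 0))),
    }
    total = dc.size
    out = {"counts": quads,
           "proportions": {k: v / total for k, v in quads.items()},
           "n": total}
    if path_prefix is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        pd.DataFrame({"dq": dq, "dc": dc}).to_csv(f"{path_prefix}.csv", index=False)
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(dq, dc, s=4, alpha=0.3)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("Incremental QALYs (FT - TAU)")
        ax.set_ylabel("Incremental cost (GBP, FT - TAU)")
        ax.set_title(f"Cost-effectiveness plane ({horizon})")
        fig.tight_layout()
        fig.savefig(f"{path_prefix}.png", dpi=120)
        plt.close(fig)
    return out
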