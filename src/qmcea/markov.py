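"""Quasi-Markov three-state engine: occupancy, cycle payoffs, discounting.

The cohort moves through three mutually exclusive states per 6-month cycle:
repeated self-harm (RSH), no self-harm (non-RSH) and death.  State-occupancy
probabilities are taken directly from the regression predictions (conditional
on being alive) scaled by the Kaplan-Meier survival curve, rather than from a
transition matrix.  Per-cycle expected costs and utilities are composed from
the conditional models, QALYs accrue at 0.5 years per cycle, and totals are
discounted at an annual rate from each cycle's start time.

All occupancy/payoff functions accept numpy arrays with an arbitrary number
of leading dimensions over the cycle axis, so the same code path serves the
deterministic run and the Monte-Carlo probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as P
from .params import ConfigurationError


@dataclass
class ModelConfig:
    """Scenario switches for the decision model."""

    rsh_definition: str = "sh"          # 'sh' (base case) | 'any' (secondary)
    horizon_cycles: int = P.N_CYCLES
    discount_rate: float = P.DISCOUNT_RATE
    include_mortality: bool = True
    include_post_trial_nonhosp: bool = True
    value_source: str = "empirical"     # 'empirical' | 'nice'
    intervention_cost: dict = field(default_factory=lambda: dict(P.INTERVENTION_COST))
    nice_utility_rsh: float = 0.68
    nice_utility_nonrsh: float = 0.93
    nice_excess_cost: float = 2134.0
    discount_from: str = "start"        # 'start' | 'midpoint' | 'end' of cycle
    wtp_grid: np.ndarray = field(default_factory=lambda: P.WTP_GRID.copy())

    def validate(self) -> None:
        if self.rsh_definition not in ("sh", "any"):
            raise ConfigurationError("rsh_definition must be 'sh' or 'any'")
        if self.value_source not in ("empirical", "nice"):
            raise ConfigurationError("value_source must be 'empirical' or 'nice'")
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if self.horizon_cycles < 1:
            raise ConfigurationError("horizon_cycles must be >= 1")
        if self.discount_from not in ("start", "midpoint", "end"):
            raise ConfigurationError("discount_from must be start, midpoint or end")


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------

def occupancy_arrays(p_event: np.ndarray, pi_death: np.ndarray) -> dict:
    """State occupancy from the alive-conditional event probability.

    ``p_event`` has the cycle axis last; ``pi_death`` is the cumulative death
    probability per cycle.  Rows satisfy pi_rsh + pi_nonrsh + pi_death = 1.
    """
    pi_death = np.broadcast_to(pi_death, p_event.shape)
    pi_rsh = p_event * (1.0 - pi_death)
    pi_nonrsh = 1.0 - pi_rsh - pi_death
    if np.any(pi_rsh < -1e-9) or np.any(pi_nonrsh < -1e-9) or np.any(pi_death < -1e-9):
        raise ConfigurationError("state occupancy outside [0, 1] after combination")
    return {"rsh": pi_rsh, "nonrsh": pi_nonrsh, "death": pi_death}


def build_occupancy(preds: dict, km: dict, config: ModelConfig) -> pd.DataFrame:
    """Per arm x cycle occupancy table (rows sum to 1).

    ``preds`` maps quantity -> {arm: array(n_cycles)} as produced by
    ``estimation.predict_grid``; ``km`` maps arm -> cumulative death curve.
    """
    config.validate()
    key = "p_sh" if config.rsh_definition == "sh" else "p_any"
    rows = []
    for arm in P.ARMS:
        p_event = np.asarray(preds[key][arm], dtype=float)[: config.horizon_cycles]
        death = np.asarray(km[arm], dtype=float)[: config.horizon_cycles]
        if not config.include_mortality:
            death = np.zeros_like(death)
        occ = occupancy_arrays(p_event, death)
        for c in range(config.horizon_cycles):
            rows.append({"arm": arm, "cycle": c, "pi_rsh": occ["rsh"][c],
                         "pi_nonrsh": occ["nonrsh"][c], "pi_death": occ["death"][c]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Payoffs
# ---------------------------------------------------------------------------

def _payoff_arrays(preds_arm: dict, occ: dict, config: ModelConfig, arm: str) -> dict:
    """Expected per-cycle cost components and utility for one arm.

    ``preds_arm`` maps quantity -> array with cycle axis last.  Death
    contributes zero cost and zero utility; alive-conditional expectations are
    scaled by survival.
    """
    n = config.horizon_cycles
    alive = 1.0 - occ["death"]
    p_sh = preds_arm["p_sh"][..., :n]

    if config.value_source == "nice":
        hosp = occ["rsh"] * config.nice_excess_cost
        nonhosp = np.zeros_like(hosp)
        utility = occ["rsh"] * config.nice_utility_rsh + occ["nonrsh"] * config.nice_utility_nonrsh
    else:
        if config.rsh_definition == "sh":
            mix_nonsh = (p_sh * preds_arm["p_nonsh_given_sh"][..., :n]
                         + (1 - p_sh) * preds_arm["p_nonsh_given_nosh"][..., :n])
            hosp = (p_sh * preds_arm["cost_sh"][..., :n]
                    + mix_nonsh * preds_arm["cost_nonsh"][..., :n]) * alive
        else:
            hosp = preds_arm["p_any"][..., :n] * preds_arm["cost_any"][..., :n] * alive
        nonhosp = (p_sh * preds_arm["p_nonhosp_given_sh"][..., :n]
                   * preds_arm["cost_nonhosp_given_sh"][..., :n]
                   + (1 - p_sh) * preds_arm["p_nonhosp_given_nosh"][..., :n]
                   * preds_arm["cost_nonhosp_given_nosh"][..., :n]) * alive
        if not config.include_post_trial_nonhosp:
            cyc = np.arange(n)
            nonhosp = np.where(cyc >= 3, 0.0, nonhosp)
        utility = (occ["rsh"] * preds_arm["u_sh"][..., :n]
                   + occ["nonrsh"] * preds_arm["u_nosh"][..., :n])

    interv = np.zeros(n)
    per_cycle = config.intervention_cost.get(arm, 0.0) / 2.0
    interv[: min(2, n)] = per_cycle
    return {"hosp_cost": hosp, "nonhosp_cost": nonhosp,
            "intervention_cost": np.broadcast_to(interv, hosp.shape),
            "utility": utility, "qaly": utility * P.CYCLE_YEARS}


def cycle_payoffs(preds: dict, occupancy: pd.DataFrame, config: ModelConfig) -> pd.DataFrame:
    """Per arm x cycle expected costs (GBP) and utility/QALY contributions."""
    config.validate()
    rows = []
    for arm in P.ARMS:
        occ_a = occupancy[occupancy["arm"] == arm].sort_values("cycle")
        occ = {"rsh": occ_a["pi_rsh"].to_numpy(), "nonrsh": occ_a["pi_nonrsh"].to_numpy(),
               "death": occ_a["pi_death"].to_numpy()}
        preds_arm = {k: np.asarray(v[arm], dtype=float) for k, v in preds.items()}
        pay = _payoff_arrays(preds_arm, occ, config, arm)
        for c in range(config.horizon_cycles):
            rows.append({"arm": arm, "cycle": c,
                         "hosp_cost": pay["hosp_cost"][c],
                         "nonhosp_cost": pay["nonhosp_cost"][c],
                         "intervention_cost": pay["intervention_cost"][c],
                         "total_cost": pay["hosp_cost"][c] + pay["nonhosp_cost"][c]
                         + pay["intervention_cost"][c],
                         "utility": pay["utility"][c], "qaly": pay["qaly"][c]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Discounting
# ---------------------------------------------------------------------------

def discount_weights(config: ModelConfig) -> np.ndarray:
    """(1 + r)^(-t) with t in years at each cycle's start (default), midpoint or end."""
    c = np.arange(config.horizon_cycles, dtype=float)
    offset = {"start": 0.0, "midpoint": 0.25, "end": 0.5}[config.discount_from]
    t = c * P.CYCLE_YEARS + offset
    return (1.0 + config.discount_rate) ** (-t)


HORIZONS = {"18m": 3, "60m": 10}


def discount_and_sum(payoffs: pd.DataFrame, config: ModelConfig) -> dict:
    """Discounted total cost and QALYs per arm at the 18- and 60-month horizons."""
    config.validate()
    w = discount_weights(config)
    out = {}
    for label, n in HORIZONS.items():
        n = min(n, config.horizon_cycles)
        out[label] = {}
        for arm in P.ARMS:
            sub = payoffs[(payoffs["arm"] == arm) & (payoffs["cycle"] < n)].sort_values("cycle")
            wc = w[: len(sub)]
            cost = float(np.sum((sub["hosp_cost"] + sub["nonhosp_cost"]).to_numpy() * wc)
                         + np.sum(sub["intervention_cost"].to_numpy()))
            qaly = float(np.sum(sub["qaly"].to_numpy() * wc))
            out[label][arm] = {"cost": cost, "qaly": qaly}
    return out


def run_model(preds: dict, km: dict, config: ModelConfig) -> dict:
    """Occupancy -> payoffs -> discounted totals, returning all three."""
    occupancy = build_occupancy(preds, km, config)
    payoffs = cycle_payoffs(preds, occupancy, config)
    totals = discount_and_sum(payoffs, config)
    return {"occupancy": occupancy, "payoffs": payoffs, "totals": totals}


def totals_vectorised(pred_arrays: dict, km: dict, config: ModelConfig) -> dict:
    """Discounted totals for stacked prediction draws.

    ``pred_arrays`` maps quantity -> {arm: array(..., n_cycles)}; the leading
    axes (e.g. simulation draws) are preserved.  Intervention costs enter
    cycles 0-1 undiscounted within the cycle, as in the deterministic path.
    """
    config.validate()
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
            p_event = np.asarray(pred_arrays[key][arm], dtype=float)[..., : config.horizon_cycles]
            occ = occupancy_arrays(p_event, death)
            preds_arm = {k: np.asarray(v[arm], dtype=float) for k, v in pred_arrays.items()}
            pay = _payoff_arrays(preds_arm, occ, config, arm)
            cost = ((pay["hosp_cost"][..., :n] + pay["nonhosp_cost"][..., :n]) * w[:n]).sum(axis=-1) \
                + pay["intervention_cost"][..., :n].sum(axis=-1)
            qaly = (pay["qaly"][..., :n] * w[:n]).sum(axis=-1)
            out[label][arm] = {"cost": cost, "qaly": qaly}
    return out
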