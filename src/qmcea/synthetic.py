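"""Synthetic two-arm trial generator.

Produces SHIFT-like datasets with the statistical structure the downstream
analysis assumes: a 1:1 randomised roster with independent baseline
covariates, per-cycle self-harm (SH) hospitalisation indicators following
arm- and cycle-specific logistic probabilities, non-SH hospitalisations
conditional on SH status, gamma-distributed conditional costs, state-dependent
EQ-5D utilities collected only over the trial window (cycles 0-2), rare
absorbing deaths, monotone trial-questionnaire dropout and administrative
censoring of the hospital-record follow-up.

Conventions
-----------
* Long format: one row per patient x cycle; cycle ``c`` covers months
  ``[6c, 6c+6)``.  A patient has rows for every cycle before death and before
  their record-censoring cycle.
* Conditional-cost convention: a cost column is strictly positive only when
  the matching event indicator is 1, and 0 when it is 0.
* Missing values are NaN (written as empty fields in CSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import params as P
from .params import ConfigurationError, substream

COVARIATES = ("female", "age_11_14", "cause_poisoning", "hospital_referred")

#: Columns collected through trial questionnaires (cycles 0-2 only).
TRIAL_COLUMNS = ("utility", "nonhosp_any", "nonhosp_cost")
#: Columns derived from hospital records (all cycles, subject to censoring).
HOSPITAL_COLUMNS = ("sh_hosp", "nonsh_hosp", "sh_hosp_cost", "nonsh_hosp_cost")

TRIAL_WINDOW_CYCLES = 3  # questionnaires at 6, 12, 18 months


@dataclass
class CohortSpec:
    """Size, randomisation and covariate mix of a simulated cohort."""

    n_ft: int = P.DEFAULT_N_FT
    n_tau: int = P.DEFAULT_N_TAU
    n_cycles: int = P.N_CYCLES
    seed: int = 0
    covariate_mix: dict = field(default_factory=lambda: dict(P.COVARIATE_MIX))

    def validate(self) -> None:
        if self.n_ft < 1 or self.n_tau < 1:
            raise ConfigurationError("n_ft and n_tau must each be >= 1")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        for name, p in self.covariate_mix.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"covariate proportion {name}={p} outside [0, 1]")


@dataclass
class TrajectoryParams:
    """Generating parameters for events, costs, utilities and follow-up.

    Defaults reproduce the published cycle-level grids (hospitalisation
    rates, conditional costs, utilities) so that large-sample empirical
    moments of the fixture recover those printed values.
    """

    p_sh: dict = field(default_factory=lambda: {a: P.P_SH_HOSP[a].copy() for a in P.ARMS})
    covariate_logodds: dict = field(default_factory=lambda: {c: 0.0 for c in COVARIATES})
    p_nonsh_given_sh: np.ndarray = field(default_factory=lambda: P.P_NONSH_GIVEN_SH.copy())
    p_nonsh_given_nosh: np.ndarray = field(default_factory=lambda: P.P_NONSH_GIVEN_NOSH.copy())
    sh_cost_mean: dict = field(default_factory=lambda: {a: P.SH_HOSP_COST[a].copy() for a in P.ARMS})
    nonsh_cost_mean: dict = field(default_factory=lambda: {a: P.NONSH_HOSP_COST[a].copy() for a in P.ARMS})
    sh_cost_shape: float = P.SH_COST_SHAPE
    nonsh_cost_shape: float = P.NONSH_COST_SHAPE
    p_nonhosp_given_sh: dict = field(default_factory=lambda: {a: P.P_NONHOSP_GIVEN_SH[a].copy() for a in P.ARMS})
    p_nonhosp_given_nosh: dict = field(default_factory=lambda: {a: P.P_NONHOSP_GIVEN_NOSH[a].copy() for a in P.ARMS})
    nonhosp_cost_mean_sh: float = P.NONHOSP_COST_GIVEN_SH
    nonhosp_cost_mean_nosh: float = P.NONHOSP_COST_GIVEN_NOSH
    nonhosp_cost_shape: float = P.NONHOSP_COST_SHAPE
    utility_mean_sh: float = P.UTILITY_GIVEN_SH
    utility_mean_nosh: float = P.UTILITY_GIVEN_NOSH
    utility_arm_effect: float = 0.0  # additive FT shift, for calibration studies
    utility_sd: float = P.UTILITY_SD
    death_hazard: dict = field(default_factory=lambda: {a: P.DEATH_HAZARD[a].copy() for a in P.ARMS})
    dropout_hazard: np.ndarray = field(default_factory=lambda: P.TRIAL_DROPOUT_HAZARD.copy())
    hosp_record_miss_prob: float = P.HOSP_RECORD_MISS_PROB
    censor_cycle_pmf: np.ndarray = field(default_factory=lambda: P.CENSOR_CYCLE_PMF.copy())

    def validate(self, n_cycles: int = P.N_CYCLES) -> None:
        def _probs(x, name):
            x = np.asarray(x, dtype=float)
            if np.any(x < 0) or np.any(x > 1):
                raise ConfigurationError(f"{name} contains probabilities outside [0, 1]")

        for a in P.ARMS:
            _probs(self.p_sh[a], f"p_sh[{a}]")
            _probs(self.p_nonhosp_given_sh[a], f"p_nonhosp_given_sh[{a}]")
            _probs(self.p_nonhosp_given_nosh[a], f"p_nonhosp_given_nosh[{a}]")
            if np.any(np.asarray(self.death_hazard[a]) < 0):
                raise ConfigurationError(f"death_hazard[{a}] must be >= 0")
            if np.any(np.asarray(self.sh_cost_mean[a]) < 0) or np.any(np.asarray(self.nonsh_cost_mean[a]) < 0):
                raise ConfigurationError("conditional cost means must be >= 0")
        _probs(self.p_nonsh_given_sh, "p_nonsh_given_sh")
        _probs(self.p_nonsh_given_nosh, "p_nonsh_given_nosh")
        _probs(self.dropout_hazard, "dropout_hazard")
        _probs(self.censor_cycle_pmf, "censor_cycle_pmf")
        if not np.isclose(float(np.sum(self.censor_cycle_pmf)), 1.0):
            raise ConfigurationError("censor_cycle_pmf must sum to 1")
        for shp in (self.sh_cost_shape, self.nonsh_cost_shape, self.nonhosp_cost_shape):
            if shp <= 0:
                raise ConfigurationError("gamma shape parameters must be > 0")
        for u in (self.utility_mean_sh, self.utility_mean_nosh):
            if not P.UTILITY_MIN <= u <= P.UTILITY_MAX:
                raise ConfigurationError("utility means must lie in the EQ-5D-3L tariff range")
        if self.utility_sd < 0:
            raise ConfigurationError("utility_sd must be >= 0")


@dataclass
class TrialDataset:
    """A simulated (or imputed) trial: patient roster plus patient x cycle rows."""

    patients: pd.DataFrame
    cycles: pd.DataFrame
    n_cycles: int = P.N_CYCLES

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.patients.copy(), self.cycles.copy(), self.n_cycles)

    def merged(self) -> pd.DataFrame:
        """Cycle rows joined with arm and baseline covariates."""
        cols = ["patient_id", "arm", *COVARIATES]
        return self.cycles.merge(self.patients[cols], on="patient_id", how="left")

    def validate(self) -> None:
        """Check structural invariants (cost convention, truncation)."""
        cyc = self.cycles
        for ind, cost in (("sh_hosp", "sh_hosp_cost"), ("nonsh_hosp", "nonsh_hosp_cost"),
                          ("nonhosp_any", "nonhosp_cost")):
            pos = cyc[cost] > 0
            bad = pos & (cyc[ind] != 1)
            if bad.any():
                raise ConfigurationError(f"{cost} > 0 with {ind} != 1 in {int(bad.sum())} rows")
        lim = self.patients.set_index("patient_id")
        end = np.fmin(lim["death_cycle"].fillna(np.inf), lim["censor_cycle"]).reindex(
            cyc["patient_id"]).to_numpy()
        if np.any(cyc["cycle"].to_numpy() >= end):
            raise ConfigurationError("cycle rows exist at or after death/censoring")

    def to_csv(self, directory: str | Path, prefix: str = "trial") -> dict:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "patients": directory / f"{prefix}_patients.csv",
            "cycles": directory / f"{prefix}_cycles.csv",
        }
        self.patients.to_csv(paths["patients"], index=False)
        self.cycles.to_csv(paths["cycles"], index=False)
        return paths

    @classmethod
    def from_csv(cls, patients_path: str | Path, cycles_path: str | Path,
                 n_cycles: int = P.N_CYCLES) -> "TrialDataset":
        patients = pd.read_csv(patients_path)
        cycles = pd.read_csv(cycles_path)
        return cls(patients, cycles, n_cycles)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Create a randomised patient roster with i.i.d. baseline covariates.

    Returns a patient-level frame with exactly ``n_ft`` FT and ``n_tau`` TAU
    patients; covariates are Bernoulli draws from ``spec.covariate_mix``.
    """
    spec.validate()
    rng = substream(spec.seed, 1)
    n = spec.n_ft + spec.n_tau
    arm = np.array(["FT"] * spec.n_ft + ["TAU"] * spec.n_tau)
    rng.shuffle(arm)
    roster = pd.DataFrame({"patient_id": np.arange(n), "arm": arm})
    for cov in COVARIATES:
        p = spec.covariate_mix.get(cov, 0.0)
        roster[cov] = (rng.random(n) < p).astype(int)
    roster["death_cycle"] = np.nan
    roster["censor_cycle"] = spec.n_cycles
    return roster


def _gamma_draw(rng, shape: float, mean: np.ndarray) -> np.ndarray:
    """Gamma draws with given shape and per-element mean (scale = mean/shape)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    out[pos] = rng.gamma(shape, mean[pos] / shape)
    return out


def _truncnorm_location(target_mean: float, sd: float,
                        lo: float = P.UTILITY_MIN, hi: float = P.UTILITY_MAX) -> float:
    """Location mu such that a normal(mu, sd) truncated to [lo, hi] has the target mean.

    Truncation at the EQ-5D ceiling of 1 would otherwise pull realised means
    below the state-mean parameters; solving for the location keeps
    large-sample empirical moments equal to the configured values.
    """
    from scipy import optimize, stats

    def gap(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    span = 6 * sd + (hi - lo)
    return float(optimize.brentq(gap, target_mean - span, target_mean + span))


def _truncnorm_draw(rng, mean: np.ndarray, sd: float,
                    lo: float = P.UTILITY_MIN, hi: float = P.UTILITY_MAX) -> np.ndarray:
    """Mean-preserving truncated-normal draws on [lo, hi] (resampling)."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return np.clip(mean, lo, hi)
    loc = np.empty_like(mean)
    for m in np.unique(mean):
        loc[mean == m] = _truncnorm_location(float(m), sd, lo, hi)
    x = rng.normal(loc, sd)
    bad = (x < lo) | (x > hi)
    for _ in range(100):
        if not bad.any():
            break
        x[bad] = rng.normal(loc[bad], sd)
        bad = (x < lo) | (x > hi)
    return np.clip(x, lo, hi)


def generate_trajectories(roster: pd.DataFrame, traj: TrajectoryParams,
                          seed: int, n_cycles: int = P.N_CYCLES) -> TrialDataset:
    """Simulate complete (pre-missingness) event, cost and utility histories.

    For every surviving patient x cycle the SH indicator is a logistic draw at
    the arm- and cycle-specific log-odds plus covariate offsets; the non-SH
    hospitalisation indicator is drawn from the SH-conditional probability;
    conditional costs are gamma draws made only when the event occurred;
    non-hospital cost occurrence is Bernoulli then gamma in magnitude; the
    EQ-5D utility (trial cycles only) is a truncated-normal draw around the
    state mean.  Death is an absorbing per-cycle hazard: a patient dying at
    cycle c has no rows from c onward.
    """
    traj.validate(n_cycles)
    rng = substream(seed, 2)
    n = len(roster)
    is_ft = (roster["arm"] == "FT").to_numpy()

    cov_lo = np.zeros(n)
    for cov in COVARIATES:
        cov_lo += traj.covariate_logodds.get(cov, 0.0) * roster[cov].to_numpy()

    def per_arm(d: dict) -> np.ndarray:
        """(n, n_cycles) grid selecting each patient's arm-specific vector."""
        ft = np.resize(np.asarray(d["FT"], dtype=float), n_cycles)
        tau = np.resize(np.asarray(d["TAU"], dtype=float), n_cycles)
        return np.where(is_ft[:, None], ft[None, :], tau[None, :])

    # Death: geometric over per-cycle hazards; death_cycle = first cycle dead.
    hz = per_arm(traj.death_hazard)
    death_draws = rng.random((n, n_cycles)) < hz
    died = death_draws.any(axis=1)
    death_cycle = np.where(died, death_draws.argmax(axis=1), n_cycles)

    # SH hospitalisation: logistic with covariate offsets on the log-odds scale.
    p_sh = np.clip(per_arm(traj.p_sh), 1e-12, 1 - 1e-12)
    logit = np.log(p_sh / (1 - p_sh)) + cov_lo[:, None]
    p = 1.0 / (1.0 + np.exp(-logit))
    p[per_arm(traj.p_sh) == 0.0] = 0.0
    p[per_arm(traj.p_sh) == 1.0] = 1.0
    sh = (rng.random((n, n_cycles)) < p).astype(int)

    p_nonsh = np.where(sh == 1, np.resize(traj.p_nonsh_given_sh, n_cycles)[None, :],
                       np.resize(traj.p_nonsh_given_nosh, n_cycles)[None, :])
    nonsh = (rng.random((n, n_cycles)) < p_nonsh).astype(int)

    sh_cost = _gamma_draw(rng, traj.sh_cost_shape, per_arm(traj.sh_cost_mean)) * sh
    nonsh_cost = _gamma_draw(rng, traj.nonsh_cost_shape, per_arm(traj.nonsh_cost_mean)) * nonsh

    p_nh = np.where(sh == 1, per_arm(traj.p_nonhosp_given_sh), per_arm(traj.p_nonhosp_given_nosh))
    nh_any = (rng.random((n, n_cycles)) < p_nh).astype(int)
    nh_mean = np.where(sh == 1, traj.nonhosp_cost_mean_sh, traj.nonhosp_cost_mean_nosh)
    nh_cost = _gamma_draw(rng, traj.nonhosp_cost_shape, nh_mean) * nh_any

    u_mean = np.where(sh == 1, traj.utility_mean_sh, traj.utility_mean_nosh) \
        + traj.utility_arm_effect * is_ft[:, None]
    utility = _truncnorm_draw(rng, u_mean, traj.utility_sd)

    trial_win = min(TRIAL_WINDOW_CYCLES, n_cycles)
    cyc_idx = np.arange(n_cycles)
    long = pd.DataFrame({
        "patient_id": np.repeat(roster["patient_id"].to_numpy(), n_cycles),
        "cycle": np.tile(cyc_idx, n),
        "sh_hosp": sh.ravel().astype(float),
        "nonsh_hosp": nonsh.ravel().astype(float),
        "sh_hosp_cost": sh_cost.ravel(),
        "nonsh_hosp_cost": nonsh_cost.ravel(),
        "nonhosp_any": nh_any.ravel().astype(float),
        "nonhosp_cost": nh_cost.ravel(),
        "utility": utility.ravel(),
    })
    long.loc[long["cycle"] >= trial_win, ["utility"]] = np.nan

    alive_limit = np.repeat(death_cycle, n_cycles)
    long = long[long["cycle"].to_numpy() < alive_limit].reset_index(drop=True)

    patients = roster.copy()
    patients["death_cycle"] = np.where(died, death_cycle, np.nan)
    patients["censor_cycle"] = n_cycles
    return TrialDataset(patients, long, n_cycles)


def apply_missingness(data: TrialDataset, traj: TrajectoryParams, seed: int) -> TrialDataset:
    """Impose trial dropout, sporadic record gaps and administrative censoring.

    * Trial-collected fields (utility, non-hospital costs) undergo monotone
      dropout over the trial window: once a patient misses a questionnaire,
      all later questionnaires are missing too.
    * Hospital-record fields within the trial window are missing sporadically
      with a small probability.
    * A censoring cycle is drawn per patient from ``censor_cycle_pmf``; all
      rows from that cycle onward are removed (end of record linkage).
    """
    rng = substream(seed, 3)
    out = data.copy()
    patients, cyc = out.patients, out.cycles
    n = len(patients)
    n_cycles = out.n_cycles
    trial_win = min(TRIAL_WINDOW_CYCLES, n_cycles)

    # Trial-collected fields are never observed after the 18-month window.
    cyc.loc[cyc["cycle"] >= trial_win, list(TRIAL_COLUMNS)] = np.nan

    # Monotone questionnaire dropout.
    hz = np.resize(np.asarray(traj.dropout_hazard, dtype=float), trial_win)
    drop = rng.random((n, trial_win)) < hz
    dropped = drop.any(axis=1)
    dropout_cycle = np.where(dropped, drop.argmax(axis=1), n_cycles)
    dc = pd.Series(dropout_cycle, index=patients["patient_id"]).reindex(cyc["patient_id"]).to_numpy()
    lost = cyc["cycle"].to_numpy() >= dc
    cyc.loc[lost, list(TRIAL_COLUMNS)] = np.nan

    # Sporadic hospital-record gaps within the trial window.
    if traj.hosp_record_miss_prob > 0:
        in_win = cyc["cycle"].to_numpy() < trial_win
        gap = in_win & (rng.random(len(cyc)) < traj.hosp_record_miss_prob)
        cyc.loc[gap, list(HOSPITAL_COLUMNS)] = np.nan

    # Administrative censoring of the record linkage.
    pmf = np.resize(np.asarray(traj.censor_cycle_pmf, dtype=float), n_cycles + 1)
    pmf = pmf / pmf.sum()
    censor = rng.choice(n_cycles + 1, size=n, p=pmf)
    patients["censor_cycle"] = np.minimum(censor, patients["censor_cycle"].to_numpy())
    cens = pd.Series(patients["censor_cycle"].to_numpy(),
                     index=patients["patient_id"]).reindex(cyc["patient_id"]).to_numpy()
    keep = cyc["cycle"].to_numpy() < cens
    out.cycles = cyc[keep].reset_index(drop=True)
    return out


def simulate_trial(spec: CohortSpec, traj: TrajectoryParams | None = None,
                   with_missingness: bool = True) -> TrialDataset:
    """Convenience wrapper: roster -> complete trajectories -> missingness."""
    traj = traj or TrajectoryParams()
    roster = generate_cohort(spec)
    data = generate_trajectories(roster, traj, spec.seed, spec.n_cycles)
    if with_missingness:
        data = apply_missingness(data, traj, spec.seed)
    return data


def check_monotone_missingness(data: TrialDataset) -> pd.DataFrame:
    """Return patient/column pairs whose trial-field missingness is not monotone."""
    trial_win = min(TRIAL_WINDOW_CYCLES, data.n_cycles)
    win = data.cycles[data.cycles["cycle"] < trial_win]
    bad = []
    for col in TRIAL_COLUMNS:
        wide = win.pivot(index="patient_id", columns="cycle", values=col)
        miss = wide.isna().to_numpy()
        # once missing, must stay missing over the columns actually present
        nonmono = (np.diff(miss.astype(int), axis=1) < 0).any(axis=1)
        for pid in wide.index[nonmono]:
            bad.append({"patient_id": pid, "column": col})
    return pd.DataFrame(bad, columns=["patient_id", "column"])
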