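"""GEE model suite for state probabilities, conditional costs and utilities.

The analysis fits, per treatment arm and 6-month cycle:

1. P(self-harm hospitalisation)                    — binomial, logit link
2. P(any hospitalisation)                          — binomial, logit link
3. E[cost | self-harm hospitalisation]             — gamma, log link
4. E[cost | any hospitalisation]                   — gamma, log link
5. P(non-SH hospitalisation | SH status)           — binomial, logit link
6. E[cost | non-SH hospitalisation]                — gamma, log link
7. P(non-hospital cost occurs | SH status)         — binomial, logit link
8. E[non-hospital cost | it occurs, SH status]     — gamma, log link
9. EQ-5D utility given SH status                   — gaussian, identity link

Each is a generalized estimating equation clustered on patient with a robust
sandwich covariance; the design is an intercept, baseline covariates, cycle
dummies, and saturated arm x cycle interaction dummies.  Interaction/time
blocks whose Wald tests are non-significant can be pruned to shared
coefficients; hospital-cost models always retain all arm x time interactions.
Death enters through a Kaplan-Meier product-limit estimate rather than a
regression.  When models are fitted within each multiply-imputed dataset the
coefficient vectors and covariances are pooled by Rubin's rules before
prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from . import params as P
from .params import ConfigurationError
from .imputation import rubin_pool
from .synthetic import COVARIATES, TrialDataset


class EstimationError(RuntimeError):
    """Raised on non-convergence or separation of a model fit."""


@dataclass
class ModelSpec:
    """One regression of the suite."""

    name: str
    outcome: str
    family: str                      # 'binomial' | 'gamma' | 'gaussian'
    extra_covariates: tuple = ()     # e.g. ('sh_hosp',) for SH-status models
    subset: str | None = None        # pandas query, e.g. "sh_hosp == 1"
    working_correlation: str = "independence"   # or 'exchangeable'
    keep_all_interactions: bool = False
    prunable: bool = True

    def sm_family(self):
        if self.family == "binomial":
            return sm.families.Binomial()
        if self.family == "gamma":
            return sm.families.Gamma(link=sm.families.links.Log())
        if self.family == "gaussian":
            return sm.families.Gaussian()
        raise ConfigurationError(f"unknown family '{self.family}'")

    def sm_cov_struct(self):
        if self.working_correlation == "independence":
            return sm.cov_struct.Independence()
        if self.working_correlation == "exchangeable":
            return sm.cov_struct.Exchangeable()
        raise ConfigurationError(f"unknown working correlation '{self.working_correlation}'")


@dataclass
class GEEFit:
    """A fitted (or Rubin-pooled) estimating-equation model."""

    spec: ModelSpec
    params: pd.Series               # coefficients on the link scale
    cov: pd.DataFrame               # robust sandwich covariance (pooled if m > 1)
    n_clusters: int
    converged: bool
    max_cycle: int                  # highest cycle with data; later cycles carry forward
    m: int = 1                      # number of imputations pooled into this fit
    df: pd.Series | None = None     # per-coefficient Rubin degrees of freedom

    @property
    def columns(self) -> list:
        return list(self.params.index)

    def wald_p(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        z = self.params.to_numpy() / np.where(se > 0, se, np.inf)
        from scipy import stats
        if self.df is not None:
            dfv = self.df.to_numpy()
            p = 2 * stats.t.sf(np.abs(z), np.where(np.isfinite(dfv), dfv, 1e9))
        else:
            p = 2 * stats.norm.sf(np.abs(z))
        return pd.Series(p, index=self.params.index)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, n_cycles: int, extra: tuple = ()) -> pd.DataFrame:
    """Intercept + covariates + cycle dummies + saturated arm x cycle dummies.

    Cycle 0 is the reference level for the cycle main effects; the FT arm
    effect is captured by one interaction dummy per cycle (no separate main
    effect), which keeps the saturated parameterisation full rank.
    """
    x = pd.DataFrame(index=df.index)
    x["const"] = 1.0
    for cov in COVARIATES:
        x[cov] = df[cov].astype(float)
    for col in extra:
        x[col] = df[col].astype(float)
    cyc = df["cycle"].to_numpy()
    ft = (df["arm"] == "FT").to_numpy().astype(float)
    for c in range(1, n_cycles):
        x[f"cyc_{c}"] = (cyc == c).astype(float)
    for c in range(n_cycles):
        x[f"ft_x_cyc_{c}"] = ft * (cyc == c)
    return x


def _prune_rank(x: pd.DataFrame) -> pd.DataFrame:
    """Drop all-zero/constant-duplicate columns so the design is full rank."""
    arr = x.to_numpy()
    keep: list[int] = []
    for j in range(arr.shape[1]):
        trial = arr[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return x.iloc[:, keep]


INTERACTION_PREFIX = "ft_x_cyc_"
CYCLE_PREFIX = "cyc_"


def _prunable_columns(fit_columns, spec: ModelSpec) -> list:
    if not spec.prunable or spec.keep_all_interactions:
        return []
    return [c for c in fit_columns
            if c.startswith(INTERACTION_PREFIX) or c.startswith(CYCLE_PREFIX)]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _prepare(data: TrialDataset | pd.DataFrame) -> pd.DataFrame:
    df = data.merged() if isinstance(data, TrialDataset) else data.copy()
    if "any_hosp" not in df.columns and {"sh_hosp", "nonsh_hosp"} <= set(df.columns):
        df["any_hosp"] = np.fmax(df["sh_hosp"], df["nonsh_hosp"])
    if "any_hosp_cost" not in df.columns and {"sh_hosp_cost", "nonsh_hosp_cost"} <= set(df.columns):
        df["any_hosp_cost"] = df["sh_hosp_cost"] + df["nonsh_hosp_cost"]
    return df


def fit_gee(data: TrialDataset | pd.DataFrame, spec: ModelSpec,
            n_cycles: int = P.N_CYCLES, columns: list | None = None) -> GEEFit:
    """Fit one GEE of the suite on long-format data.

    With independence working correlation and a gaussian identity family the
    point estimates coincide with ordinary least squares on the stacked data;
    the clustered sandwich covariance is reported in all cases.
    """
    df = _prepare(data)
    if spec.subset:
        df = df.query(spec.subset)
    x = build_design(df, n_cycles, spec.extra_covariates)
    y = df[spec.outcome].to_numpy(dtype=float)
    ok = ~np.isnan(y) & ~x.isna().any(axis=1).to_numpy()
    df, x, y = df[ok], x[ok], y[ok]
    if df["patient_id"].nunique() < 2:
        raise EstimationError(f"model '{spec.name}': fewer than 2 clusters")
    x = x[columns] if columns is not None else _prune_rank(x)
    max_cycle = int(df["cycle"].max())

    groups = df["patient_id"].to_numpy()
    for _ in range(3):
        model = sm.GEE(y, x, groups=groups,
                       family=spec.sm_family(), cov_struct=spec.sm_cov_struct())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, ctol=1e-8)
        params = pd.Series(res.params, index=x.columns)
        cov = pd.DataFrame(res.cov_params(), index=x.columns, columns=x.columns)
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov.to_numpy())):
            raise EstimationError(f"model '{spec.name}': non-finite estimates (no convergence)")
        if spec.family != "binomial" or np.abs(params).max() <= 15:
            break
        # diverging logistic coefficients: an empty outcome cell behind a
        # time/interaction dummy is dropped (the cell borrows the reference
        # coefficient); divergence on a substantive covariate is separation
        blown = [c for c in x.columns if abs(params[c]) > 15]
        droppable = [c for c in blown
                     if c.startswith(CYCLE_PREFIX) or c.startswith(INTERACTION_PREFIX)]
        if droppable != blown:
            raise EstimationError(f"model '{spec.name}': apparent separation in logistic fit "
                                  f"(|coef| up to {np.abs(params).max():.1f})")
        warnings.warn(f"model '{spec.name}': dropping sparse-cell dummies {droppable}",
                      stacklevel=2)
        x = x[[c for c in x.columns if c not in droppable]]
    else:
        raise EstimationError(f"model '{spec.name}': apparent separation in logistic fit "
                              f"(|coef| up to {np.abs(params).max():.1f})")
    return GEEFit(spec=spec, params=params, cov=cov,
                  n_clusters=int(df["patient_id"].nunique()), converged=True,
                  max_cycle=max_cycle)


def pool_fits(fits: list[GEEFit]) -> GEEFit:
    """Rubin-pool coefficient vectors and covariances across imputations."""
    if len(fits) == 1:
        return fits[0]
    cols = fits[0].columns
    for f in fits[1:]:
        cols = [c for c in cols if c in f.columns]
    q = np.stack([f.params[cols].to_numpy() for f in fits])
    u = np.stack([f.cov.loc[cols, cols].to_numpy() for f in fits])
    m = len(fits)
    point = q.mean(axis=0)
    within = u.mean(axis=0)
    dev = q - point
    between = dev.T @ dev / (m - 1)
    total = within + (1.0 + 1.0 / m) * between
    dfs = []
    for j in range(len(cols)):
        pe = rubin_pool(q[:, j], u[:, j, j])
        dfs.append(pe.df)
    return GEEFit(spec=fits[0].spec,
                  params=pd.Series(point, index=cols),
                  cov=pd.DataFrame(total, index=cols, columns=cols),
                  n_clusters=fits[0].n_clusters, converged=all(f.converged for f in fits),
                  max_cycle=max(f.max_cycle for f in fits), m=m,
                  df=pd.Series(dfs, index=cols))


def prune_interactions(fit: GEEFit, data, alpha: float = 0.05,
                       n_cycles: int = P.N_CYCLES) -> GEEFit:
    """Backward-eliminate non-significant cycle and arm x cycle dummies.

    Wald tests on the robust covariance; terms with p >= alpha are merged
    into the shared (reference) coefficient and the reduced model refitted.
    Hospital-cost models are exempt (all interactions retained).
    """
    datasets = data if isinstance(data, list) else [data]
    current = fit
    for _ in range(4):  # batch elimination; a few passes suffice in practice
        cand = _prunable_columns(current.columns, current.spec)
        if not cand:
            return current
        p = current.wald_p()[cand]
        drop = set(p.index[p >= alpha])
        if not drop:
            return current
        cols = [c for c in current.columns if c not in drop]
        fits = [fit_gee(d, current.spec, n_cycles, columns=cols) for d in datasets]
        current = pool_fits(fits) if len(fits) > 1 else fits[0]
    return current


# ---------------------------------------------------------------------------
# The model suite
# ---------------------------------------------------------------------------

def default_model_specs(working_correlation: str = "independence") -> list[ModelSpec]:
    wc = working_correlation
    return [
        ModelSpec("p_sh", "sh_hosp", "binomial", working_correlation=wc),
        ModelSpec("p_any", "any_hosp", "binomial", working_correlation=wc),
        ModelSpec("cost_sh", "sh_hosp_cost", "gamma", subset="sh_hosp == 1",
                  working_correlation=wc, keep_all_interactions=True),
        ModelSpec("cost_any", "any_hosp_cost", "gamma", subset="any_hosp == 1",
                  working_correlation=wc, keep_all_interactions=True),
        ModelSpec("p_nonsh", "nonsh_hosp", "binomial", extra_covariates=("sh_hosp",),
                  working_correlation=wc),
        ModelSpec("cost_nonsh", "nonsh_hosp_cost", "gamma", subset="nonsh_hosp == 1",
                  extra_covariates=("sh_hosp",), working_correlation=wc,
                  keep_all_interactions=True),
        ModelSpec("p_nonhosp", "nonhosp_any", "binomial", extra_covariates=("sh_hosp",),
                  working_correlation=wc),
        ModelSpec("cost_nonhosp", "nonhosp_cost", "gamma", subset="nonhosp_any == 1",
                  extra_covariates=("sh_hosp",), working_correlation=wc),
        ModelSpec("utility", "utility", "gaussian", extra_covariates=("sh_hosp",),
                  working_correlation=wc),
    ]


@dataclass
class ModelSuite:
    """All fitted models plus the mortality curve and covariate profile."""

    fits: dict
    covariate_means: pd.Series
    km: dict                       # arm -> cumulative death probability per cycle
    logrank_p: float
    n_cycles: int = P.N_CYCLES

    def __getitem__(self, name: str) -> GEEFit:
        return self.fits[name]


def km_death(patients: pd.DataFrame, n_cycles: int = P.N_CYCLES) -> tuple[dict, float]:
    """Kaplan-Meier cumulative death probability at each cycle start, by arm.

    A death during cycle c is placed at time c + 0.5 on the cycle axis, so it
    contributes to the occupancy of cycles c+1 onward.  Also returns the
    log-rank p-value between arms.
    """
    curves = {}
    groups = {}
    for arm in P.ARMS:
        sub = patients[patients["arm"] == arm]
        event = sub["death_cycle"].notna().to_numpy()
        dur = np.where(event, sub["death_cycle"].to_numpy(dtype=float) + 0.5,
                       sub["censor_cycle"].to_numpy(dtype=float))
        groups[arm] = (dur, event)
        kmf = KaplanMeierFitter()
        kmf.fit(dur, event_observed=event)
        surv = kmf.survival_function_at_times(np.arange(n_cycles)).to_numpy()
        curves[arm] = 1.0 - surv
    if all(len(groups[a][0]) > 0 for a in P.ARMS):
        lr = logrank_test(groups["FT"][0], groups["TAU"][0],
                          event_observed_A=groups["FT"][1], event_observed_B=groups["TAU"][1])
        p = float(lr.p_value)
    else:
        p = float("nan")
    return curves, p


def fit_suite(data, n_cycles: int = P.N_CYCLES, alpha: float | None = 0.05,
              working_correlation: str = "independence",
              specs: list[ModelSpec] | None = None) -> ModelSuite:
    """Fit the full model suite, pooling over multiply-imputed datasets.

    ``data`` may be a single TrialDataset or a list of imputed ones.  Each
    model is fitted within every dataset and Rubin-pooled; pruning (if
    ``alpha`` is not None) is decided on pooled Wald tests and applied by
    refitting the reduced design in every dataset.
    """
    datasets = data if isinstance(data, list) else [data]
    specs = specs or default_model_specs(working_correlation)
    fits = {}
    for spec in specs:
        per = [fit_gee(d, spec, n_cycles) for d in datasets]
        pooled = pool_fits(per) if len(per) > 1 else per[0]
        if alpha is not None:
            pooled = prune_interactions(pooled, datasets, alpha, n_cycles)
        fits[spec.name] = pooled
    first = datasets[0]
    cov_means = first.patients[list(COVARIATES)].mean().astype(float)
    km, logrank_p = km_death(first.patients, n_cycles)
    return ModelSuite(fits=fits, covariate_means=cov_means, km=km,
                      logrank_p=logrank_p, n_cycles=n_cycles)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _inv_link(family: str, eta):
    if family == "binomial":
        return 1.0 / (1.0 + np.exp(-eta))
    if family == "gamma":
        return np.exp(eta)
    return eta


def design_row(fit: GEEFit, arm: str, cycle: int, covariate_means: pd.Series,
               sh_status: float | None = None, n_cycles: int = P.N_CYCLES) -> np.ndarray:
    """The "average participant" design row for one arm x cycle cell.

    Covariates sit at their sample means; cycles beyond the model's observed
    window (trial-collected outcomes) carry the last observed cycle's
    coefficients forward.
    """
    if not 0 <= cycle < n_cycles:
        raise ConfigurationError(f"cycle {cycle} outside the modelled horizon 0..{n_cycles - 1}")
    eff = min(cycle, fit.max_cycle)
    row = np.zeros(len(fit.columns))
    for j, col in enumerate(fit.columns):
        if col == "const":
            row[j] = 1.0
        elif col in covariate_means.index:
            row[j] = covariate_means[col]
        elif col == "sh_hosp":
            row[j] = 0.0 if sh_status is None else float(sh_status)
        elif col.startswith(INTERACTION_PREFIX):
            row[j] = float(arm == "FT" and int(col[len(INTERACTION_PREFIX):]) == eff)
        elif col.startswith(CYCLE_PREFIX):
            row[j] = float(int(col[len(CYCLE_PREFIX):]) == eff)
    return row


def _predict(fit: GEEFit, arm: str, cycle: int, means: pd.Series,
             sh_status: float | None = None, n_cycles: int = P.N_CYCLES) -> float:
    x = design_row(fit, arm, cycle, means, sh_status, n_cycles)
    return float(_inv_link(fit.spec.family, x @ fit.params.to_numpy()))


#: Quantities emitted per arm x cycle, with the model and SH status they use.
PREDICTION_MAP = {
    "p_sh": ("p_sh", None),
    "p_any": ("p_any", None),
    "p_nonsh_given_sh": ("p_nonsh", 1.0),
    "p_nonsh_given_nosh": ("p_nonsh", 0.0),
    "cost_sh": ("cost_sh", None),
    "cost_any": ("cost_any", None),
    "cost_nonsh": ("cost_nonsh", 0.0),
    "p_nonhosp_given_sh": ("p_nonhosp", 1.0),
    "p_nonhosp_given_nosh": ("p_nonhosp", 0.0),
    "cost_nonhosp_given_sh": ("cost_nonhosp", 1.0),
    "cost_nonhosp_given_nosh": ("cost_nonhosp", 0.0),
    "u_sh": ("utility", 1.0),
    "u_nosh": ("utility", 0.0),
}


def predict_suite(suite: ModelSuite, arm: str, cycle: int) -> dict:
    """All state probabilities, conditional costs and utilities for one cell."""
    out = {}
    for key, (model, sh) in PREDICTION_MAP.items():
        if model in suite.fits:  # partial suites predict what they can
            out[key] = _predict(suite[model], arm, cycle, suite.covariate_means,
                                sh, suite.n_cycles)
    return out


def predict_grid(suite: ModelSuite) -> dict:
    """Every quantity as an (arm, cycle) grid: dict key -> {arm: array(n_cycles)}."""
    grid = {k: {a: np.zeros(suite.n_cycles) for a in P.ARMS}
            for k, (m, _) in PREDICTION_MAP.items() if m in suite.fits}
    for arm in P.ARMS:
        for c in range(suite.n_cycles):
            pred = predict_suite(suite, arm, c)
            for k, v in pred.items():
                grid[k][arm][c] = v
    return grid
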