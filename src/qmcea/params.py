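"""Reference parameter tables and default study conditions.

The values below transcribe the published cycle-level parameter grids of the
SHIFT long-term follow-up (two-arm RCT of systemic family therapy vs treatment
as usual after adolescent self-harm): per-cycle self-harm hospitalisation
rates, conditional hospital costs, the treatment-invariant probability of a
hospitalisation without evidence of self-harm, conditional non-hospital costs,
state-conditional EQ-5D utilities, and the NICE evidence-review parameter
distributions.  They serve two purposes:

* defaults for the synthetic-trial generator, so the shipped fixture has the
  statistical structure of the real cohort; and
* printed-table inputs for desk-calculation checks (arm differences,
  incremental costs, net-benefit arithmetic).

All costs are GBP; cycles are 6 months long and indexed 0..9 (months 0-60).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

ARMS = ("FT", "TAU")
N_CYCLES = 10
CYCLE_YEARS = 0.5

#: EQ-5D-3L national tariff bounds for a utility value.
UTILITY_MIN = -0.594
UTILITY_MAX = 1.0


class ConfigurationError(ValueError):
    """Raised when a specification or parameter set fails validation."""


# ---------------------------------------------------------------------------
# Per-cycle probability of at least one self-harm hospitalisation, by arm
# (post-imputation cohort rates, declining from ~43-47% to ~6-8%).
# ---------------------------------------------------------------------------
P_SH_HOSP = {
    "FT":  np.array([0.430, 0.297, 0.218, 0.209, 0.167, 0.112, 0.113, 0.098, 0.093, 0.058]),
    "TAU": np.array([0.470, 0.250, 0.259, 0.211, 0.163, 0.138, 0.123, 0.092, 0.089, 0.075]),
}

# ---------------------------------------------------------------------------
# Probability of a hospitalisation without evidence of self-harm, conditional
# on whether a self-harm hospitalisation occurred in the same cycle
# (treatment-invariant).
# ---------------------------------------------------------------------------
P_NONSH_GIVEN_SH = np.array([0.338, 0.296, 0.255, 0.219, 0.188, 0.146, 0.132, 0.124, 0.122, 0.087])
P_NONSH_GIVEN_NOSH = np.array([0.268, 0.232, 0.197, 0.167, 0.143, 0.109, 0.098, 0.092, 0.091, 0.064])

# ---------------------------------------------------------------------------
# Conditional mean costs (GBP) given the corresponding hospitalisation
# occurred, per arm and cycle.
# ---------------------------------------------------------------------------
SH_HOSP_COST = {
    "FT":  np.array([1050.65, 1692.41, 1431.47, 1697.69, 1042.65, 657.86, 489.10, 785.75, 187.67, 146.19]),
    "TAU": np.array([684.43, 980.63, 667.83, 553.13, 1042.65, 657.86, 489.10, 785.75, 187.67, 146.19]),
}
NONSH_HOSP_COST = {
    "FT":  np.array([648.29, 940.25, 727.97, 437.16, 562.54, 901.23, 734.25, 440.37, 416.66, 436.28]),
    "TAU": np.array([1076.22, 1156.76, 1204.11, 568.07, 415.30, 328.53, 372.74, 460.23, 1248.69, 252.06]),
}

# ---------------------------------------------------------------------------
# Probability that any non-hospital (primary/community care, medication) cost
# occurs in a cycle, by arm and by self-harm hospitalisation status.  An arm
# difference exists only in months 0-6; from 12-18 months on the grid is flat
# (the trial window ends at 18 months and later cycles carry the last value).
# ---------------------------------------------------------------------------
P_NONHOSP_GIVEN_SH = {
    "FT":  np.array([0.963] + [0.872] + [0.879] * 8),
    "TAU": np.array([0.980] + [0.872] + [0.879] * 8),
}
P_NONHOSP_GIVEN_NOSH = {
    "FT":  np.array([0.925] + [0.762] + [0.773] * 8),
    "TAU": np.array([0.958] + [0.762] + [0.773] * 8),
}

#: Conditional mean non-hospital cost (GBP), time- and arm-invariant.
NONHOSP_COST_GIVEN_SH = 933.35
NONHOSP_COST_GIVEN_NOSH = 705.03

#: State-conditional EQ-5D utility expectations (time- and arm-invariant).
UTILITY_GIVEN_SH = 0.674
UTILITY_GIVEN_NOSH = 0.792

# ---------------------------------------------------------------------------
# NICE evidence-review parameter distributions for the two live states and
# the per-cycle excess cost of the repeated-self-harm state.
# ---------------------------------------------------------------------------
NICE_UTILITY_NONRSH = {"alpha": 2025.242, "beta": 152.438}
NICE_UTILITY_RSH = {"alpha": 1529.743, "beta": 719.879}
NICE_EXCESS_COST_RSH = {"shape": 4.0, "scale": 533.38}


def nice_value_distributions() -> dict:
    """Frozen scipy distributions for the NICE-preferred state values.

    Returns Beta distributions for the non-RSH and RSH utilities and a Gamma
    distribution for the per-cycle excess cost of the RSH state.
    """
    return {
        "utility_nonrsh": stats.beta(NICE_UTILITY_NONRSH["alpha"], NICE_UTILITY_NONRSH["beta"]),
        "utility_rsh": stats.beta(NICE_UTILITY_RSH["alpha"], NICE_UTILITY_RSH["beta"]),
        "excess_cost_rsh": stats.gamma(NICE_EXCESS_COST_RSH["shape"],
                                       scale=NICE_EXCESS_COST_RSH["scale"]),
    }


# ---------------------------------------------------------------------------
# Published deterministic cost-effectiveness totals (GBP, QALYs), used as
# printed-table inputs for desk-calculation checks.
# ---------------------------------------------------------------------------
REPORTED_CE_TOTALS = {
    ("base", "18m"): {"TAU": {"cost": 3281.0, "qaly": 1.160}, "FT": {"cost": 4986.0, "qaly": 1.159}},
    ("base", "60m"): {"TAU": {"cost": 7283.0, "qaly": 3.68}, "FT": {"cost": 8975.0, "qaly": 3.67}},
    ("nice", "18m"): {"TAU": {"cost": 1268.82, "qaly": 1.349}, "FT": {"cost": 2618.50, "qaly": 1.346}},
    ("nice", "60m"): {"TAU": {"cost": 1512.79, "qaly": 4.30}, "FT": {"cost": 2845.35, "qaly": 4.29}},
}

#: Published base-case 60-month increments (FT minus TAU).
REPORTED_BASE_60M_INCREMENTS = {"cost": 1693.0, "qaly": -0.010}

# ---------------------------------------------------------------------------
# Follow-up pattern of the extended hospital-record linkage: probability of a
# patient's records being observed at each cycle (administrative censoring).
# Near-complete to 36 months, ~74% at 42-48 months, ~40% at 54-60 months.
# Encoded as a pmf over the censoring cycle C (records cover cycles < C;
# C = 10 means complete follow-up).  Censoring before the end of the trial
# window (cycle 3) is folded into C = 3.
# ---------------------------------------------------------------------------
CENSOR_CYCLE_PMF = np.array(
    [0.0, 0.0, 0.0, 0.038, 0.008, 0.004, 0.082, 0.133, 0.193, 0.142, 0.40]
)

#: Monotone trial-questionnaire dropout hazard over the three trial cycles
#: (gives ~60% / ~53% / ~50% of patients still providing EQ-5D and
#: self-reported costs, matching the observed within-trial response pattern).
TRIAL_DROPOUT_HAZARD = np.array([0.40, 0.12, 0.05])

#: Sporadic (non-monotone) missingness of within-trial hospital indicators.
HOSP_RECORD_MISS_PROB = 0.01

#: Per-cycle death hazard; two deaths were seen over 60 months, both in FT.
DEATH_HAZARD = {
    "FT": np.full(N_CYCLES, 0.0005),
    "TAU": np.zeros(N_CYCLES),
}

# ---------------------------------------------------------------------------
# Cohort composition: randomised 398 (FT) vs 397 (TAU); covariates sampled
# independently.  The mix is a plausible description of a hospital-presenting
# adolescent self-harm cohort (predominantly female, self-poisoning the
# commonest index method).
# ---------------------------------------------------------------------------
DEFAULT_N_FT = 398
DEFAULT_N_TAU = 397
COVARIATE_MIX = {
    "female": 0.85,
    "age_11_14": 0.45,
    "cause_poisoning": 0.60,
    "hospital_referred": 0.55,
}

#: Micro-costed per-patient intervention cost (GBP), incurred over the first
#: 12 months (cycles 0-1).  The source worksheets are not public, so these
#: are placeholder config inputs sized so that the fixture's incremental cost
#: is on the reported ~+GBP 1,700 scale.
INTERVENTION_COST = {"FT": 1800.0, "TAU": 300.0}

#: Gamma shape parameters for conditional cost draws (right-skewed costs;
#: shape fixed, scale set per-cell from the mean grids above).
SH_COST_SHAPE = 1.5
NONSH_COST_SHAPE = 1.5
NONHOSP_COST_SHAPE = 2.0

#: Gaussian noise s.d. around the state-conditional utility means.
UTILITY_SD = 0.20

DISCOUNT_RATE = 0.035
WTP_GRID = np.arange(0.0, 50001.0, 500.0)


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent random generator from a master seed.

    Every randomised operation draws from its own substream so that stages
    are reproducible in isolation and adding draws to one stage never
    perturbs another.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *(int(k) & 0xFFFFFFFF for k in keys)])
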