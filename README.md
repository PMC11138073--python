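# qmcea — long-term cost-utility analysis of family therapy after adolescent self-harm

`qmcea` is a tested, reproducible pipeline for a question in adolescent
mental-health economics: is systemic family therapy (FT) added to treatment
as usual good value for money compared with treatment as usual alone (TAU)
for young people seen by services after repeated self-harm, once trial
follow-up is extended to five years of linked hospital records?

It is written for health economists and trial statisticians.  Because the
underlying cohort data (the SHIFT trial linked to NHS hospital-episode
records) are held under a restricted data-sharing agreement, the package
ships a synthetic-trial generator whose defaults reproduce the published
cycle-level parameter grids, so every stage of the analysis is runnable and
testable end to end without any data access.

## The model

A **quasi-Markov three-state cohort model** over ten 6-month cycles.  Each
cycle a patient is in one of: repeated self-harm (RSH — at least one
self-harm hospitalisation in the cycle), non-RSH, or death.  There is no
transition matrix; state-occupancy probabilities are predicted directly:

    pi_RSH(c)    = P(event at cycle c | alive) * (1 - pi_death(c))
    pi_nonRSH(c) = 1 - pi_RSH(c) - pi_death(c)

where `P(event | alive)` comes from a GEE logistic regression on the
cycle-level hospitalisation panel (patient-clustered, robust sandwich
covariance, saturated arm × cycle interactions) and `pi_death` from a
Kaplan–Meier estimate.  Conditional gamma-log GEE models supply hospital and
non-hospital cost expectations, and a gaussian GEE links EQ-5D utility to SH
status (u_SH = 0.674, u_noSH = 0.792 on the published grids).  Costs (GBP,
NHS + Personal Social Services perspective) and QALYs accrue per cycle and
are discounted at 3.5%/year.  Missing trial-window data are multiply imputed
by predictive mean matching and pooled by Rubin's rules.  Results are
summarised as the incremental cost-effectiveness ratio ΔC/ΔQ with dominance
handling, net benefits INHB(λ) = ΔQ − ΔC/λ and INMB(λ) = λ·ΔQ − ΔC, and a
10,000-draw probabilistic sensitivity analysis feeding the
cost-effectiveness plane and acceptability curves up to λ = £50,000/QALY.

See `docs/methods.md` for assumptions, design choices and limitations.

## Worked example

Run the whole pipeline — simulate a 795-patient cohort, impute (M = 10),
fit the GEE suite, roll up the Markov model and run a 2,000-draw PSA:

```python
from qmcea import RunConfig, run_pipeline

cfg = RunConfig.from_dict({"seed": 1, "imputation": {"m": 10}, "n_sims": 2000,
                           "scenarios": ["base", "nice"]})
results = run_pipeline(cfg, "demo")
print(open("demo/report.md").read())
```

prints (this exact output for this seed):

```
| Scenario | Horizon | TAU cost | FT cost | TAU QALYs | FT QALYs | dC | dQ | ICER | INHB@30k |
|---|---|---|---|---|---|---|---|---|---|
| base | 18m | 3,717 | 5,709 | 1.122 | 1.118 | 1,993 | -0.0041 | Dominated | -0.0706 |
| base | 60m | 8,336 | 10,536 | 3.590 | 3.572 | 2,200 | -0.0178 | Dominated | -0.0912 |
| nice | 18m | 2,185 | 3,834 | 1.261 | 1.252 | 1,649 | -0.0087 | Dominated | -0.0637 |
| nice | 60m | 3,869 | 5,511 | 4.100 | 4.075 | 1,642 | -0.0245 | Dominated | -0.0793 |

## PSA (base, 2000 simulations)
- maximum CEAC probability: 0.000
- CE-plane quadrant proportions: north_east=0.00, north_west=1.00, south_west=0.00, south_east=0.00
```

Reading the base-case 60-month row: on the synthetic cohort FT costs £2,200
more per patient and yields 0.018 fewer QALYs, so it is *dominated* (costlier
and less effective); the net health benefit at £30,000/QALY is −0.09 QALYs.
The PSA cloud sits entirely in the north-west quadrant (costlier, less
effective) and the probability that FT is cost-effective stays at ~0 across
the whole willingness-to-pay range — the qualitative conclusion of the
source analysis.

The same run is available from the shell:

```sh
qmcea write-config cfg.yaml            # editable default configuration
qmcea -v run-all --config cfg.yaml --seed 1 --out demo
```

Other subcommands (`simulate`, `impute`) expose the individual stages; every
randomised stage takes `--seed`, and identical configurations produce
byte-identical result manifests.

Library highlights:

```python
import qmcea

qmcea.qaly_auc([0.7536, 0.7536, 0.7835, 0.8097])   # 1.159 QALYs over 18 months
qmcea.icer(1693.0, -0.010)                         # ('dominated', None)
qmcea.inhb(1693.0, -0.010, 30000.0)                # -0.0664
```

## Layout

| Path | Contents |
|---|---|
| `src/qmcea/synthetic.py` | cohort roster, event/cost/utility trajectories, missingness and censoring |
| `src/qmcea/imputation.py` | predictive mean matching, multiple imputation, Rubin's rules |
| `src/qmcea/estimation.py` | GEE model suite, pruning, prediction, Kaplan–Meier mortality |
| `src/qmcea/markov.py` | three-state occupancy, cycle payoffs, discounting |
| `src/qmcea/econ.py` | QALY AUC, ICER/INHB/INMB, PSA, CEAC, CE plane |
| `src/qmcea/params.py` | published parameter grids and study-condition defaults |
| `src/qmcea/config.py`, `pipeline.py`, `cli.py` | configuration, orchestration, CLI |
| `docs/methods.md` | model assumptions, design decisions, limitations |
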