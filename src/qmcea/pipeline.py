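"""End-to-end orchestration: simulate -> impute -> estimate -> model -> PSA.

``run_pipeline`` executes the whole analysis from a ``RunConfig``, writes the
intermediate CSVs, per-scenario ledgers, the results JSON, CEAC/CE-plane
exports and a manifest recording seeds, the config hash and SHA-256 digests
of every text output, so that identical configs yield byte-identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import params as P
from .config import RunConfig
from .econ import ce_plane, ceac, deterministic_totals, econ_result, psa_run
from .estimation import fit_suite, predict_grid
from .imputation import multiple_impute
from .markov import run_model
from .synthetic import TrajectoryParams, apply_missingness, generate_cohort, generate_trajectories

log = logging.getLogger("qmcea")


def run_pipeline(config: RunConfig, outdir: str | Path, psa_scenarios=("base",)) -> dict:
    """Run every stage and write the results bundle under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log.info("simulate: %d + %d patients, %d cycles",
             config.cohort.n_ft, config.cohort.n_tau, config.cohort.n_cycles)
    roster = generate_cohort(config.cohort)
    complete = generate_trajectories(roster, config.trajectory, config.seed,
                                     config.cohort.n_cycles)
    observed = apply_missingness(complete, config.trajectory, config.seed)
    written += observed.to_csv(outdir, prefix="trial").values()

    log.info("impute: M=%d", config.imputation.m)
    imputed = multiple_impute(observed, config.imputation)

    log.info("estimate: GEE suite over %d imputations", len(imputed))
    suite = fit_suite(imputed, config.cohort.n_cycles, alpha=config.prune_alpha,
                      working_correlation=config.working_correlation)
    coef_path = outdir / "coefficients.csv"
    _write_coefficients(suite, coef_path)
    written.append(coef_path)

    results = {"scenarios": {}, "logrank_p": suite.logrank_p}
    grid = predict_grid(suite)
    for name in config.scenarios:
        mc = config.scenario_model(name)
        bundle = run_model(grid, suite.km, mc)
        ledger_path = outdir / f"ledger_{name}.csv"
        ledger = bundle["occupancy"].merge(bundle["payoffs"], on=["arm", "cycle"])
        ledger.to_csv(ledger_path, index=False)
        written.append(ledger_path)
        results["scenarios"][name] = {
            h: econ_result(bundle["totals"], h).to_dict() for h in ("18m", "60m")
        }

    log.info("psa: %d simulations", config.n_sims)
    results["psa"] = {}
    for name in psa_scenarios:
        if name not in config.scenarios:
            continue
        mc = config.scenario_model(name)
        draws = psa_run(suite, mc, n_sims=config.n_sims, seed=config.seed)
        cc = ceac(draws, mc.wtp_grid)
        ceac_path = outdir / f"ceac_{name}.csv"
        cc.to_csv(ceac_path, index=False)
        written.append(ceac_path)
        plane = ce_plane(draws, path_prefix=str(outdir / f"ce_plane_{name}"))
        written.append(outdir / f"ce_plane_{name}.csv")
        results["psa"][name] = {
            "n_sims": draws.n_sims,
            "quadrants": plane,
            "ceac_max": float(cc["p_cost_effective"].max()),
            "mean_dc_60m": float(draws.draws["dc_60m"].mean()),
            "mean_dq_60m": float(draws.draws["dq_60m"].mean()),
        }

    results_path = outdir / "results.json"
    results_path.write_text(json.dumps(results, indent=2, sort_keys=True))
    written.append(results_path)

    report_path = outdir / "report.md"
    report_path.write_text(report(results))
    written.append(report_path)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "files": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_coefficients(suite, path: Path) -> None:
    rows = []
    for name, fit in sorted(suite.fits.items()):
        se = np.sqrt(np.diag(fit.cov.to_numpy()))
        for col, b, s in zip(fit.columns, fit.params.to_numpy(), se):
            rows.append({"model": name, "term": col, "coef": b, "robust_se": s})
    pd.DataFrame(rows).to_csv(path, index=False)


def report(results: dict) -> str:
    """Human-readable Markdown tables for the results bundle."""
    lines = ["# Cost-effectiveness results", ""]
    lines.append("| Scenario | Horizon | TAU cost | FT cost | TAU QALYs | FT QALYs | "
                 "dC | dQ | ICER | INHB@30k |")
    lines.append("|---|---|---|---|---|---|---|---|---|---|")
    for name, horizons in sorted(results.get("scenarios", {}).items()):
        for h, r in sorted(horizons.items()):
            if r["icer_label"] == "ratio":
                icer_txt = f"{r['icer_value']:,.0f}"
            else:
                icer_txt = r["icer_label"].capitalize()
            lines.append(
                f"| {name} | {h} | {r['cost']['TAU']:,.0f} | {r['cost']['FT']:,.0f} "
                f"| {r['qaly']['TAU']:.3f} | {r['qaly']['FT']:.3f} "
                f"| {r['incremental_cost']:,.0f} | {r['incremental_qaly']:.4f} "
                f"| {icer_txt} | {r['inhb_30k']:.4f} |")
    for name, psa in sorted(results.get("psa", {}).items()):
        lines += ["", f"## PSA ({name}, {psa['n_sims']} simulations)",
                  f"- maximum CEAC probability: {psa['ceac_max']:.3f}",
                  f"- CE-plane quadrant proportions: "
                  + ", ".join(f"{k}={v:.2f}" for k, v in psa["quadrants"]["proportions"].items())]
    lines.append("")
    return "\n".join(lines)
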