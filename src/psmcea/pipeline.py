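"""End-to-end pipeline: reconstruct (optional) -> fit -> partitioned
survival model -> sensitivity analyses, with delimited-text outputs and
a reproducibility manifest.

All randomness flows from a single master seed, split deterministically
per stage with numpy's SeedSequence.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import load_config
from .fitting import fit_all_families, select_model, survival_at
from .psm import CEModel, ModelParams, build_trace, first_line_strategy
from .reconstruct import clean_curve, reconstruct_ipd
from .trial_synth import (
    DigitizedCurve,
    RiskTable,
    TrialSimConfig,
    digitize_curve,
    km_estimate,
    make_risk_table,
    simulate_trial,
)
from .uncertainty import (
    apply_scenario_pap,
    ceac,
    default_wtp_grid,
    run_dsa,
    run_psa,
)

logger = logging.getLogger(__name__)

ARMS = ("P", "C")
ENDPOINTS = ("PFS", "OS")


class PipelineError(RuntimeError):
    pass


# --------------------------------------------------------------------- io

def write_ipd(ipd: pd.DataFrame, path: Union[str, Path]) -> None:
    ipd.to_csv(path, index=False)


def read_ipd(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_curve(curve: DigitizedCurve, path: Union[str, Path]) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_curve(path: Union[str, Path]) -> DigitizedCurve:
    df = pd.read_csv(path)
    return DigitizedCurve(times=df["time_days"].to_numpy(),
                          survival=df["survival"].to_numpy())


def write_risk(risk: RiskTable, path: Union[str, Path]) -> None:
    risk.to_frame().to_csv(path, index=False)


def read_risk(path: Union[str, Path]) -> RiskTable:
    df = pd.read_csv(path)
    return RiskTable(times=df["time_days"].to_numpy(),
                     n_at_risk=df["n_at_risk"].to_numpy())


def _stage_seeds(master_seed: int, n: int = 4) -> list:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ----------------------------------------------------------- input synthesis

def synthesize_inputs(sim_config: TrialSimConfig, out_dir: Union[str, Path],
                      grid_step_days: float = 30.0, jitter_sd: float = 0.003,
                      risk_interval_days: float = 6 * 30.4375) -> Dict:
    """Simulate a trial and emit, per arm and endpoint, the three file
    kinds the reconstruction stage consumes: IPD (ground truth),
    digitized curve and number-at-risk table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ipd = simulate_trial(sim_config)
    write_ipd(ipd, out_dir / "ipd_true.csv")
    rng = np.random.default_rng(sim_config.seed + 1)
    manifest = {"ipd": str(out_dir / "ipd_true.csv"), "curves": {}}
    for arm in ARMS:
        for ep in ENDPOINTS:
            km = km_estimate(ipd, arm, ep)
            curve = digitize_curve(km, grid_step_days, jitter_sd, rng)
            risk = make_risk_table(ipd, arm, ep, risk_interval_days)
            cpath = out_dir / f"curve_{arm}_{ep}.csv"
            rpath = out_dir / f"risk_{arm}_{ep}.csv"
            write_curve(curve, cpath)
            write_risk(risk, rpath)
            manifest["curves"][f"{arm}_{ep}"] = {"curve": str(cpath),
                                                 "risk": str(rpath)}
    return manifest


# ------------------------------------------------------------------ pipeline

def run_pipeline(
    config_path: Union[str, Path, None],
    out_dir: Union[str, Path],
    seed: int,
    ipd: Optional[pd.DataFrame] = None,
    curves: Optional[Dict[Tuple[str, str], Tuple[DigitizedCurve, RiskTable]]] = None,
    n_psa: int = 500,
    selection: str = "aic",
) -> dict:
    """Run the full analysis and write all outputs under ``out_dir``.

    Exactly one of ``ipd`` (subject-level records for both arms and
    endpoints) or ``curves`` (digitized curve + risk table per
    arm/endpoint, reconstructed into pseudo-IPD first) must be given.

    Returns the summary dictionary (also written as summary.json).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params, registry = load_config(config_path)
    seeds = _stage_seeds(seed)

    # --- stage 1: obtain IPD ------------------------------------------
    if (ipd is None) == (curves is None):
        raise PipelineError("provide exactly one of ipd= or curves=")
    if curves is not None:
        frames = []
        for arm in ARMS:
            for ep in ENDPOINTS:
                if (arm, ep) not in curves:
                    raise PipelineError(f"missing input for arm {arm} endpoint {ep}")
                curve, risk = curves[(arm, ep)]
                try:
                    rec = reconstruct_ipd(clean_curve(curve), risk,
                                          arm=arm, endpoint=ep)
                except Exception as exc:
                    raise PipelineError(
                        f"reconstruction failed for arm {arm} endpoint {ep}: {exc}"
                    ) from exc
                frames.append(rec)
        ipd = pd.concat(frames, ignore_index=True)
        ipd["subject_id"] = np.arange(1, len(ipd) + 1)
    else:
        for arm in ARMS:
            for ep in ENDPOINTS:
                if len(ipd[(ipd["arm"] == arm) & (ipd["endpoint"] == ep)]) == 0:
                    raise PipelineError(f"missing input for arm {arm} endpoint {ep}")
    write_ipd(ipd, out_dir / "ipd_used.csv")

    # --- stage 2: fit & select ----------------------------------------
    selected = {}
    fit_report = {}
    for arm in ARMS:
        for ep in ENDPOINTS:
            sub = ipd[(ipd["arm"] == arm) & (ipd["endpoint"] == ep)]
            try:
                fits = fit_all_families(sub)
                ranked = select_model(fits)
            except Exception as exc:
                raise PipelineError(
                    f"fitting failed for arm {arm} endpoint {ep}: {exc}"
                ) from exc
            selected[(arm, ep)] = ranked[0]
            fit_report[f"{arm}_{ep}"] = [
                dict(f.to_dict(), rank=i + 1) for i, f in enumerate(ranked)
            ]
    with open(out_dir / "fit_report.json", "w") as fh:
        json.dump(fit_report, fh, indent=2)

    evaluators = {
        key: (lambda t, f=fit: survival_at(f, t)) for key, fit in selected.items()
    }
    model = CEModel(evaluators)

    # --- stage 3: base case -------------------------------------------
    outcome_p = model.arm_outcome("P", params)
    outcome_c = model.arm_outcome("C", params)
    base = model.evaluate(params)
    for arm in ARMS:
        trace = build_trace(evaluators[(arm, "PFS")], evaluators[(arm, "OS")], params)
        pd.DataFrame(
            {
                "time_days": trace.times,
                "pfs_occupancy": trace.pfs,
                "pd_occupancy": trace.pd,
                "dead_occupancy": trace.dead,
                "discount_factor": trace.df,
            }
        ).to_csv(out_dir / f"trace_{arm}.csv", index=False)

    # --- stage 4: PAP scenario ----------------------------------------
    pap_result = model.evaluate(apply_scenario_pap(params))

    # --- stage 5: DSA --------------------------------------------------
    tornado = run_dsa(params, registry, model)
    tornado.rename(
        columns={
            "icer_base": "icer_base_usd_per_qaly",
            "icer_low": "icer_low_usd_per_qaly",
            "icer_high": "icer_high_usd_per_qaly",
            "width": "width_usd_per_qaly",
        }
    ).to_csv(out_dir / "tornado.csv", index=False)

    # --- stage 6: PSA + CEAC ------------------------------------------
    draws = run_psa(params, registry, n_psa, seeds[2], model)
    pd.DataFrame(
        {
            "iteration": [d.iteration for d in draws],
            "d_cost_usd": [d.d_cost for d in draws],
            "d_qaly": [d.d_qaly for d in draws],
        }
    ).to_csv(out_dir / "psa_draws.csv", index=False)
    grid = default_wtp_grid()
    ceac_points = ceac(draws, grid)
    pd.DataFrame(
        {
            "wtp_usd_per_qaly": [p.wtp for p in ceac_points],
            "probability_cost_effective": [p.probability for p in ceac_points],
        }
    ).to_csv(out_dir / "ceac.csv", index=False)
    prob_at_wtp = float(
        np.mean([params.wtp * d.d_qaly - d.d_cost > 0 for d in draws])
    )

    summary = {
        "arms": {"P": outcome_p.to_dict(), "C": outcome_c.to_dict()},
        "incremental": base.to_dict(),
        "pap_scenario": pap_result.to_dict(),
        "probability_cost_effective_at_wtp": prob_at_wtp,
        "wtp": params.wtp,
        "selected_families": {f"{a}_{e}": selected[(a, e)].family
                              for a in ARMS for e in ENDPOINTS},
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    cfg_path = config_path or "builtin:table1_baseline"
    cfg_hash = ""
    if config_path is not None:
        cfg_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:16]
    manifest = {
        "psmcea_version": __version__,
        "numpy_version": np.__version__,
        "config": str(cfg_path),
        "config_sha256_16": cfg_hash,
        "master_seed": seed,
        "stage_seeds": seeds,
        "n_psa": n_psa,
        "selection_policy": selection,
        "selected_families": summary["selected_families"],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
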