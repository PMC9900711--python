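"""Reproducible analysis tasks behind the CLI: run, write CSVs + summary."""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .adaptive_dynamics import (ResidentContext, classify_singular_strategy,
                                css_parameter_sweep, find_singular_strategy,
                                pairwise_invasion_plot)
from .attractor import compute_attractor
from .config import RunConfig
from .evo_sim import evolve

__all__ = ["run_task", "TASKS"]

TASKS = ("attractor", "pip", "singular", "sweep", "evosim")


def _write_summary(out: Path, payload: dict) -> None:
    with (out / "run_summary.json").open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_task(task: str, cfg: RunConfig, verbose: bool = False) -> dict:
    """Execute one named task, writing CSV artifacts and a run summary.

    Returns the summary dict (also written as ``run_summary.json`` in
    ``cfg.out_dir``).  CSV contents are deterministic for a fixed config
    and seed.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    solver = cfg.solver_options()
    ts = cfg.task_settings
    t_start = time.perf_counter()
    result: dict = {}
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if task == "attractor":
            cyc, trace = compute_attractor(cfg.variant, cfg.epi, cfg.tradeoff,
                                           burn_in=cfg.burn_in,
                                           n_samples=cfg.samples_per_period,
                                           solver=solver)
            cyc.to_dataframe().to_csv(out / "cycle.csv", index=False)
            result = {"kind": cyc.kind, "period": cyc.period,
                      "multiplicity": cyc.multiplicity, "closure_gap": cyc.closure_gap,
                      "end_state": trace.end_state.tolist()}
        elif task == "pip":
            ctx = ResidentContext(cfg.variant, cfg.epi, cfg.tradeoff, solver=solver,
                                  attractor_kwargs={"burn_in": cfg.burn_in})
            pip = pairwise_invasion_plot(cfg.variant, cfg.epi, cfg.tradeoff,
                                         cfg.trait_range, n=ts.get("n", 41),
                                         zero_tolerance=ts.get("zero_tolerance", 1e-5),
                                         context=ctx)
            pip.to_dataframe().to_csv(out / "pip.csv", index=False)
            result = {"n": len(pip.trait_values), "failed_columns": pip.failed_columns}
            try:
                sing = find_singular_strategy(cfg.variant, cfg.epi, cfg.tradeoff,
                                              ts.get("bracket", cfg.trait_range), context=ctx)
                sing = classify_singular_strategy(cfg.variant, cfg.epi, cfg.tradeoff,
                                                  sing.beta_star, context=ctx)
                result["singular_strategy"] = {"beta_star": sing.beta_star,
                                               "label": sing.label,
                                               "converg_stable": sing.converg_stable,
                                               "evol_stable": sing.evol_stable}
            except ValueError as err:
                result["singular_strategy"] = {"error": str(err)}
        elif task == "singular":
            ctx = ResidentContext(cfg.variant, cfg.epi, cfg.tradeoff, solver=solver,
                                  attractor_kwargs={"burn_in": cfg.burn_in})
            sing = find_singular_strategy(cfg.variant, cfg.epi, cfg.tradeoff,
                                          ts.get("bracket", cfg.trait_range), context=ctx)
            sing = classify_singular_strategy(cfg.variant, cfg.epi, cfg.tradeoff,
                                              sing.beta_star, context=ctx)
            result = {"beta_star": sing.beta_star, "label": sing.label,
                      "converg_stable": sing.converg_stable,
                      "evol_stable": sing.evol_stable,
                      "evol_curvature": sing.evol_curvature,
                      "conv_slope": sing.conv_slope}
        elif task == "sweep":
            sweep = ts.get("sweep")
            if not sweep:
                raise ValueError("sweep task needs task_settings['sweep'] = "
                                 "{'parameter': name, 'values': [...]}")
            df = css_parameter_sweep(cfg.variant, cfg.epi, cfg.tradeoff,
                                     sweep["parameter"], sweep["values"],
                                     ts.get("bracket", cfg.trait_range),
                                     solver=solver,
                                     attractor_kwargs={"burn_in": cfg.burn_in})
            df.to_csv(out / "sweep.csv", index=False)
            result = {"rows": len(df), "lost": int((df["kind"] == "lost").sum())}
        elif task == "evosim":
            traj = evolve(cfg.variant, cfg.epi, cfg.tradeoff, cfg.trait_range,
                          n_strains=ts.get("n_strains", 61),
                          start_beta=ts.get("start_beta"),
                          n_steps=ts.get("n_steps", 100),
                          epoch_length=ts.get("epoch_length", 50.0),
                          extinction_threshold=ts.get("extinction_threshold", 1e-5),
                          mutant_seed_density=ts.get("mutant_seed_density", 1e-3),
                          seed=cfg.seed)
            traj.to_dataframe().to_csv(out / "trajectory.csv", index=False)
            result = {"steps": len(traj.steps), "all_extinct": traj.all_extinct,
                      "dominant_beta": traj.dominant_trait()}
        caught = [str(w.message) for w in wlist]

    summary = {
        "task": task,
        "config": cfg.to_dict(),
        "result": result,
        "warnings": caught,
        "versions": {"evocycles": __version__,
                     "numpy": np.__version__,
                     "scipy": __import__("scipy").__version__},
        "elapsed_seconds": round(time.perf_counter() - t_start, 3),
    }
    _write_summary(out, summary)
    if verbose:
        print(json.dumps(result, indent=2, default=str))
    return summary
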