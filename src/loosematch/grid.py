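"""Scenario-grid construction and the experiment driver.

The study grid crosses mu0 in {50, 60, 65} (mu1 = 70, sigma = 10),
OR_age10 in {1, 1.5, 2, 3}, caliper d in {0..3} and matching ratio k in
{1..4}, under the null (OR_e = 1) and the alternative (OR_e = 1.5), with
p_e = 0.3 and prevalence K = 0.1.  The number of matched sets is tied to the
exposed/unexposed mean-age gap — 400, 500 and 900 sets for gaps of 5, 10 and
20 years — sized by pilot simulation for roughly 80% power.  The study-facing
default fixes k = 1 (96 cells over both hypotheses); the full grid has 384.

Each cell owns an independent RNG substream keyed by (root seed, scenario
key, replicate index), with the scenario key a stable CRC of the scenario id,
so results are invariant to execution order and worker count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .evaluation import run_replicates, summarize
from .scenario import Scenario

__all__ = ["GridCell", "build_scenario_grid", "run_experiment", "DEFAULT_CONFIG"]

logger = logging.getLogger("loosematch")

#: matched sets per case-control mean-age gap (years): chosen for ~80% power
N_CASES_BY_GAP = {5: 400, 10: 500, 20: 900}

DEFAULT_CONFIG: dict = {
    "mu0": [65.0, 60.0, 50.0],
    "or_age_per10": [1.0, 1.5, 2.0, 3.0],
    "caliper_d": [0, 1, 2, 3],
    "ratio_k": [1],
    "hypotheses": ["null", "alternative"],
    "or_exposure_alt": 1.5,
    "p_e": 0.3,
    "mu1": 70.0,
    "sigma": 10.0,
    "prevalence": 0.1,
    "reps_null": 10_000,
    "reps_alt": 1_000,
    "alpha": 0.05,
    "root_seed": 20180302,
    "n_cases": None,  # override; default is the gap-based lookup
}


def default_n_cases(mu0: float, mu1: float = 70.0) -> int:
    gap = round(abs(mu1 - mu0))
    if gap not in N_CASES_BY_GAP:
        raise ValueError(
            f"no default sample size for a mean-age gap of {gap} years; set n_cases explicitly"
        )
    return N_CASES_BY_GAP[gap]


def scenario_key(scenario: Scenario) -> int:
    """Stable 31-bit substream key derived from the scenario id."""
    return zlib.crc32(scenario.scenario_id.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class GridCell:
    scenario: Scenario
    hypothesis: str  # "null" | "alternative"
    n_reps: int

    @property
    def key(self) -> int:
        return scenario_key(self.scenario)


def build_scenario_grid(config: dict | None = None) -> list[GridCell]:
    """Deterministic, ordered list of grid cells from a flat config mapping.

    Unknown keys or out-of-range values are rejected with a message.  Any
    axis is subsettable by listing fewer values.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    bad_hyp = set(cfg["hypotheses"]) - {"null", "alternative"}
    if bad_hyp:
        raise ValueError(f"unknown hypotheses: {sorted(bad_hyp)}")
    cells: list[GridCell] = []
    for hypothesis in cfg["hypotheses"]:
        or_e = 1.0 if hypothesis == "null" else cfg["or_exposure_alt"]
        n_reps = cfg["reps_null"] if hypothesis == "null" else cfg["reps_alt"]
        for mu0 in cfg["mu0"]:
            n_cases = cfg["n_cases"] or default_n_cases(mu0, cfg["mu1"])
            for or_age in cfg["or_age_per10"]:
                for d in cfg["caliper_d"]:
                    for k in cfg["ratio_k"]:
                        scen = Scenario(
                            mu0=mu0,
                            or_exposure=or_e,
                            or_age_per10=or_age,
                            caliper_d=int(d),
                            ratio_k=int(k),
                            n_cases=int(n_cases),
                            p_e=cfg["p_e"],
                            mu1=cfg["mu1"],
                            sigma=cfg["sigma"],
                            prevalence=cfg["prevalence"],
                        )
                        cells.append(GridCell(scenario=scen, hypothesis=hypothesis, n_reps=n_reps))
    return cells


def _run_cell(cell: GridCell, root_seed: int, alpha: float) -> tuple[list[dict], dict]:
    t0 = time.time()
    summary = run_replicates(cell.scenario, cell.n_reps, root_seed, scenario_key=cell.key)
    rows = []
    for row in summarize(summary, alpha=alpha):
        rec = dataclasses.asdict(row)
        rec.update(
            hypothesis=cell.hypothesis,
            mu0=cell.scenario.mu0,
            or_age_per10=cell.scenario.or_age_per10,
            or_exposure=cell.scenario.or_exposure,
            caliper_d=cell.scenario.caliper_d,
            ratio_k=cell.scenario.ratio_k,
            n_cases=cell.scenario.n_cases,
        )
        rows.append(rec)
    cell_log = {
        "scenario_id": cell.scenario.scenario_id,
        "hypothesis": cell.hypothesis,
        "scenario_key": cell.key,
        "n_reps": cell.n_reps,
        "n_excluded": {
            name: int(cell.n_reps - m.n_used) for name, m in summary.models.items()
        },
        "exclusion_flagged": summary.exclusion_flagged(),
        "seconds": round(time.time() - t0, 2),
    }
    logger.info(
        "cell %s (%s): %d reps in %.1fs, excluded %s",
        cell.scenario.scenario_id,
        cell.hypothesis,
        cell.n_reps,
        cell_log["seconds"],
        cell_log["n_excluded"],
    )
    return rows, cell_log


def run_experiment(
    config: dict | None = None, output_dir: str | Path = "results", workers: int = 1
) -> pd.DataFrame:
    """Execute the scenario grid and write tidy metrics, tables and manifest.

    Results are independent of ``workers``: every cell's randomness is keyed
    only to (root seed, scenario key, replicate index).  Returns the tidy
    metric frame; side effects are ``metrics.csv``, one study-style table per
    metric, ``manifest.json`` and a log of per-cell progress.
    """
    from .reporting import render_table, table_metrics

    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)  # validated inside build_scenario_grid
    cells = build_scenario_grid(config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed, alpha = cfg["root_seed"], cfg["alpha"]

    if workers > 1:
        results = Parallel(n_jobs=workers)(
            delayed(_run_cell)(cell, root_seed, alpha) for cell in cells
        )
    else:
        results = [_run_cell(cell, root_seed, alpha) for cell in cells]

    tidy = pd.DataFrame([row for rows, _ in results for row in rows])
    tidy.to_csv(outdir / "metrics.csv", index=False)

    for hypothesis in cfg["hypotheses"]:
        sub = tidy[tidy["hypothesis"] == hypothesis]
        if sub.empty:
            continue
        for metric in table_metrics(hypothesis):
            table = render_table(sub, metric)
            table.to_csv(outdir / f"table_{hypothesis}_{metric}.csv")

    manifest = {
        "package": "loosematch",
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "root_seed": root_seed,
        "n_cells": len(cells),
        "cells": [log for _, log in results],
        "any_failure": False,
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return tidy
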