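"""Serialization of run results: per-run JSON, archive CSV, grid summary CSV."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .his import HISResult

__all__ = [
    "result_to_dict",
    "write_result_json",
    "write_archive_csv",
    "write_grid_summary",
    "cell_label",
]

_EVOLVER_PREFIX = {"pso": "P", "gsa": "G", "fa": "F"}


def cell_label(cfg) -> str:
    """Short label for one grid cell, e.g. ``PSVM`` or ``Basic-MLP+RS``."""
    base = cfg.classifier.upper()
    if cfg.evolver == "none":
        name = f"Basic-{base}"
    else:
        name = f"{_EVOLVER_PREFIX[cfg.evolver]}{base}"
    return name + ("+RS" if cfg.resample else "")


def result_to_dict(result: HISResult) -> dict:
    cfg = result.config
    out = {
        "label": cell_label(cfg),
        "config": {
            "classifier": cfg.classifier,
            "evolver": cfg.evolver,
            "resample": cfg.resample,
            "seed": cfg.seed,
            "weights": [cfg.weights.w1, cfg.weights.w2, cfg.weights.w3],
            "n_folds": cfg.cv.n_folds,
            "n_agents": cfg.evolver_cfg.n_agents,
            "n_iterations": cfg.evolver_cfg.n_iterations,
        },
        "error": result.error,
    }
    if result.failed:
        return out
    obj = result.best_objectives
    out.update(
        {
            "best_params": result.best_params,
            "PAC": obj.pac,
            "SEY": obj.sey,
            "SPY": obj.spy,
            "Z": result.best_z,
            "precision": result.secondary.get("precision"),
            "recall": result.secondary.get("recall"),
            "f_measure": result.secondary.get("f_measure"),
            **result.confusion,
            "gd": result.gd,
            "sp": result.sp,
            "n_evaluations": result.n_evaluations,
            "fitness_history": [float(v) for v in result.fitness_history],
        }
    )
    return out


def write_result_json(result: HISResult, path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2, sort_keys=True))


def write_archive_csv(result: HISResult, path) -> None:
    """One row per fitness evaluation: iteration, agent, position..., objectives."""
    rows = []
    param_names = list(result.best_params) or [
        f"p{i}" for i in range(len(result.evaluation_archive[0].position))
    ]
    for e in result.evaluation_archive:
        row = {"iteration": e.iteration, "agent": e.agent}
        row.update({name: v for name, v in zip(param_names, e.position)})
        if e.aux is not None:
            row.update({"PAC": e.aux.pac, "SEY": e.aux.sey, "SPY": e.aux.spy})
        row["Z"] = e.fitness
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_grid_summary(results, path) -> None:
    """Wide CSV: rows are metrics, columns are the 16 grid configurations."""
    metrics = ["PAC", "SEY", "SPY", "Z", "precision", "recall", "f_measure", "gd", "sp"]
    table = {}
    for r in results:
        label = cell_label(r.config)
        if r.failed:
            table[label] = {m: None for m in metrics}
            continue
        d = result_to_dict(r)
        table[label] = {m: d.get(m) for m in metrics}
    pd.DataFrame(table).reindex(metrics).to_csv(path)
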