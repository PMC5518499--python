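"""Pipeline orchestration: preprocessing, evolver-driven tuning, grid runs.

A single run wires dataset -> impute -> normalize -> (optional resample)
-> evolver-driven search over the chosen classifier's parameters, with
the scalarized (PAC, SPY, SEY) fitness evaluated by stratified k-fold
cross-validation.  The full 16-cell grid crosses {svm, mlp} x
{none, pso, gsa, fa} x {resample off, on}; one master seed fans out
deterministically to fold shuffling, resampling and each cell's evolver.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .classifiers import (
    CVConfig,
    default_params,
    evaluate_params,
    mlp_spec,
    svm_spec,
)
from .data import Dataset, impute_missing, minmax_normalize, supervised_resample
from .errors import EvoHISError
from .evolvers import EVOLVERS, ArchiveEntry, EvolverConfig, OptimizationResult
from .objectives import (
    ObjectiveVector,
    ObjectiveWeights,
    primary_objectives,
    scalarize,
    secondary_metrics,
)
from .pareto import (
    Front,
    build_reference_front,
    generational_distance,
    nondominated,
    normalize_front,
    spacing,
)

__all__ = ["HISConfig", "HISResult", "run_his", "run_grid", "select_best", "GRID_ORDER"]

CLASSIFIERS = ("svm", "mlp")
EVOLVER_ORDER = ("none", "pso", "gsa", "fa")

#: fixed grid order: classifier-major, then evolver, then resample off/on
GRID_ORDER = tuple(
    (clf, evo, rs)
    for clf in CLASSIFIERS
    for evo in EVOLVER_ORDER
    for rs in (False, True)
)


@dataclass(frozen=True)
class HISConfig:
    classifier: str = "svm"
    evolver: str = "pso"
    resample: bool = False
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    cv: CVConfig = field(default_factory=CVConfig)
    evolver_cfg: EvolverConfig = field(default_factory=EvolverConfig)
    seed: int = 0
    resample_bias: float = 0.0
    resample_size: float = 100.0
    svm_kernel: str = "linear"
    svm_gamma: float = 1.0
    mlp_epochs: int = 500

    def __post_init__(self):
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.evolver not in EVOLVER_ORDER:
            raise ValueError(f"evolver must be one of {EVOLVER_ORDER}")


@dataclass
class HISResult:
    config: HISConfig
    best_params: dict
    best_objectives: ObjectiveVector
    best_z: float
    secondary: dict
    confusion: dict
    evaluation_archive: tuple
    fitness_history: np.ndarray
    n_evaluations: int
    wall_time: float
    gd: float = float("nan")
    sp: float = float("nan")
    error: str = ""

    @property
    def failed(self) -> bool:
        return bool(self.error)


def _sub_seeds(cfg: HISConfig) -> dict:
    ss = np.random.SeedSequence((cfg.seed, cfg.cv.shuffle_seed))
    resample_s, cv_s, evolver_s, train_s = (int(s) for s in ss.generate_state(4))
    return {"resample": resample_s, "cv": cv_s, "evolver": evolver_s, "train": train_s}


def _classifier_spec(cfg: HISConfig):
    if cfg.classifier == "svm":
        return svm_spec(kernel=cfg.svm_kernel, gamma=cfg.svm_gamma)
    return mlp_spec(epochs=cfg.mlp_epochs)


def preprocess(ds: Dataset, cfg: HISConfig, seeds: dict) -> Dataset:
    ds = impute_missing(ds)
    ds = minmax_normalize(ds)
    if cfg.resample:
        ds = supervised_resample(
            ds,
            seed=seeds["resample"],
            bias_to_uniform=cfg.resample_bias,
            size_percent=cfg.resample_size,
        )
    return ds


def run_his(ds: Dataset, cfg: HISConfig) -> HISResult:
    """Execute one (classifier x evolver x resampling) configuration."""
    t0 = time.perf_counter()
    seeds = _sub_seeds(cfg)
    data = preprocess(ds, cfg, seeds)
    spec = _classifier_spec(cfg)
    cv = replace(cfg.cv, shuffle_seed=seeds["cv"])
    weights = cfg.weights
    cache: dict = {}

    def fitness(params: np.ndarray):
        key = np.round(params, 12).tobytes()
        if key not in cache:
            cc = evaluate_params(spec, params, data, cv, seed=seeds["train"])
            obj = primary_objectives(cc)
            cache[key] = (cc, obj, scalarize(obj, weights))
        cc, obj, z = cache[key]
        return z, obj

    defaults = default_params(spec)
    if cfg.evolver == "none":
        z, obj = fitness(defaults)
        best_pos = defaults
        archive = (ArchiveEntry(0, 0, defaults.copy(), z, obj),)
        history = np.array([z])
        result = OptimizationResult(defaults, z, history, archive)
    else:
        evolver_cfg = replace(
            cfg.evolver_cfg,
            seed=seeds["evolver"],
            initial_positions=(tuple(defaults),),
        )
        result = EVOLVERS[cfg.evolver](fitness, spec.tunables, evolver_cfg)
        best_pos = result.best_position

    cc, best_obj, best_z = cache[np.round(best_pos, 12).tobytes()]
    return HISResult(
        config=cfg,
        best_params={p.name: float(v) for p, v in zip(spec.tunables, best_pos)},
        best_objectives=best_obj,
        best_z=float(best_z),
        secondary=secondary_metrics(cc),
        confusion={"TP": cc.tp, "TN": cc.tn, "FP": cc.fp, "FN": cc.fn},
        evaluation_archive=result.evaluation_archive,
        fitness_history=result.fitness_history,
        n_evaluations=len(result.evaluation_archive),
        wall_time=time.perf_counter() - t0,
    )


def attach_front_metrics(results, mode: str = "nondominated") -> None:
    """Compute GD/SP for each result against the run-set reference front.

    The reference front is built from every archived objective vector
    across all (successful) results; each result's own front is the
    nondominated set of its archive.  Fronts are min-max normalized over
    the union before metric computation.  A one-point front has SP = 0
    by convention.
    """
    ok = [r for r in results if not r.failed]
    if not ok:
        return
    archives = [
        np.array([e.aux.as_array() for e in r.evaluation_archive]) for r in ok
    ]
    reference = build_reference_front(archives, mode=mode)
    for r, pts in zip(ok, archives):
        q = nondominated(pts)
        qn, rn = normalize_front(q, reference)
        r.gd = generational_distance(qn, rn)
        r.sp = spacing(qn) if len(qn) >= 2 else 0.0


def run_grid(ds: Dataset, base_cfg: HISConfig) -> list:
    """Run all 16 grid cells; per-cell failures are recorded, not raised."""
    results = []
    for idx, (clf, evo, rs) in enumerate(GRID_ORDER):
        cell_seed = int(np.random.SeedSequence((base_cfg.seed, idx)).generate_state(1)[0])
        cfg = replace(base_cfg, classifier=clf, evolver=evo, resample=rs, seed=cell_seed)
        try:
            results.append(run_his(ds, cfg))
        except EvoHISError as exc:  # record and continue
            results.append(
                HISResult(
                    config=cfg,
                    best_params={},
                    best_objectives=ObjectiveVector(0, 0, 0),
                    best_z=float("nan"),
                    secondary={},
                    confusion={},
                    evaluation_archive=(),
                    fitness_history=np.array([]),
                    n_evaluations=0,
                    wall_time=0.0,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    attach_front_metrics(results)
    return results


def select_best(results) -> HISResult:
    """Pick the result with maximal Z; ties broken by higher PAC, then by
    lower (classifier, evolver) enumeration order."""
    ok = [r for r in results if not r.failed]
    if not ok:
        raise ValueError("select_best requires at least one successful result")

    def key(r: HISResult):
        return (
            -r.best_z,
            -r.best_objectives.pac,
            CLASSIFIERS.index(r.config.classifier),
            EVOLVER_ORDER.index(r.config.evolver),
        )

    return min(ok, key=key)
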