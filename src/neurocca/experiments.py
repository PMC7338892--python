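"""Config-driven experiment runner: dataset generation, multi-repeat
training, metric traces and aggregate tables.

An :class:`ExperimentConfig` names a dataset generator and an algorithm
with their parameters; :func:`run_experiment` executes ``repeats``
independently seeded trainings and writes per-run traces, per-metric
mean/SD aggregates, final states and a manifest.  Rerunning a manifest
reproduces every file bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (
    make_correlated_images,
    make_gaussian,
    make_planted_gaussian,
    make_svdmax,
    split_image_quadrants,
    split_image_rows,
)
from .multiview import train_multiview
from .network import train_network, train_nonlocal
from .oracle import solve_cca, solve_multiview_reference
from .schedules import LearningSchedule
from .single import train

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment", "compare_algorithms"]

DATASET_GENERATORS = (
    "gaussian",
    "planted",
    "svd-max",
    "correlated-image-rows",
    "correlated-image-quadrants",
)
ALGORITHMS = ("single", "network-simultaneous", "network-sequential", "nonlocal", "multiview")

# mean over the trailing fraction of logged points used for "final" values
FINAL_WINDOW = 0.05


class ConfigError(ValueError):
    """An experiment config references unknown keys, generators or algorithms."""


@dataclass
class ExperimentConfig:
    """Dataset + algorithm + repeat specification for one experiment.

    ``dataset`` and ``algorithm`` are flat dicts: ``dataset`` needs a
    ``name`` from ``DATASET_GENERATORS`` plus generator parameters and a
    ``seed``; ``algorithm`` needs a ``name`` from ``ALGORITHMS`` plus
    trainer parameters (``d``, ``n_steps``, ``schedule`` sub-dict, ...).
    """

    dataset: dict
    algorithm: dict
    repeats: int = 10
    seed: int = 0
    metric_every: int = 2000
    label: str | None = None

    def __post_init__(self) -> None:
        bad = []
        if self.dataset.get("name") not in DATASET_GENERATORS:
            bad.append(f"dataset.name={self.dataset.get('name')!r}")
        if self.algorithm.get("name") not in ALGORITHMS:
            bad.append(f"algorithm.name={self.algorithm.get('name')!r}")
        if self.repeats < 1:
            bad.append(f"repeats={self.repeats}")
        if bad:
            raise ConfigError(
                "invalid config keys: " + ", ".join(bad)
                + f"; datasets: {DATASET_GENERATORS}; algorithms: {ALGORITHMS}"
            )
        if self.label is None:
            self.label = f"{self.dataset['name']}__{self.algorithm['name']}"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {"dataset", "algorithm", "repeats", "seed", "metric_every", "label"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "algorithm": self.algorithm,
            "repeats": self.repeats,
            "seed": self.seed,
            "metric_every": self.metric_every,
            "label": self.label,
        }


def build_dataset(spec: dict):
    """Instantiate a dataset (and optional ground truth) from its spec dict."""
    spec = dict(spec)
    name = spec.pop("name")
    seed = spec.pop("seed", 0)
    if name == "gaussian":
        return make_gaussian(seed=seed, **spec), None
    if name == "planted":
        return make_planted_gaussian(seed=seed, **spec), None
    if name == "svd-max":
        return make_svdmax(seed=seed, **spec)
    if name == "correlated-image-rows":
        T = spec.pop("T", 10_000)
        H = spec.pop("H", 28)
        W = spec.pop("W", 28)
        ls = spec.pop("length_scale", 3.0)
        row = spec.pop("row_index", H // 2)
        cols_x = tuple(spec.pop("cols_x", (W // 2 - 5, W // 2)))
        cols_y = tuple(spec.pop("cols_y", (W // 2, W // 2 + 5)))
        images = make_correlated_images(T, H, W, ls, seed=seed)
        return split_image_rows(images, row, cols_x, cols_y), None
    if name == "correlated-image-quadrants":
        # 8x8 default: at the constant multiview rate 0.005 the dynamics
        # are stable for 16-dimensional quadrant views; much larger views
        # need a smaller rate
        T = spec.pop("T", 5000)
        H = spec.pop("H", 8)
        W = spec.pop("W", 8)
        ls = spec.pop("length_scale", 2.0)
        images = make_correlated_images(T, H, W, ls, seed=seed)
        return split_image_quadrants(images), None
    raise ConfigError(f"unknown dataset generator {name!r}")


def _schedule_from(spec: dict | None, default: LearningSchedule) -> LearningSchedule:
    if not spec:
        return default
    return LearningSchedule.from_dict(spec)


def _run_one(dataset, ground_truth, algo: dict, seed: int, metric_every: int):
    algo = dict(algo)
    name = algo.pop("name")
    n_steps = algo.pop("n_steps", None)
    sched_spec = algo.pop("schedule", None)
    diverged = False
    if name == "multiview":
        rates = _schedule_from(sched_spec, LearningSchedule.constant(0.005))
        ref = algo.pop("reference", "auto")
        reference = None
        if ref == "auto":
            if ground_truth is not None:
                reference = solve_multiview_reference(dataset, ground_truth)
            else:
                try:
                    reference = solve_multiview_reference(dataset, tol=1e-6)
                except Exception:
                    reference = None
        state, trace = train_multiview(
            dataset, rates=rates, n_steps=n_steps or 10_000_000, seed=seed,
            metric_every=max(metric_every, 10_000), reference_weights=reference, **algo,
        )
        return state, trace, diverged
    oracle = solve_cca(dataset, d=algo.get("d", 3) if name != "single" else 1)
    if name == "single":
        rates = _schedule_from(sched_spec, LearningSchedule())
        state, trace = train(
            dataset, rates=rates, n_steps=n_steps or 400_000, seed=seed,
            metric_every=metric_every, oracle=oracle, **algo,
        )
    elif name in ("network-simultaneous", "network-sequential"):
        rates = _schedule_from(sched_spec, LearningSchedule())
        mode = name.split("-", 1)[1]
        state, trace = train_network(
            dataset, rates=rates, n_steps=n_steps or 400_000, seed=seed, mode=mode,
            metric_every=metric_every, oracle=oracle, **algo,
        )
    else:  # nonlocal
        rates = _schedule_from(sched_spec, LearningSchedule.constant(0.02))
        state, trace = train_nonlocal(
            dataset, rates=rates, n_steps=n_steps or 400_000, seed=seed,
            metric_every=metric_every, oracle=oracle, on_divergence="stop", **algo,
        )
        diverged = "diverged_at" in trace.metadata
    return state, trace, diverged


def _aggregate(traces: list) -> dict:
    """Per-metric frame of step, mean, sd across runs (inner-joined on step)."""
    out = {}
    names = sorted(set().union(*(t.metrics for t in traces)))
    for name in names:
        series = []
        for i, t in enumerate(traces):
            if name in t.metrics:
                s, v = t.series(name)
                series.append(pd.Series(v, index=s, name=f"run{i}"))
        frame = pd.concat(series, axis=1, join="inner")
        out[name] = pd.DataFrame(
            {"step": frame.index, "mean": frame.mean(axis=1), "sd": frame.std(axis=1, ddof=0)}
        ).reset_index(drop=True)
    return out


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Run ``config.repeats`` seeded trainings; write traces, aggregates,
    final states and a manifest under ``out_dir``.  Returns ``out_dir``.

    Run ``r`` trains with seed ``config.seed + r``.  Divergences are
    recorded in the manifest (the nonlocal baseline is allowed to
    diverge; any other algorithm re-raises).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset, ground_truth = build_dataset(config.dataset)
    traces, divergences = [], []
    for r in range(config.repeats):
        run_seed = config.seed + r
        state, trace, diverged = _run_one(
            dataset, ground_truth, config.algorithm, run_seed, config.metric_every
        )
        trace.metadata.update({"dataset": config.dataset, "run": r, "seed": run_seed})
        trace.to_csv(out_dir / f"run{r:02d}_trace.csv")
        state.to_json(out_dir / f"run{r:02d}_state.json")
        traces.append(trace)
        divergences.append(diverged)
    for name, frame in _aggregate(traces).items():
        frame.to_csv(out_dir / f"aggregate_{name}.csv", index=False)
    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "seeds": [config.seed + r for r in range(config.repeats)],
        "diverged": divergences,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def final_table(traces: list, label: str) -> pd.DataFrame:
    """Final-window (trailing 5% of logged points) mean and SD per metric."""
    rows = []
    names = sorted(set().union(*(t.metrics for t in traces)))
    for name in names:
        finals = [
            t.final_window_mean(name, FINAL_WINDOW) for t in traces if name in t.metrics
        ]
        rows.append(
            {
                "algorithm": label,
                "metric": name,
                "final_mean": float(np.mean(finals)),
                "final_sd": float(np.std(finals)),
                "n_runs": len(finals),
            }
        )
    return pd.DataFrame(rows)


def compare_algorithms(configs: list, out_dir=None) -> pd.DataFrame:
    """Run several configs on a shared dataset spec; tabulate final metrics.

    All configs must name the identical dataset spec.  Returns a frame of
    final-window mean and SD per metric per algorithm, the tabular
    analogue of the convergence-curve figures.
    """
    if not configs:
        raise ValueError("need at least one config")
    ds_spec = configs[0].dataset
    for c in configs[1:]:
        if c.dataset != ds_spec:
            raise ValueError("compare_algorithms requires a shared dataset spec")
    dataset, ground_truth = build_dataset(ds_spec)
    tables = []
    for c in configs:
        traces = []
        for r in range(c.repeats):
            _, trace, _ = _run_one(
                dataset, ground_truth, c.algorithm, c.seed + r, c.metric_every
            )
            traces.append(trace)
        tables.append(final_table(traces, c.label))
    result = pd.concat(tables, ignore_index=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.to_csv(out_dir / "comparison.csv", index=False)
    return result
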