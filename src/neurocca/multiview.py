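"""Online multiview (sum-of-correlations) CCA by a k-compartment neuron.

Each of the ``k`` dendritic compartments receives one view and computes
a current ``c^(i) = a^(i)' x^(i)``; the soma outputs their sum ``c``.
Every compartment runs the same plasticity as the two-compartment
neuron:

    a^(i)     <- a^(i) + eta_a^(i) (c - alpha^(i) c^(i)) x^(i)
    alpha^(i) <- alpha^(i) + eta_alpha^(i)/2 (c^(i)^2 - 1)

which ascends the sum-of-pairwise-correlations objective under unit
projection-variance constraints.  With ``k = 2`` this is exactly the
single-channel neuron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from .datasets import MultiviewDataset
from .metrics import MetricTrace, absolute_objective, multiview_angular_error
from .schedules import LearningSchedule
from .single import DivergenceError, WEIGHT_GUARD

__all__ = [
    "MultiviewState",
    "MultiviewCurrents",
    "mv_forward",
    "mv_update",
    "train_multiview",
    "variance_contribution",
]


@dataclass
class MultiviewState:
    """Per-view weight vectors and dendritic variables of one k-compartment neuron."""

    weights: list
    alphas: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=np.float64) for w in self.weights]
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=np.float64))
        if len(self.weights) < 2:
            raise ValueError("need k >= 2 views")
        if self.alphas.size != len(self.weights):
            raise ValueError("one alpha per view required")

    @property
    def k(self) -> int:
        return len(self.weights)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "weights": [w.tolist() for w in self.weights],
                "alphas": self.alphas.tolist(),
                "t": self.t,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "MultiviewState":
        d = json.loads(text)
        return cls([np.asarray(w) for w in d["weights"]], np.asarray(d["alphas"]), d["t"])


@dataclass(frozen=True)
class MultiviewCurrents:
    """Compartment currents and their somatic sum."""

    c_view: np.ndarray
    c: float


def mv_forward(state: MultiviewState, *inputs) -> MultiviewCurrents:
    """Compartment currents ``c^(i) = a^(i)'x^(i)`` and output ``c``."""
    if len(inputs) == 1 and isinstance(inputs[0], (list, tuple)):
        inputs = tuple(inputs[0])
    if len(inputs) != state.k:
        raise ValueError(f"expected {state.k} inputs, got {len(inputs)}")
    c_view = np.empty(state.k)
    for i, (w, x) in enumerate(zip(state.weights, inputs)):
        x = np.asarray(x, dtype=np.float64)
        if x.shape != w.shape:
            raise ValueError(f"view {i} input dim {x.shape} != weight dim {w.shape}")
        c_view[i] = w @ x
    return MultiviewCurrents(c_view, float(c_view.sum()))


def mv_update(
    state: MultiviewState,
    inputs,
    currents: MultiviewCurrents,
    rates: LearningSchedule | list,
) -> MultiviewState:
    """One plasticity step (all compartments); returns a new state."""
    per_view = rates if isinstance(rates, (list, tuple)) else [rates] * state.k
    weights = []
    alphas = np.empty(state.k)
    for i, (w, x, r) in enumerate(zip(state.weights, inputs, per_view)):
        f = r.factor(state.t)
        g = currents.c - state.alphas[i] * currents.c_view[i]
        weights.append(w + (r.rate_a * f) * g * np.asarray(x, dtype=np.float64))
        alphas[i] = state.alphas[i] + 0.5 * (r.rate_alpha * f) * (
            currents.c_view[i] ** 2 - 1.0
        )
    new = MultiviewState(weights, alphas, state.t + 1)
    if not all(np.all(np.isfinite(w)) for w in weights) or not np.all(np.isfinite(alphas)):
        raise DivergenceError(new.t)
    return new


def train_multiview(
    dataset: MultiviewDataset,
    rates: LearningSchedule | None = None,
    n_steps: int = 10_000_000,
    seed: int = 0,
    init_scale: float = 1.0,
    metric_every: int = 50_000,
    reference_weights=None,
):
    """Train the k-compartment neuron online.

    Weights are initialized i.i.d. standard Gaussian per view, dendritic
    variables at zero; the default schedule is a constant shared rate of
    0.005.  The trace records the mean pairwise projection correlation
    (``absolute_objective``), per-view projection variances, and — when
    ``reference_weights`` are given — the multiview angular error.

    Returns ``(MultiviewState, MetricTrace)``.
    """
    if rates is None:
        rates = LearningSchedule.constant(0.005)
    per_view = rates if isinstance(rates, (list, tuple)) else [rates] * dataset.k
    if len(per_view) != dataset.k:
        raise ValueError("one LearningSchedule per view required")
    decays = {(r.decay, r.slope, r.floor) for r in per_view}
    if len(decays) > 1:
        raise ValueError("per-view schedules must share the decay profile")
    rng = np.random.default_rng(seed)
    w = np.concatenate(
        [init_scale * rng.standard_normal(ni) for ni in dataset.dims]
    )
    alphas = np.zeros(dataset.k)
    idx = rng.integers(0, dataset.T, size=n_steps)

    offsets = np.concatenate([[0], np.cumsum(dataset.dims)]).astype(np.int64)
    Xc = np.ascontiguousarray(np.concatenate(dataset.views, axis=1))
    ba = np.array([r.rate_a for r in per_view])
    balpha = np.array([r.rate_alpha for r in per_view])
    cview = np.empty(dataset.k)
    T = dataset.T
    sched = per_view[0]

    trace = MetricTrace(metadata={"algorithm": "multiview", "k": dataset.k,
                                  "seed": seed, "n_steps": n_steps})

    def split(wvec):
        return [wvec[offsets[i] : offsets[i + 1]].copy() for i in range(dataset.k)]

    def record(step):
        ws = split(w)
        cs = np.stack([v @ wi for v, wi in zip(dataset.views, ws)])
        var = (cs * cs).sum(axis=1) / T
        if np.all(var > 0):
            trace.log(step, "absolute_objective", absolute_objective(ws, dataset))
        for i, v in enumerate(var):
            trace.log(step, f"variance_view{i}", float(v))
        if reference_weights is not None and np.all(var > 0):
            trace.log(step, "angular_error",
                      multiview_angular_error(ws, dataset, reference_weights))

    record(0)
    done = 0
    while done < n_steps:
        chunk = min(metric_every, n_steps - done)
        fac = sched.factors(done, chunk)
        _kernels.multiview_chunk(Xc, offsets, idx[done : done + chunk], fac,
                                 ba, balpha, w, alphas, cview)
        done += chunk
        if not np.all(np.isfinite(w)) or np.abs(w).max() > WEIGHT_GUARD:
            raise DivergenceError(done, trace=trace)
        record(done)
    return MultiviewState(split(w), alphas, done), trace


def variance_contribution(state: MultiviewState, dataset: MultiviewDataset) -> list:
    """Per-input variance contribution ``u_i = (1/T) sum_t (a_i x_{i,t})^2``.

    Returned per view, in input order; for image-derived views this maps
    back to pixel positions and shows where the learned weights
    concentrate.
    """
    out = []
    for w, v in zip(state.weights, dataset.views):
        out.append(np.mean((v * w) ** 2, axis=0))
    return out
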