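"""Online single-channel CCA as a two-compartment pyramidal neuron.

The neuron receives one input stream on its distal dendrite (weights
``a``, current ``c_a = a'x``) and another on its proximal dendrite
(weights ``b``, current ``c_b = b'y``); the somatic output is
``c = c_a + c_b``.  Stochastic gradient ascent on the weights and
descent on the per-compartment variance multipliers ``alpha, beta``
drives ``(a, b)`` to the top canonical pair, up to a joint sign:

    a     <- a + eta_a (c - alpha c_a) x
    b     <- b + eta_b (c - beta  c_b) y
    alpha <- alpha + eta_alpha/2 (c_a^2 - 1)
    beta  <- beta  + eta_beta /2 (c_b^2 - 1)

At the fixed point the projection variances equal 1 and
``alpha = beta = 1 + rho_1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from .datasets import PairedDataset
from .metrics import MetricTrace, PairedMoments
from .schedules import LearningSchedule

__all__ = ["SingleState", "Currents", "DivergenceError", "forward", "update", "train"]

WEIGHT_GUARD = 1e6  # abort when any |weight| exceeds this


class DivergenceError(FloatingPointError):
    """Training produced non-finite or runaway state."""

    def __init__(self, step: int, message: str = "", trace: MetricTrace | None = None):
        super().__init__(message or f"training diverged by step {step}")
        self.step = step
        self.trace = trace


@dataclass
class SingleState:
    """Synaptic weights and dendritic variables of one pyramidal neuron."""

    a: np.ndarray
    b: np.ndarray
    alpha: float = 0.0
    beta: float = 0.0
    t: int = 0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "a": self.a.tolist(),
                "b": self.b.tolist(),
                "alpha": self.alpha,
                "beta": self.beta,
                "t": self.t,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "SingleState":
        d = json.loads(text)
        return cls(np.asarray(d["a"]), np.asarray(d["b"]), d["alpha"], d["beta"], d["t"])


@dataclass(frozen=True)
class Currents:
    """Dendritic currents and somatic output for one presented sample."""

    c_a: float
    c_b: float
    c: float


def forward(state: SingleState, x: np.ndarray, y: np.ndarray) -> Currents:
    """Compute distal/proximal currents and the somatic output."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != state.a.shape or y.shape != state.b.shape:
        raise ValueError(
            f"input dims {x.shape}/{y.shape} do not match weights "
            f"{state.a.shape}/{state.b.shape}"
        )
    c_a = float(state.a @ x)
    c_b = float(state.b @ y)
    return Currents(c_a, c_b, c_a + c_b)


def update(
    state: SingleState,
    x: np.ndarray,
    y: np.ndarray,
    currents: Currents,
    rates: LearningSchedule,
) -> SingleState:
    """One plasticity step; returns a new state with ``t`` incremented."""
    f = rates.factor(state.t)
    ga = currents.c - state.alpha * currents.c_a
    gb = currents.c - state.beta * currents.c_b
    a = state.a + (rates.rate_a * f) * ga * np.asarray(x, dtype=np.float64)
    b = state.b + (rates.rate_b * f) * gb * np.asarray(y, dtype=np.float64)
    alpha = state.alpha + 0.5 * (rates.rate_alpha * f) * (currents.c_a**2 - 1.0)
    beta = state.beta + 0.5 * (rates.rate_beta * f) * (currents.c_b**2 - 1.0)
    new = SingleState(a, b, alpha, beta, state.t + 1)
    if not (
        np.all(np.isfinite(a)) and np.all(np.isfinite(b)) and np.isfinite(alpha) and np.isfinite(beta)
    ):
        raise DivergenceError(new.t)
    return new


def _check_finite(step: int, trace: MetricTrace, *arrays) -> None:
    for arr in arrays:
        a = np.asarray(arr)
        if not np.all(np.isfinite(a)) or np.abs(a).max() > WEIGHT_GUARD:
            raise DivergenceError(step, trace=trace)


def train(
    dataset: PairedDataset,
    rates: LearningSchedule | None = None,
    n_steps: int = 400_000,
    seed: int = 0,
    init_scale: float = 1.0,
    metric_every: int = 2000,
    metric_hooks: dict | None = None,
    oracle=None,
):
    """Train one pyramidal neuron online on a centered paired dataset.

    Weights are initialized i.i.d. standard Gaussian (scaled by
    ``init_scale``), dendritic variables at zero.  Each step presents one
    uniformly resampled stored sample.  Every ``metric_every`` steps the
    trace records the projection correlation, projection variances and
    dendritic variables (plus ``angular_error`` when an oracle
    ``CCASolution`` is given, and any ``metric_hooks``:
    ``{name: fn(state) -> float}``).

    Returns ``(SingleState, MetricTrace)``.  Fully reproducible: the seed
    drives both the initialization and the sample stream.
    """
    if not dataset.centered:
        raise ValueError("dataset must be centered before online training")
    if rates is None:
        rates = LearningSchedule()
    rng = np.random.default_rng(seed)
    a = init_scale * rng.standard_normal(dataset.n)
    b = init_scale * rng.standard_normal(dataset.m)
    ab = np.array([0.0, 0.0])
    idx = rng.integers(0, dataset.T, size=n_steps)

    mom = PairedMoments(dataset)
    if oracle is not None and oracle.d > 1:
        from .oracle import CCASolution

        oracle = CCASolution(oracle.A[:, :1], oracle.B[:, :1], oracle.rho[:1])
    trace = MetricTrace(metadata={"algorithm": "single", "seed": seed, "n_steps": n_steps})

    def record(step: int) -> None:
        va = a @ mom.Cxx @ a
        vb = b @ mom.Cyy @ b
        corr = (a @ mom.Cxy @ b) / np.sqrt(va * vb) if va > 0 and vb > 0 else np.nan
        trace.log(step, "objective_corr", corr)
        trace.log(step, "variance_a", va)
        trace.log(step, "variance_b", vb)
        trace.log(step, "alpha", ab[0])
        trace.log(step, "beta", ab[1])
        if oracle is not None:
            from .metrics import angular_error

            trace.log(step, "angular_error", angular_error(a, b, mom, oracle))
        for name, fn in (metric_hooks or {}).items():
            trace.log(step, name, fn(SingleState(a, b, ab[0], ab[1], step)))

    record(0)
    done = 0
    while done < n_steps:
        chunk = min(metric_every, n_steps - done)
        fac = rates.factors(done, chunk)
        _kernels.single_chunk(
            dataset.X, dataset.Y, idx[done : done + chunk], fac,
            rates.rate_a, rates.rate_b, rates.rate_alpha, rates.rate_beta,
            a, b, ab,
        )
        done += chunk
        _check_finite(done, trace, a, b, ab)
        record(done)
    return SingleState(a, b, float(ab[0]), float(ab[1]), done), trace
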