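"""Multi-channel CCA by a network of pyramidal neurons with asymmetric
anti-Hebbian lateral connections.

Neuron ``i`` extracts the ``i``-th canonical pair.  Its somatic output
subtracts lateral input from neurons ``j < i`` only (strictly
lower-triangular lateral matrix ``M``), realizing deflation in the
architecture:

    c_i = c^a_i + c^b_i - sum_{j<i} M[i,j] c_j

Synaptic updates are those of the single neuron driven by ``c_i``; the
lateral weights learn with the local anti-Hebbian rule
``M[i,j] += eta_m c_i c_j`` and decay to zero at the fixed point.  The
network can be trained with all neurons learning simultaneously or
sequentially (each neuron trained to convergence while its predecessors
are frozen).

The module also provides the non-local baseline derived from the
standard multi-channel Lagrangian, whose decorrelation multipliers
require access to the individual dendritic currents of other neurons.
It is included because — unlike the deflation network — it fails to
converge under online training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .datasets import PairedDataset
from .metrics import MetricTrace, PairedMoments, angular_error, normalized_objective
from .schedules import LearningSchedule
from .single import DivergenceError, WEIGHT_GUARD

__all__ = [
    "NetworkState",
    "NetworkCurrents",
    "NonlocalState",
    "network_forward",
    "network_update",
    "train_network",
    "nonlocal_update",
    "train_nonlocal",
]


def _assert_strictly_lower(M: np.ndarray) -> None:
    if np.any(np.triu(M) != 0):
        raise ValueError("M must be strictly lower triangular (M[i,j] = 0 for j >= i)")


@dataclass
class NetworkState:
    """Synaptic state of a d-neuron CCA network.

    ``A`` (n x d) and ``B`` (m x d) hold one neuron per *column*; ``M``
    (d x d) is strictly lower triangular at all times.
    """

    A: np.ndarray
    B: np.ndarray
    M: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        self.M = np.asarray(self.M, dtype=np.float64)
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=np.float64))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        _assert_strictly_lower(self.M)

    @property
    def d(self) -> int:
        return self.A.shape[1]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "A": self.A.tolist(),
                "B": self.B.tolist(),
                "M": self.M.tolist(),
                "alpha": self.alpha.tolist(),
                "beta": self.beta.tolist(),
                "t": self.t,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "NetworkState":
        d = json.loads(text)
        return cls(
            np.asarray(d["A"]), np.asarray(d["B"]), np.asarray(d["M"]),
            np.asarray(d["alpha"]), np.asarray(d["beta"]), d["t"],
        )


@dataclass(frozen=True)
class NetworkCurrents:
    """Per-neuron dendritic currents and lateral-corrected outputs."""

    c_a: np.ndarray
    c_b: np.ndarray
    c: np.ndarray


@dataclass
class NonlocalState:
    """State of the non-local multi-channel baseline.

    ``Gamma_a``/``Gamma_b`` are the symmetric, zero-diagonal Lagrange
    multipliers of the distal/proximal decorrelation constraints.
    """

    A: np.ndarray
    B: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    Gamma_a: np.ndarray
    Gamma_b: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=np.float64))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        self.Gamma_a = np.asarray(self.Gamma_a, dtype=np.float64)
        self.Gamma_b = np.asarray(self.Gamma_b, dtype=np.float64)
        for name, G in (("Gamma_a", self.Gamma_a), ("Gamma_b", self.Gamma_b)):
            if np.any(np.diag(G) != 0):
                raise ValueError(f"{name} must have a zero diagonal")

    @property
    def d(self) -> int:
        return self.A.shape[1]


def network_forward(state: NetworkState, x: np.ndarray, y: np.ndarray) -> NetworkCurrents:
    """One feed-forward pass; no settling needed since ``M`` is strictly lower."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape[0] != state.A.shape[0] or y.shape[0] != state.B.shape[0]:
        raise ValueError("input dims do not match network weights")
    c_a = state.A.T @ x
    c_b = state.B.T @ y
    c = np.empty(state.d)
    for i in range(state.d):
        c[i] = c_a[i] + c_b[i] - state.M[i, :i] @ c[:i]
    return NetworkCurrents(c_a, c_b, c)


def network_update(
    state: NetworkState,
    x: np.ndarray,
    y: np.ndarray,
    currents: NetworkCurrents,
    rates: LearningSchedule,
    local_rule: bool = True,
) -> NetworkState:
    """One plasticity step for every neuron; returns a new state.

    ``local_rule=True`` (default) uses the anti-Hebbian lateral update
    ``M[i,j] += eta_m c_i c_j``; ``False`` uses the
    ``(c^a_i + c^b_i) c_j`` form that needs compartment access.
    """
    f = rates.factor(state.t)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ga = currents.c - state.alpha * currents.c_a
    gb = currents.c - state.beta * currents.c_b
    A = state.A + (rates.rate_a * f) * np.outer(x, ga)
    B = state.B + (rates.rate_b * f) * np.outer(y, gb)
    drive = currents.c if local_rule else currents.c_a + currents.c_b
    M = state.M + (rates.rate_m * f) * np.tril(np.outer(drive, currents.c), k=-1)
    alpha = state.alpha + 0.5 * (rates.rate_alpha * f) * (currents.c_a**2 - 1.0)
    beta = state.beta + 0.5 * (rates.rate_beta * f) * (currents.c_b**2 - 1.0)
    new = NetworkState(A, B, M, alpha, beta, state.t + 1)
    if not all(np.all(np.isfinite(v)) for v in (A, B, M, alpha, beta)):
        raise DivergenceError(new.t)
    return new


def _truncate_oracle(oracle, d: int):
    """Restrict an exact solution to its top-d components for metrics."""
    if oracle is None or oracle.d == d:
        return oracle
    if oracle.d < d:
        raise ValueError(f"oracle has {oracle.d} components, trainer needs {d}")
    from .oracle import CCASolution

    return CCASolution(oracle.A[:, :d], oracle.B[:, :d], oracle.rho[:d])


def _record_network(trace, step, Ar, Br, M, alpha, beta, mom, oracle):
    A, B = Ar.T, Br.T
    trace.log(step, "max_abs_M", float(np.abs(M).max()) if M.size else 0.0)
    va = np.einsum("ij,jk,ki->i", A.T, mom.Cxx, A)
    vb = np.einsum("ij,jk,ki->i", B.T, mom.Cyy, B)
    trace.log(step, "mean_variance_violation",
              float(np.mean(np.abs(np.concatenate([va, vb]) - 1.0))))
    if oracle is not None:
        trace.log(step, "normalized_objective", normalized_objective(A, B, mom, oracle))
        trace.log(step, "angular_error", angular_error(A, B, mom, oracle))


def train_network(
    dataset: PairedDataset,
    d: int = 3,
    rates: LearningSchedule | None = None,
    n_steps: int = 400_000,
    seed: int = 0,
    mode: str = "simultaneous",
    init_scale: float = 1.0,
    metric_every: int = 2000,
    oracle=None,
    local_rule: bool = True,
    seq_window: int = 1000,
    seq_tol: float = 1e-4,
    lateral_removal: str = "auto",
):
    """Train the d-neuron CCA network online.

    ``mode="simultaneous"`` trains all neurons at once through the
    asymmetric lateral architecture.  ``mode="sequential"`` gives each
    neuron an equal share of ``n_steps`` and trains it with its
    predecessors frozen, declaring convergence when the relative weight
    change over a ``seq_window``-step window falls below ``seq_tol``;
    on freezing, a neuron's lateral weights are removed (they decay to
    zero at the fixed point — ``lateral_removal`` is ``"auto"`` (zero
    them if decayed, else keep and warn), ``"zero"`` or ``"keep"``).

    ``A`` and ``B`` are initialized standard Gaussian, ``M`` at zero,
    dendritic variables at zero.  Default rates are the linearly
    floored schedule (base 0.02, slope 5e-6, floor 0.1); sequential mode
    restarts the schedule for each neuron.

    Returns ``(NetworkState, MetricTrace)``.
    """
    if not dataset.centered:
        raise ValueError("dataset must be centered before online training")
    if not (1 <= d <= min(dataset.n, dataset.m)):
        raise ValueError(f"d={d} must lie in [1, {min(dataset.n, dataset.m)}]")
    if mode not in ("simultaneous", "sequential"):
        raise ValueError("mode must be 'simultaneous' or 'sequential'")
    if lateral_removal not in ("auto", "zero", "keep"):
        raise ValueError("lateral_removal must be 'auto', 'zero' or 'keep'")
    if rates is None:
        rates = LearningSchedule()
    oracle = _truncate_oracle(oracle, d)
    rng = np.random.default_rng(seed)
    # row-major draws so the d=1 stream matches the single neuron's
    Ar = np.ascontiguousarray(init_scale * rng.standard_normal((dataset.n, d)).T)
    Br = np.ascontiguousarray(init_scale * rng.standard_normal((dataset.m, d)).T)
    M = np.zeros((d, d))
    alpha = np.zeros(d)
    beta = np.zeros(d)
    idx = rng.integers(0, dataset.T, size=n_steps)
    ca, cb, c = np.empty(d), np.empty(d), np.empty(d)

    mom = PairedMoments(dataset)
    trace = MetricTrace(
        metadata={"algorithm": f"network-{mode}", "d": d, "seed": seed, "n_steps": n_steps}
    )
    rule_flag = 1 if local_rule else 0

    def run_chunk(lo: int, hi: int, gate: np.ndarray, t0: int) -> None:
        fac = rates.factors(t0, hi - lo)
        _kernels.network_chunk(
            dataset.X, dataset.Y, idx[lo:hi], fac,
            rates.rate_a, rates.rate_b, rates.rate_alpha, rates.rate_beta, rates.rate_m,
            gate, Ar, Br, M, alpha, beta, ca, cb, c, rule_flag,
        )
        for arr in (Ar, Br, M, alpha, beta):
            if not np.all(np.isfinite(arr)) or (arr.size and np.abs(arr).max() > WEIGHT_GUARD):
                raise DivergenceError(hi, trace=trace)

    _record_network(trace, 0, Ar, Br, M, alpha, beta, mom, oracle)
    if mode == "simultaneous":
        gate = np.ones(d)
        done = 0
        while done < n_steps:
            chunk = min(metric_every, n_steps - done)
            run_chunk(done, done + chunk, gate, done)
            done += chunk
            _record_network(trace, done, Ar, Br, M, alpha, beta, mom, oracle)
    else:
        budget = n_steps // d
        done = 0
        for neuron in range(d):
            gate = np.zeros(d)
            gate[neuron] = 1.0
            local_t = 0
            converged = False
            prev = np.concatenate([Ar[neuron], Br[neuron]])
            check_every = max(seq_window, metric_every)
            while local_t < budget:
                chunk = min(check_every, budget - local_t)
                run_chunk(done, done + chunk, gate, local_t)
                done += chunk
                local_t += chunk
                _record_network(trace, done, Ar, Br, M, alpha, beta, mom, oracle)
                cur = np.concatenate([Ar[neuron], Br[neuron]])
                rel = np.linalg.norm(cur - prev) / (np.linalg.norm(prev) + 1e-30)
                prev = cur
                # scale the per-window change to the convergence window
                if rel * (seq_window / chunk) < seq_tol and local_t >= 2 * check_every:
                    converged = True
                    break
            if not converged:
                warnings.warn(
                    f"sequential mode: neuron {neuron} did not meet the convergence "
                    f"criterion within its {budget}-step budget", RuntimeWarning,
                )
                trace.log(done, f"neuron{neuron}_converged", 0.0)
            else:
                trace.log(done, f"neuron{neuron}_converged", 1.0)
            decayed = np.abs(M[neuron, :neuron]).max() < 0.1 if neuron else True
            if lateral_removal == "zero" or (lateral_removal == "auto" and decayed):
                M[neuron, :] = 0.0
            elif lateral_removal == "auto":
                warnings.warn(
                    f"sequential mode: neuron {neuron} lateral weights did not decay "
                    "below 0.1; keeping them", RuntimeWarning,
                )
    state = NetworkState(Ar.T.copy(), Br.T.copy(), M, alpha, beta, done)
    return state, trace


def nonlocal_update(
    state: NonlocalState,
    x: np.ndarray,
    y: np.ndarray,
    rates: LearningSchedule,
) -> NonlocalState:
    """One step of the non-local baseline (reference implementation)."""
    f = rates.factor(state.t)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ca = state.A.T @ x
    cb = state.B.T @ y
    csum = ca + cb
    ga = csum - state.alpha * ca - state.Gamma_a @ ca
    gb = csum - state.beta * cb - state.Gamma_b @ cb
    A = state.A + (rates.rate_a * f) * np.outer(x, ga)
    B = state.B + (rates.rate_b * f) * np.outer(y, gb)
    off = 1.0 - np.eye(state.d)
    Ga = state.Gamma_a + (rates.rate_m * f) * np.outer(ca, ca) * off
    Gb = state.Gamma_b + (rates.rate_m * f) * np.outer(cb, cb) * off
    alpha = state.alpha + 0.5 * (rates.rate_alpha * f) * (ca**2 - 1.0)
    beta = state.beta + 0.5 * (rates.rate_beta * f) * (cb**2 - 1.0)
    new = NonlocalState(A, B, alpha, beta, Ga, Gb, state.t + 1)
    if not all(np.all(np.isfinite(v)) for v in (A, B, Ga, Gb, alpha, beta)):
        raise DivergenceError(new.t)
    return new


def train_nonlocal(
    dataset: PairedDataset,
    d: int = 3,
    rates: LearningSchedule | None = None,
    n_steps: int = 400_000,
    seed: int = 0,
    init_scale: float = 1.0,
    metric_every: int = 2000,
    oracle=None,
    on_divergence: str = "raise",
):
    """Train the non-local multi-channel baseline online.

    Same initialization and (by default constant, base 0.02) rates as
    the deflation network.  ``on_divergence="stop"`` returns the last
    finite state and the trace up to failure instead of raising — the
    baseline is expected not to converge, and often blows up.

    Returns ``(NonlocalState, MetricTrace)``.
    """
    if not dataset.centered:
        raise ValueError("dataset must be centered before online training")
    if on_divergence not in ("raise", "stop"):
        raise ValueError("on_divergence must be 'raise' or 'stop'")
    if rates is None:
        rates = LearningSchedule.constant(0.02)
    oracle = _truncate_oracle(oracle, d)
    rng = np.random.default_rng(seed)
    Ar = np.ascontiguousarray(init_scale * rng.standard_normal((dataset.n, d)).T)
    Br = np.ascontiguousarray(init_scale * rng.standard_normal((dataset.m, d)).T)
    Ga = np.zeros((d, d))
    Gb = np.zeros((d, d))
    alpha = np.zeros(d)
    beta = np.zeros(d)
    idx = rng.integers(0, dataset.T, size=n_steps)
    ca, cb = np.empty(d), np.empty(d)

    mom = PairedMoments(dataset)
    trace = MetricTrace(metadata={"algorithm": "nonlocal", "d": d, "seed": seed,
                                  "n_steps": n_steps})

    def record(step):
        A, B = Ar.T, Br.T
        va = np.einsum("ij,jk,ki->i", A.T, mom.Cxx, A)
        vb = np.einsum("ij,jk,ki->i", B.T, mom.Cyy, B)
        trace.log(step, "mean_variance_violation",
                  float(np.mean(np.abs(np.concatenate([va, vb]) - 1.0))))
        if oracle is not None:
            trace.log(step, "normalized_objective",
                      normalized_objective(A, B, mom, oracle))
            trace.log(step, "angular_error", angular_error(A, B, mom, oracle))

    record(0)
    snapshot = (Ar.copy(), Br.copy(), Ga.copy(), Gb.copy(), alpha.copy(), beta.copy())
    done = 0
    while done < n_steps:
        chunk = min(metric_every, n_steps - done)
        fac = rates.factors(done, chunk)
        _kernels.nonlocal_chunk(
            dataset.X, dataset.Y, idx[done : done + chunk], fac,
            rates.rate_a, rates.rate_b, rates.rate_alpha, rates.rate_beta, rates.rate_m,
            Ar, Br, Ga, Gb, alpha, beta, ca, cb,
        )
        done += chunk
        bad = any(
            not np.all(np.isfinite(arr)) or np.abs(arr).max() > WEIGHT_GUARD
            for arr in (Ar, Br, Ga, Gb, alpha, beta)
        )
        if bad:
            if on_divergence == "raise":
                raise DivergenceError(done, trace=trace)
            trace.metadata["diverged_at"] = done
            Ar, Br, Ga, Gb, alpha, beta = snapshot
            break
        snapshot = (Ar.copy(), Br.copy(), Ga.copy(), Gb.copy(), alpha.copy(), beta.copy())
        record(done)
    state = NonlocalState(Ar.T.copy(), Br.T.copy(), alpha, beta, Ga, Gb, done)
    return state, trace
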