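"""Evaluation metrics for online CCA training.

All metrics are computed from ``1/T``-normalized sample second moments.
The two angular metrics resolve the inherent sign ambiguity of the
online algorithms (a solution and its negation are equally optimal):
per-component joint sign alignment for the multichannel metric, one
global sign flip for the multiview metric.  Alignment lives here, never
in the trainers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MultiviewDataset, PairedDataset
from .oracle import CCASolution

__all__ = [
    "MetricTrace",
    "UndefinedMetricError",
    "PairedMoments",
    "normalized_objective",
    "angular_error",
    "absolute_objective",
    "multiview_angular_error",
    "constraint_violations",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined (zero variance or zero norm in a denominator)."""


# ---------------------------------------------------------------------------
# trace container
# ---------------------------------------------------------------------------

@dataclass
class MetricTrace:
    """Time-indexed record of named metrics over a training run.

    Stored long-form as ``(step, metric, value)`` rows; steps must be
    nondecreasing within each metric.
    """

    metadata: dict = field(default_factory=dict)
    _steps: dict = field(default_factory=dict, repr=False)
    _values: dict = field(default_factory=dict, repr=False)

    def log(self, step: int, name: str, value: float) -> None:
        steps = self._steps.setdefault(name, [])
        if steps and step < steps[-1]:
            raise ValueError(f"steps must be nondecreasing for {name!r}")
        steps.append(int(step))
        self._values.setdefault(name, []).append(float(value))

    @property
    def metrics(self) -> list:
        return sorted(self._steps)

    def series(self, name: str):
        """``(steps, values)`` arrays for one metric."""
        return np.asarray(self._steps[name]), np.asarray(self._values[name])

    def final(self, name: str) -> float:
        return self._values[name][-1]

    def final_window_mean(self, name: str, frac: float = 0.05) -> float:
        """Mean over the trailing ``frac`` of logged points (at least one)."""
        v = self._values[name]
        k = max(1, int(round(frac * len(v))))
        return float(np.mean(v[-k:]))

    def smoothed(self, name: str, window: int = 9):
        """Centered moving average for presentation (never for acceptance)."""
        steps, vals = self.series(name)
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.concatenate([np.repeat(vals[0], pad), vals, np.repeat(vals[-1], pad)])
        return steps, np.convolve(padded, kernel, mode="valid")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, name, v)
            for name in self.metrics
            for s, v in zip(self._steps[name], self._values[name])
        ]
        return pd.DataFrame(rows, columns=["step", "metric", "value"])

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if self.metadata:
            path.with_suffix(".meta.json").write_text(json.dumps(self.metadata, indent=2))
        return path

    @classmethod
    def from_csv(cls, path) -> "MetricTrace":
        path = Path(path)
        frame = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        trace = cls(metadata=json.loads(meta_path.read_text()) if meta_path.exists() else {})
        for _, row in frame.iterrows():
            trace.log(int(row["step"]), str(row["metric"]), float(row["value"]))
        return trace


# ---------------------------------------------------------------------------
# second moments
# ---------------------------------------------------------------------------

class PairedMoments:
    """Cached ``1/T`` second moments of a paired dataset."""

    def __init__(self, dataset: PairedDataset):
        T = dataset.T
        self.Cxx = dataset.X.T @ dataset.X / T
        self.Cyy = dataset.Y.T @ dataset.Y / T
        self.Cxy = dataset.X.T @ dataset.Y / T


def _as_moments(dataset) -> PairedMoments:
    return dataset if isinstance(dataset, PairedMoments) else PairedMoments(dataset)


def _columns(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=np.float64)
    return W[:, None] if W.ndim == 1 else W


# ---------------------------------------------------------------------------
# multichannel metrics
# ---------------------------------------------------------------------------

def pooled_objective(A, B, dataset) -> float:
    """Pooled correlation objective of weight matrices ``A`` (n x d), ``B`` (m x d).

    Numerator: sum over components of the projection cross-moments;
    denominator: product of the square roots of the pooled (summed over
    components) projection variances.
    """
    mom = _as_moments(dataset)
    A, B = _columns(A), _columns(B)
    num = float(np.einsum("ij,jk,ki->", A.T, mom.Cxy, B))
    va = float(np.einsum("ij,jk,ki->", A.T, mom.Cxx, A))
    vb = float(np.einsum("ij,jk,ki->", B.T, mom.Cyy, B))
    if va <= 0 or vb <= 0:
        raise UndefinedMetricError("pooled projection variance is zero")
    return num / np.sqrt(va * vb)


def normalized_objective(A, B, dataset, oracle: CCASolution) -> float:
    """Pooled objective of ``(A, B)`` divided by its value at the exact solution.

    Converges to 1 on success; can legitimately exceed 1 while the
    variance constraints are violated.
    """
    mom = _as_moments(dataset)
    return pooled_objective(A, B, mom) / pooled_objective(oracle.A, oracle.B, mom)


def _aligned_oracle(A, B, mom: PairedMoments, oracle: CCASolution):
    """Jointly flip each oracle pair toward the learned pair (data inner product)."""
    Ao = oracle.A.copy()
    Bo = oracle.B.copy()
    A, B = _columns(A), _columns(B)
    for i in range(Ao.shape[1]):
        ip = A[:, i] @ mom.Cxx @ Ao[:, i] + B[:, i] @ mom.Cyy @ Bo[:, i]
        if ip < 0:
            Ao[:, i] *= -1
            Bo[:, i] *= -1
    return Ao, Bo


def angular_error(
    A, B, dataset, oracle: CCASolution, align_signs: bool = True
) -> float:
    """Data-weighted angle (radians) between ``(A, B)`` and the exact solution.

    The inner product weighs each synapse by its input variance, i.e.
    ``<(A,B),(Ao,Bo)> = sum_i [a_i' Cxx ao_i + b_i' Cyy bo_i]``.  Each
    oracle column pair is jointly sign-aligned to the learned pair first
    (the online algorithms converge to either sign); pass
    ``align_signs=False`` for the raw definition.
    """
    mom = _as_moments(dataset)
    A, B = _columns(A), _columns(B)
    Ao, Bo = (
        _aligned_oracle(A, B, mom, oracle) if align_signs else (oracle.A, oracle.B)
    )
    ip = float(
        np.einsum("ij,jk,ki->", A.T, mom.Cxx, Ao)
        + np.einsum("ij,jk,ki->", B.T, mom.Cyy, Bo)
    )
    na = np.einsum("ij,jk,ki->", A.T, mom.Cxx, A) + np.einsum(
        "ij,jk,ki->", B.T, mom.Cyy, B
    )
    no = np.einsum("ij,jk,ki->", Ao.T, mom.Cxx, Ao) + np.einsum(
        "ij,jk,ki->", Bo.T, mom.Cyy, Bo
    )
    if na <= 0 or no <= 0:
        raise UndefinedMetricError("zero-norm weights in angular error")
    # atan2 form of arccos(ip / sqrt(na*no)): stable near 0 and exactly 0
    # when the arguments coincide
    sin2 = max(na * no - ip * ip, 0.0)
    return float(np.arctan2(np.sqrt(sin2), ip))


# ---------------------------------------------------------------------------
# multiview metrics
# ---------------------------------------------------------------------------

def _view_currents(weights, dataset: MultiviewDataset) -> np.ndarray:
    if len(weights) != dataset.k:
        raise ValueError("one weight vector per view required")
    return np.stack(
        [v @ np.asarray(w, dtype=np.float64) for w, v in zip(weights, dataset.views)]
    )  # (k, T)


def absolute_objective(weights, dataset: MultiviewDataset) -> float:
    """Mean pairwise normalized correlation of the per-view projections.

    Average over ordered pairs ``i < j`` of
    ``<c_i c_j> / (<c_i^2>^1/2 <c_j^2>^1/2)`` with ``1/T`` moments;
    bounded by 1 in magnitude (Cauchy-Schwarz) and invariant to per-view
    weight rescaling.
    """
    c = _view_currents(weights, dataset)
    T = dataset.T
    var = (c * c).sum(axis=1) / T
    if np.any(var <= 0):
        raise UndefinedMetricError("a projection has zero variance")
    k = dataset.k
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            total += (c[i] @ c[j] / T) / np.sqrt(var[i] * var[j])
    return float(2.0 * total / (k * (k - 1)))


def multiview_angular_error(
    weights, dataset: MultiviewDataset, reference_weights, align_sign: bool = True
) -> float:
    """Angle (radians) between concatenated projection currents and a reference.

    Cosine of the stacked per-view currents against the reference
    currents, with one *global* sign flip applied to the reference when
    the inner product is negative (the k projections can only flip
    jointly).
    """
    c = _view_currents(weights, dataset)
    cr = _view_currents(reference_weights, dataset)
    T = dataset.T
    ip = float((c * cr).sum()) / T
    if align_sign and ip < 0:
        ip = -ip
    nc = float((c * c).sum()) / T
    nr = float((cr * cr).sum()) / T
    if nc <= 0 or nr <= 0:
        raise UndefinedMetricError("zero-norm currents in multiview angular error")
    sin2 = max(nc * nr - ip * ip, 0.0)
    return float(np.arctan2(np.sqrt(sin2), ip))


# ---------------------------------------------------------------------------
# constraint diagnostics
# ---------------------------------------------------------------------------

def constraint_violations(state, dataset) -> dict:
    """Deviations from the unit-variance and decorrelation constraints.

    Accepts a single-neuron, network, multiview state (or a
    ``CCASolution``) together with its dataset.  Returns per-component
    ``|variance - 1|`` for each view and, for multichannel states, the
    absolute off-diagonal second moments of the summed outputs
    ``c_i = a_i'x + b_i'y`` (which the deflation constraints drive to
    zero).
    """
    if hasattr(state, "views") or isinstance(dataset, MultiviewDataset):
        weights = state.weights if hasattr(state, "weights") else state
        c = _view_currents(weights, dataset)
        var = (c * c).sum(axis=1) / dataset.T
        return {"variance_violation": np.abs(var - 1.0)}
    if hasattr(state, "A"):
        A, B = _columns(state.A), _columns(state.B)
    else:
        A, B = _columns(state.a), _columns(state.b)
    mom = _as_moments(dataset)
    va = np.einsum("ij,jk,ki->i", A.T, mom.Cxx, A)
    vb = np.einsum("ij,jk,ki->i", B.T, mom.Cyy, B)
    cx = dataset.X @ A + dataset.Y @ B  # (T, d) summed outputs
    Cc = cx.T @ cx / dataset.T
    off = np.abs(Cc - np.diag(np.diag(Cc)))
    return {
        "variance_violation_x": np.abs(va - 1.0),
        "variance_violation_y": np.abs(vb - 1.0),
        "output_cross_moment": off,
        "max_output_cross_moment": float(off.max()) if off.size else 0.0,
    }
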