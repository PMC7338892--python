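"""Exact offline CCA solvers used as ground truth for all metrics.

``solve_cca`` is the standard whitened-SVD solution of the two-view
problem; ``solve_multiview_reference`` supplies reference weights for
the sum-of-correlations multiview problem, either analytically (svd-max
construction) or by a full-batch version of the online multiview
algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .datasets import MultiviewDataset, PairedDataset, SvdMaxGroundTruth

__all__ = [
    "CCASolution",
    "SingularCovarianceError",
    "ConvergenceError",
    "solve_cca",
    "solve_multiview_reference",
]


class SingularCovarianceError(np.linalg.LinAlgError):
    """A view's covariance is rank-deficient and no ridge was applied."""


class ConvergenceError(RuntimeError):
    """The offline iterative reference solver failed to converge."""


@dataclass
class CCASolution:
    """Canonical vectors and correlations of a paired dataset.

    Columns of ``A`` (``n x d``) and ``B`` (``m x d``) are the canonical
    vector pairs, normalized to unit projection variance under the
    ``1/T`` sample second moment; ``rho`` holds the canonical
    correlations in descending order.  Signs: the first nonzero entry of
    each ``A`` column is positive and the paired ``B`` column's sign is
    slaved so that ``rho_i >= 0``.
    """

    A: np.ndarray
    B: np.ndarray
    rho: np.ndarray

    @property
    def d(self) -> int:
        return self.rho.size

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"A": self.A.tolist(), "B": self.B.tolist(), "rho": self.rho.tolist()},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CCASolution":
        """Load from a JSON string or a path to a JSON file."""
        try:
            d = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            d = json.loads(Path(source).read_text())
        return cls(np.asarray(d["A"]), np.asarray(d["B"]), np.asarray(d["rho"]))

    def to_csv(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "A.csv", self.A, delimiter=",")
        np.savetxt(directory / "B.csv", self.B, delimiter=",")
        np.savetxt(directory / "rho.csv", self.rho, delimiter=",")
        return directory


def _inv_sqrt(C: np.ndarray, name: str, ridge: float) -> np.ndarray:
    C = C + ridge * np.eye(C.shape[0])
    w, V = np.linalg.eigh(C)
    if w.min() <= 0 or w.min() / w.max() < 1e-14:
        raise SingularCovarianceError(
            f"{name} is singular (min eigenvalue {w.min():.3e}); "
            "supply a positive ridge"
        )
    return (V / np.sqrt(w)) @ V.T


def _fix_signs(A: np.ndarray, B: np.ndarray) -> None:
    # first nonzero entry of each a-column positive; b flipped jointly so
    # the canonical correlation keeps its sign
    for j in range(A.shape[1]):
        nz = np.flatnonzero(np.abs(A[:, j]) > 1e-12)
        if nz.size and A[nz[0], j] < 0:
            A[:, j] *= -1
            B[:, j] *= -1


def solve_cca(
    dataset: PairedDataset, d: int | None = None, ridge: float | None = None
) -> CCASolution:
    """Exact CCA of a centered paired dataset via whitening + SVD.

    Sample covariances use the ``1/T`` normalization.  Both views are
    whitened with ``(C + ridge I)^(-1/2)``, the top-``d`` SVD of the
    whitened cross-covariance is taken, and the singular vectors are
    mapped back and scaled to unit projection variance.

    Parameters
    ----------
    d:
        Number of canonical pairs (default ``min(n, m)``).
    ridge:
        Diagonal loading added to each view covariance before whitening.
        Default ``1e-10 * trace(C)/dim`` per view; pass ``0`` to insist
        on exact invertibility (raises on rank deficiency).
    """
    if not dataset.centered:
        dataset = dataset.center()
    X, Y, T = dataset.X, dataset.Y, dataset.T
    n, m = dataset.n, dataset.m
    if d is None:
        d = min(n, m)
    if not (1 <= d <= min(n, m)):
        raise ValueError(f"d={d} must lie in [1, min(n, m)={min(n, m)}]")
    Cxx = X.T @ X / T
    Cyy = Y.T @ Y / T
    Cxy = X.T @ Y / T
    rx = 1e-10 * np.trace(Cxx) / n if ridge is None else float(ridge)
    ry = 1e-10 * np.trace(Cyy) / m if ridge is None else float(ridge)
    Wx = _inv_sqrt(Cxx, "C_xx", rx)
    Wy = _inv_sqrt(Cyy, "C_yy", ry)
    U, s, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    A = Wx @ U[:, :d]
    B = Wy @ Vt[:d].T
    # exact unit projection variance (whitening with ridge is only approximate)
    A /= np.sqrt(np.einsum("ij,jk,ki->i", A.T, Cxx, A))
    B /= np.sqrt(np.einsum("ij,jk,ki->i", B.T, Cyy, B))
    _fix_signs(A, B)
    rho = np.einsum("ij,jk,ki->i", A.T, Cxy, B)
    return CCASolution(A, B, rho)


def solve_multiview_reference(
    dataset: MultiviewDataset,
    ground_truth: SvdMaxGroundTruth | None = None,
    lr: float = 0.05,
    tol: float = 1e-9,
    max_iter: int = 200_000,
    seed: int = 0,
) -> list:
    """Reference weights for the sum-of-correlations multiview objective.

    With an svd-max ``ground_truth``, returns the analytic optimum
    rescaled by ``sqrt(T)`` so the unit-projection-variance constraint
    holds (the raw ``u1/s1`` weights give projection variance ``1/T``;
    the rescaling leaves every scale-invariant metric unchanged).

    Otherwise runs the full-batch (offline) version of the online
    multiview algorithm — deterministic gradient ascent on the weights
    and descent on the variance multipliers using exact covariances —
    until the update norm drops below ``tol``.
    """
    if ground_truth is not None:
        return [np.sqrt(dataset.T) * w for w in ground_truth.optimal_weights]

    k = dataset.k
    T = dataset.T
    C = [[vi.T @ vj / T for vj in dataset.views] for vi in dataset.views]
    rng = np.random.default_rng(seed)
    a = [rng.standard_normal(ni) for ni in dataset.dims]
    alpha = np.zeros(k)
    grad_norm = np.inf
    for _ in range(max_iter):
        grads = []
        for i in range(k):
            g = sum(C[i][j] @ a[j] for j in range(k)) - alpha[i] * (C[i][i] @ a[i])
            grads.append(g)
        galpha = np.array(
            [0.5 * (a[i] @ C[i][i] @ a[i] - 1.0) for i in range(k)]
        )
        for i in range(k):
            a[i] = a[i] + lr * grads[i]
        alpha = alpha + lr * galpha
        grad_norm = max(max(np.abs(g).max() for g in grads), np.abs(galpha).max())
        if grad_norm < tol:
            return a
        if not np.isfinite(grad_norm) or grad_norm > 1e12:
            raise ConvergenceError(
                f"offline multiview solver diverged (gradient norm {grad_norm:.3e}); "
                "try a smaller lr"
            )
    raise ConvergenceError(
        f"offline multiview solver did not converge in {max_iter} iterations "
        f"(final gradient norm {grad_norm:.3e})"
    )
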