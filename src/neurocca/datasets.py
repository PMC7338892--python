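"""Synthetic datasets and view splitters for online CCA experiments.

Conventions
-----------
Samples are rows: a paired dataset holds ``X`` of shape ``(T, n)`` and
``Y`` of shape ``(T, m)``; a multiview dataset holds ``k >= 2`` views of
shape ``(T, n_i)``.  All second moments downstream use the ``1/T``
normalization.  Generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PairedDataset",
    "MultiviewDataset",
    "SvdMaxGroundTruth",
    "UniformSampler",
    "make_gaussian",
    "make_planted_gaussian",
    "make_svdmax",
    "make_correlated_images",
    "split_image_rows",
    "split_image_quadrants",
    "center",
    "sample_minibatch",
    "save_dataset",
    "load_dataset",
]

@dataclass
class PairedDataset:
    """Two sample matrices with a common number of rows ``T``."""

    X: np.ndarray
    Y: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D (samples as rows)")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X and Y must share the sample count: {self.X.shape[0]} != {self.Y.shape[0]}"
            )
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples")

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.Y.shape[1]

    def center(self) -> "PairedDataset":
        """Return a column-mean-centered copy (idempotent)."""
        return PairedDataset(
            self.X - self.X.mean(axis=0), self.Y - self.Y.mean(axis=0), centered=True
        )


@dataclass
class MultiviewDataset:
    """An ordered collection of ``k >= 2`` views sharing the sample axis."""

    views: list
    centered: bool = False

    def __post_init__(self) -> None:
        self.views = [np.asarray(v, dtype=np.float64) for v in self.views]
        if len(self.views) < 2:
            raise ValueError("need at least 2 views")
        T = self.views[0].shape[0]
        for i, v in enumerate(self.views):
            if v.ndim != 2:
                raise ValueError(f"view {i} must be 2-D")
            if v.shape[0] != T:
                raise ValueError("all views must share the sample count")
        if T < 2:
            raise ValueError("need at least 2 samples")

    @property
    def T(self) -> int:
        return self.views[0].shape[0]

    @property
    def k(self) -> int:
        return len(self.views)

    @property
    def dims(self) -> tuple:
        return tuple(v.shape[1] for v in self.views)

    def center(self) -> "MultiviewDataset":
        return MultiviewDataset([v - v.mean(axis=0) for v in self.views], centered=True)


@dataclass
class SvdMaxGroundTruth:
    """Analytic optimum of the svd-max construction.

    ``optimal_weights[i] = u1^(i) / s1^(i)`` projects view ``i`` exactly
    onto ``shared_direction``, so all pairwise projection correlations
    equal one.  Note the projection variance at these weights is ``1/T``;
    rescale by ``sqrt(T)`` (see :func:`neurocca.oracle.solve_multiview_reference`)
    when the unit-variance constraint itself is needed.
    """

    U: list
    S: list
    shared_direction: np.ndarray
    optimal_weights: list


def center(dataset):
    """Center a paired or multiview dataset (column means to zero)."""
    return dataset.center()


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_gaussian(
    n_x: int = 5,
    n_y: int = 5,
    T: int = 10_000,
    scale_divisor: float = 100.0,
    seed: int = 0,
) -> PairedDataset:
    """Jointly Gaussian paired views with covariance ``G.T @ G / scale_divisor``.

    A square mixing matrix ``G`` of side ``n_x + n_y`` is drawn with
    standard-Gaussian entries; ``T`` joint samples are drawn from the
    zero-mean Gaussian with covariance ``G.T G / scale_divisor``; the
    first ``n_x`` coordinates become ``X``, the rest ``Y``; both are
    centered.  Defaults reproduce the 10-dimensional benchmark
    (``n_x = n_y = 5``, ``T = 10000``, divisor 100).
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("view dimensions must be positive")
    if T < 2:
        raise ValueError("need T >= 2 samples")
    if scale_divisor <= 0:
        raise ValueError("scale_divisor must be positive")
    rng = np.random.default_rng(seed)
    dim = n_x + n_y
    G = rng.standard_normal((dim, dim))
    Z = rng.standard_normal((T, dim))
    # Z @ G / sqrt(s) has covariance G.T G / s exactly.
    samples = Z @ G / np.sqrt(scale_divisor)
    return PairedDataset(samples[:, :n_x], samples[:, n_x:], centered=False).center()


def make_planted_gaussian(
    n_x: int = 5,
    n_y: int = 5,
    T: int = 10_000,
    rhos=(0.9, 0.2),
    seed: int = 0,
) -> PairedDataset:
    """Gaussian paired views with planted population canonical correlations.

    Shared latent factors ``z_i`` enter ``X`` directly and ``Y`` as
    ``rho_i z_i + sqrt(1 - rho_i^2) w_i``; remaining coordinates are
    independent noise.  Each view is then mixed by a random invertible
    matrix (canonical correlations are invariant to invertible linear
    maps), so the population canonical correlations are exactly ``rhos``
    padded with zeros.  Useful for parameter-recovery tests with a
    dominant, well-separated top canonical pair.
    """
    rhos = np.atleast_1d(np.asarray(rhos, dtype=np.float64))
    d = rhos.size
    if d > min(n_x, n_y):
        raise ValueError("len(rhos) must not exceed min(n_x, n_y)")
    if np.any((rhos < 0) | (rhos > 1)):
        raise ValueError("rhos must lie in [0, 1]")
    if np.any(np.diff(rhos) > 0):
        raise ValueError("rhos must be nonincreasing")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((T, d))
    w = rng.standard_normal((T, d))
    X = np.concatenate([z, rng.standard_normal((T, n_x - d))], axis=1)
    Ysig = rhos * z + np.sqrt(1.0 - rhos**2) * w
    Y = np.concatenate([Ysig, rng.standard_normal((T, n_y - d))], axis=1)
    # random well-conditioned mixing, to hide the planted axes
    Rx = rng.standard_normal((n_x, n_x)) + 3.0 * np.eye(n_x)
    Ry = rng.standard_normal((n_y, n_y)) + 3.0 * np.eye(n_y)
    X = X @ Rx.T
    Y = Y @ Ry.T
    # match the variance scale of the Gaussian benchmark (mean column
    # variance 0.1) so the same learning rates are stable
    X *= np.sqrt(0.1 / np.mean(np.var(X, axis=0)))
    Y *= np.sqrt(0.1 / np.mean(np.var(Y, axis=0)))
    return PairedDataset(X, Y, centered=False).center()


def _fix_column_signs(U: np.ndarray) -> np.ndarray:
    """Make the first nonzero entry of each column positive (SVD sign fix)."""
    U = U.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-14)
        if nz.size and col[nz[0]] < 0:
            U[:, j] = -col
    return U


def make_svdmax(dims=(4, 5, 6), T: int = 10_000, seed: int = 0):
    """Multiview dataset with a shared top singular direction (known optimum).

    Each view is ``X^(i) = U^(i) S^(i) V^(i)^T`` (stored transposed, with
    samples as rows): ``U^(i)`` comes from the SVD of a standard-Gaussian
    square matrix, the singular values are Uniform([0.1, 1]) sorted
    descending, the first column of every ``V^(i)`` is one shared unit
    vector and all remaining columns across views are mutually
    orthonormal.  Projecting view ``i`` onto ``u1^(i)/s1^(i)`` recovers
    the shared direction exactly, so the analytic optimum of the
    sum-of-correlations objective is known.

    Returns ``(MultiviewDataset, SvdMaxGroundTruth)``.
    """
    dims = [int(d) for d in dims]
    k = len(dims)
    if k < 2:
        raise ValueError("need at least 2 views")
    if any(d < 1 for d in dims):
        raise ValueError("view dimensions must be positive")
    p = sum(dims) - k + 1  # shared column + (n_i - 1) extras per view
    if T < p:
        raise ValueError(
            f"T={T} too small for {p} mutually orthonormal columns; need T >= {p}"
        )
    rng = np.random.default_rng(seed)
    # one T x p matrix with orthonormal columns, sliced across views
    Q, _ = np.linalg.qr(rng.standard_normal((T, p)))
    shared = Q[:, 0].copy()
    views, Us, Ss, weights = [], [], [], []
    offset = 1
    for n in dims:
        G = rng.standard_normal((n, n))
        U, _, _ = np.linalg.svd(G)
        U = _fix_column_signs(U)
        s = np.sort(rng.uniform(0.1, 1.0, size=n))[::-1]
        V = np.concatenate([shared[:, None], Q[:, offset : offset + n - 1]], axis=1)
        offset += n - 1
        views.append(V * s @ U.T)  # (T, n): transpose of U S V^T
        Us.append(U)
        Ss.append(s)
        weights.append(U[:, 0] / s[0])
    gt = SvdMaxGroundTruth(Us, Ss, shared, weights)
    return MultiviewDataset(views, centered=False), gt


def make_correlated_images(
    T: int, H: int, W: int, length_scale: float, seed: int = 0
) -> np.ndarray:
    """Image stack from a Gaussian random field with distance-decaying correlation.

    Pixel covariance is the squared-exponential kernel
    ``exp(-||p - q||^2 / (2 length_scale^2))`` over the ``H x W`` grid;
    each of the ``T`` images applies the grid-covariance Cholesky factor
    to white noise.  Synthetic stand-in for natural-image stacks in which
    nearby pixels are more correlated than distant ones.
    """
    if T < 1 or H < 1 or W < 1:
        raise ValueError("T, H, W must be positive")
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    rng = np.random.default_rng(seed)
    r, c = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pos = np.stack([r.ravel(), c.ravel()], axis=1).astype(np.float64)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * length_scale**2))
    L = np.linalg.cholesky(K + 1e-10 * np.eye(H * W))
    Z = rng.standard_normal((T, H * W))
    return (Z @ L.T).reshape(T, H, W)


# ---------------------------------------------------------------------------
# view splitters
# ---------------------------------------------------------------------------

def split_image_rows(
    images: np.ndarray, row_index: int, cols_x, cols_y
) -> PairedDataset:
    """Paired views from one pixel row of an image stack.

    ``cols_x`` and ``cols_y`` are half-open ``(start, stop)`` ranges of
    0-based column indices; ``X`` holds the ``cols_x`` pixels of row
    ``row_index`` for every image, ``Y`` the ``cols_y`` pixels.  Both
    views are centered.  (The classic handwritten-digit benchmark's
    1-based "15th row, pixels 10-14 / 15-19" is row 14, ranges (9, 14)
    and (14, 19) in this convention.)
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ValueError("images must be a (T, H, W) stack")
    T, H, W = images.shape
    if not (0 <= row_index < H):
        raise IndexError(f"row_index {row_index} out of range for H={H}")
    for name, (lo, hi) in (("cols_x", tuple(cols_x)), ("cols_y", tuple(cols_y))):
        if not (0 <= lo < hi <= W):
            raise IndexError(f"{name}=({lo}, {hi}) out of range for W={W}")
    x0, x1 = cols_x
    y0, y1 = cols_y
    row = images[:, row_index, :]
    return PairedDataset(row[:, x0:x1], row[:, y0:y1], centered=False).center()


def split_image_quadrants(images: np.ndarray) -> MultiviewDataset:
    """Four views from the quadrants of an even-sided image stack.

    Order: top-left, top-right, bottom-left, bottom-right; each quadrant
    is flattened row-major into a ``(T, H/2 * W/2)`` view and centered.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ValueError("images must be a (T, H, W) stack")
    T, H, W = images.shape
    if H % 2 or W % 2:
        raise ValueError(f"H and W must be even, got ({H}, {W})")
    h, w = H // 2, W // 2
    quads = [
        images[:, :h, :w],
        images[:, :h, w:],
        images[:, h:, :w],
        images[:, h:, w:],
    ]
    return MultiviewDataset([q.reshape(T, h * w) for q in quads], centered=False).center()


# ---------------------------------------------------------------------------
# minibatch sampling
# ---------------------------------------------------------------------------

class UniformSampler:
    """Seeded stream of sample indices over a pregenerated dataset.

    ``order="random"`` draws uniformly with replacement (the default,
    matching the online training protocol); ``order="epoch"`` cycles
    through seeded permutations.
    """

    def __init__(self, dataset, seed: int = 0, order: str = "random"):
        if dataset.T < 1:
            raise ValueError("empty dataset")
        if order not in ("random", "epoch"):
            raise ValueError("order must be 'random' or 'epoch'")
        self.dataset = dataset
        self.seed = seed
        self.order = order

    def indices(self, n_steps: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        T = self.dataset.T
        if self.order == "random":
            return rng.integers(0, T, size=n_steps)
        reps = -(-n_steps // T)
        return np.concatenate([rng.permutation(T) for _ in range(reps)])[:n_steps]

    def sample(self, t: int):
        """The sample presented at step ``t`` (0-based)."""
        idx = int(self.indices(t + 1)[t])
        ds = self.dataset
        if isinstance(ds, MultiviewDataset):
            return tuple(v[idx] for v in ds.views)
        return ds.X[idx], ds.Y[idx]


def sample_minibatch(dataset, seed: int, t: int):
    """Single-sample minibatch at step ``t`` of the seeded uniform stream."""
    return UniformSampler(dataset, seed).sample(t)


# ---------------------------------------------------------------------------
# delimited I/O with a JSON sidecar
# ---------------------------------------------------------------------------

def _save_matrix(M: np.ndarray, path: Path, delimiter: str) -> None:
    np.savetxt(path, M, delimiter=delimiter)


def save_dataset(dataset, directory, delimiter: str = ",", metadata: dict | None = None):
    """Write a dataset as delimited matrices plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    meta["centered"] = bool(dataset.centered)
    meta["delimiter"] = delimiter
    if isinstance(dataset, PairedDataset):
        meta["kind"] = "paired"
        meta["shape"] = {"T": dataset.T, "n": dataset.n, "m": dataset.m}
        _save_matrix(dataset.X, directory / "X.csv", delimiter)
        _save_matrix(dataset.Y, directory / "Y.csv", delimiter)
    elif isinstance(dataset, MultiviewDataset):
        meta["kind"] = "multiview"
        meta["shape"] = {"T": dataset.T, "dims": list(dataset.dims)}
        for i, v in enumerate(dataset.views):
            _save_matrix(v, directory / f"view{i}.csv", delimiter)
    else:
        raise TypeError(f"cannot save {type(dataset).__name__}")
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_dataset(directory):
    """Load a dataset written by :func:`save_dataset`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    delim = meta.get("delimiter", ",")
    if meta["kind"] == "paired":
        X = np.loadtxt(directory / "X.csv", delimiter=delim, ndmin=2)
        Y = np.loadtxt(directory / "Y.csv", delimiter=delim, ndmin=2)
        return PairedDataset(X, Y, centered=meta.get("centered", False))
    if meta["kind"] == "multiview":
        k = len(meta["shape"]["dims"])
        views = [
            np.loadtxt(directory / f"view{i}.csv", delimiter=delim, ndmin=2)
            for i in range(k)
        ]
        return MultiviewDataset(views, centered=meta.get("centered", False))
    raise ValueError(f"unknown dataset kind {meta['kind']!r}")
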