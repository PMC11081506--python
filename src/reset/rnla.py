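"""Randomized numerical linear algebra primitives.

Implements the two building blocks of the randomized scoring pipeline: an
approximate orthonormal basis for the dominant column space of a matrix
(randomized rangefinder) and a randomized truncated SVD built on top of it.
Both follow the standard Gaussian-sketch / power-iteration scheme with QR
re-orthonormalization after every multiplication for numerical stability.

Sparse inputs (any scipy.sparse matrix) are supported; all sketch products
yield small dense matrices without densifying the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse

__all__ = ["SketchParams", "SvdResult", "random_column_space", "random_svd"]


@dataclass(frozen=True)
class SketchParams:
    """Parameters controlling a randomized sketch.

    Attributes
    ----------
    target_rank:
        Rank of the requested basis / truncated SVD (``k`` or ``b``). Must
        be >= 1. The effective rank is capped at the matrix dimensions.
    oversample:
        Additional sketch dimensions ``d`` beyond the target rank. Extra
        columns improve subspace capture at modest cost. Default 10.
    power_iters:
        Number of power iterations ``q``; each sharpens the singular-value
        spectrum by one multiplication with ``M M^T``. Default 2.
    seed:
        Integer seed, ``numpy.random.Generator`` or ``None``. Identical
        seed and input give bit-identical output. Passing a Generator lets
        a caller thread one stream through several sketches so an entire
        pipeline is reproducible from a single seed.
    """

    target_rank: int
    oversample: int = 10
    power_iters: int = 2
    seed: int | np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self.target_rank < 1:
            raise ValueError("target_rank must be >= 1")
        if self.oversample < 0:
            raise ValueError("oversample must be >= 0")
        if self.power_iters < 0:
            raise ValueError("power_iters must be >= 0")


@dataclass(frozen=True)
class SvdResult:
    """Truncated SVD ``M ~= U diag(sigma) V^T``.

    ``U`` is n x b and ``V`` is p x b, both with orthonormal columns;
    ``sigma`` is non-increasing and non-negative.
    """

    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray

    @property
    def rank(self) -> int:
        return self.sigma.shape[0]


def _validate(M) -> tuple[int, int]:
    if M.ndim != 2:
        raise ValueError("input must be a 2-D matrix")
    n, l = M.shape
    if n == 0 or l == 0:
        raise ValueError("input matrix is empty")
    data = M.data if sparse.issparse(M) else M
    if not np.isfinite(np.asarray(data)).all():
        raise ValueError("input matrix contains non-finite entries")
    return n, l


def _sketch_basis(M, width: int, power_iters: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal basis for the range of a Gaussian sketch of ``M``.

    Draws an l x width standard-Gaussian test matrix, forms the sample
    matrix ``Y = M G`` and orthonormalizes. Each power iteration replaces
    the basis with an orthonormalized ``M (M^T Q)``, re-orthonormalizing
    after every product to prevent collapse of small singular directions.
    """
    _, l = M.shape
    G = rng.standard_normal((l, width))
    Q, _ = linalg.qr(M @ G, mode="economic")
    for _ in range(power_iters):
        Z, _ = linalg.qr(M.T @ Q, mode="economic")
        Q, _ = linalg.qr(M @ Z, mode="economic")
    return Q


def random_column_space(M, params: SketchParams) -> np.ndarray:
    """Approximate orthonormal basis for the dominant column space of ``M``.

    Returns an n x r matrix ``Q`` with orthonormal columns,
    ``r = min(target_rank, n, l)``, approximately spanning the span of the
    top ``r`` left singular vectors of ``M``. When the sketch is wider than
    the target rank the basis is rotated onto the top singular directions
    of the sketched matrix before truncation, so the retained columns are
    ordered by captured variance.

    Deterministic given ``params.seed``.
    """
    n, l = _validate(M)
    rng = np.random.default_rng(params.seed)
    width = min(params.target_rank + params.oversample, l, n)
    Q = _sketch_basis(M, width, params.power_iters, rng)
    r = min(params.target_rank, l, n)
    if Q.shape[1] > r:
        # Rotate onto the top-r singular directions within the sketch.
        B = Q.T @ M
        if sparse.issparse(B):
            B = B.toarray()
        Ub, _, _ = linalg.svd(np.asarray(B), full_matrices=False)
        Q = Q @ Ub[:, :r]
    return Q


def random_svd(M, params: SketchParams) -> SvdResult:
    """Randomized truncated SVD of rank ``target_rank``.

    Sketches the column space at width ``target_rank + oversample`` (capped
    at the matrix dimensions), projects ``M`` into the sketch and takes the
    exact SVD of the small projected matrix. For matrices of exact rank
    ``r <= target_rank`` the reconstruction is exact up to roundoff.
    """
    n, p = _validate(M)
    b = params.target_rank
    if b > min(n, p):
        raise ValueError(f"target_rank {b} exceeds min(n, p) = {min(n, p)}")
    rng = np.random.default_rng(params.seed)
    width = min(b + params.oversample, p, n)
    Q = _sketch_basis(M, width, params.power_iters, rng)
    B = Q.T @ M
    if sparse.issparse(B):
        B = B.toarray()
    Ub, s, Vt = linalg.svd(np.asarray(B), full_matrices=False)
    U = Q @ Ub
    return SvdResult(U=U[:, :b], sigma=s[:b], V=Vt[:b].T)
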