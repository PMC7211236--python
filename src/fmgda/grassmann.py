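"""Grassmann manifold geometry under the projection metric.

A point on the Grassmann manifold G(p, D) is a p-dimensional linear
subspace of R^D, represented here by any D x p matrix with orthonormal
columns (Stiefel representation).  Two bases that differ by a right
p x p orthogonal factor denote the *same* manifold point, and every
operation in this module is invariant to that choice.

The metric used throughout is the projection metric

    delta_P(X1, X2) = (1/2) * || X1 X1^T - X2 X2^T ||_F^2,

a squared chordal distance between the orthogonal-projection matrices of
the two subspaces.  Its Frechet mean has a closed form: the span of the
top-p eigenvectors of the summed projectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

#: Frobenius-norm tolerance on ||basis^T basis - I_p|| for a valid point.
#: Double-precision QR/eig noise is ~1e-14, leaving ample margin.
ORTHONORMALITY_TOL = 1e-8


class GrassmannError(ValueError):
    """Base class for errors raised by Grassmann geometry operations."""


class InvalidPointError(GrassmannError):
    """A matrix claimed as a subspace basis is not orthonormal."""


class ShapeError(GrassmannError):
    """Operands live on different Grassmann manifolds."""


class RankError(GrassmannError):
    """A matrix does not have the full column rank an operation requires."""


class EmptyInputError(GrassmannError):
    """An aggregate operation received no points."""


@dataclass(frozen=True)
class GrassmannPoint:
    """One subspace in G(p, D), stored as an orthonormal D x p basis.

    Parameters
    ----------
    basis
        Real matrix of shape (D, p) with orthonormal columns
        (``basis.T @ basis == I_p`` within :data:`ORTHONORMALITY_TOL`).
    """

    basis: np.ndarray

    def __post_init__(self) -> None:
        basis = np.ascontiguousarray(np.asarray(self.basis, dtype=float))
        if basis.ndim != 2:
            raise InvalidPointError(f"basis must be 2-D, got shape {basis.shape}")
        D, p = basis.shape
        if not 1 <= p <= D:
            raise InvalidPointError(f"need 1 <= p <= D, got D={D}, p={p}")
        dev = np.linalg.norm(basis.T @ basis - np.eye(p))
        if not np.isfinite(dev) or dev > ORTHONORMALITY_TOL:
            raise InvalidPointError(
                f"basis columns are not orthonormal (||B^T B - I||_F = {dev:.3g})"
            )
        object.__setattr__(self, "basis", basis)

    @property
    def ambient_dim(self) -> int:
        return self.basis.shape[0]

    @property
    def subspace_dim(self) -> int:
        return self.basis.shape[1]


@dataclass(frozen=True)
class LabeledGrassmannSet:
    """A collection of Grassmann points with integer class labels.

    ``bases`` is a (n, D, p) stack of orthonormal bases; ``labels`` holds
    class ids in 0..K-1 with every class non-empty.  ``label_names`` is an
    optional human-readable name per class id (e.g. Bonn group letters).
    """

    bases: np.ndarray
    labels: np.ndarray
    label_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        bases = np.ascontiguousarray(np.asarray(self.bases, dtype=float))
        labels = np.asarray(self.labels, dtype=int)
        if bases.ndim != 3:
            raise ShapeError(f"bases must be (n, D, p), got shape {bases.shape}")
        n, D, p = bases.shape
        if n == 0:
            raise EmptyInputError("a labeled set needs at least one point")
        if labels.shape != (n,):
            raise ShapeError(f"labels must have shape ({n},), got {labels.shape}")
        K = int(labels.max()) + 1
        counts = np.bincount(labels, minlength=K)
        if labels.min() < 0 or np.any(counts == 0):
            raise ValueError("labels must cover 0..K-1 with every class non-empty")
        if self.label_names is not None and len(self.label_names) != K:
            raise ValueError("label_names must have one entry per class")
        # validate every basis once, up front
        grams = np.einsum("ndp,ndq->npq", bases, bases)
        dev = np.linalg.norm(grams - np.eye(p), axis=(1, 2))
        if dev.max() > ORTHONORMALITY_TOL:
            bad = int(np.argmax(dev))
            raise InvalidPointError(
                f"point {bad} is not orthonormal (deviation {dev.max():.3g})"
            )
        object.__setattr__(self, "bases", bases)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_points(
        cls,
        points: Sequence[GrassmannPoint],
        labels: Iterable[int],
        label_names: Sequence[str] | None = None,
    ) -> "LabeledGrassmannSet":
        if len(points) == 0:
            raise EmptyInputError("no points given")
        shapes = {(pt.ambient_dim, pt.subspace_dim) for pt in points}
        if len(shapes) != 1:
            raise ShapeError(f"points live on different manifolds: {sorted(shapes)}")
        bases = np.stack([pt.basis for pt in points])
        names = tuple(label_names) if label_names is not None else None
        return cls(bases, np.fromiter(labels, dtype=int), names)

    @property
    def n_points(self) -> int:
        return self.bases.shape[0]

    @property
    def ambient_dim(self) -> int:
        return self.bases.shape[1]

    @property
    def subspace_dim(self) -> int:
        return self.bases.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def point(self, i: int) -> GrassmannPoint:
        return GrassmannPoint(self.bases[i])

    def points(self) -> list[GrassmannPoint]:
        return [GrassmannPoint(b) for b in self.bases]

    def class_bases(self, k: int) -> np.ndarray:
        return self.bases[self.labels == k]

    def subset(self, indices: np.ndarray) -> "LabeledGrassmannSet":
        """Subset keeping the original label ids (all classes must survive)."""
        return LabeledGrassmannSet(
            self.bases[indices], self.labels[indices], self.label_names
        )


def project_embed(X: GrassmannPoint) -> np.ndarray:
    """Projection embedding Pi(X) = X X^T.

    Maps a subspace to its orthogonal-projection matrix: a symmetric,
    idempotent, positive-semidefinite D x D matrix of trace p.  The
    embedding is well defined on the manifold (independent of the basis).
    """
    B = X.basis
    return B @ B.T


def projection_distance(X1: GrassmannPoint, X2: GrassmannPoint) -> float:
    """Projection metric delta_P(X1, X2) = (1/2) ||X1X1^T - X2X2^T||_F^2.

    Computed in the algebraically identical form ``p - ||X1^T X2||_F^2``
    (O(D p^2) instead of O(D^2 p)).  Symmetric, zero iff the two bases span
    the same subspace, and invariant to right-rotation of either basis.
    For two p-dimensional subspaces the value lies in [0, p], the maximum
    attained by fully orthogonal subspaces.
    """
    if (X1.ambient_dim, X1.subspace_dim) != (X2.ambient_dim, X2.subspace_dim):
        raise ShapeError(
            f"points live on different manifolds: "
            f"G({X1.subspace_dim},{X1.ambient_dim}) vs "
            f"G({X2.subspace_dim},{X2.ambient_dim})"
        )
    cross = X1.basis.T @ X2.basis
    return float(max(X1.subspace_dim - np.sum(cross * cross), 0.0))


def pairwise_projection_distances(
    A: np.ndarray | LabeledGrassmannSet, B: np.ndarray | LabeledGrassmannSet
) -> np.ndarray:
    """Matrix of delta_P between two stacks of bases, shapes (na,D,p), (nb,D,p)."""
    Ab = A.bases if isinstance(A, LabeledGrassmannSet) else np.asarray(A, float)
    Bb = B.bases if isinstance(B, LabeledGrassmannSet) else np.asarray(B, float)
    if Ab.shape[1:] != Bb.shape[1:]:
        raise ShapeError(f"incompatible stacks: {Ab.shape} vs {Bb.shape}")
    p = Ab.shape[2]
    cross = np.einsum("idp,jdq->ijpq", Ab, Bb, optimize=True)
    return np.maximum(p - np.einsum("ijpq,ijpq->ij", cross, cross), 0.0)


def frechet_mean(
    points: Sequence[GrassmannPoint] | np.ndarray | LabeledGrassmannSet,
    tie_rtol: float = 1e-8,
) -> GrassmannPoint:
    """Frechet mean of a set of subspaces under the projection metric.

    The minimizer of ``sum_i delta_P(X_i, M)`` over G(p, D) is the span of
    the p largest-eigenvalue eigenvectors of ``sum_i X_i X_i^T``.  When the
    p-th and (p+1)-th eigenvalues tie (within ``tie_rtol`` relative to the
    largest), the mean is only defined up to the tied directions and a
    warning is emitted; the solver's eigenvector order then breaks the tie.
    """
    if isinstance(points, LabeledGrassmannSet):
        bases = points.bases
    elif isinstance(points, np.ndarray):
        bases = points
    else:
        pts = list(points)
        if len(pts) == 0:
            raise EmptyInputError("frechet_mean of an empty collection")
        shapes = {(pt.ambient_dim, pt.subspace_dim) for pt in pts}
        if len(shapes) != 1:
            raise ShapeError(f"points live on different manifolds: {sorted(shapes)}")
        bases = np.stack([pt.basis for pt in pts])
    if bases.ndim != 3 or bases.shape[0] == 0:
        raise EmptyInputError("frechet_mean needs a non-empty (n, D, p) stack")
    n, D, p = bases.shape
    if n == 1:
        return GrassmannPoint(bases[0])
    # sum_i X_i X_i^T = S S^T with S the horizontal stack of bases; its
    # eigenvalues are the squared singular values of S.
    stacked = np.moveaxis(bases, 0, 1).reshape(D, n * p)
    if n * p <= D:
        # n >= 2 here, so the economic SVD yields at least p+1 singular values
        U, s, _ = scipy.linalg.svd(stacked, full_matrices=False)
        evals = s**2
        mean_basis = U[:, :p]
    else:
        S = stacked @ stacked.T
        w, V = scipy.linalg.eigh(S)
        evals = w[::-1]
        mean_basis = V[:, ::-1][:, :p]
    if evals.size > p:
        gap = evals[p - 1] - evals[p]
        if gap <= tie_rtol * max(evals[0], 1.0):
            warnings.warn(
                f"Frechet mean ill-defined: eigenvalues {p} and {p + 1} tie "
                f"(gap {gap:.3g}); mean fixed up to the tied directions",
                RuntimeWarning,
                stacklevel=2,
            )
    # re-orthonormalize to wash out accumulated rounding
    q, _ = orthonormalize(mean_basis)
    return GrassmannPoint(q)


def orthonormalize(
    M: np.ndarray, tol: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """QR factorization M = Q R with the sign convention diag(R) >= 0.

    Returns ``(Q, R)`` with Q a D x p orthonormal basis spanning the column
    space of M and R nonsingular upper-triangular.  Forcing a nonnegative
    diagonal on R makes Q a deterministic function of M.  Raises
    :class:`RankError` (reporting the numerical rank) if M is column-rank
    deficient.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ShapeError(f"expected a 2-D matrix, got shape {M.shape}")
    D, p = M.shape
    if p > D:
        raise RankError(f"a {D}x{p} matrix cannot have column rank {p}")
    Q, R = scipy.linalg.qr(M, mode="economic")
    diag = np.abs(np.diag(R))
    scale = diag.max(initial=0.0)
    if tol is None:
        tol = max(D, p) * np.finfo(float).eps * scale
    if scale == 0.0 or diag.min() <= tol:
        s = scipy.linalg.svdvals(M)
        rank = int(np.sum(s > max(D, p) * np.finfo(float).eps * (s[0] if s.size else 0)))
        if rank < p:
            raise RankError(f"matrix has numerical rank {rank} < {p} columns")
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs, signs[:, None] * R
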