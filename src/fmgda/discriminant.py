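"""Frechet-mean Grassmann discriminant analysis (FMGDA).

Supervised dimensionality reduction for subspace-valued data.  Given n
labeled points X_i in G(p, D), the method learns a mapping matrix
A in R^{D x d} (p <= d < D) such that the reduced points A^T X_i — made
valid Grassmann points again by QR re-orthonormalization — have small
within-class and large between-class spread under the projection metric,
with class centres represented by projection-metric Frechet means.

The objective is the ratio d_b(A) / d_w(A) where

    d_w(A) = sum_k sum_i w_k * delta_P(f(X_i^(k), A), f(M^(k), A)),
    d_b(A) = sum_k n_k * delta_P(f(M^(k), A), f(M, A)),

f(X, A) is the orthonormalized A^T X, M^(k) the class Frechet mean and M
the global Frechet mean.  The default within-class weight is w_k = n_k
(``within_weighting="classwise"``); ``"uniform"`` (w_k = 1) gives the
classical LDA-style weighting.  The problem is solved
by alternating between (i) freezing the QR normalizations at the current
A to build quadratic scatter surrogates B~ and Q~, and (ii) maximizing
the trace ratio tr(A^T B~ A) / tr(A^T Q~ A) by the standard iterated
shifted-eigenproblem scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .grassmann import (
    GrassmannError,
    GrassmannPoint,
    LabeledGrassmannSet,
    RankError,
    ShapeError,
    frechet_mean,
    orthonormalize,
)


class ConfigurationError(GrassmannError):
    """An FMGDA configuration is inconsistent with the data."""


class DegenerateProblemError(GrassmannError):
    """The within-scatter surrogate vanished; the trace ratio is undefined."""


class NumericError(GrassmannError):
    """The optimization produced a non-finite objective."""


@dataclass(frozen=True)
class FMGDAConfig:
    """Hyper-parameters of an FMGDA fit.

    Parameters
    ----------
    target_dim
        Reduced ambient dimension d, with p <= d < D.
    outer_iters
        Maximum number of surrogate-rebuild (outer) iterations.
    trace_ratio_iters
        Maximum iterations of the inner trace-ratio eigen solver.
    tol
        Relative-change stopping tolerance on the exact objective d_b/d_w.
    inner_tol
        Stopping tolerance on the trace-ratio value lambda.
    within_weighting
        "classwise" keeps the n_k factor inside the within-class double sum;
        "uniform" uses weight 1 per point (classical LDA convention).
    init
        "identity" starts from the first d coordinate axes (deterministic);
        "random" draws a seeded random orthonormal D x d start.
    seed
        Seed for the random initialization (unused for "identity").
    """

    target_dim: int
    outer_iters: int = 20
    trace_ratio_iters: int = 50
    tol: float = 1e-6
    inner_tol: float = 1e-8
    within_weighting: str = "classwise"
    init: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_dim < 1:
            raise ConfigurationError("target_dim must be >= 1")
        if self.outer_iters < 1 or self.trace_ratio_iters < 1:
            raise ConfigurationError("iteration counts must be >= 1")
        if self.tol <= 0 or self.inner_tol <= 0:
            raise ConfigurationError("tolerances must be > 0")
        if self.within_weighting not in ("classwise", "uniform"):
            raise ConfigurationError(
                f"within_weighting must be 'classwise' or 'uniform', "
                f"got {self.within_weighting!r}"
            )
        if self.init not in ("identity", "random"):
            raise ConfigurationError(f"init must be 'identity' or 'random', got {self.init!r}")


@dataclass(frozen=True)
class FMGDAModel:
    """A fitted FMGDA mapping plus diagnostics.

    ``A`` is the learned D x d mapping (orthonormal columns as returned by
    the trace-ratio solver, though :func:`transform` never relies on that);
    ``objective_trace`` records the exact objective d_b/d_w at
    initialization and after every outer iteration; ``lambda_traces`` holds
    the inner trace-ratio value sequence of each outer iteration.
    """

    A: np.ndarray
    class_means: tuple[GrassmannPoint, ...]
    global_mean: GrassmannPoint
    objective_trace: np.ndarray
    lambda_traces: tuple[np.ndarray, ...]
    config: FMGDAConfig
    label_names: tuple[str, ...] | None = None

    @property
    def ambient_dim(self) -> int:
        return self.A.shape[0]

    @property
    def target_dim(self) -> int:
        return self.A.shape[1]


def class_frechet_means(
    data: LabeledGrassmannSet,
) -> tuple[list[GrassmannPoint], GrassmannPoint]:
    """Per-class Frechet means M^(k) and the global Frechet mean M."""
    per_class = [frechet_mean(data.class_bases(k)) for k in range(data.n_classes)]
    return per_class, frechet_mean(data.bases)


def _primed(A: np.ndarray, basis: np.ndarray, what: str) -> np.ndarray:
    """Normalized representative X' = X R^{-1} where A^T X = Q R.

    A^T X' is then orthonormal and spans the same subspace as A^T X.
    """
    Y = A.T @ basis
    try:
        _, R = orthonormalize(Y)
    except RankError as exc:
        raise RankError(f"A^T {what} is rank deficient: {exc}") from exc
    # X' = X R^{-1}  <=>  X'^T = R^{-T} X^T with R^T lower-triangular
    return scipy.linalg.solve_triangular(R.T, basis.T, lower=True).T


def _class_weights(data: LabeledGrassmannSet, weighting: str) -> np.ndarray:
    if weighting == "classwise":
        return data.class_sizes.astype(float)
    if weighting == "uniform":
        return np.ones(data.n_classes)
    raise ConfigurationError(f"unknown within_weighting {weighting!r}")


def scatter_surrogates(
    data: LabeledGrassmannSet,
    class_means: list[GrassmannPoint],
    global_mean: GrassmannPoint,
    A_prev: np.ndarray,
    weighting: str = "classwise",
) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic between/within scatter surrogates B~ and Q~ at A_prev.

    With all primed (QR-normalized) quantities frozen at ``A_prev``:

        B~ = sum_k n_k B^(k) A A^T B^(k),   B^(k) = M'^(k) M'^(k)T - M' M'T
        Q~ = sum_k sum_i w_k Q_ik A A^T Q_ik,
                                  Q_ik = X'_i^(k) X'_i^(k)T - M'^(k) M'^(k)T

    Both are D x D, symmetric and PSD, and satisfy
    tr(A^T B~ A) / tr(A^T Q~ A) = d_b(A)/d_w(A) at A = A_prev.  They are
    assembled through their rank factors (each summand is (S A)(S A)^T for
    a symmetric S), then explicitly symmetrized for numerical hygiene.
    """
    A = np.asarray(A_prev, dtype=float)
    D = data.ambient_dim
    if A.shape[0] != D:
        raise ShapeError(f"A_prev has {A.shape[0]} rows, data is {D}-dimensional")
    n_k = data.class_sizes.astype(float)
    w_k = _class_weights(data, weighting)

    Mg = _primed(A, global_mean.basis, "global mean")
    MgA = Mg @ (Mg.T @ A)  # M' M'^T A, D x d
    B_cols = []
    Q_cols = []
    for k in range(data.n_classes):
        Mk = _primed(A, class_means[k].basis, f"class {k} mean")
        MkA = Mk @ (Mk.T @ A)
        B_cols.append(np.sqrt(n_k[k]) * (MkA - MgA))
        for i, basis in enumerate(data.class_bases(k)):
            Xp = _primed(A, basis, f"point {i} of class {k}")
            Q_cols.append(np.sqrt(w_k[k]) * (Xp @ (Xp.T @ A) - MkA))
    Hb = np.concatenate(B_cols, axis=1)
    Hq = np.concatenate(Q_cols, axis=1)
    Btil = Hb @ Hb.T
    Qtil = Hq @ Hq.T
    return 0.5 * (Btil + Btil.T), 0.5 * (Qtil + Qtil.T)


def exact_objective(
    data: LabeledGrassmannSet,
    class_means: list[GrassmannPoint],
    global_mean: GrassmannPoint,
    A: np.ndarray,
    weighting: str = "classwise",
) -> tuple[float, float, float]:
    """Exact (d_b, d_w, d_b/d_w) at A, with fresh QR normalizations.

    delta_P distances are evaluated between the orthonormalized reduced
    bases f(., A) in G(p, d).  A zero d_w (perfect within-class collapse)
    yields an infinite ratio.
    """
    A = np.asarray(A, dtype=float)
    p = data.subspace_dim

    def f(basis: np.ndarray, what: str) -> np.ndarray:
        Y = A.T @ basis
        try:
            Q, _ = orthonormalize(Y)
        except RankError as exc:
            raise RankError(f"A^T {what} is rank deficient: {exc}") from exc
        return Q

    fM = f(global_mean.basis, "global mean")
    n_k = data.class_sizes.astype(float)
    w_k = _class_weights(data, weighting)
    d_b = 0.0
    d_w = 0.0
    for k in range(data.n_classes):
        fMk = f(class_means[k].basis, f"class {k} mean")
        cross = fMk.T @ fM
        d_b += n_k[k] * max(p - np.sum(cross * cross), 0.0)
        for i, basis in enumerate(data.class_bases(k)):
            fX = f(basis, f"point {i} of class {k}")
            cross = fX.T @ fMk
            d_w += w_k[k] * max(p - np.sum(cross * cross), 0.0)
    ratio = np.inf if d_w == 0.0 else d_b / d_w
    return d_b, d_w, ratio


def solve_trace_ratio(
    B: np.ndarray,
    Q: np.ndarray,
    d: int,
    max_iters: int = 50,
    tol: float = 1e-8,
    A0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Maximize tr(A^T B A) / tr(A^T Q A) over orthonormal D x d matrices.

    Standard iterated shifted eigenproblem: repeat
    ``lambda <- tr(A^T B A)/tr(A^T Q A); A <- top-d eigenvectors of
    B - lambda Q`` until the lambda increment drops below ``tol``.  The
    lambda sequence is monotonically non-decreasing.

    Returns ``(A, lambda_star, lambda_trace)``.
    """
    B = np.asarray(B, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1] or B.shape != Q.shape:
        raise ShapeError(f"B and Q must be square and congruent, got {B.shape}, {Q.shape}")
    sym_tol = 1e-8 * max(np.linalg.norm(B), np.linalg.norm(Q), 1.0)
    if np.linalg.norm(B - B.T) > sym_tol or np.linalg.norm(Q - Q.T) > sym_tol:
        raise ShapeError("B and Q must be symmetric")
    D = B.shape[0]
    if not 1 <= d <= D:
        raise ConfigurationError(f"need 1 <= d <= D, got d={d}, D={D}")
    trQ = float(np.trace(Q))
    if trQ <= 0.0:
        raise DegenerateProblemError(
            "tr(Q) = 0: the within-scatter surrogate vanished; add a small "
            "ridge (eps * I) to Q before solving"
        )
    if A0 is None:
        A = np.eye(D)[:, :d]
    else:
        A = np.asarray(A0, dtype=float)
        if A.shape != (D, d):
            raise ShapeError(f"A0 must be {D}x{d}, got {A.shape}")
    lam_trace: list[float] = []
    lam_prev = -np.inf
    for _ in range(max_iters):
        num = float(np.einsum("ij,ik,jk->", B, A, A))
        den = float(np.einsum("ij,ik,jk->", Q, A, A))
        den = max(den, 1e-15 * trQ)
        lam = num / den
        lam_trace.append(lam)
        if lam - lam_prev < tol * (1.0 + abs(lam)) and len(lam_trace) > 1:
            break
        lam_prev = lam
        _, V = scipy.linalg.eigh(B - lam * Q)
        A = np.ascontiguousarray(V[:, ::-1][:, :d])
    return A, lam_trace[-1], np.asarray(lam_trace)


def _initial_mapping(D: int, d: int, config: FMGDAConfig) -> np.ndarray:
    if config.init == "identity":
        return np.eye(D)[:, :d]
    rng = np.random.default_rng(config.seed)
    Q, _ = orthonormalize(rng.standard_normal((D, d)))
    return Q


def fit(data: LabeledGrassmannSet, config: FMGDAConfig) -> FMGDAModel:
    """Fit FMGDA by alternating surrogate construction and trace-ratio solves.

    Each outer iteration rebuilds B~ and Q~ at the current A (one QR
    normalization per point per iteration), solves the trace ratio, and
    re-evaluates the exact objective d_b/d_w; the loop stops on relative
    objective change below ``config.tol``, on the d_w -> 0 guard (perfectly
    separated classes), or after ``config.outer_iters`` iterations.
    """
    D, p, d = data.ambient_dim, data.subspace_dim, config.target_dim
    if not p <= d < D:
        raise ConfigurationError(
            f"need subspace_dim <= target_dim < ambient_dim, "
            f"got p={p}, d={d}, D={D}"
        )
    means, global_mean = class_frechet_means(data)
    A = _initial_mapping(D, d, config)
    _, _, obj = exact_objective(data, means, global_mean, A, config.within_weighting)
    obj_trace = [obj]
    lam_traces: list[np.ndarray] = []
    for t in range(config.outer_iters):
        if not np.isfinite(obj_trace[-1]):
            break  # d_w -> 0: classes already perfectly collapsed
        Btil, Qtil = scatter_surrogates(
            data, means, global_mean, A, config.within_weighting
        )
        # d_w -> 0 guard: ridge Q~ so the trace ratio stays well posed
        if float(np.einsum("ij,ik,jk->", Qtil, A, A)) < 1e-12:
            trQ = float(np.trace(Qtil))
            eps = 1e-10 * trQ / D if trQ > 0 else 1e-10
            Qtil = Qtil + eps * np.eye(D)
        A_new, _, lam_trace = solve_trace_ratio(
            Btil, Qtil, d, config.trace_ratio_iters, config.inner_tol, A0=A
        )
        try:
            _, _, obj = exact_objective(
                data, means, global_mean, A_new, config.within_weighting
            )
        except RankError:
            # on (near-)separable data the solver can drift into a mapping
            # that annihilates part of a class subspace; keep the last
            # evaluable mapping instead
            warnings.warn(
                f"outer iteration {t}: trace-ratio step produced a mapping "
                f"with rank-deficient reduced bases; stopping early",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        lam_traces.append(lam_trace)
        if np.isnan(obj):
            raise NumericError(f"objective became NaN at outer iteration {t}")
        obj_trace.append(obj)
        A = A_new
        prev = obj_trace[-2]
        if np.isfinite(obj) and np.isfinite(prev):
            if abs(obj - prev) < config.tol * max(1.0, abs(prev)):
                break
    return FMGDAModel(
        A=A,
        class_means=tuple(means),
        global_mean=global_mean,
        objective_trace=np.asarray(obj_trace),
        lambda_traces=tuple(lam_traces),
        config=config,
        label_names=data.label_names,
    )


def transform(model: FMGDAModel, X: GrassmannPoint) -> GrassmannPoint:
    """Map one point to G(p, d): the orthonormalized columns of A^T X."""
    if X.ambient_dim != model.ambient_dim:
        raise ShapeError(
            f"point lives in dimension {X.ambient_dim}, model expects "
            f"{model.ambient_dim}"
        )
    Q, _ = orthonormalize(model.A.T @ X.basis)
    return GrassmannPoint(Q)


def transform_set(model: FMGDAModel, data: LabeledGrassmannSet) -> LabeledGrassmannSet:
    """Map every point of a labeled set, keeping labels and names."""
    if data.ambient_dim != model.ambient_dim:
        raise ShapeError(
            f"set lives in dimension {data.ambient_dim}, model expects "
            f"{model.ambient_dim}"
        )
    out = np.empty((data.n_points, model.target_dim, data.subspace_dim))
    for i in range(data.n_points):
        out[i], _ = orthonormalize(model.A.T @ data.bases[i])
    return LabeledGrassmannSet(out, data.labels, data.label_names)


def euclidean_lda_reference(
    vectors: np.ndarray, labels: np.ndarray, out_dim: int
) -> np.ndarray:
    """Classical LDA directions for plain vectors (test oracle only).

    Solves the generalized eigenproblem S_b a = lambda S_t a and returns
    the ``out_dim`` leading eigenvectors as columns.  S_b has rank at most
    K-1, so at most K-1 directions carry discriminative signal.  A singular
    total scatter S_t triggers a pseudo-inverse fallback with a warning.
    """
    X = np.asarray(vectors, dtype=float)
    y = np.asarray(labels, dtype=int)
    n, f = X.shape
    mu = X.mean(axis=0)
    Sb = np.zeros((f, f))
    for k in np.unique(y):
        Xk = X[y == k]
        dk = Xk.mean(axis=0) - mu
        Sb += len(Xk) * np.outer(dk, dk)
    Xc = X - mu
    St = Xc.T @ Xc
    try:
        w, V = scipy.linalg.eigh(Sb, St)
        order = np.argsort(w)[::-1]
    except scipy.linalg.LinAlgError:
        warnings.warn(
            "total scatter matrix is singular; falling back to pinv(S_t) S_b",
            RuntimeWarning,
            stacklevel=2,
        )
        w, V = np.linalg.eig(np.linalg.pinv(St) @ Sb)
        order = np.argsort(w.real)[::-1]
        V = V.real
    return V[:, order[:out_dim]]
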