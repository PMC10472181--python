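"""Functional principal component analysis on a dense evaluation grid.

Curves evaluated on a common grid are centered and the sample covariance
operator K(s, t) = (n-1)^-1 sum_i c_i(s) c_i(t) is eigendecomposed under the
trapezoidal inner product <f, g> = sum_i w_i f(t_i) g(t_i): with
W = diag(weights), the symmetric problem W^{1/2} K W^{1/2} u = lambda u is
solved densely, eigenvectors back-transformed by W^{-1/2} and normalized so
<phi, phi> = 1.  Components are retained up to a cumulative variance cutoff
(default 70%, capped at 2), oriented so PC1 points toward "high adherence
level" and PC2 toward "late behavior change", and summarized by per-curve
scores and mean +/- sqrt(lambda_k) phi_k perturbation curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh


@dataclass
class QuadratureGrid:
    """Grid points and trapezoidal weights defining the inner product."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.shape != self.weights.shape:
            raise ValueError("points and weights must have the same shape")
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")

    @classmethod
    def trapezoid(cls, points: np.ndarray) -> "QuadratureGrid":
        points = np.asarray(points, dtype=float)
        if points.size < 2 or np.any(np.diff(points) <= 0):
            raise ValueError("grid must be strictly increasing with >= 2 points")
        w = np.zeros_like(points)
        w[1:] += np.diff(points) / 2
        w[:-1] += np.diff(points) / 2
        return cls(points=points, weights=w)

    def inner(self, f: np.ndarray, g: np.ndarray) -> float:
        return float(np.sum(self.weights * f * g))


@dataclass
class FPCAModel:
    """Fitted FPCA: mean, orthonormal eigenfunctions, spectrum, and scores."""

    grid: QuadratureGrid
    mean_curve: np.ndarray  # (g,)
    eigenfunctions: np.ndarray  # (n_components, g), rows orthonormal under grid
    eigenvalues: np.ndarray  # (n_components,), descending, >= 0
    variance_proportions: np.ndarray
    scores: np.ndarray  # (n_participants, n_components)
    n_retained: int
    mission: str = ""
    participant_ids: list[str] | None = None


def grid_alignment(f: np.ndarray, g: np.ndarray, quad: QuadratureGrid) -> float:
    """|cos angle| between two functions under the quadrature inner product.

    The natural agreement measure for eigenfunctions, which are defined only
    up to sign and for which Pearson correlation degenerates when one function
    is constant.  1 means identical up to sign and scale.
    """
    num = quad.inner(f, g)
    den = np.sqrt(quad.inner(f, f) * quad.inner(g, g))
    if den == 0:
        raise ValueError("zero-norm function has no alignment")
    return abs(num) / den


def mean_function(values: np.ndarray) -> np.ndarray:
    """Pointwise arithmetic mean curve of a participant x grid matrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    return values.mean(axis=0)


def eigendecompose(
    centered: np.ndarray, quad: QuadratureGrid, center_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenfunctions (rows) and eigenvalues of the sample covariance operator.

    ``centered`` must have (numerically) zero column means.  Negative
    eigenvalues arising from roundoff are clipped at zero.
    """
    C = np.atleast_2d(np.asarray(centered, dtype=float))
    col_means = C.mean(axis=0)
    scale = max(1.0, float(np.abs(C).max(initial=0.0)))
    if np.abs(col_means).max(initial=0.0) > center_tol * scale:
        raise ValueError("input must be column-centered before eigendecomposition")
    n, g = C.shape
    if C.shape[1] != quad.points.size:
        raise ValueError("curve grid does not match quadrature grid")
    K = (C.T @ C) / (n - 1)
    sqw = np.sqrt(quad.weights)
    A = (sqw[:, None] * K) * sqw[None, :]
    evals, evecs = eigh(A)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    phis = (evecs[:, order] / sqw[:, None]).T  # rows phi_k, <phi,phi> = 1
    return phis, evals


def pc_scores(
    curve_values: np.ndarray,
    mean_curve: np.ndarray,
    eigenfunctions: np.ndarray,
    quad: QuadratureGrid,
) -> np.ndarray:
    """Scores <curve - mean, phi_k> under quadrature; rows curves, cols components."""
    curves = np.atleast_2d(np.asarray(curve_values, dtype=float))
    mean_curve = np.asarray(mean_curve, dtype=float)
    phis = np.atleast_2d(np.asarray(eigenfunctions, dtype=float))
    if curves.shape[1] != quad.points.size or mean_curve.size != quad.points.size:
        raise ValueError("curves, mean and quadrature grid sizes do not match")
    centered = curves - mean_curve
    return (centered * quad.weights) @ phis.T


def variance_proportions(eigenvalues: np.ndarray) -> np.ndarray:
    """lambda_k / sum(lambda); requires a not-all-zero nonnegative spectrum."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < 0):
        raise ValueError("eigenvalues must be nonnegative")
    total = ev.sum()
    if total == 0:
        raise ValueError("all-zero spectrum has no variance proportions")
    return ev / total


def retained_components(
    proportions: np.ndarray, cutoff: float = 0.70, max_k: int | None = None
) -> int:
    """Smallest K whose cumulative variance proportion reaches ``cutoff``.

    Capped at ``max_k`` when given; always at least 1.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    props = np.asarray(proportions, dtype=float)
    cum = np.cumsum(props)
    reached = np.flatnonzero(cum >= cutoff - 1e-12)
    k = int(reached[0]) + 1 if reached.size else props.size
    if max_k is not None:
        if k > max_k:
            warnings.warn(
                f"cumulative variance reaches {cutoff:.0%} only at K={k}; "
                f"capping at max_k={max_k}",
                stacklevel=2,
            )
        k = min(k, max_k)
    return max(k, 1)


def orient_components(model: FPCAModel) -> FPCAModel:
    """Fix eigenfunction signs to the field's interpretation (idempotent).

    PC1 is flipped (with its scores) so <phi_1, 1> > 0: positive scores mean
    overall high adherence.  PC2 is flipped so its mean over the final third
    of the domain exceeds its mean over the first third: positive scores mean
    late behavior change.  Components beyond 2 get their largest-magnitude
    entry made positive.  Reconstruction mean + sum_k score_k phi_k is
    unchanged.
    """
    phis = model.eigenfunctions.copy()
    scores = model.scores.copy()
    t = model.grid.points
    lo, hi = t[0], t[-1]
    third = (hi - lo) / 3
    for k in range(phis.shape[0]):
        if k == 0:
            stat = model.grid.inner(phis[0], np.ones_like(phis[0]))
        elif k == 1:
            late = phis[1][t >= hi - third].mean()
            early = phis[1][t <= lo + third].mean()
            stat = late - early
        else:
            stat = phis[k][np.argmax(np.abs(phis[k]))]
        if stat < 0:
            phis[k] = -phis[k]
            scores[:, k] = -scores[:, k]
        elif stat == 0:
            warnings.warn(
                f"component {k + 1}: orientation statistic is exactly zero; "
                "sign left unchanged",
                stacklevel=2,
            )
    return FPCAModel(
        grid=model.grid,
        mean_curve=model.mean_curve,
        eigenfunctions=phis,
        eigenvalues=model.eigenvalues,
        variance_proportions=model.variance_proportions,
        scores=scores,
        n_retained=model.n_retained,
        mission=model.mission,
        participant_ids=model.participant_ids,
    )


def perturbation_curves(
    model: FPCAModel, k: int, multiple: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- multiple * sqrt(lambda_k) * phi_k on the grid (k is 1-based)."""
    if not 1 <= k <= model.eigenvalues.size:
        raise ValueError(f"component {k} out of range")
    lam = model.eigenvalues[k - 1]
    if lam == 0:
        warnings.warn(f"component {k} has zero variance; returning the mean curve",
                      stacklevel=2)
        return model.mean_curve.copy(), model.mean_curve.copy()
    offset = multiple * np.sqrt(lam) * model.eigenfunctions[k - 1]
    return model.mean_curve + offset, model.mean_curve - offset


def fit_fpca(
    values: np.ndarray,
    grid: np.ndarray,
    cutoff: float = 0.70,
    max_k: int | None = 2,
    mission: str = "",
    participant_ids: list[str] | None = None,
) -> FPCAModel:
    """Full FPCA of a participant x grid value matrix, oriented and scored."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    quad = QuadratureGrid.trapezoid(grid)
    mean = mean_function(values)
    centered = values - mean
    phis, evals = eigendecompose(centered, quad)
    props = variance_proportions(evals) if evals.sum() > 0 else np.zeros_like(evals)
    n_ret = retained_components(props, cutoff, max_k) if evals.sum() > 0 else 1
    scores = pc_scores(values, mean, phis, quad)
    model = FPCAModel(
        grid=quad,
        mean_curve=mean,
        eigenfunctions=phis,
        eigenvalues=evals,
        variance_proportions=props,
        scores=scores,
        n_retained=n_ret,
        mission=mission,
        participant_ids=participant_ids,
    )
    return orient_components(model)
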