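"""Roughness-penalized B-spline smoothing of discrete adherence series.

Each participant's biweekly Likert series is converted into a smooth curve by
minimizing

    sum_i (y_i - f(t_i))^2 + lambda * int f''(t)^2 dt

over cubic B-spline expansions f = sum_j c_j B_j.  The penalty matrix is
computed exactly by Gauss-Legendre quadrature per knot span, and lambda is
chosen by generalized cross-validation (GCV) on a log grid; one shared lambda
per mission (the grid value nearest the median of per-participant GCV picks)
keeps curves comparable across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

DEFAULT_LAMBDA_GRID: np.ndarray = np.geomspace(1e-6, 1e6, 25)


@dataclass
class SplineBasis:
    """Open-uniform B-spline basis on [t_min, t_max] (order 4 = cubic)."""

    knots: np.ndarray  # full knot vector with order-fold boundary knots
    order: int
    n_basis: int
    domain: tuple[float, float]

    @property
    def degree(self) -> int:
        return self.order - 1

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(f"evaluation points outside basis domain [{lo}, {hi}]")
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False).toarray()

    def derivative_matrix(self, x: np.ndarray, deriv: int) -> np.ndarray:
        """Values of the ``deriv``-th derivative of each basis function at x."""
        x = np.asarray(x, dtype=float)
        spl = BSpline(self.knots, np.eye(self.n_basis), self.degree, extrapolate=True)
        return spl.derivative(deriv)(x)


@dataclass
class SmoothingConfig:
    """Settings for the penalized fit; ``lambda_smooth="gcv"`` selects by GCV."""

    lambda_smooth: float | str = "gcv"
    penalty_order: int = 2
    n_basis: int | None = None  # default min(13, n_obs)
    order: int = 4
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())

    def __post_init__(self) -> None:
        if isinstance(self.lambda_smooth, str):
            if self.lambda_smooth != "gcv":
                raise ValueError("lambda_smooth must be a number or 'gcv'")
        elif self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)


@dataclass
class SmoothCurveSet:
    """Fitted smooth curves for one mission: shared basis + coefficient rows."""

    basis: SplineBasis
    coefficients: np.ndarray  # (n_participants, n_basis)
    mission: str = ""
    lambda_smooth: float = 0.0
    participant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("spline coefficients must be finite")


def build_basis(obs_weeks: np.ndarray, n_basis: int | None = None, order: int = 4) -> SplineBasis:
    """Open-uniform knot vector over [min week, max week].

    ``n_basis`` defaults to min(13, number of observation points).  Interior
    knots (n_basis - order of them) are evenly spaced; the basis is a partition
    of unity on the domain.
    """
    weeks = np.unique(np.asarray(obs_weeks, dtype=float))
    if weeks.size < 2:
        raise ValueError("need at least 2 distinct weeks")
    if n_basis is None:
        n_basis = min(13, weeks.size)
    if n_basis < order:
        raise ValueError(f"n_basis ({n_basis}) must be >= order ({order})")
    lo, hi = weeks[0], weeks[-1]
    n_interior = n_basis - order
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([np.full(order, lo), interior, np.full(order, hi)])
    return SplineBasis(knots=knots, order=order, n_basis=n_basis, domain=(lo, hi))


def penalty_matrix(basis: SplineBasis, deriv: int = 2) -> np.ndarray:
    """P_jk = int B_j^(deriv) B_k^(deriv) dt, exact Gauss-Legendre per knot span."""
    breaks = np.unique(basis.knots)
    # integrand is piecewise polynomial of degree 2*(degree - deriv)
    npts = max(basis.degree - deriv + 1, 1) + 1
    nodes, wts = np.polynomial.legendre.leggauss(npts)
    P = np.zeros((basis.n_basis, basis.n_basis))
    for a, b in zip(breaks[:-1], breaks[1:]):
        x = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        w = 0.5 * (b - a) * wts
        D = basis.derivative_matrix(x, deriv)
        P += D.T @ (D * w[:, None])
    return P


def fit_penalized_spline(
    y: np.ndarray,
    weeks: np.ndarray,
    basis: SplineBasis,
    lambda_smooth: float,
    penalty_order: int = 2,
    _cache: dict | None = None,
) -> np.ndarray:
    """Coefficients minimizing ||y - Bc||^2 + lambda * c' P c.

    Solves the normal equations (B'B + lambda P) c = B'y.  At lambda = 0 a
    rank-deficient design raises rather than returning one of infinitely many
    interpolants.
    """
    y = np.asarray(y, dtype=float)
    if _cache is not None and "B" in _cache:
        B, P = _cache["B"], _cache["P"]
    else:
        B = basis.design_matrix(weeks)
        P = penalty_matrix(basis, penalty_order)
        if _cache is not None:
            _cache.update(B=B, P=P)
    if lambda_smooth == 0 and np.linalg.matrix_rank(B) < basis.n_basis:
        raise np.linalg.LinAlgError(
            "singular system: lambda = 0 with rank-deficient design matrix"
        )
    A = B.T @ B + lambda_smooth * P
    return np.linalg.solve(A, B.T @ y)


def _edf_and_rss(y, B, P, lam):
    A = B.T @ B + lam * P
    Ainv_BtB = np.linalg.solve(A, B.T @ B)
    coef = np.linalg.solve(A, B.T @ y)
    resid = y - B @ coef
    return float(np.trace(Ainv_BtB)), float(resid @ resid)


def gcv_score(y: np.ndarray, weeks: np.ndarray, basis: SplineBasis, lam: float,
              penalty_order: int = 2) -> float:
    """GCV(lambda) = n RSS / (n - tr H)^2 with H the smoother hat matrix."""
    y = np.asarray(y, dtype=float)
    B = basis.design_matrix(weeks)
    P = penalty_matrix(basis, penalty_order)
    n = y.size
    edf, rss = _edf_and_rss(y, B, P, lam)
    denom = (n - edf) ** 2
    if denom <= 0:
        return np.inf
    return n * rss / denom


def select_lambda_gcv(
    y: np.ndarray,
    weeks: np.ndarray,
    basis: SplineBasis,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    penalty_order: int = 2,
) -> float:
    """Grid lambda minimizing GCV; ties broken toward the larger lambda."""
    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("lambda_grid must be nonempty")
    y = np.asarray(y, dtype=float)
    B = basis.design_matrix(weeks)
    P = penalty_matrix(basis, penalty_order)
    n = y.size
    scores = np.empty(grid.size)
    for i, lam in enumerate(grid):
        edf, rss = _edf_and_rss(y, B, P, lam)
        denom = (n - edf) ** 2
        scores[i] = n * rss / denom if denom > 0 else np.inf
    best = np.flatnonzero(scores == scores.min())[-1]  # ascending grid -> larger lambda
    return float(grid[best])


def smooth_mission(
    values: np.ndarray,
    weeks: np.ndarray,
    config: SmoothingConfig | None = None,
    mission: str = "",
    participant_ids: list[str] | None = None,
) -> SmoothCurveSet:
    """Fit all participants of one mission with a shared smoothing penalty.

    With ``lambda_smooth="gcv"`` each participant's GCV-optimal lambda is found
    on the grid and the shared lambda is the grid value nearest the median in
    log space.
    """
    config = config or SmoothingConfig()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    weeks = np.asarray(weeks, dtype=float)
    basis = build_basis(weeks, n_basis=config.n_basis, order=config.order)
    if config.lambda_smooth == "gcv":
        picks = np.array([
            select_lambda_gcv(row, weeks, basis, config.lambda_grid, config.penalty_order)
            for row in values
        ])
        grid = np.sort(config.lambda_grid)
        target = np.median(np.log(picks))
        lam = float(grid[np.argmin(np.abs(np.log(grid) - target))])
    else:
        lam = float(config.lambda_smooth)
    cache: dict = {}
    coefs = np.vstack([
        fit_penalized_spline(row, weeks, basis, lam, config.penalty_order, _cache=cache)
        for row in values
    ])
    return SmoothCurveSet(
        basis=basis,
        coefficients=coefs,
        mission=mission,
        lambda_smooth=lam,
        participant_ids=participant_ids,
    )


def evaluate_curves(curves: SmoothCurveSet, grid: np.ndarray) -> np.ndarray:
    """Participant x grid matrix of curve values; no extrapolation."""
    B = curves.basis.design_matrix(grid)  # raises outside the domain
    return curves.coefficients @ B.T
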