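"""Elastic-net regression of the intervention outcome on phenotype scores.

The design couples the per-mission functional PC scores (5 missions x 2 PCs)
with 22 baseline covariates; columns are standardized so coefficient sizes
are comparable.  The elastic net minimizes

    (2n)^-1 ||y - b0 - X b||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||^2)

with the mixing fixed near ridge (alpha = 0.01) and lambda tuned by seeded
10-fold cross-validation over a 100-point log path.  Stability is assessed by
a two-stage protocol: (1) the CV + fit cycle is repeated with fresh fold
splits and each predictor's nonzero survival fraction recorded; (2) bootstrap
resamples of participants give median coefficients and percentile confidence
intervals on both the standardized and the original scale.  A predictor is
selected when its survival fraction strictly exceeds the threshold (default
10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold


@dataclass
class NetConfig:
    alpha: float = 0.01
    n_folds: int = 10
    n_reps: int = 1000
    n_boot: int = 500
    survival_threshold: float = 0.10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    ci_level: float = 0.95
    seed: int = 0
    standardize_outcome: bool = False
    global_lambda: bool = False  # bootstrap reuses the stage-1 median lambda

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for name in ("survival_threshold", "ci_level"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class StandardizationRecord:
    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray  # sample SD (n-1 denominator)
    y_mean: float
    y_sd: float


@dataclass
class StabilityFit:
    """Per-predictor stability-selection summary.

    ``table`` columns: beta_std_median / _lo / _hi (standardized scale),
    B_unstd_median / _lo / _hi (original scale), survival_fraction, selected,
    and reported_beta_std / reported_B_unstd (the point estimate with
    non-survivors zeroed out, as reported in the results tables).
    """

    table: pd.DataFrame
    log_lambda_median: float
    lambda_draws: np.ndarray  # stage-1 lambda_min per repetition
    boot_coefs_std: np.ndarray  # (n_boot, p) standardized-scale draws
    config: NetConfig
    record: StandardizationRecord


def assemble_design(
    scores: dict[str, pd.DataFrame], covariates: pd.DataFrame
) -> pd.DataFrame:
    """Join per-mission PC-score tables with the covariate table.

    ``scores`` maps mission id to a DataFrame indexed by participant_id with
    columns pc1, pc2, ...; output columns are M1_pc1 ... M5_pc2 followed by
    the covariates, rows sorted by participant id.
    """
    cov = covariates.copy()
    if "participant_id" in cov.columns:
        cov = cov.set_index("participant_id")
    ref = set(cov.index)
    blocks = []
    for mission in sorted(scores):
        df = scores[mission]
        if "participant_id" in df.columns:
            df = df.set_index("participant_id")
        if set(df.index) != ref:
            extra = sorted(set(df.index) - ref)
            lacking = sorted(ref - set(df.index))
            raise ValueError(
                f"participant mismatch for mission {mission}: "
                f"not in covariates {extra}; missing scores {lacking}"
            )
        blocks.append(df.rename(columns={c: f"{mission}_{c}" for c in df.columns}))
    design = pd.concat(blocks + [cov], axis=1).sort_index()
    if design.isna().any().any():
        raise ValueError("design matrix has missing cells")
    return design


def standardize(
    X: pd.DataFrame, y: pd.Series, standardize_outcome: bool = False
) -> tuple[pd.DataFrame, pd.Series, StandardizationRecord]:
    """Center/scale columns by sample mean and SD (n-1 denominator)."""
    mean = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=1).to_numpy()
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance columns: {list(X.columns[zero])}")
    Xs = (X - mean) / sd
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    ys = (y - y_mean) / y_sd if standardize_outcome else y.copy()
    record = StandardizationRecord(
        columns=list(X.columns), mean=mean, sd=sd, y_mean=y_mean, y_sd=y_sd
    )
    return Xs, ys, record


def elastic_net_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambda_: float,
    tol: float = 1e-9,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Single elastic-net solve by cyclic coordinate descent (scikit-learn).

    At lambda = 0 the unpenalized least-squares solution is returned.
    Returns (coefficients, intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or outcome")
    if lambda_ == 0:
        Z = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        return beta[1:], float(beta[0])
    model = ElasticNet(
        alpha=lambda_, l1_ratio=alpha, fit_intercept=True, tol=tol, max_iter=max_iter,
        precompute=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"coordinate descent did not converge at lambda={lambda_:g}, "
                f"alpha={alpha:g} within {max_iter} sweeps"
            ) from exc
    return model.coef_.copy(), float(model.intercept_)


def lambda_path(X: np.ndarray, y: np.ndarray, alpha: float,
                n_lambda: int = 100, min_ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced path from lambda_max = max|x_j'y| / (n max(alpha, 1e-3))."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    lam_max = float(np.abs(X.T @ (y - y.mean())).max()) / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    config: NetConfig,
    fold_seed: int,
    lambdas: np.ndarray | None = None,
    tol: float = 1e-6,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean-squared-error cross-validation over the lambda path.

    Returns (lambda_min, path, mean CV errors); folds are a seeded shuffled
    K-fold split.  Ties go to the larger lambda (first on the descending path).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n // config.n_folds < 2:
        raise ValueError("fewer than 2 observations per fold")
    if lambdas is None:
        lambdas = lambda_path(X, y, config.alpha, config.n_lambda, config.lambda_min_ratio)
    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=fold_seed)
    sse = np.zeros(lambdas.size)
    for train, test in kf.split(X):
        Xtr, ytr = X[train], y[train]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        _, coefs, _ = enet_path(
            Xtr - xm, ytr - ym, l1_ratio=max(config.alpha, 1e-12),
            alphas=lambdas, tol=tol,
        )
        pred = (X[test] - xm) @ coefs + ym  # (n_test, n_lambda)
        sse += ((pred - y[test][:, None]) ** 2).sum(axis=0)
    cv_mse = sse / n
    return float(lambdas[int(np.argmin(cv_mse))]), lambdas, cv_mse


def _child_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0]) % (2**31)


def stability_selection(
    X: pd.DataFrame, y: pd.Series, config: NetConfig
) -> StabilityFit:
    """Two-stage repeated-CV / bootstrap elastic-net protocol.

    Stage 1 repeats [CV-tune lambda, fit, record nonzero pattern] ``n_reps``
    times with fresh fold splits on the full sample; stage 2 draws ``n_boot``
    participant bootstrap resamples and records the refitted coefficients
    (re-tuning lambda per resample unless ``global_lambda``).  The raw design
    is standardized internally; both coefficient scales are reported.
    """
    Xs, ys, record = standardize(X, y, config.standardize_outcome)
    Xv = Xs.to_numpy(dtype=float)
    yv = ys.to_numpy(dtype=float)
    n, p = Xv.shape
    path = lambda_path(Xv, yv, config.alpha, config.n_lambda, config.lambda_min_ratio)

    # stage 1: survival fractions over repeated CV fold splits
    nonzero = np.zeros(p)
    lam_draws = np.empty(config.n_reps)
    for r in range(config.n_reps):
        lam, _, _ = cv_lambda(Xv, yv, config, _child_seed(config.seed, 1, r), lambdas=path)
        coef, _ = elastic_net_fit(Xv, yv, config.alpha, lam)
        nonzero += coef != 0
        lam_draws[r] = lam
    survival = nonzero / config.n_reps
    lam_global = float(np.exp(np.median(np.log(lam_draws))))

    # stage 2: bootstrap medians and percentile CIs
    boot = np.empty((config.n_boot, p))
    for b in range(config.n_boot):
        child = np.random.SeedSequence(config.seed, spawn_key=(2, b))
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        Xb, yb = Xv[idx], yv[idx]
        if config.global_lambda:
            lam = lam_global
        else:
            lam, _, _ = cv_lambda(Xb, yb, config, _child_seed(config.seed, 3, b))
        coef, _ = elastic_net_fit(Xb, yb, config.alpha, lam)
        boot[b] = coef

    lo_q, hi_q = (1 - config.ci_level) / 2, 1 - (1 - config.ci_level) / 2
    med = np.median(boot, axis=0)
    lo = np.quantile(boot, lo_q, axis=0)
    hi = np.quantile(boot, hi_q, axis=0)
    # coefficient scales: fits used standardized X and (by default) raw y, so
    # beta_std = coef / sd_y and B_unstd = coef / sd_x
    y_scale = 1.0 if config.standardize_outcome else record.y_sd
    selected = survival > config.survival_threshold
    table = pd.DataFrame(
        {
            "beta_std_median": med / y_scale,
            "beta_std_lo": lo / y_scale,
            "beta_std_hi": hi / y_scale,
            "B_unstd_median": med / record.sd * (record.y_sd if config.standardize_outcome else 1.0),
            "B_unstd_lo": lo / record.sd * (record.y_sd if config.standardize_outcome else 1.0),
            "B_unstd_hi": hi / record.sd * (record.y_sd if config.standardize_outcome else 1.0),
            "survival_fraction": survival,
            "selected": selected,
        },
        index=pd.Index(record.columns, name="predictor"),
    )
    table["reported_beta_std"] = np.where(selected, table["beta_std_median"], 0.0)
    table["reported_B_unstd"] = np.where(selected, table["B_unstd_median"], 0.0)
    return StabilityFit(
        table=table,
        log_lambda_median=float(np.log(lam_global)),
        lambda_draws=lam_draws,
        boot_coefs_std=boot,
        config=config,
        record=record,
    )
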