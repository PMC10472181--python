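"""Synthetic adherence cohorts with a latent two-phenotype structure.

The generator emulates a pediatric obesity mHealth intervention cohort:
~88 analyzable participants, five daily behavior goals ("missions"),
biweekly 5-point Likert adherence ratings over weeks 1-25, first/last
observations always present, and interior cells missing completely at
random.  Each participant x mission trajectory is

    x(t) = mu(t) + level * phi_level(t) + timing * phi_timing(t) + noise,

discretized to the Likert scale.  ``phi_level`` is a constant function
(consistently high vs low adherence) and ``phi_timing`` a zero-mean
sigmoid transition centered near week 9 (late vs early behavior change);
both are unit-norm under trapezoidal quadrature on the observation grid.
The continuous outcome (BMI z-score change) is a linear function of the
latent scores and covariates plus Gaussian noise, so downstream recovery
of eigenfunctions, coefficients, and cluster structure can be tested
against stored ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AdherencePanel

#: The 22 baseline covariates of the adjustment set, already scored.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "age",
    "sex",
    "income",
    "baseline_bmi_z",
    "self_esteem",
    "internalizing",
    "externalizing",
    "stages_of_change",
    "beverage_intake",
    "vegetable_intake",
    "sleep_duration",
    "screen_time",
    "exercise_frequency",
    "attendance_rate",
    "maternal_bmi",
    "paternal_bmi",
    "maternal_stress",
    "paternal_stress",
    "maternal_positive_parenting",
    "paternal_positive_parenting",
    "maternal_negative_parenting",
    "paternal_negative_parenting",
)

DEFAULT_OBS_WEEKS: tuple[float, ...] = tuple(range(1, 26, 2))  # 13 biweekly points


def default_outcome_betas(n_missions: int = 5, n_covariates: int = 22) -> np.ndarray:
    """True outcome coefficients: 4 nonzero latent-score effects, null covariates.

    Order: [M1_level, M1_timing, ..., Mn_level, Mn_timing, covariates...].
    """
    beta = np.zeros(2 * n_missions + n_covariates)
    beta[0] = -0.30  # mission 1 level
    if n_missions >= 2:
        beta[3] = 0.30  # mission 2 timing
    if n_missions >= 3:
        beta[4] = 0.30  # mission 3 level
    if n_missions >= 5:
        beta[9] = -0.30  # mission 5 timing
    return beta


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_participants: int = 88
    n_missions: int = 5
    obs_weeks: tuple[float, ...] = DEFAULT_OBS_WEEKS
    level_sd: float = 1.0
    timing_sd: float = 0.6
    changepoint_week: float = 9.0
    transition_scale: float = 1.0  # logistic time scale; ~4.4 weeks for 12%->88%
    noise_sd: float = 0.3
    missing_rate: float = 0.10
    mean_baseline: float = 2.8
    mean_gain: float = 0.8
    outcome_betas: np.ndarray | None = None
    outcome_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        weeks = np.asarray(self.obs_weeks, dtype=float)
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if weeks.size < 3:
            raise ValueError("need at least 3 observation weeks")
        if np.any(np.diff(weeks) <= 0):
            raise ValueError("obs_weeks must be strictly increasing")
        for name in ("level_sd", "timing_sd", "noise_sd", "outcome_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not weeks[0] <= self.changepoint_week <= weeks[-1]:
            raise ValueError("changepoint_week must lie within the observation window")
        self.obs_weeks = tuple(weeks)
        if self.outcome_betas is None:
            self.outcome_betas = default_outcome_betas(self.n_missions)
        self.outcome_betas = np.asarray(self.outcome_betas, dtype=float)
        expected = 2 * self.n_missions + len(COVARIATE_COLUMNS)
        if self.outcome_betas.shape != (expected,):
            raise ValueError(f"outcome_betas must have length {expected}")

    @property
    def mission_ids(self) -> list[str]:
        return [f"M{j + 1}" for j in range(self.n_missions)]


@dataclass
class SimTruth:
    """Ground truth stored alongside a generated cohort for recovery tests."""

    latent_scores: np.ndarray  # (n, n_missions, 2): level, timing
    true_eigenfunctions: np.ndarray  # (2, w) on obs_weeks: phi_level, phi_timing
    true_outcome_betas: np.ndarray
    covariates: pd.DataFrame
    continuous_trajectories: np.ndarray = field(default=None)  # type: ignore[assignment]
    # (n, w, m): pre-discretization trajectories (mean + modes + noise)
    mean_profile: np.ndarray = field(default=None)  # type: ignore[assignment]

    def reproduce_outcome(self) -> np.ndarray:
        """Noise-free outcome implied by the stored scores and covariates."""
        n, m, _ = self.latent_scores.shape
        scores_flat = self.latent_scores.reshape(n, 2 * m)
        cov = self.covariates[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
        return np.concatenate([scores_flat, cov], axis=1) @ self.true_outcome_betas


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    w = np.zeros_like(grid)
    w[1:] += np.diff(grid) / 2
    w[:-1] += np.diff(grid) / 2
    return w


def mean_profile(t: np.ndarray, baseline: float = 2.8, gain: float = 0.8,
                 changepoint: float = 9.0) -> np.ndarray:
    """Population-mean adherence: gentle logistic improvement over the study."""
    t = np.asarray(t, dtype=float)
    return baseline + gain / (1.0 + np.exp(-(t - changepoint) / 3.0))


def level_shape(t: np.ndarray, domain: tuple[float, float]) -> np.ndarray:
    """Constant mode of variation, unit-norm on the full domain: 1/sqrt(T)."""
    t = np.asarray(t, dtype=float)
    length = domain[1] - domain[0]
    return np.full(t.shape, 1.0 / np.sqrt(length))


def timing_shape(t: np.ndarray, changepoint: float, scale: float,
                 quad_grid: np.ndarray) -> np.ndarray:
    """Zero-mean logistic transition, unit-norm under quadrature on ``quad_grid``.

    Positive scores mean low-then-rising adherence (late change); negative
    scores the mirror image (early change that fades).  Mean-centering makes
    the mode orthogonal to the constant level mode.
    """
    t = np.asarray(t, dtype=float)
    quad_grid = np.asarray(quad_grid, dtype=float)
    w = trapezoid_weights(quad_grid)

    def raw(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(x - changepoint) / scale))

    on_grid = raw(quad_grid)
    center = np.sum(w * on_grid) / np.sum(w)
    norm = np.sqrt(np.sum(w * (on_grid - center) ** 2))
    return (raw(t) - center) / norm


def discretize_likert(x: float | np.ndarray) -> np.ndarray:
    """Round half away from zero, then clamp to the 1-5 Likert range."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("discretize_likert requires finite input")
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(rounded, 1.0, 5.0)


def apply_missingness(panel: AdherencePanel, rate: float, seed: int) -> AdherencePanel:
    """Mask interior cells independently with probability ``rate`` (MCAR).

    Endpoint cells (first and last week of every participant x mission) are
    never masked.  Values stay in place as a shadow copy; only the mask changes.
    """
    if not 0 <= rate < 1:
        raise ValueError("missing rate must be in [0, 1)")
    out = panel.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    draw = rng.random(out.values.shape) < rate
    draw[:, 0, :] = False
    draw[:, -1, :] = False
    out.mask &= ~draw
    return out


def generate_cohort(
    config: SimConfig,
) -> tuple[AdherencePanel, pd.DataFrame, pd.Series, SimTruth]:
    """Generate one synthetic cohort.

    Returns the adherence panel (Likert values + missingness mask), the
    covariate table, the outcome vector (BMI z-score change, post minus pre),
    and the ground truth used by recovery tests.  Identical config (including
    seed) gives bit-identical output.
    """
    weeks = np.asarray(config.obs_weeks, dtype=float)
    n, w, m = config.n_participants, weeks.size, config.n_missions
    # spawn once, fixed order -> stable independent streams per ingredient
    children = np.random.SeedSequence(config.seed).spawn(5)
    rng_scores = np.random.default_rng(children[0])
    rng_noise = np.random.default_rng(children[1])
    rng_cov = np.random.default_rng(children[2])
    rng_out = np.random.default_rng(children[3])
    missing_seed = int(children[4].generate_state(1)[0])

    domain = (weeks[0], weeks[-1])
    phi_level = level_shape(weeks, domain)
    phi_timing = timing_shape(weeks, config.changepoint_week, config.transition_scale, weeks)
    mu = mean_profile(weeks, config.mean_baseline, config.mean_gain, config.changepoint_week)

    # latent scores, centered per mission so sample means are exactly zero
    scores = rng_scores.normal(size=(n, m, 2)) * np.array([config.level_sd, config.timing_sd])
    scores -= scores.mean(axis=0, keepdims=True)

    # trajectory: (n, w, m)
    traj = (
        mu[None, :, None]
        + phi_level[None, :, None] * scores[:, :, 0][:, None, :]
        + phi_timing[None, :, None] * scores[:, :, 1][:, None, :]
    )
    if config.noise_sd > 0:
        traj = traj + rng_noise.normal(scale=config.noise_sd, size=traj.shape)
    likert = discretize_likert(traj)

    participant_ids = [f"P{i + 1:03d}" for i in range(n)]
    panel = AdherencePanel(
        participant_ids=participant_ids,
        mission_ids=config.mission_ids,
        obs_weeks=weeks,
        values=likert,
    )
    panel = apply_missingness(panel, config.missing_rate, missing_seed)

    covariates = _generate_covariates(participant_ids, rng_cov)

    cov_values = covariates[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    design = np.concatenate([scores.reshape(n, 2 * m), cov_values], axis=1)
    outcome_values = design @ config.outcome_betas
    if config.outcome_noise_sd > 0:
        outcome_values = outcome_values + rng_out.normal(
            scale=config.outcome_noise_sd, size=n
        )
    outcome = pd.Series(outcome_values, index=pd.Index(participant_ids, name="participant_id"),
                        name="delta_bmi_z")

    truth = SimTruth(
        latent_scores=scores,
        true_eigenfunctions=np.vstack([phi_level, phi_timing]),
        true_outcome_betas=config.outcome_betas.copy(),
        covariates=covariates,
        continuous_trajectories=traj,
        mean_profile=mu,
    )
    return panel, covariates, outcome, truth


def _generate_covariates(participant_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """22 baseline covariates: binary sex ~ Bernoulli(0.7), the rest N(0, 1).

    Covariates are generated independently; they stand in for already-scored
    questionnaire and anthropometric measures.
    """
    n = len(participant_ids)
    data = {}
    for name in COVARIATE_COLUMNS:
        if name == "sex":
            data[name] = rng.binomial(1, 0.7, size=n).astype(float)
        else:
            data[name] = rng.normal(size=n)
    df = pd.DataFrame(data, index=pd.Index(participant_ids, name="participant_id"))
    return df
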