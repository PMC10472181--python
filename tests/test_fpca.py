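"""FPCA: closed forms, dense-eigensolver oracle, retention, orientation, scores."""

import contextlib

import numpy as np
import pytest
from scipy.linalg import eig as dense_eig

from trajphen import (
    QuadratureGrid,
    eigendecompose,
    fit_fpca,
    mean_function,
    orient_components,
    pc_scores,
    perturbation_curves,
    retained_components,
    variance_proportions,
)
from trajphen.fpca import grid_alignment

GRID = np.linspace(1, 25, 25)


def oracle_eigendecompose(centered, quad):
    """Independent route: non-symmetric eigenproblem of K W (covariance times weights)."""
    n = centered.shape[0]
    K = centered.T @ centered / (n - 1)
    W = np.diag(quad.weights)
    evals, evecs = dense_eig(K @ W)
    order = np.argsort(evals.real)[::-1]
    evals = np.clip(evals.real[order], 0, None)
    phis = []
    for k in range(evecs.shape[1]):
        v = evecs[:, order[k]].real
        v = v / np.sqrt(quad.inner(v, v))
        phis.append(v)
    return np.array(phis), evals


class TestMeanFunction:
    def test_identical_curves(self):
        curve = np.sin(GRID)
        assert np.allclose(mean_function(np.tile(curve, (4, 1))), curve)

    def test_symmetric_pair_cancels(self):
        c = np.cos(GRID)
        assert np.allclose(mean_function(np.vstack([c, -c])), 0.0)

    def test_matches_column_mean_oracle(self, rng):
        values = rng.normal(size=(50, 13))
        assert np.allclose(mean_function(values), values.mean(axis=0), atol=1e-12)

    def test_rejects_single_curve(self):
        with pytest.raises(ValueError):
            mean_function(np.ones((1, 5)))


class TestEigendecompose:
    def test_two_constant_curves_closed_form(self):
        # +/-1 constants on [1, 25]: phi1 = 1/sqrt(24), lambda1 = 48
        quad = QuadratureGrid.trapezoid(GRID)
        centered = np.vstack([np.ones(25), -np.ones(25)])
        phis, evals = eigendecompose(centered, quad)
        assert evals[0] == pytest.approx(48.0, abs=1e-9)
        assert np.allclose(np.abs(phis[0]), 1 / np.sqrt(24), atol=1e-9)
        assert np.allclose(evals[1:], 0.0, atol=1e-9)
        scores = pc_scores(centered, np.zeros(25), phis[:1], quad)
        assert np.allclose(np.abs(scores[:, 0]), np.sqrt(24), atol=1e-8)

    def test_degenerate_identical_curves(self):
        quad = QuadratureGrid.trapezoid(GRID)
        centered = np.zeros((5, 25))
        _, evals = eigendecompose(centered, quad)
        assert np.allclose(evals, 0.0)

    def test_matches_dense_oracle(self, rng):
        quad = QuadratureGrid.trapezoid(np.arange(1, 26, 2.0))
        values = rng.normal(size=(30, 13))
        centered = values - values.mean(axis=0)
        phis, evals = eigendecompose(centered, quad)
        o_phis, o_evals = oracle_eigendecompose(centered, quad)
        top = min(12, len(evals))
        assert np.allclose(evals[:top], o_evals[:top], atol=1e-8)
        for k in range(top):
            if evals[k] > 1e-10:
                assert abs(quad.inner(phis[k], o_phis[k])) >= 1 - 1e-8

    def test_rejects_uncentered_input(self, rng):
        quad = QuadratureGrid.trapezoid(GRID)
        with pytest.raises(ValueError):
            eigendecompose(rng.normal(3, 1, size=(10, 25)), quad)


class TestScores:
    def test_mean_curve_scores_zero(self, rng):
        values = rng.normal(size=(20, 25))
        model = fit_fpca(values, GRID)
        s = pc_scores(model.mean_curve, model.mean_curve, model.eigenfunctions,
                      model.grid)
        assert np.allclose(s, 0.0, atol=1e-10)

    def test_unit_displacement_along_eigenfunction(self, rng):
        values = rng.normal(size=(20, 25))
        model = fit_fpca(values, GRID)
        curve = model.mean_curve + 2 * model.eigenfunctions[0]
        s = pc_scores(curve, model.mean_curve, model.eigenfunctions[:2], model.grid)
        assert s[0, 0] == pytest.approx(2.0, abs=1e-8)
        assert s[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_closed_form_integral_on_unit_interval(self):
        # <t, sqrt(3)(2t-1)> on [0,1] = sqrt(3)/6
        for npts in (51, 201, 801):
            grid = np.linspace(0, 1, npts)
            quad = QuadratureGrid.trapezoid(grid)
            s = pc_scores(grid, np.zeros(npts), np.sqrt(3) * (2 * grid - 1), quad)
            if npts == 801:
                assert s[0, 0] == pytest.approx(np.sqrt(3) / 6, abs=1e-4)

    def test_grid_mismatch_rejected(self, rng):
        values = rng.normal(size=(10, 25))
        model = fit_fpca(values, GRID)
        with pytest.raises(ValueError):
            pc_scores(np.ones(13), model.mean_curve, model.eigenfunctions, model.grid)


class TestSpectrumSummaries:
    def test_variance_proportions_arithmetic(self):
        assert np.allclose(variance_proportions([6, 3, 1]), [0.6, 0.3, 0.1])
        assert np.allclose(variance_proportions([5.0]), [1.0])

    def test_variance_proportions_random_oracle(self, rng):
        ev = rng.uniform(0, 10, size=8)
        assert np.allclose(variance_proportions(ev), ev / ev.sum(), atol=1e-12)

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            variance_proportions(np.zeros(3))

    @pytest.mark.parametrize(
        "props, cutoff, max_k, expected",
        [
            ((0.69, 0.11, 0.10, 0.10), 0.70, None, 2),
            ((0.95, 0.05), 0.70, None, 1),
            ((0.48, 0.17, 0.15, 0.12, 0.08), 0.70, None, 3),
            ((0.48, 0.17, 0.15, 0.12, 0.08), 0.70, 2, 2),
            ((0.30, 0.25, 0.20, 0.15, 0.10), 1.00, None, 5),
        ],
    )
    def test_retention_rule(self, props, cutoff, max_k, expected):
        with pytest.warns(UserWarning) if (max_k and expected == max_k) else _noop():
            assert retained_components(np.array(props), cutoff, max_k) == expected

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            retained_components(np.array([1.0]), cutoff=0.0)
        with pytest.raises(ValueError):
            retained_components(np.array([1.0]), cutoff=1.5)


@contextlib.contextmanager
def _noop():
    yield


class TestOrientation:
    def test_negative_first_component_flipped(self, rng):
        values = rng.normal(size=(20, 25))
        model = fit_fpca(values, GRID)
        flipped = orient_components(_flip(model, 0))
        assert np.allclose(flipped.eigenfunctions[0], model.eigenfunctions[0])
        assert np.allclose(flipped.scores[:, 0], model.scores[:, 0])

    def test_idempotent(self, rng):
        values = rng.normal(size=(20, 25))
        model = fit_fpca(values, GRID)
        twice = orient_components(orient_components(model))
        assert np.allclose(twice.eigenfunctions, orient_components(model).eigenfunctions)
        assert np.allclose(twice.scores, orient_components(model).scores)

    def test_reconstruction_unchanged(self, rng):
        values = rng.normal(size=(15, 25))
        model = fit_fpca(values, GRID)
        flipped = orient_components(_flip(_flip(model, 0), 1))
        r1 = model.mean_curve + model.scores @ model.eigenfunctions
        r2 = flipped.mean_curve + flipped.scores @ flipped.eigenfunctions
        assert np.allclose(r1, r2, atol=1e-12)


def _flip(model, k):
    import dataclasses
    phis = model.eigenfunctions.copy()
    scores = model.scores.copy()
    phis[k] = -phis[k]
    scores[:, k] = -scores[:, k]
    return dataclasses.replace(model, eigenfunctions=phis, scores=scores)


class TestPerturbationCurves:
    def test_zero_multiple_returns_mean(self, rng):
        model = fit_fpca(rng.normal(size=(10, 25)), GRID)
        plus, minus = perturbation_curves(model, 1, multiple=0)
        assert np.allclose(plus, model.mean_curve)
        assert np.allclose(minus, model.mean_curve)

    def test_plus_minus_average_to_mean(self, rng):
        model = fit_fpca(rng.normal(size=(10, 25)), GRID)
        plus, minus = perturbation_curves(model, 2)
        assert np.allclose((plus + minus) / 2, model.mean_curve, atol=1e-12)

    def test_constant_eigenfunction_closed_form(self):
        # lambda = 4, phi = 1/sqrt(24) on [1, 25]: offset 2/sqrt(24) everywhere
        quad = QuadratureGrid.trapezoid(GRID)
        centered = np.vstack([np.ones(25), -np.ones(25)]) * np.sqrt(2.0)
        phis, evals = eigendecompose(centered, quad)
        from trajphen.fpca import FPCAModel
        model = FPCAModel(
            grid=quad, mean_curve=np.zeros(25), eigenfunctions=phis,
            eigenvalues=np.array([4.0]), variance_proportions=np.array([1.0]),
            scores=np.zeros((2, 1)), n_retained=1,
        )
        plus, minus = perturbation_curves(model, 1)
        assert np.allclose(np.abs(plus), 2 / np.sqrt(24), atol=1e-9)
        assert np.allclose(plus, -minus, atol=1e-12)

    def test_zero_eigenvalue_warns_and_returns_mean(self, rng):
        model = fit_fpca(np.tile(rng.normal(size=25), (3, 1)) + np.array([[1.], [0.], [-1.]]),
                         GRID)
        k_zero = int(np.flatnonzero(model.eigenvalues == 0)[0]) + 1
        with pytest.warns(UserWarning):
            plus, minus = perturbation_curves(model, k_zero)
        assert np.allclose(plus, model.mean_curve)


class TestModelInvariants:
    def test_orthonormality_score_variance_reconstruction(self, rng):
        values = rng.normal(size=(40, 25)) + 3
        model = fit_fpca(values, GRID)
        gram = (model.eigenfunctions * model.grid.weights) @ model.eigenfunctions.T
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-8
        for k, lam in enumerate(model.eigenvalues):
            if lam > 1e-8:
                sv = model.scores[:, k].var(ddof=1)
                assert abs(sv - lam) / lam < 1e-6
        recon = model.mean_curve + model.scores @ model.eigenfunctions
        assert np.abs(recon - values).max() < 1e-6

    def test_scores_stable_under_grid_refinement(self, rng):
        # evaluate the same smooth curves on 1x and 2x grids
        coarse = np.linspace(1, 25, 101)  # the pipeline's default evaluation grid
        fine = np.linspace(1, 25, 201)
        freqs = rng.uniform(0.1, 0.3, size=(12, 1))
        phases = rng.uniform(0, 2 * np.pi, size=(12, 1))
        make = lambda g: 3 + np.sin(freqs * g[None, :] + phases)
        m1 = fit_fpca(make(coarse), coarse)
        m2 = fit_fpca(make(fine), fine)
        assert np.abs(m1.scores[:, :2] - m2.scores[:, :2]).max() < 1e-3

    def test_recovery_on_noisy_continuous_cohort(self):
        # the generator's modes are recovered from noisy functional observations
        from trajphen import SimConfig, generate_cohort
        cfg = SimConfig(n_participants=200, seed=11, noise_sd=0.3,
                        level_sd=1.0, timing_sd=0.6)
        *_, truth = generate_cohort(cfg)
        weeks = np.asarray(cfg.obs_weeks)
        quad = QuadratureGrid.trapezoid(weeks)
        model = fit_fpca(truth.continuous_trajectories[:, :, 0], weeks)
        assert grid_alignment(model.eigenfunctions[0], truth.true_eigenfunctions[0], quad) >= 0.95
        assert grid_alignment(model.eigenfunctions[1], truth.true_eigenfunctions[1], quad) >= 0.95
        # PC1 share of observed-process variance (signal modes + white noise)
        lv = truth.latent_scores[:, 0, 0].var(ddof=1)
        tv = truth.latent_scores[:, 0, 1].var(ddof=1)
        noise_total = cfg.noise_sd**2 * (weeks[-1] - weeks[0])
        expected = lv / (lv + tv + noise_total)
        assert abs(model.variance_proportions[0] - expected) < 0.10
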