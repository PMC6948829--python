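"""Sampling adequacy, retention rule, Promax rotation and scoring."""

import numpy as np
import pandas as pd
import pytest

from oracles import align_columns, partial_correlation_by_regression, promax_2factor
from painnet import (
    AnalysisConfig,
    default_loading_matrix,
    fit_factor_model,
    kmo,
    promax,
    retain_components,
    sample_measure_matrix,
    score_subjects,
    varimax,
)
from painnet.factor_reduction import SingularCorrelationError


class TestKMO:
    def test_equicorrelated_three_measures(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        overall, per = kmo(R)
        # partial correlations are 1/3 each: 6*0.25 / (6*0.25 + 6*(1/9))
        assert overall == pytest.approx(1.5 / (1.5 + 2 / 3.0), abs=1e-10)
        assert np.allclose(per, per[0])

    def test_block_diagonal_symmetry(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.8
        R[2, 3] = R[3, 2] = 0.8
        _, per = kmo(R)
        assert per[0] == pytest.approx(per[1])
        assert per[2] == pytest.approx(per[3])

    def test_near_identity_tends_to_half(self):
        R = np.eye(3) + 1e-6 * (np.ones((3, 3)) - np.eye(3))
        overall, _ = kmo(R)
        assert overall == pytest.approx(0.5, abs=1e-4)

    def test_partials_match_regression_oracle(self):
        """Anti-image partials agree with explicit residual regression."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((4000, 4)) @ rng.uniform(-1, 1, (4, 4))
        R = np.corrcoef(X, rowvar=False)
        Rinv = np.linalg.inv(R)
        d = 1 / np.sqrt(np.diag(Rinv))
        partial = -Rinv * np.outer(d, d)
        for i, j in [(0, 1), (1, 3), (0, 2)]:
            assert partial[i, j] == pytest.approx(
                partial_correlation_by_regression(X, i, j), abs=1e-9)

    def test_singular_matrix_raises_informative_error(self):
        R = np.ones((3, 3))
        with pytest.raises(SingularCorrelationError, match="ridge|collinear"):
            kmo(R)


class TestRetention:
    @pytest.mark.parametrize("eigs,expected", [
        ([3.2, 2.1, 1.4, 1.01, 0.99], 4),
        ([1.0, 1.0, 1.0], 0),        # strictly greater than the cut
        ([5.0], 1),
    ])
    def test_kaiser_rule(self, eigs, expected):
        assert retain_components(eigs) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            retain_components([])


class TestPromax:
    def test_perfect_simple_structure_is_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = 0.8
        L[3:, 1] = 0.8
        pattern, phi, _ = promax(L)
        assert align_columns(pattern, L) < 1e-8
        assert np.abs(phi - np.eye(2)).max() < 1e-8

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_closed_form_two_factor_oracle(self, seed):
        """Iterated varimax + power transform equals the spelled-out
        closed-form 2-factor computation."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((8, 2)) * 0.5
        pattern, phi, _ = promax(A)
        oracle_pattern, oracle_phi = promax_2factor(A)
        assert align_columns(oracle_pattern, pattern) < 1e-8
        assert abs(abs(oracle_phi[0, 1]) - abs(phi[0, 1])) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_phi_symmetric_unit_diagonal(self, seed):
        rng = np.random.default_rng(100 + seed)
        A = rng.standard_normal((10, 3)) * 0.6
        _, phi, _ = promax(A)
        np.testing.assert_allclose(phi, phi.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-12)

    def test_single_component_identity_with_warning(self):
        A = np.ones((5, 1)) * 0.7
        with pytest.warns(UserWarning):
            pattern, phi, _ = promax(A)
        np.testing.assert_array_equal(pattern, A)
        assert phi.shape == (1, 1)

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((9, 3))
        pattern, _, _ = promax(A)
        for j in range(3):
            assert pattern[np.argmax(np.abs(pattern[:, j])), j] > 0


def _planted_frame(n=84, seed=0):
    L, measures, factors = default_loading_matrix()
    u = 1 - np.sum(L ** 2, axis=1)
    X = sample_measure_matrix(L, u, n, seed=seed)
    return pd.DataFrame(X, columns=measures), factors


class TestFitFactorModel:
    def test_recovers_planted_structure(self, registry, config):
        df, factors = _planted_frame(n=84, seed=3)
        model = fit_factor_model(df, config, community_labels=registry.communities)
        assert model.retained_k == 5
        agree = sum(model.membership[m] == registry[m].community
                    for m in model.measure_ids)
        assert agree >= 19

    def test_single_factor_data(self, config):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((200, 1))
        X = f @ np.full((1, 5), 0.8) + 0.3 * rng.standard_normal((200, 5))
        model = fit_factor_model(pd.DataFrame(X, columns=list("abcde")), config)
        assert model.retained_k == 1

    def test_eigenvalues_sum_to_measure_count(self, config):
        df, _ = _planted_frame(seed=9)
        model = fit_factor_model(df, config)
        assert model.eigenvalues.sum() == pytest.approx(21.0, abs=1e-8)

    def test_rotation_preserves_column_space(self, config):
        df, _ = _planted_frame(seed=5)
        model = fit_factor_model(df, config)
        A, P = model.loadings_unrotated, model.pattern
        proj = A @ np.linalg.lstsq(A, P, rcond=None)[0]
        assert np.abs(proj - P).max() < 1e-8

    def test_phi_near_identity_for_orthogonal_factors(self, config):
        df, _ = _planted_frame(n=2000, seed=6)
        model = fit_factor_model(df, config)
        off = model.phi[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_kmo_adequate_on_planted_cohort(self, config):
        df, _ = _planted_frame(seed=12)
        model = fit_factor_model(df, config)
        assert model.kmo_overall > 0.5


class TestScoreSubjects:
    def test_fitting_sample_scores_have_zero_mean(self, config):
        df, _ = _planted_frame(seed=8)
        model = fit_factor_model(df, config)
        scores = score_subjects(model, df)
        assert np.abs(scores.mean().to_numpy()).max() < 1e-10

    def test_all_mean_subject_scores_zero(self, config):
        df, _ = _planted_frame(seed=8)
        model = fit_factor_model(df, config)
        mean_subject = pd.DataFrame([df.mean()], index=["mean"])
        scores = score_subjects(model, mean_subject)
        assert np.abs(scores.to_numpy()).max() < 1e-10

    def test_cross_group_projection_recovers_planted_factors(self, registry, config):
        """Hip-arm-like subjects scored with knee-arm weights still track
        their own planted factor scores."""
        df, factors = _planted_frame(n=84, seed=21)
        model = fit_factor_model(df, config, community_labels=registry.communities)
        L, measures, _ = default_loading_matrix()
        u = 1 - np.sum(L ** 2, axis=1)
        rng = np.random.default_rng(22)
        f_other = rng.standard_normal((300, 5))
        X_other = f_other @ L.T + rng.standard_normal((300, 21)) * np.sqrt(u)
        scores = score_subjects(model, pd.DataFrame(X_other, columns=measures))
        for k, label in enumerate(factors):
            col = scores[label] if label in scores.columns else scores.iloc[:, k]
            r = max(abs(np.corrcoef(col, f_other[:, j])[0, 1]) for j in range(5))
            assert r > 0.8

    def test_missing_measure_column_rejected(self, config):
        df, _ = _planted_frame(seed=8)
        model = fit_factor_model(df, config)
        with pytest.raises(ValueError, match="lacks"):
            score_subjects(model, df.drop(columns=["TUG"]))
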