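"""Waveform PCA: SVD model, limit curves, region extraction."""

import numpy as np
import pytest

import grfwave as g
from grfwave.pca import PCReconstruction, _runs


def brute_force_pca(X):
    """Independent oracle: eigendecomposition of the sample covariance."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order].T
    # same sign canon as the implementation: largest |element| positive
    for k in range(evecs.shape[0]):
        j = np.argmax(np.abs(evecs[k]))
        if evecs[k, j] < 0:
            evecs[k] = -evecs[k]
    fractions = np.clip(evals, 0, None) / np.sum(np.clip(evals, 0, None))
    return fractions, evecs


def random_curves(rng, n_subjects=3, n_speeds=2, channel="vertical"):
    curves = []
    for speed in [2.7, 3.0, 3.3, 3.7][:n_speeds]:
        for s in range(n_subjects):
            curves.append(
                g.StanceCurve(
                    channel=channel,
                    values=rng.normal(1.0, 0.1, 100),
                    contact_time=0.25,
                    subject_id=f"F{s:02d}",
                    sex="female",
                    speed=speed,
                )
            )
    return curves


class TestBuildMatrix:
    def test_row_count_is_subjects_times_speeds(self, rng):
        m = g.build_matrix(random_curves(rng, 3, 2), "female", "vertical")
        assert m.X.shape == (6, 100)
        m15 = g.build_matrix(random_curves(rng, 15, 4), "female", "vertical")
        assert m15.X.shape == (60, 100)

    def test_order_canonicalization(self, rng):
        curves = random_curves(rng, 4, 3)
        m1 = g.build_matrix(curves, "female", "vertical")
        shuffled = [curves[i] for i in rng.permutation(len(curves))]
        m2 = g.build_matrix(shuffled, "female", "vertical")
        np.testing.assert_array_equal(m1.X, m2.X)
        assert m1.row_meta.equals(m2.row_meta)

    def test_duplicate_rows_rejected(self, rng):
        curves = random_curves(rng, 3, 2)
        with pytest.raises(g.GroupingError):
            g.build_matrix(curves + curves[:1], "female", "vertical")


class TestFitPCA:
    def test_matches_covariance_eigendecomposition(self, rng):
        for _ in range(5):
            m = int(rng.integers(5, 13))
            X = rng.normal(size=(m, 10))
            model = g.fit_pca(X)
            fr_oracle, load_oracle = brute_force_pca(X)
            p = model.n_components_
            np.testing.assert_allclose(
                model.explained_variance_ratio_, fr_oracle[:p], atol=1e-8
            )
            np.testing.assert_allclose(
                model.components_, load_oracle[:p], atol=1e-8
            )

    def test_identical_rows_give_degenerate_model(self):
        X = np.tile(np.linspace(0, 2, 100), (6, 1))
        model = g.fit_pca(X)
        assert model.n_components_ == 0
        np.testing.assert_allclose(model.mean_, X[0], atol=1e-12)
        assert model.explained_variance_ratio_.size == 0

    def test_rank_one_matrix_fully_explained_by_pc1(self, rng):
        gvec = rng.normal(size=100)
        gvec /= np.linalg.norm(gvec)
        scores = rng.normal(0, 2.0, size=12)
        X = 1.0 + np.outer(scores, gvec)
        model = g.fit_pca(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(model.components_[0] @ gvec) == pytest.approx(1.0, abs=1e-9)

    def test_full_reconstruction_identity_and_fraction_sum(self, rng):
        X = rng.normal(size=(20, 100))
        model = g.fit_pca(X)
        recon = model.scores_ @ model.components_ + model.mean_
        np.testing.assert_allclose(recon, X, atol=1e-8)
        assert np.sum(model.explained_variance_ratio_) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_orthonormal_loadings_and_uncorrelated_scores(self, rng):
        X = rng.normal(size=(15, 100))
        model = g.fit_pca(X)
        gram = model.components_ @ model.components_.T
        np.testing.assert_allclose(gram, np.eye(model.n_components_), atol=1e-8)
        Zc = model.scores_ - model.scores_.mean(axis=0)
        cross = Zc.T @ Zc
        np.testing.assert_allclose(
            cross - np.diag(np.diag(cross)), 0, atol=1e-8 * np.max(cross)
        )
        # projection identity Z = (X - mean) @ T'
        np.testing.assert_allclose(
            model.scores_, (X - model.mean_) @ model.components_.T, atol=1e-9
        )

    def test_residual_q_matches_definition(self, rng):
        X = rng.normal(size=(10, 100))
        model = g.fit_pca(X)
        k = model.n_retained_
        Xc = X - model.mean_
        expected = np.sum(
            (Xc - model.scores_[:, :k] @ model.components_[:k]) ** 2, axis=1
        )
        np.testing.assert_allclose(model.residual_q_, expected, atol=1e-9)

    def test_refit_is_deterministic(self, rng):
        X = rng.normal(size=(9, 100))
        m1, m2 = g.fit_pca(X), g.fit_pca(X)
        np.testing.assert_array_equal(m1.components_, m2.components_)
        np.testing.assert_array_equal(m1.scores_, m2.scores_)

    def test_row_permutation_permutes_scores_only(self, rng):
        X = rng.normal(size=(12, 100))
        perm = rng.permutation(12)
        m1, m2 = g.fit_pca(X), g.fit_pca(X[perm])
        np.testing.assert_allclose(m1.components_, m2.components_, atol=1e-9)
        np.testing.assert_allclose(
            m1.explained_variance_ratio_, m2.explained_variance_ratio_, atol=1e-12
        )
        np.testing.assert_allclose(m1.scores_[perm], m2.scores_, atol=1e-9)

    def test_planted_mode_recovery_at_cohort_scale(self):
        # single magnitude mode + white noise: PC1 must align with the mode
        # and its variance fraction approach s^2 / (s^2 + 100 sigma^2)
        rng = np.random.default_rng(2024)
        X, truth = g.make_waveform_matrix(
            n_subjects=15, n_speeds=4, mode="magnitude",
            mode_sd=0.10, noise_sd=0.02, rng=rng,
        )
        model = g.fit_pca(X)
        cos = abs(model.components_[0] @ truth["direction"])
        assert cos >= 0.99
        s = np.std(truth["scores"] * np.linalg.norm(truth["base_curve"]), ddof=1)
        theory = s**2 / (s**2 + 100 * truth["noise_sd"] ** 2)
        assert model.explained_variance_ratio_[0] == pytest.approx(
            theory, abs=0.02
        )


class TestSelectComponents:
    @pytest.mark.parametrize(
        "fractions,coverage,kmax,expected",
        [
            ((0.85, 0.07, 0.05, 0.01, 0.02), 0.95, 4, 3),
            ((0.50, 0.20, 0.15, 0.05, 0.05, 0.05), 0.95, 4, 4),  # capped
            ((0.96, 0.04), 0.95, 4, 1),
            ((), 0.95, 4, 0),
        ],
    )
    def test_smallest_k_reaching_coverage(self, fractions, coverage, kmax, expected):
        assert g.select_components(np.array(fractions), coverage, kmax) == expected

    def test_capped_selection_reports_shortfall(self, rng):
        X = rng.normal(size=(30, 100))  # flat spectrum: 4 PCs cover little
        model = g.WaveformPCA(coverage=0.95, k_max=4).fit(X)
        assert model.n_retained_ == 4
        assert model.coverage_achieved_ < 0.95


class TestLimitCurves:
    def test_upper_lower_average_to_mean_exactly(self, rng):
        model = g.fit_pca(rng.normal(size=(10, 100)))
        rec = model.reconstruct_limits(1)
        np.testing.assert_allclose(
            (rec.upper + rec.lower) / 2, model.mean_, atol=1e-12
        )
        np.testing.assert_allclose(
            rec.upper - rec.lower,
            2 * rec.score_sd * model.components_[0],
            atol=1e-12,
        )

    def test_rank_one_limits_recover_planted_sd_times_direction(self, rng):
        gvec = rng.normal(size=100)
        gvec /= np.linalg.norm(gvec)
        scores = rng.normal(0, 1.5, size=20)
        X = np.outer(scores, gvec)
        model = g.fit_pca(X)
        rec = model.reconstruct_limits(1)
        s = np.std(scores - scores.mean(), ddof=1)
        sign = np.sign(model.components_[0] @ gvec)
        np.testing.assert_allclose(
            rec.upper - rec.mean, s * sign * gvec, atol=1e-9
        )

    def test_out_of_range_index_rejected(self, rng):
        model = g.fit_pca(rng.normal(size=(5, 100)))
        with pytest.raises(g.ParameterError):
            model.reconstruct_limits(0)
        with pytest.raises(g.ParameterError):
            model.reconstruct_limits(model.n_components_ + 1)


class TestExtractRegions:
    def _rec(self, loading, sd=1.0):
        mean = np.zeros(100)
        return PCReconstruction(
            pc_index=1,
            mean=mean,
            upper=mean + sd * loading,
            lower=mean - sd * loading,
            score_sd=sd,
            variance_fraction=1.0,
        )

    def test_constructed_sign_pattern_yields_exact_intervals(self):
        loading = np.zeros(100)
        loading[2:58] = 1.0
        loading[58:100] = -1.0
        rec = g.extract_regions(self._rec(loading))
        assert rec.regions_upper_over_lower == [[2, 57]]
        assert rec.regions_lower_over_upper == [[58, 99]]

    def test_zero_loading_gives_no_regions(self):
        rec = g.extract_regions(self._rec(np.zeros(100)))
        assert rec.regions_upper_over_lower == []
        assert rec.regions_lower_over_upper == []

    def test_region_lists_are_disjoint(self, rng):
        loading = rng.normal(size=100)
        rec = g.extract_regions(self._rec(loading))
        covered = set()
        for a, b in rec.regions_upper_over_lower + rec.regions_lower_over_upper:
            pts = set(range(a, b + 1))
            assert not covered & pts
            covered |= pts

    def test_subthreshold_dip_splits_run_per_strict_rule(self):
        loading = np.zeros(100)
        loading[10:40] = 1.0
        loading[20:23] = 0.03  # dip below the 5% threshold
        rec = g.extract_regions(self._rec(loading), epsilon=0.05)
        assert rec.regions_upper_over_lower == [[10, 19], [23, 39]]

    def test_matches_brute_force_pointwise_scan(self, rng):
        for _ in range(10):
            loading = rng.normal(size=100)
            eps = 0.05 * 2 * np.max(np.abs(loading))
            rec = g.extract_regions(self._rec(loading), epsilon=0.05)
            d = rec.upper - rec.lower
            # brute force: collect maximal runs point by point
            runs, cur = [], None
            for i in range(100):
                if d[i] > eps:
                    cur = [i, i] if cur is None else [cur[0], i]
                else:
                    if cur is not None:
                        runs.append(cur)
                    cur = None
            if cur is not None:
                runs.append(cur)
            assert rec.regions_upper_over_lower == runs


def test_runs_helper_inclusive_bounds():
    mask = np.array([True, True, False, True, False, False, True])
    assert _runs(mask) == [[0, 1], [3, 3], [6, 6]]
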