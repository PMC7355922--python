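import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import ramanscreen as rs
from ramanscreen.classification import (
    PCSelection,
    fit_logistic,
    fit_pca,
    lesion_auroc,
    project,
)
from ramanscreen.dataset_io import Label, LesionRecord, SpectraDataset
from ramanscreen.errors import ConfigError, FitError, ShapeError

from conftest import fast_config


class TestFitPCA:
    def test_two_point_dataset_has_single_difference_component(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        model = fit_pca(X, 1)
        direction = (X[1] - X[0]) / np.linalg.norm(X[1] - X[0])
        assert np.allclose(np.abs(model.components[0]), np.abs(direction))
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 30))
        model = fit_pca(X, 11)
        scores = project(model, X)
        recon = model.mean + scores @ model.components
        assert np.allclose(recon, X, atol=1e-8)

    def test_components_orthonormal_and_signed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 40))
        model = fit_pca(X, 8)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(8), atol=1e-8)
        for row in model.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_matches_sklearn_pca(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 60))
        model = fit_pca(X, 5)
        ref = sklearn_pca(n_components=5, svd_solver="full").fit(X)
        for mine, theirs in zip(model.components, ref.components_):
            assert abs(abs(mine @ theirs) - 1.0) < 1e-8
        assert np.allclose(
            model.explained_variance_fraction, ref.explained_variance_ratio_, atol=1e-10
        )

    def test_rank_deficiency_flagged(self):
        X = np.vstack([np.arange(10.0)] * 5) + np.arange(5.0)[:, None]  # rank 2
        model = fit_pca(X, 4)
        assert model.rank_deficient
        assert model.n_components < 4


class TestProject:
    def test_mean_spectrum_projects_to_zero(self):
        X = np.random.default_rng(3).normal(size=(10, 20))
        model = fit_pca(X, 3)
        assert np.allclose(project(model, model.mean), 0.0, atol=1e-12)

    def test_duplicate_of_training_row_gets_training_scores(self):
        X = np.random.default_rng(4).normal(size=(10, 20))
        model = fit_pca(X, 3)
        train_scores = project(model, X)
        assert np.allclose(project(model, X[4]), train_scores[4], atol=1e-12)

    def test_shape_mismatch_raises(self):
        model = fit_pca(np.random.default_rng(5).normal(size=(6, 10)), 2)
        with pytest.raises(ShapeError):
            project(model, np.zeros((3, 11)))


class TestEnumerateSubsets:
    def test_single_pc_space(self):
        assert rs.enumerate_pc_subsets(1, 1) == [PCSelection((1,))]

    def test_three_choose_up_to_two(self):
        got = [s.indices for s in rs.enumerate_pc_subsets(3, 2)]
        assert got == [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3)]

    def test_full_search_space_size_matches_binomial_sum(self):
        subsets = rs.enumerate_pc_subsets(15, 6)
        expected = sum(math.comb(15, k) for k in range(1, 7))
        assert len(subsets) == expected == 9948
        assert len(set(subsets)) == len(subsets)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigError):
            rs.enumerate_pc_subsets(5, 6)


def brute_force_logistic(Z, y, reg, spans, n_grid=41, n_refine=8):
    """Coarse-to-fine grid minimizer of the penalized negative
    log-likelihood — independent of the Newton implementation."""
    Z = np.column_stack([np.ones(len(y)), Z])

    def nll(b):
        eta = Z @ b
        return float(np.sum(np.logaddexp(0, eta) - y * eta) + reg * np.sum(b[1:] ** 2))

    center = np.zeros(Z.shape[1])
    width = np.array(spans, dtype=float)
    for _ in range(n_refine):
        axes = [np.linspace(c - w, c + w, n_grid) for c, w in zip(center, width)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        values = [nll(p) for p in pts]
        center = pts[int(np.argmin(values))]
        width = width * (2.5 / (n_grid - 1))
    return center


class TestFitLogistic:
    def test_balanced_symmetric_data_has_zero_intercept(self):
        Z = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_logistic(Z, y, reg=1e-3)
        assert abs(model.intercept) < 1e-6

    def test_separable_data_stays_finite_and_monotone(self):
        Z = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic(Z, y, reg=1e-4)
        assert np.isfinite(model.coefficients).all()
        probs = model.predict_proba(Z)
        assert np.all(np.diff(probs) > 0)

    def test_six_point_fixture_matches_grid_oracle(self):
        Z = np.array([[-1.5], [-0.7], [-0.2], [0.3], [0.8], [1.6]])
        y = np.array([0, 0, 1, 0, 1, 1])
        reg = 0.05
        model = fit_logistic(Z, y, reg=reg)
        ref = brute_force_logistic(Z, y, reg, spans=(6.0, 8.0))
        assert model.intercept == pytest.approx(ref[0], abs=1e-4)
        assert model.coefficients[0] == pytest.approx(ref[1], abs=1e-4)

    def test_matches_sklearn_ridge_logistic(self):
        LogisticRegression = pytest.importorskip("sklearn.linear_model").LogisticRegression
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(60, 3))
        y = (rng.random(60) < expit(Z @ [1.0, -0.5, 0.2])).astype(float)
        reg = 1e-2
        model = fit_logistic(Z, y, reg=reg)
        # sklearn minimizes C·Σ logloss + ½‖w‖² ⇒ C = 1/(2·reg)
        ref = LogisticRegression(C=1.0 / (2 * reg), tol=1e-12, max_iter=10000).fit(Z, y)
        assert np.allclose(model.coefficients, ref.coef_[0], atol=1e-5)
        assert model.intercept == pytest.approx(ref.intercept_[0], abs=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            fit_logistic(np.ones((4, 1)), np.ones(4), reg=1e-4)


@pytest.fixture(scope="module")
def small_fold(small_cohort_preprocessed):
    return rs.lolo_fold_scores(small_cohort_preprocessed, n_pcs=4)


class TestFoldScores:
    def test_fold_count_equals_lesion_count(self, small_cohort_preprocessed, small_fold):
        assert len(small_fold.lesion_ids) == len(small_cohort_preprocessed.lesions)
        assert small_fold.scores.shape[0] == len(small_fold.lesion_ids)

    def test_cached_fold_equals_from_scratch_fit(self, small_cohort_preprocessed, small_fold):
        pre = small_cohort_preprocessed
        X, ids = pre.intensity_matrix()
        f = 2
        held_lesion = small_fold.lesion_ids[f]
        held = np.array([s.lesion_id == held_lesion for s in pre.spectra])
        model = fit_pca(X[~held], 4)
        assert np.allclose(project(model, X), small_fold.scores[f], atol=1e-10)

    def test_no_leakage_from_held_out_lesion(self, small_cohort_preprocessed):
        pre = small_cohort_preprocessed
        f = 0
        held_lesion = pre.lesions[f].lesion_id
        tampered = rs.SpectraDataset(
            spectra=[
                s.with_intensities(s.intensities[::-1]) if s.lesion_id == held_lesion else s
                for s in pre.spectra
            ],
            lesions=list(pre.lesions),
        )
        a = rs.lolo_fold_scores(pre, n_pcs=3)
        b = rs.lolo_fold_scores(tampered, n_pcs=3)
        train = ~a.test_mask[f]
        assert np.allclose(a.scores[f][train], b.scores[f][train], atol=1e-12)


class TestCVPredict:
    def test_posterior_is_max_over_measurements(self, small_cohort_preprocessed, small_fold):
        pre = small_cohort_preprocessed
        pred = rs.lolo_cv_predict(small_fold, pre, PCSelection((1, 2)))
        for lesion in pre.lesions:
            probs = [pred.spectrum_probabilities[m] for m in lesion.measurement_ids]
            assert pred.lesion_posteriors[lesion.lesion_id] == pytest.approx(max(probs))
        assert pred.n_folds == len(pre.lesions)

    def test_label_swap_maps_probabilities_to_complement(
        self, small_cohort_preprocessed, small_fold
    ):
        pre = small_cohort_preprocessed
        swapped = rs.SpectraDataset(
            spectra=list(pre.spectra),
            lesions=[
                LesionRecord(
                    l.lesion_id,
                    l.patient_id,
                    Label.PIGMENTED if l.label is Label.MELANOMA else Label.MELANOMA,
                    l.measurement_ids,
                )
                for l in pre.lesions
            ],
        )
        p1 = rs.lolo_cv_predict(small_fold, pre, PCSelection((1, 3)))
        p2 = rs.lolo_cv_predict(small_fold, swapped, PCSelection((1, 3)))
        for mid, p in p1.spectrum_probabilities.items():
            assert p2.spectrum_probabilities[mid] == pytest.approx(1.0 - p, abs=1e-8)

    def test_strong_noiseless_effect_ranks_perfectly(self):
        cfg = fast_config(
            seed=8, n_pigmented_lesions=8, n_melanoma_lesions=4, n_patients=12,
            noise_sd=0.0, cosmic_ray_rate=0.0, weight_cv=0.02, intra_lesion_cv=0.0,
            n_points=600,
        )
        ds, _ = rs.generate_cohort(cfg)
        pre, _ = rs.preprocess_dataset(ds)
        fold = rs.lolo_fold_scores(pre, n_pcs=3)
        res = rs.search_best_subset(fold, pre, rs.enumerate_pc_subsets(3, 2))
        assert res.best_auroc == 1.0
        pred = rs.lolo_cv_predict(fold, pre, res.best_subset)
        labels = pre.labels()
        mel = [p for l, p in pred.lesion_posteriors.items() if labels[l] is Label.MELANOMA]
        pig = [p for l, p in pred.lesion_posteriors.items() if labels[l] is Label.PIGMENTED]
        assert min(mel) > max(pig)


def naive_cv_posteriors(pre, subset, reg=1e-4):
    """Uncached reference pipeline: refit PCA and logistic per fold from
    scratch, no shared projections."""
    labels = pre.labels()
    X, ids = pre.intensity_matrix()
    lesion_of = np.array([s.lesion_id for s in pre.spectra])
    y_all = np.array([1.0 if labels[l] is Label.MELANOMA else 0.0 for l in lesion_of])
    out_spec = {}
    for lesion in pre.lesions:
        held = lesion_of == lesion.lesion_id
        model = fit_pca(X[~held], max(subset.indices))
        Z_train = project(model, X[~held])[:, np.array(subset.indices) - 1]
        Z_test = project(model, X[held])[:, np.array(subset.indices) - 1]
        lm = fit_logistic(Z_train, y_all[~held], reg=reg)
        for mid, p in zip(np.array(ids)[held], lm.predict_proba(Z_test)):
            out_spec[mid] = float(p)
    posteriors = {
        l.lesion_id: max(out_spec[m] for m in l.measurement_ids) for l in pre.lesions
    }
    return out_spec, posteriors


class TestSearchAndCacheCorrectness:
    def test_single_subset_search(self, small_cohort_preprocessed, small_fold):
        res = rs.search_best_subset(
            small_fold, small_cohort_preprocessed, [PCSelection((2,))]
        )
        assert res.best_subset == PCSelection((2,))

    def test_duplicate_subsets_score_identically(self, small_cohort_preprocessed, small_fold):
        res = rs.search_best_subset(
            small_fold, small_cohort_preprocessed, [PCSelection((1, 2))] * 2 + [PCSelection((3,))]
        )
        assert len(res.aurocs) == 2  # dict collapses the duplicate: same key, same value

    def test_cached_pipeline_equals_naive_recomputation(
        self, small_cohort_preprocessed, small_fold
    ):
        pre = small_cohort_preprocessed
        for subset in rs.enumerate_pc_subsets(4, 2):
            cached = rs.lolo_cv_predict(small_fold, pre, subset)
            spec_ref, post_ref = naive_cv_posteriors(pre, subset)
            for mid, p in cached.spectrum_probabilities.items():
                assert p == pytest.approx(spec_ref[mid], abs=1e-10)
            for lid, p in cached.lesion_posteriors.items():
                assert p == pytest.approx(post_ref[lid], abs=1e-10)

    def test_auroc_invariant_to_measurement_order(self, small_cohort_preprocessed):
        pre = small_cohort_preprocessed
        shuffled = rs.SpectraDataset(
            spectra=list(reversed(pre.spectra)), lesions=list(pre.lesions)
        )
        subsets = rs.enumerate_pc_subsets(3, 2)
        r1 = rs.search_best_subset(rs.lolo_fold_scores(pre, 3), pre, subsets)
        r2 = rs.search_best_subset(rs.lolo_fold_scores(shuffled, 3), shuffled, subsets)
        for s in subsets:
            assert r1.aurocs[s] == pytest.approx(r2.aurocs[s], abs=1e-10)

    def test_selection_optimism_on_null_cohorts(self):
        """Best-over-subsets AUROC exceeds a fixed subset's AUROC on
        average when there is no real effect — the bias the randomization
        null exists to measure."""
        diffs = []
        for seed in range(10):
            # study-scale lesion counts: with very few lesions the
            # leave-one-out prevalence shift pins every subset's AUROC to
            # the same degenerate value and the comparison is vacuous
            cfg = rs.null_config(seed=100 + seed, n_points=300)
            ds, _ = rs.generate_cohort(cfg)
            pre, _ = rs.preprocess_dataset(ds)
            fold = rs.lolo_fold_scores(pre, n_pcs=4)
            res = rs.search_best_subset(fold, pre, rs.enumerate_pc_subsets(4, 2))
            fixed = res.aurocs[PCSelection((1,))]
            diffs.append(res.best_auroc - fixed)
        assert np.mean(diffs) > 0


def test_lesion_auroc_requires_both_classes():
    with pytest.raises(FitError):
        lesion_auroc(np.array([0.1, 0.2]), np.array([1.0, 1.0]))
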