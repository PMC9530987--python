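import dataclasses

import numpy as np
import pytest

import conservarf as c
from conservarf.applicability_domain import (ADModel, ad_from_dict,
                                             ad_threshold, ad_to_dict,
                                             fit_dknn, fit_pca, in_domain,
                                             optimize_m, with_m)
from conservarf.core_data import CONTINUOUS, FingerprintMatrix
from conservarf.metrics import balanced_accuracy, confusion
from conservarf.synthetic_data import OOD_PREFIX, GeneratorSpec, generate


def _fpm(X):
    X = np.asarray(X, dtype=float)
    return FingerprintMatrix([f"s{i}" for i in range(X.shape[0])], X,
                             [f"d{j}" for j in range(X.shape[1])],
                             [CONTINUOUS] * X.shape[1])


class TestAdThreshold:
    def test_direct_evaluation(self):
        assert ad_threshold(10_000, 2.0) == pytest.approx(100.0)

    def test_n_one(self):
        for m in (0.5, 1.0, 7.3):
            assert ad_threshold(1, m) == 1.0

    def test_large_m_limit(self):
        assert ad_threshold(5000, 1e9) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_m(self):
        with pytest.raises(ValueError, match="m"):
            ad_threshold(10, 0.0)


class TestFitPca:
    def test_component_count_from_variance_ratios(self):
        """Data constructed with exact sample variance ratios
        0.6/0.3/0.05/0.05: the cumulative sum crosses the 0.95 target at 3
        components."""
        rng = np.random.default_rng(0)
        n = 400
        raw = rng.standard_normal((n, 4))
        raw -= raw.mean(axis=0)
        u, _, _ = np.linalg.svd(raw, full_matrices=False)
        X = u * np.sqrt(n - 1) * np.sqrt([0.6, 0.3, 0.05, 0.05])
        emb = fit_pca(_fpm(X), var_target=0.95)
        assert emb.n_components == 3

    def test_single_column(self):
        emb = fit_pca(_fpm(np.array([[1.0], [2.0], [4.0]])))
        assert emb.n_components == 1
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 5)) @ rng.standard_normal((5, 5))
        emb = fit_pca(_fpm(X), var_target=0.95)
        cov = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ratios = eigvals / eigvals.sum()
        expected_r = int(np.searchsorted(np.cumsum(ratios), 0.95 - 1e-12) + 1)
        assert emb.n_components == expected_r
        Z = emb.transform(X)
        got = Z.var(axis=0, ddof=1) / eigvals.sum()
        np.testing.assert_allclose(got, ratios[:expected_r], rtol=1e-8)

    def test_deterministic_signs(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        e1 = fit_pca(_fpm(X))
        e2 = fit_pca(_fpm(X))
        np.testing.assert_array_equal(e1.components, e2.components)
        for row in e1.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_invalid_target(self):
        with pytest.raises(ValueError, match="var_target"):
            fit_pca(_fpm(np.random.default_rng(0).random((5, 2))), 1.5)


class TestDknn:
    def test_training_points_in_domain(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 4))
        fp = _fpm(X)
        ad = fit_dknn(fit_pca(fp), fp, k=5, m=3.0)
        assert in_domain(ad, fp).all()

    def test_far_query_out_of_domain(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 4))
        fp = _fpm(X)
        ad = fit_dknn(fit_pca(fp), fp, k=5, m=3.0)
        far = np.full((1, 4), 1e6)
        assert not in_domain(ad, far).any()

    def test_mid_gap_query_out_between_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((40, 3)) * 0.5
        b = rng.standard_normal((40, 3)) * 0.5 + 10.0
        X = np.vstack([a, b])
        fp = _fpm(X)
        ad = fit_dknn(fit_pca(fp, 0.999), fp, k=5, m=3.0)
        flags = in_domain(ad, fp)
        assert flags.all()
        mid = np.full((1, 3), 5.0)
        assert not in_domain(ad, mid).any()

    def test_duplicate_of_training_substance_in_domain(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 3))
        fp = _fpm(X)
        ad = fit_dknn(fit_pca(fp), fp, k=4, m=3.0)
        assert in_domain(ad, X[[7]]).all()

    def test_k_too_large(self):
        fp = _fpm(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError, match="k="):
            fit_dknn(fit_pca(fp), fp, k=5)

    def test_dimension_mismatch(self):
        fp = _fpm(np.random.default_rng(0).random((20, 3)))
        ad = fit_dknn(fit_pca(fp, 0.999), fp, k=3)
        with pytest.raises(ValueError, match="descriptors"):
            in_domain(ad, np.zeros((1, 7)))

    def test_shifted_distribution_lower_coverage(self):
        rng = np.random.default_rng(7)
        train = rng.standard_normal((200, 4))
        fp = _fpm(train)
        ad = fit_dknn(fit_pca(fp, 0.999), fp, k=5, m=3.0)
        held_out = rng.standard_normal((200, 4))
        shifted = rng.standard_normal((200, 4)) + 5.0
        assert in_domain(ad, held_out).mean() > in_domain(ad, shifted).mean()

    def test_coverage_monotone_under_radius_shrink(self):
        rng = np.random.default_rng(8)
        train = rng.standard_normal((150, 4))
        fp = _fpm(train)
        ad = fit_dknn(fit_pca(fp, 0.999), fp, k=5, m=3.0)
        queries = rng.standard_normal((300, 4)) * 1.5
        prev = None
        for s in (1.0, 0.7, 0.4, 0.2, 0.05):
            shrunk = dataclasses.replace(ad, radii=ad.radii * s)
            cov = in_domain(shrunk, queries).mean()
            if prev is not None:
                assert cov <= prev + 1e-12
            prev = cov

    def test_query_order_independent(self):
        rng = np.random.default_rng(9)
        fp = _fpm(rng.standard_normal((60, 3)))
        ad = fit_dknn(fit_pca(fp, 0.999), fp, k=4, m=2.0)
        q = rng.standard_normal((40, 3))
        flags = in_domain(ad, q)
        perm = rng.permutation(40)
        np.testing.assert_array_equal(in_domain(ad, q[perm]), flags[perm])

    def test_distance_matches_brute_force(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((25, 3))
        fp = _fpm(X)
        emb = fit_pca(fp, 0.999)
        ad = fit_dknn(emb, fp, k=3, m=3.0)
        Z = emb.transform(X)
        # brute-force mean-3NN distance per point
        D = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D, np.inf)
        expected = np.sort(D, axis=1)[:, :3].mean(axis=1)
        np.testing.assert_allclose(ad.raw_radii, expected, rtol=1e-10)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(11)
        fp = _fpm(rng.standard_normal((30, 3)))
        ad = fit_dknn(fit_pca(fp, 0.999), fp, k=4, m=2.5)
        back = ad_from_dict(ad_to_dict(ad))
        q = rng.standard_normal((20, 3))
        np.testing.assert_array_equal(in_domain(back, q), in_domain(ad, q))


@pytest.fixture(scope="module")
def contaminated():
    fp, labels, _ = generate(GeneratorSpec(
        n_substances=900, n_binary_descriptors=80,
        n_continuous_descriptors=10, class_priors=(0.9, 0.1),
        n_informative_bits=20, contamination_fraction=0.15, seed=21))
    split = c.stratified_split(labels, 0.75, seed=21)
    fp_train = fp.take_substances(split.train_indices)
    y_train = labels.take(split.train_indices)
    # fit everything on the clean part of train only
    clean = [i for i, sid in enumerate(fp_train.substance_ids)
             if not sid.startswith(OOD_PREFIX)]
    fp_clean = fp_train.take_substances(clean)
    model = c.train_forest(fp_clean, y_train.take(clean), n_trees=31,
                           seed=21)
    ad = fit_dknn(fit_pca(fp_clean), fp_clean, k=5)
    fp_test = fp.take_substances(split.test_indices)
    y_test = labels.take(split.test_indices)
    return model, ad, fp_test, y_test


class TestOptimizeM:
    def test_singleton_grid(self, contaminated):
        model, ad, fp_test, y_test = contaminated
        m, _ = optimize_m(ad, model, fp_test, y_test, m_grid=[2.5])
        assert m == 2.5

    def test_constraint_prefers_coverage_over_raw_ba(self, contaminated):
        model, ad, fp_test, y_test = contaminated
        m, records = optimize_m(ad, model, fp_test, y_test)
        chosen = next(r for r in records if r.m == m)
        feasible = [r for r in records if r.coverage >= 0.85]
        if feasible:
            assert chosen.coverage >= 0.85
            assert chosen.ba_in_domain == max(r.ba_in_domain for r in feasible)

    def test_domain_excludes_contaminants_and_improves_ba(self, contaminated):
        """The out-of-distribution block carries random labels; restricting
        to the fitted domain should remove mostly those substances and raise
        balanced accuracy."""
        model, ad, fp_test, y_test = contaminated
        m, _ = optimize_m(ad, model, fp_test, y_test)
        flags = in_domain(with_m(ad, m), fp_test)
        is_ood = np.array([sid.startswith(OOD_PREFIX)
                           for sid in fp_test.substance_ids])
        # contaminants are excluded at a much higher rate than clean data
        assert flags[is_ood].mean() < 0.5 * flags[~is_ood].mean()
        preds = c.forest_predict(model, fp_test)
        ba_all = balanced_accuracy(confusion(y_test, preds),
                                   ignore_empty=True)
        idx = np.flatnonzero(flags)
        ba_in = balanced_accuracy(
            confusion(y_test.take(idx), preds[idx]), ignore_empty=True)
        assert ba_in > ba_all

    def test_empty_grid_error(self, contaminated):
        model, ad, fp_test, y_test = contaminated
        with pytest.raises(ValueError, match="m_grid"):
            optimize_m(ad, model, fp_test, y_test, m_grid=[])
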