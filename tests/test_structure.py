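"""PCA, K-means BIC scan, DAPC and cross-validated assignment."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

from rohstruct import (MISSING, center_matrix, pca, pca_genotypes,
                       kmeans_bic_scan, dapc_fit, dapc_fit_genotypes,
                       dapc_predict, reassignment_accuracy, xval_select_npcs,
                       pairwise_external_validation, SimParams,
                       simulate_subpopulations)


def test_center_matrix_imputes_missing_with_column_mean():
    X, means = center_matrix(np.array([[0, 0], [MISSING, 1], [2, 2]], dtype=np.int8))
    assert means == pytest.approx([1.0, 1.0])
    assert X[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
    assert np.abs(X.mean(axis=0)).max() < 1e-12


def test_center_matrix_all_missing_column_errors():
    with pytest.raises(ValueError, match="all-missing"):
        center_matrix(np.full((3, 1), MISSING, dtype=np.int8))


def test_pca_rank_one_concentrates_variance():
    X = np.outer([1.0, -1.0, 2.0, -2.0], [3.0, 1.0, -1.0])
    X -= X.mean(axis=0)
    basis, _ = pca(X)
    assert basis.explained_variance_fraction(1) == pytest.approx(1.0)


def test_pca_full_reconstruction():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 8))
    X -= X.mean(axis=0)
    basis, scores = pca(X)
    assert np.allclose(scores @ basis.loadings.T, X, atol=1e-8)


def test_pca_eigenvalues_match_dense_covariance_eigendecomposition():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 200))
    X -= X.mean(axis=0)
    basis, _ = pca(X)
    ref = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
    assert np.allclose(basis.eigenvalues, ref[:basis.n_components], atol=1e-8)


def test_pca_too_many_components_errors():
    with pytest.raises(ValueError):
        pca(np.zeros((5, 3)), n_components=6)


def test_bic_delta_arithmetic_and_wss_monotonicity():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(120, 5))
    scan = kmeans_bic_scan(X, k_max=8, seed=3)
    assert np.all(np.diff(scan.wss) <= 1e-9)
    assert scan.delta_bic == pytest.approx(scan.bic[:-1] - scan.bic[1:])


def test_two_separated_blobs_select_k2():
    """The spherical-likelihood BIC targets the many-PC regime the scan runs
    in (scores from hundreds of SNPs), so fixtures use comparable width."""
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(0, 1, size=(100, 60)),
                   rng.normal(3, 1, size=(100, 60))])
    assert kmeans_bic_scan(X, k_max=8, seed=0).k_best == 2


def test_single_blob_selects_k1():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(150, 60))
    assert kmeans_bic_scan(X, k_max=8, seed=0).k_best == 1


def test_dapc_identical_group_means_have_null_discriminant():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(200, 5))
    labels = np.repeat(["a", "b"], 100)
    model = dapc_fit(X, labels)
    # under the null, lambda ~ d/(n-1-d) * F(d, n-1-d): ~0.026 expected here
    assert model.eigenvalues[0] < 0.12


def test_dapc_separable_groups_reassign_perfectly():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 1, size=(40, 3)), rng.normal(20, 1, size=(40, 3))])
    labels = np.repeat(["a", "b"], 40)
    model = dapc_fit(X, labels)
    res = reassignment_accuracy(dapc_predict(model, X, kind="scores"), labels)
    assert res.accuracy_overall == 1.0


def test_dapc_axes_match_generalized_eigenproblem_oracle():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(20, 4)) + np.repeat([[0, 0, 0, 0], [2, 1, 0, -1]],
                                             10, axis=0)
    labels = np.repeat(["a", "b"], 10)
    model = dapc_fit(X, labels)
    # independent dense solve of B a = lambda W a
    grand = X.mean(axis=0)
    W = np.zeros((4, 4))  # within-group scatter
    B = np.zeros((4, 4))  # between-group scatter
    for grp in ("a", "b"):
        Xg = X[labels == grp]
        mg = Xg.mean(axis=0)
        W += (Xg - mg).T @ (Xg - mg)
        B += len(Xg) * np.outer(mg - grand, mg - grand)
    evals, evecs = scipy.linalg.eig(np.linalg.solve(W, B))
    top = evecs[:, np.argmax(evals.real)].real
    a = model.discriminant_axes[:, 0]
    cos = abs(a @ top) / (np.linalg.norm(a) * np.linalg.norm(top))
    assert cos == pytest.approx(1.0, abs=1e-8)
    assert model.eigenvalues[0] == pytest.approx(float(np.max(evals.real)), abs=1e-8)


def test_dapc_posterior_rows_sum_to_one(small_cohort):
    ds, _ = small_cohort
    labels = ds.samples["subgroup"].to_numpy()
    model = dapc_fit_genotypes(ds, labels, n_pcs=20)
    res = dapc_predict(model, ds)
    assert np.allclose(res.posterior.sum(axis=1), 1.0, atol=1e-9)


def test_dapc_invariant_to_group_relabeling():
    rng = np.random.default_rng(9)
    X = np.vstack([rng.normal(0, 1, size=(30, 4)), rng.normal(3, 1, size=(30, 4))])
    lab1 = np.repeat(["a", "b"], 30)
    lab2 = np.repeat(["z", "b"], 30)  # reverses sorted group order
    p1 = dapc_predict(dapc_fit(X, lab1), X, kind="scores").posterior
    p2 = dapc_predict(dapc_fit(X, lab2), X, kind="scores").posterior
    assert np.allclose(p1, p2[:, ::-1], atol=1e-9)


def test_dapc_predict_variant_mismatch_errors(small_cohort):
    ds, _ = small_cohort
    model = dapc_fit_genotypes(ds, ds.samples["subgroup"], n_pcs=10)
    with pytest.raises(ValueError, match="variant mismatch"):
        dapc_predict(model, ds.calls[:, :100], kind="genotypes")


def test_holdout_centering_uses_training_means():
    """Prediction must centre new data with the model's stored means."""
    rng = np.random.default_rng(10)
    calls = rng.binomial(2, 0.5, size=(60, 300)).astype(np.int8)
    labels = np.repeat(["a", "b"], 30)
    model = dapc_fit_genotypes(calls[:40], labels[:40], n_pcs=5)
    shifted = calls[40:]
    s1 = model.basis.project_raw(shifted, n_pcs=5)
    X_own = shifted - shifted.mean(axis=0)  # wrong centring for contrast
    assert not np.allclose(s1, X_own @ model.basis.loadings[:, :5])


def test_null_holdout_accuracy_is_chance():
    ds, _ = simulate_subpopulations(SimParams(n_pops=2, n_per_pop=100,
                                              n_snps=2000, fst=0.0, seed=21))
    labels = ds.samples["subgroup"].to_numpy()
    res = pairwise_external_validation(ds, labels, ("AS", "DM"), n_pcs=20,
                                       reps=10, seed=5)
    n_draws = 10 * 40
    lo, hi = scipy.stats.binom.ppf([0.005, 0.995], n_draws, 0.5) / n_draws
    assert lo <= res.mean <= hi


def test_pairwise_validation_reproducible_and_separates_divergent_groups():
    ds, _ = simulate_subpopulations(SimParams(n_pops=2, n_per_pop=60,
                                              n_snps=1500, fst=0.10, seed=22))
    labels = ds.samples["subgroup"].to_numpy()
    r1 = pairwise_external_validation(ds, labels, ("AS", "DM"), n_pcs=15, seed=9)
    r2 = pairwise_external_validation(ds, labels, ("AS", "DM"), n_pcs=15, seed=9)
    assert np.array_equal(r1.per_rep_accuracy, r2.per_rep_accuracy)
    assert r1.mean >= 0.9
    assert len(r1.per_rep_accuracy) == 10


def test_xval_deterministic_and_prefers_informative_pc_counts(small_cohort):
    ds, _ = small_cohort
    labels = ds.samples["subgroup"].to_numpy()
    res = xval_select_npcs(ds, labels, npc_grid=[2, 10, 30], reps=6, seed=13)
    res2 = xval_select_npcs(ds, labels, npc_grid=[2, 10, 30], reps=6, seed=13)
    assert np.array_equal(res.success_by_rep, res2.success_by_rep)
    assert res.chosen_npcs in (2, 10, 30)
    assert res.rmse.min() >= 0.0


def test_reassignment_accuracy_identity():
    rng = np.random.default_rng(14)
    labels = rng.choice(["a", "b", "c"], size=200)
    assigned = labels.copy()
    wrong = rng.choice(200, size=30, replace=False)
    assigned[wrong] = np.where(assigned[wrong] == "a", "b", "a")
    from rohstruct.structure import AssignmentResult
    res = AssignmentResult(posterior=np.zeros((200, 3)), assigned=assigned)
    res = reassignment_accuracy(res, labels)
    # weighted per-group accuracies reproduce the overall accuracy
    weights = {g: (labels == g).sum() / 200 for g in np.unique(labels)}
    recomposed = sum(weights[g] * res.accuracy_by_group[g] for g in weights)
    assert res.accuracy_overall == pytest.approx(recomposed)
    assert res.accuracy_overall == pytest.approx(1 - 30 / 200)


def test_accuracy_monotone_in_divergence():
    """Mean training reassignment accuracy does not decrease with F_ST."""
    means = []
    for fst in (0.0, 0.01, 0.05, 0.10):
        accs = []
        for seed in range(3):
            ds, _ = simulate_subpopulations(SimParams(
                n_pops=3, n_per_pop=40, n_snps=1500, fst=fst, seed=300 + seed))
            labels = ds.samples["subgroup"].to_numpy()
            model = dapc_fit_genotypes(ds, labels, n_pcs=20)
            res = reassignment_accuracy(dapc_predict(model, ds), labels)
            accs.append(res.accuracy_overall)
        means.append(np.mean(accs))
    assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
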