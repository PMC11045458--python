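"""Marker selection, class-balanced logistic fits, AUC and split evaluation."""

import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression

from omic import (
    Modality,
    SimulationSpec,
    State,
    auc,
    build_design,
    classify,
    fit_weighted_logistic,
    repeated_split_evaluation,
    simulate,
    wilcoxon_select,
)
from omic.interpret import class_balance_weights
from omic.preprocess import scale_features

from conftest import make_matrix


class TestWilcoxonSelect:
    def test_identical_gene_excluded_with_p_one(self, rng):
        X = rng.normal(size=(40, 3))
        X[:, 1] = 7.0  # identical in both groups
        labels = np.repeat([0, 1], 20)
        selected, pvals = wilcoxon_select(
            make_matrix(X, State.NORMALIZED), labels, 0, alpha=0.01, return_pvalues=True
        )
        assert pvals["gene_1"] == pytest.approx(1.0)
        assert "gene_1" not in selected

    def test_fully_separated_gene_included(self, rng):
        X = rng.normal(size=(40, 2))
        labels = np.repeat([0, 1], 20)
        X[labels == 0, 0] += 100.0
        selected = wilcoxon_select(make_matrix(X, State.NORMALIZED), labels, 0, alpha=0.01)
        assert "gene_0" in selected

    def test_degenerate_cluster_errors(self, rng):
        X = rng.normal(size=(10, 2))
        labels = np.array([0] + [1] * 9)
        with pytest.raises(ValueError, match=">= 2"):
            wilcoxon_select(make_matrix(X, State.NORMALIZED), labels, 0)

    def test_planted_de_gene_found_with_bounded_false_positives(self):
        rng = np.random.default_rng(42)
        n, n_genes = 200, 101
        X = rng.normal(size=(n, n_genes))
        labels = rng.integers(2, size=n)
        X[labels == 0, 0] += 2.0  # planted 2-SD effect in gene_0
        selected, pvals = wilcoxon_select(
            make_matrix(X, State.NORMALIZED), labels, 0, alpha=0.01, return_pvalues=True
        )
        assert "gene_0" in selected
        assert len(selected) <= 1 + 6  # ~1 expected null hit at alpha=0.01
        # agreement with a direct per-gene scipy call
        direct = stats.mannwhitneyu(X[labels == 0, 5], X[labels != 0, 5]).pvalue
        assert pvals["gene_5"] == pytest.approx(direct, rel=1e-9)

    def test_ordering_is_by_ascending_p(self, rng):
        X = rng.normal(size=(60, 4))
        labels = np.repeat([0, 1], 30)
        X[labels == 0, 2] += 3.0
        X[labels == 0, 0] += 1.0
        selected, pvals = wilcoxon_select(
            make_matrix(X, State.NORMALIZED), labels, 0, alpha=1.0, return_pvalues=True
        )
        assert pvals[selected].is_monotonic_increasing


class TestBuildDesign:
    def test_integrated_width_and_block_order(self, rng):
        Y = make_matrix(rng.normal(size=(10, 3)), State.NORMALIZED, Modality.ADT)
        X = make_matrix(rng.normal(size=(10, 5)), State.NORMALIZED)
        design, names = build_design(Y, X, ["gene_1", "gene_3"], "integrated")
        assert design.shape == (10, 5)
        assert names.tolist() == ["adt_0", "adt_1", "adt_2", "gene_1", "gene_3"]
        np.testing.assert_allclose(design[:, :3], Y.values)
        np.testing.assert_allclose(design[:, 3], X.values[:, 1])

    def test_rna_only_with_no_genes_errors_with_guidance(self, rng):
        Y = make_matrix(rng.normal(size=(10, 3)), State.NORMALIZED, Modality.ADT)
        X = make_matrix(rng.normal(size=(10, 5)), State.NORMALIZED)
        with pytest.raises(ValueError, match="alpha"):
            build_design(Y, X, [], "rna_only")

    def test_intercept_appends_column_of_ones(self, rng):
        Y = make_matrix(rng.normal(size=(8, 2)), State.NORMALIZED, Modality.ADT)
        X = make_matrix(rng.normal(size=(8, 3)), State.NORMALIZED)
        design, names = build_design(Y, X, [], "adt_only", intercept=True)
        assert names[-1] == "(intercept)"
        np.testing.assert_array_equal(design[:, -1], 1.0)


class TestWeights:
    @pytest.mark.parametrize("n_pos", [1, 5, 25, 49])
    def test_each_class_sums_to_half_n_squared(self, n_pos):
        n = 50
        z = np.zeros(n, dtype=int)
        z[:n_pos] = 1
        w = class_balance_weights(z)
        assert w[z == 1].sum() == pytest.approx(0.5 * n * n)
        assert w[z == 0].sum() == pytest.approx(0.5 * n * n)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            class_balance_weights(np.ones(10))


class TestWeightedLogistic:
    def test_separable_1d_sign_and_training_auc(self, rng):
        x = np.concatenate([rng.normal(-3, 0.5, 30), rng.normal(3, 0.5, 30)])[:, None]
        z = np.repeat([0, 1], 30)
        beta, converged = fit_weighted_logistic(x, z, ridge=1e-2)
        assert converged
        assert beta[0] > 0
        assert auc(x @ beta, z) == 1.0

    def test_parameter_recovery_on_balanced_logistic_draws(self):
        rng = np.random.default_rng(11)
        n, d = 2000, 5
        beta_true = np.array([1.0, -0.5, 0.25, 0.0, 0.75])
        X = rng.normal(size=(n, d))
        p = 1 / (1 + np.exp(-X @ beta_true))
        z = (rng.random(n) < p).astype(int)
        beta, _ = fit_weighted_logistic(X, z, ridge=0.0)
        # Fisher information at the truth gives the asymptotic SEs
        w = p * (1 - p)
        cov = np.linalg.inv((X.T * w) @ X)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(beta - beta_true) < 3 * se)

    def test_balanced_classes_match_unweighted_sklearn_fit(self, rng):
        n = 400
        X = rng.normal(size=(n, 3))
        z = np.repeat([0, 1], n // 2)
        X[z == 1] += 0.8
        beta, _ = fit_weighted_logistic(X, z, ridge=1e-6)
        # with pi = 0.5 the balancing weights are constant (= n), so the fit
        # must coincide with plain logistic regression
        sk = LogisticRegression(penalty=None, fit_intercept=False, tol=1e-10, max_iter=1000)
        sk.fit(X, z)
        np.testing.assert_allclose(beta, sk.coef_.ravel(), atol=1e-4)

    def test_imbalanced_fit_matches_sklearn_with_explicit_weights(self, rng):
        n = 300
        X = rng.normal(size=(n, 2))
        z = (rng.random(n) < 0.15).astype(int)
        X[z == 1] += 1.0
        beta, _ = fit_weighted_logistic(X, z, ridge=1e-8)
        w = class_balance_weights(z)
        sk = LogisticRegression(penalty=None, fit_intercept=False, tol=1e-12, max_iter=5000)
        sk.fit(X, z, sample_weight=w)
        np.testing.assert_allclose(beta, sk.coef_.ravel(), rtol=1e-3, atol=1e-5)

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_weighted_logistic(rng.normal(size=(10, 2)), np.zeros(10))


class TestClassify:
    def test_zero_coefficients_predict_all_negative(self, rng):
        X = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(classify(X, np.zeros(3)), 0)

    def test_threshold_is_strict_zero(self):
        X = np.array([[1e-12], [-1e-12], [0.0]])
        np.testing.assert_array_equal(classify(X, np.array([1.0])), [1, 0, 0])

    def test_matches_sign_oracle_on_random_inputs(self, rng):
        X = rng.normal(size=(50, 4))
        beta = rng.normal(size=4)
        np.testing.assert_array_equal(classify(X, beta), (X @ beta > 0).astype(int))


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_brute_force(self, rng):
        scores = rng.normal(size=40)
        scores[rng.random(40) < 0.3] = 0.0  # inject ties
        truth = rng.integers(2, size=40)
        if truth.sum() in (0, 40):
            truth[0] = 1 - truth[0]
        pos, neg = scores[truth == 1], scores[truth == 0]
        brute = np.mean([
            1.0 if s1 > s0 else 0.5 if s1 == s0 else 0.0 for s1 in pos for s0 in neg
        ])
        assert auc(scores, truth) == pytest.approx(brute, abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        truth = rng.integers(2, size=60)
        truth[:2] = [0, 1]
        assert auc(np.exp(scores), truth) == pytest.approx(auc(scores, truth))
        assert auc(3 * scores + 7, truth) == pytest.approx(auc(scores, truth))


@pytest.fixture(scope="module")
def adt_marker_data():
    spec = SimulationSpec(
        n_cells=500, n_genes=60, n_adts=8, n_clusters=3,
        rna_effect=0.0, adt_residual_effect=3.0, n_marker_adts=1, seed=21,
    )
    b = simulate(spec)
    return scale_features(b.rna), scale_features(b.adt), b.true_labels


class TestRepeatedSplitEvaluation:
    def test_single_repeat_fixed_seed_deterministic(self, adt_marker_data):
        X, Y, labels = adt_marker_data
        ev1 = repeated_split_evaluation(Y, X, labels, 0, n_repeats=1, seed=5)
        ev2 = repeated_split_evaluation(Y, X, labels, 0, n_repeats=1, seed=5)
        for mode in ev1.aucs:
            np.testing.assert_array_equal(ev1.aucs[mode], ev2.aucs[mode])

    def test_adt_defined_cluster_favors_adt_and_integrated(self, adt_marker_data):
        X, Y, labels = adt_marker_data
        ev = repeated_split_evaluation(Y, X, labels, 0, n_repeats=10, seed=6)
        assert ev.mean_auc("adt_only") >= ev.mean_auc("rna_only")
        assert ev.mean_auc("integrated") >= ev.mean_auc("rna_only")
        assert ev.mean_auc("adt_only") > 0.85

    def test_gene_defined_cluster_favors_rna_and_integrated(self):
        spec = SimulationSpec(
            n_cells=500, n_genes=60, n_adts=8, n_clusters=3,
            rna_effect=2.0, adt_residual_effect=0.0, b_density=0.01, seed=22,
        )
        b = simulate(spec)
        # keep ADT essentially uninformative: regenerate Y as pure noise
        rng = np.random.default_rng(23)
        Y = scale_features(b.adt.copy_with(rng.normal(size=b.adt.shape)))
        X = scale_features(b.rna)
        ev = repeated_split_evaluation(Y, X, b.true_labels, 0, n_repeats=10, seed=6)
        assert ev.mean_auc("rna_only") >= ev.mean_auc("adt_only")
        assert ev.mean_auc("integrated") >= ev.mean_auc("adt_only")
        assert ev.mean_auc("rna_only") > 0.9

    def test_gene_selection_never_sees_test_cells(self, adt_marker_data):
        """Leakage check: perturbing cells outside a given training split does
        not change the genes selected on that split."""
        X, Y, labels = adt_marker_data
        from omic.interpret import _select_with_fallback, _stratified_split

        z = (labels == 0).astype(int)
        rng = np.random.default_rng(6)
        tr, te = _stratified_split(z, 0.7, rng)
        genes_before = _select_with_fallback(
            X.copy_with(X.values), labels, 0, 0.05
        )
        X_perturbed = X.values.copy()
        X_perturbed[te] = np.random.default_rng(0).normal(size=(te.size, X.n_features))
        sub_clean = X.values[tr]
        sub_pert = X_perturbed[tr]
        np.testing.assert_array_equal(sub_clean, sub_pert)
        g1 = _select_with_fallback(make_matrix(sub_clean, State.SCALED), labels[tr], 0, 0.05)
        g2 = _select_with_fallback(make_matrix(sub_pert, State.SCALED), labels[tr], 0, 0.05)
        assert g1 == g2

    def test_final_coefficients_reported_per_mode(self, adt_marker_data):
        X, Y, labels = adt_marker_data
        ev = repeated_split_evaluation(Y, X, labels, 0, n_repeats=2, seed=1)
        assert set(ev.coefficients) == {"rna_only", "adt_only", "integrated"}
        assert len(ev.coefficients["adt_only"]) == Y.n_features
        # the marker protein should dominate the ADT coefficients
        assert ev.coefficients["adt_only"].abs().idxmax() == "adt_0"
        assert ev.coefficients["adt_only"]["adt_0"] > 0

    def test_tiny_cluster_errors(self, adt_marker_data):
        X, Y, labels = adt_marker_data
        labels = labels.copy()
        labels[labels == 2] = 1
        labels[:1] = 2  # cluster with a single member
        with pytest.raises(ValueError, match="too small"):
            repeated_split_evaluation(Y, X, labels, 2, n_repeats=1, seed=0)
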