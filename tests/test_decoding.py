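"""Item-wise SVM decoding: bootstrap balance, SMC, similarity, permutation, FDR."""

import numpy as np
import pandas as pd
import pytest

from lesion_rsa.core import GridSpec, LesionCohort, NamingMatrix
from lesion_rsa.decoding import (assemble_neural_rdm, balanced_bootstrap,
                                 build_similarity, decode_connection,
                                 fdr_select, permutation_test, predict_scores,
                                 smc)
from lesion_rsa.features import ConnectionFeatureMatrix
from lesion_rsa import synth


class TestSMC:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 0, 1, 1], [1, 1, 1, 0], 0.5),
        ([1, 0, 1], [1, 0, 1], 1.0),
        ([1, 0, 1], [0, 1, 0], 0.0),
    ])
    def test_values(self, a, b, expected):
        assert smc(a, b) == expected
        assert smc(b, a) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            smc([1, 0], [1, 0, 1])


class TestBalancedBootstrap:
    def test_minority_plus_equal_draw(self):
        labels = np.array([0] * 6 + [1] * 14)
        plan = balanced_bootstrap(labels, reps=25, seed=1, item_id="x")
        assert not plan.skipped and plan.n_reps == 25
        for subset in plan.subsets:
            assert len(subset) == 12
            assert labels[subset].sum() == 6  # exactly half each class
            assert len(np.unique(subset)) == 12

    def test_already_balanced_uses_everyone(self):
        labels = np.array([0] * 10 + [1] * 10)
        plan = balanced_bootstrap(labels, reps=3, seed=1)
        for subset in plan.subsets:
            np.testing.assert_array_equal(subset, np.arange(20))

    @pytest.mark.parametrize("labels", [np.ones(15), np.zeros(15),
                                        np.array([0] + [1] * 19)])
    def test_degenerate_items_skipped(self, labels):
        plan = balanced_bootstrap(labels.astype(int), reps=5, min_minority=2,
                                  seed=1)
        assert plan.skipped and plan.subsets == []

    def test_all_subsets_balanced_on_real_world(self, tiny_world):
        naming = tiny_world["naming"]
        for i in range(naming.n_items):
            labels = naming.values[:, i]
            plan = balanced_bootstrap(labels, reps=10, seed=3, item_id=f"i{i}")
            if plan.skipped:
                continue
            for subset in plan.subsets:
                sub = labels[subset]
                assert (sub == 0).sum() == (sub == 1).sum()


def _toy_features(values):
    values = np.asarray(values, dtype=np.uint8)
    return ConnectionFeatureMatrix("toy", np.arange(values.shape[0]),
                                   [f"p{k}" for k in range(values.shape[1])],
                                   values)


class TestPredictScores:
    def test_perfectly_informative_voxel(self):
        labels = np.array([0, 1] * 10)
        values = np.zeros((8, 20), dtype=np.uint8)
        values[3] = labels  # one voxel equals the label exactly
        f = _toy_features(values)
        subset = np.arange(20)
        preds = predict_scores(f, labels, subset, seed=4)
        np.testing.assert_array_equal(preds, labels)

    def test_agreement_with_reference_svm(self, rng):
        # sklearn's exact SVC is the independent check of the CD solver
        from sklearn.svm import SVC
        from lesion_rsa._svm import fit_svm
        agree = []
        for _ in range(25):
            n = int(rng.integers(14, 50)) & ~1
            fdim = int(rng.integers(5, 80))
            X = (rng.random((n, fdim)) < 0.3).astype(float)
            w = rng.normal(size=fdim)
            y = (X @ w + 0.4 * rng.normal(size=n) > np.median(X @ w)).astype(int)
            if y.sum() in (0, n):
                continue
            Xb = np.hstack([X, np.ones((n, 1))])
            w_fit, _ = fit_svm(Xb, 2.0 * y - 1.0)
            Xt = (rng.random((150, fdim)) < 0.3).astype(float)
            mine = (np.hstack([Xt, np.ones((150, 1))]) @ w_fit >= 0).astype(int)
            ref = SVC(kernel="linear", C=1.0).fit(X, y).predict(Xt)
            agree.append((mine == ref).mean())
        assert np.mean(agree) > 0.9

    def test_constant_features_constant_predictions(self):
        labels = np.array([1] * 14 + [0] * 6)
        values = np.zeros((10, 20), dtype=np.uint8)  # nothing to learn from
        f = _toy_features(values)
        subset = np.concatenate([np.flatnonzero(labels == 0),
                                 np.flatnonzero(labels == 1)[:6]])
        preds = predict_scores(f, labels, np.sort(subset), seed=4)
        out = preds[~np.isin(np.arange(20), subset)]
        assert len(np.unique(out)) == 1

    def test_zero_voxels_rejected(self):
        f = ConnectionFeatureMatrix("empty", np.empty(0, dtype=int),
                                    ["p0", "p1"], np.zeros((0, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="zero voxels"):
            predict_scores(f, np.array([0, 1]), np.array([0, 1]), seed=0)

    def test_unbalanced_subset_rejected(self):
        labels = np.array([0, 0, 1, 1, 1, 1])
        f = _toy_features(np.eye(6, dtype=np.uint8))
        with pytest.raises(ValueError, match="not balanced"):
            predict_scores(f, labels, np.array([0, 2, 3, 4]), seed=0)


class TestBuildSimilarity:
    def _setup(self, rng):
        n, n_items = 24, 6
        values = (rng.random((30, n)) < 0.3).astype(np.uint8)
        naming_vals = (rng.random((n, n_items)) < 0.6).astype(np.uint8)
        naming_vals[:, 1] = naming_vals[:, 0]        # item 1 duplicates item 0
        naming_vals[:, 2] = 1 - naming_vals[:, 0]    # item 2 is the complement
        naming = NamingMatrix([f"p{k}" for k in range(n)],
                              [f"i{k}" for k in range(n_items)], naming_vals)
        f = _toy_features(values)
        plans = [balanced_bootstrap(naming_vals[:, i], reps=5, seed=9,
                                    item_id=f"i{i}")
                 for i in range(n_items)]
        return f, naming, plans

    def test_identical_and_complement_items(self, rng):
        f, naming, plans = self._setup(rng)
        sim = build_similarity(f, naming, plans, seed=9)
        assert sim[0, 1] == pytest.approx(sim[0, 0])
        assert sim[0, 2] == pytest.approx(1 - sim[0, 0])

    def test_skipped_rows_are_nan(self, rng):
        f, naming, plans = self._setup(rng)
        vals = naming.values.copy()
        vals[:, 3] = 1  # degenerate item
        naming2 = NamingMatrix(naming.patient_ids, naming.item_ids, vals)
        plans = [balanced_bootstrap(vals[:, i], reps=5, seed=9, item_id=f"i{i}")
                 for i in range(naming2.n_items)]
        sim = build_similarity(f, naming2, plans, seed=9)
        assert np.isnan(sim[3]).all()
        assert not np.isnan(sim[0, 3])  # other items still scored against item 3


class TestAssembleNeuralRDM:
    def test_symmetrization_arithmetic(self):
        sim = np.array([[0.9, 0.4], [0.6, 0.8]])
        out = assemble_neural_rdm(sim, ["a", "b"], "conn")
        assert out.rdm.values[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(out.within_item, [0.9, 0.8])
        assert out.rdm.values[0, 0] == 0.0

    def test_symmetric_input_unchanged(self, rng):
        m = rng.random((5, 5))
        sim = (m + m.T) / 2
        out = assemble_neural_rdm(sim, [f"i{k}" for k in range(5)], "c")
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(out.rdm.values[iu], (1 - sim)[iu])

    def test_bounds_preserved(self, rng):
        m = rng.random((8, 8))
        out = assemble_neural_rdm(m, [f"i{k}" for k in range(8)], "c")
        vals = out.rdm.values[~np.isnan(out.rdm.values)]
        assert vals.min() >= 0 and vals.max() <= 1

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            assemble_neural_rdm(np.zeros((3, 4)), ["a", "b", "c"], "c")


class TestPermutationTest:
    def test_separable_features_unbeatable(self):
        n = 20
        rng = np.random.default_rng(3)
        naming_vals = (rng.random((n, 4)) < 0.6).astype(np.uint8)
        values = naming_vals.T.copy()  # one voxel per item equal to its labels
        f = _toy_features(values)
        naming = NamingMatrix([f"p{k}" for k in range(n)],
                              [f"i{k}" for k in range(4)], naming_vals)
        p, stats = permutation_test(f, naming, reps=2, n_perm=60, seed=5)
        assert p == 0.0
        assert len(stats) == 60

    def test_add_one_estimator(self):
        n = 16
        rng = np.random.default_rng(4)
        naming_vals = (rng.random((n, 3)) < 0.5).astype(np.uint8)
        f = _toy_features((rng.random((10, n)) < 0.4).astype(np.uint8))
        naming = NamingMatrix([f"p{k}" for k in range(n)],
                              [f"i{k}" for k in range(3)], naming_vals)
        p, stats = permutation_test(f, naming, reps=1, n_perm=19, seed=5,
                                    add_one=True)
        k = int((stats > np.nanmean(stats)).sum())  # sanity: p in (0, 1]
        assert 0 < p <= 1


class TestFDR:
    def _bh_oracle(self, pvals, q):
        m = len(pvals)
        order = np.argsort(pvals)
        keep = np.zeros(m, dtype=bool)
        thresh = 0
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= rank * q / m:
                thresh = rank
        keep[order[:thresh]] = True
        return keep

    def test_examples(self):
        assert fdr_select([0.01], 0.05).tolist() == [True]
        assert not fdr_select([1.0, 1.0, 1.0], 0.05).any()

    def test_matches_bruteforce_stepup(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            pvals = rng.random(m) ** rng.uniform(0.5, 3)
            np.testing.assert_array_equal(fdr_select(pvals, 0.05),
                                          self._bh_oracle(pvals, 0.05))

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            fdr_select([0.1, 1.2])


def test_decode_connection_end_to_end(tiny_world):
    """Planted informative regions should carry category structure in the
    neural RDM: within-category dissimilarity below between-category."""
    from lesion_rsa.features import extract_features
    template, cohort = tiny_world["template"], tiny_world["cohort"]
    naming, truth = tiny_world["naming"], tiny_world["truth"]
    name = tiny_world["informative"][0]
    f = extract_features(template, cohort, name)
    out = decode_connection(f, naming, reps=8, seed=21, n_perm=0)
    assert out.rdm.n_items == naming.n_items
    cats = np.array(truth.categories)
    vals = out.rdm.values
    iu = np.triu_indices(naming.n_items, 1)
    same = cats[iu[0]] == cats[iu[1]]
    assert np.nanmean(vals[iu][same]) < np.nanmean(vals[iu][~same])
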