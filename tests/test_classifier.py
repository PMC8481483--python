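"""Tests of the two-tiered classifier: label transfer, softmax net, rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from cordatlas import classifier as clf, qc


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="module")
def coarse_data():
    """Three well-separated coarse types with raw counts."""
    rng = np.random.default_rng(5)
    n, g = 360, 80
    genes = [f"g{i}" for i in range(g)]
    labels = np.repeat(["astro", "neuron", "doublet"], n // 3)
    X = rng.poisson(1.0, size=(n, g))
    for i, c in enumerate(["astro", "neuron", "doublet"]):
        X[labels == c, 20 * i : 20 * i + 15] += rng.poisson(6, ((labels == c).sum(), 15))
    adata = AnnData(
        X=sp.csr_matrix(X.astype(np.int64)),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=genes),
    )
    return adata, labels


@pytest.fixture(scope="module")
def tier1_model(coarse_data):
    adata, labels = coarse_data
    norm = qc.log_normalize(adata)
    Xs, state = qc.scale_regress(norm, params=qc.ScalingParams(covariates=()))
    return clf.train_tier1(Xs, labels, state, n_dims=10,
                           routing_set=("neuron", "doublet")), norm


class TestSplit:
    def test_holdout_fraction_exact(self):
        labels = np.repeat(["a", "b"], 500)
        train, test = clf.split_train_test(labels, 0.1, seed=0)
        assert len(test) == 100 and len(train) == 900

    def test_stratified_by_class(self):
        labels = np.array(["a"] * 900 + ["b"] * 100)
        _, test = clf.split_train_test(labels, 0.1, seed=1)
        assert (labels[test] == "b").sum() == 10

    def test_tiny_class_stays_in_train(self):
        labels = np.array(["a"] * 50 + ["b"])
        with pytest.warns(UserWarning, match="too small"):
            train, test = clf.split_train_test(labels, 0.9, seed=0)
        assert "b" in labels[train]

    def test_deterministic(self):
        labels = np.repeat(list("abc"), 40)
        t1 = clf.split_train_test(labels, 0.2, seed=9)
        t2 = clf.split_train_test(labels, 0.2, seed=9)
        np.testing.assert_array_equal(t1[0], t2[0])
        np.testing.assert_array_equal(t1[1], t2[1])


class TestTier1:
    def test_self_projection_matches_training_embedding(self, tier1_model):
        model, norm = tier1_model
        Z = model.scale_state.transform(norm)
        np.testing.assert_allclose(
            model.embedding.project(Z), model.embedding.coords, atol=1e-8
        )

    def test_serialization_roundtrip(self, tier1_model, tmp_path):
        model, _ = tier1_model
        model.save(tmp_path / "t1")
        loaded = clf.Tier1Model.load(tmp_path / "t1")
        np.testing.assert_array_equal(loaded.embedding.loadings,
                                      model.embedding.loadings)
        np.testing.assert_array_equal(loaded.labels.astype(str),
                                      model.labels.astype(str))
        assert loaded.genes == model.genes

    def test_query_equals_reference_recovers_labels(self, coarse_data, tier1_model):
        adata, labels = coarse_data
        model, _ = tier1_model
        preds = clf.predict_tier1(model, adata)
        assert (preds["label"].to_numpy() == labels).mean() >= 0.99

    def test_routing_mask_follows_routing_set(self, coarse_data, tier1_model):
        adata, labels = coarse_data
        model, _ = tier1_model
        preds = clf.predict_tier1(model, adata)
        routed = preds["routed"].to_numpy()
        lab = preds["label"].to_numpy()
        assert routed[lab == "neuron"].all()
        assert routed[lab == "doublet"].all()
        assert not routed[lab == "astro"].any()

    def test_disjoint_gene_sets_rejected(self, tier1_model):
        model, _ = tier1_model
        other = AnnData(
            X=sp.csr_matrix(np.ones((5, 3))),
            var=pd.DataFrame(index=["x1", "x2", "x3"]),
        )
        with pytest.raises(ValueError, match="no genes"):
            clf.predict_tier1(model, other)


class TestPreprocessTier2:
    def test_stated_transform(self):
        X = np.array([[0.0, np.e - 1, np.e**2 - 1]])
        F, genes, flagged = clf.preprocess_tier2(X)
        np.testing.assert_allclose(F, [[0.5, 1.0]])  # zero gene dropped
        F2, _, _ = clf.preprocess_tier2(np.array([[0.0, np.e - 1, np.e**2 - 1]]),
                                        gene_list=["0", "1", "2"])
        np.testing.assert_allclose(F2, [[0.0, 0.5, 1.0]])

    def test_all_zero_cell_flagged(self):
        X = np.array([[0, 0, 0], [1, 2, 3]], dtype=float)
        F, _, flagged = clf.preprocess_tier2(X, gene_list=["0", "1", "2"])
        assert flagged[0] and not flagged[1]
        np.testing.assert_array_equal(F[0], 0.0)

    def test_per_cell_max_is_one(self, rng):
        X = rng.poisson(3, size=(20, 10)).astype(float) + 1
        F, _, _ = clf.preprocess_tier2(X)
        np.testing.assert_allclose(F.max(axis=1), 1.0)

    def test_training_mode_drops_empty_genes(self, rng):
        X = rng.poisson(2, size=(10, 5)).astype(float)
        X[:, 2] = 0
        F, genes, _ = clf.preprocess_tier2(X)
        assert F.shape[1] == 4 and "2" not in genes


class TestTier2:
    def _separable(self, rng, n=200, d=20):
        y = np.repeat(["u", "v"], n // 2)
        X = rng.normal(size=(n, d)) * 0.1
        X[y == "u", :5] += 1.0
        X[y == "v", 5:10] += 1.0
        return X, y

    @pytest.mark.parametrize("arch", ["linear", "h64", "h32x16+l2first"])
    def test_separable_data_learned(self, rng, arch):
        X, y = self._separable(rng)
        m = clf.train_tier2(X, y, [str(i) for i in range(X.shape[1])],
                            architecture=arch, epochs=30, seed=0)
        acc = (m.predict(X) == y).mean()
        assert acc >= 0.98

    def test_zero_epochs_near_chance(self, rng):
        X, y = self._separable(rng)
        m = clf.train_tier2(X, y, [str(i) for i in range(20)], epochs=0, seed=0)
        proba = m.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        acc = (m.predict(X) == y).mean()
        assert 0.3 <= acc <= 0.7

    def test_deterministic_in_seed(self, rng):
        X, y = self._separable(rng)
        m1 = clf.train_tier2(X, y, [str(i) for i in range(20)], epochs=5, seed=3)
        m2 = clf.train_tier2(X, y, [str(i) for i in range(20)], epochs=5, seed=3)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_softmax_rows_sum_to_one(self, rng):
        X, y = self._separable(rng)
        m = clf.train_tier2(X, y, [str(i) for i in range(20)], epochs=3, seed=0)
        p = m.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_architecture_rejected(self, rng):
        X, y = self._separable(rng)
        with pytest.raises(ValueError, match="architecture"):
            clf.train_tier2(X, y, [], architecture="resnet50")
        with pytest.raises(ValueError, match="optimizer"):
            clf.train_tier2(X, y, [], optimizer="rmsprop")

    def test_serialization_roundtrip(self, rng, tmp_path):
        X, y = self._separable(rng)
        m = clf.train_tier2(X, y, [str(i) for i in range(20)], epochs=5, seed=0)
        m.save(tmp_path / "t2")
        loaded = clf.Tier2Model.load(tmp_path / "t2")
        np.testing.assert_array_equal(loaded.predict(X), m.predict(X))


class TestSVMBaseline:
    def test_separable_counts_classified(self, rng):
        n = 100
        X = rng.poisson(1, size=(2 * n, 30))
        X[:n, :10] += rng.poisson(8, (n, 10))
        y = np.repeat(["a", "b"], n)
        bundle = clf.train_svm_baseline(sp.csr_matrix(X), y)
        preds = clf.predict_svm(bundle, sp.csr_matrix(X))
        assert (preds == y).mean() == 1.0

    def test_maxabs_scaling_bounded(self, rng):
        X = sp.csr_matrix(rng.poisson(5, size=(50, 10)).astype(float))
        bundle = clf.train_svm_baseline(X, np.repeat(["a", "b"], 25))
        Xs = bundle["scaler"].transform(X)
        assert np.abs(Xs.toarray()).max() <= 1.0 + 1e-12


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "a", "b"])
        rep = clf.evaluate(y, y)
        assert rep["accuracy"] == 1.0
        assert (rep["per_class"]["f1"] == 1.0).all()
        cm = rep["confusion"].to_numpy()
        assert np.all(cm == np.diag(np.diag(cm)))

    def test_constant_predictor_on_balanced_classes(self):
        y = np.array(["a", "b"] * 50)
        preds = np.array(["a"] * 100)
        rep = clf.evaluate(preds, y)
        assert rep["accuracy"] == 0.5

    def test_confusion_rows_sum_to_support(self, rng):
        y = rng.choice(list("abc"), 90)
        p = rng.choice(list("abc"), 90)
        rep = clf.evaluate(p, y)
        rows = rep["confusion"].sum(axis=1)
        for c in "abc":
            assert rows[c] == (y == c).sum()


class TestUnknownClusterRule:
    @pytest.mark.parametrize(
        "n_match,expected", [(9, "X"), (8, "X"), (7, None)]
    )
    def test_majority_threshold(self, n_match, expected):
        clusters = np.array(["u1"] * 10)
        preds = np.array(["X"] * n_match + ["Y"] * (10 - n_match))
        out = clf.identify_unknown_clusters(clusters, preds)
        assert out["u1"] == expected

    def test_excluded_class_rejected_even_at_majority(self):
        clusters = np.array(["u1"] * 10)
        preds = np.array(["doublet"] * 8 + ["X"] * 2)
        out = clf.identify_unknown_clusters(clusters, preds)
        assert out["u1"] is None


class TestBenchmark:
    def test_positive_rank_correlation_detected(self):
        f1 = pd.Series({"a": 0.9, "b": 0.7, "c": 0.5, "d": 0.3})
        freq = {"a": 0.95, "b": 0.8, "c": 0.6, "d": 0.4}
        out = clf.benchmark_expectation(f1, freq)
        assert out["spearman"] == pytest.approx(1.0)
        assert out["mean_cocluster_frequency"] == pytest.approx(np.mean(list(freq.values())))

    def test_constant_inputs_report_no_correlation(self):
        f1 = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        out = clf.benchmark_expectation(f1, {"a": 1.0, "b": 1.0, "c": 1.0})
        assert out["spearman"] is None

    def test_single_class_no_correlation(self):
        out = clf.benchmark_expectation(pd.Series({"a": 0.9}), {"a": 0.5})
        assert out["spearman"] is None
        assert len(out["table"]) == 1


class TestTwoPhaseTransfer:
    def _build(self, rng):
        """One dorsal-like type plus two blending mid/ventral types."""
        n, g = 120, 60
        genes = [f"g{i}" for i in range(g)]
        X = rng.poisson(1.0, size=(3 * n, g))
        fine = np.repeat(["dorsal1", "mv1", "mv2"], n)
        X[fine == "dorsal1", :15] += rng.poisson(6, (n, 15))
        X[fine == "mv1", 15:30] += rng.poisson(6, (n, 15))
        X[fine == "mv2", 25:40] += rng.poisson(6, (n, 15))
        adata = AnnData(
            X=sp.csr_matrix(X.astype(np.int64)),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(3 * n)]),
            var=pd.DataFrame(index=genes),
        )
        return adata, fine

    def test_midventral_cells_resolved_in_phase_two(self, rng):
        adata, fine = self._build(rng)
        norm = qc.log_normalize(adata)
        merged = np.where(np.isin(fine, ["mv1", "mv2"]), "midventral", fine)
        Xs, state = qc.scale_regress(norm, params=qc.ScalingParams(covariates=()))
        model_all = clf.train_tier1(Xs, merged, state, n_dims=10)
        mv = merged == "midventral"
        mv_norm = norm[mv].copy()
        Xmv, state_mv = qc.scale_regress(mv_norm,
                                         params=qc.ScalingParams(covariates=()))
        model_mv = clf.train_tier1(Xmv, fine[mv], state_mv, n_dims=10)
        out = clf.two_phase_transfer(model_all, model_mv, adata)
        labels = out["label"].to_numpy()
        # dorsal cells never get a mid/ventral fine label
        assert (labels[fine == "dorsal1"] == "dorsal1").mean() >= 0.95
        # mid/ventral cells receive fine mid/ventral labels, not dorsal ones
        mv_labels = labels[np.isin(fine, ["mv1", "mv2"])]
        assert set(mv_labels) <= {"mv1", "mv2"}
        acc = (labels[mv] == fine[mv]).mean()
        assert acc >= 0.8

    def test_dorsal_only_query_skips_phase_two(self, rng):
        adata, fine = self._build(rng)
        norm = qc.log_normalize(adata)
        merged = np.where(np.isin(fine, ["mv1", "mv2"]), "midventral", fine)
        Xs, state = qc.scale_regress(norm, params=qc.ScalingParams(covariates=()))
        model_all = clf.train_tier1(Xs, merged, state, n_dims=10)
        mv = merged == "midventral"
        mv_norm = norm[mv].copy()
        Xmv, state_mv = qc.scale_regress(mv_norm,
                                         params=qc.ScalingParams(covariates=()))
        model_mv = clf.train_tier1(Xmv, fine[mv], state_mv, n_dims=10)
        dorsal_query = adata[fine == "dorsal1"].copy()
        out = clf.two_phase_transfer(model_all, model_mv, dorsal_query)
        assert not out["phase2"].any() or out["phase2"].mean() < 0.05


class TestTwoTier:
    def test_routing_partition_and_tiers(self, coarse_data, tier1_model):
        adata, labels = coarse_data
        model, norm = tier1_model
        rng = np.random.default_rng(0)
        # tier2 trained to distinguish neuron sub-identities vs doublet
        routed_truth = np.isin(labels, ["neuron", "doublet"])
        counts = adata.X[routed_truth]
        F, genes, _ = clf.preprocess_tier2(
            clf._CountsView(counts, list(adata.var_names))
        )
        fine = np.where(labels[routed_truth] == "neuron", "neuron.f1", "doublet")
        t2 = clf.train_tier2(F, fine, genes, architecture="h32", epochs=20, seed=0)
        out = clf.predict_two_tier(model, t2, adata)
        assert set(out.columns) >= {"tier1_label", "final_label", "confidence", "tier"}
        assert (out["tier"].isin([1, 2])).all()
        astro = out["tier1_label"] == "astro"
        assert (out.loc[astro, "tier"] == 1).all()
        routed = out["tier1_label"].isin(["neuron", "doublet"])
        assert (out.loc[routed, "tier"] == 2).all()
        assert ((out.loc[routed, "confidence"] > 0)
                & (out.loc[routed, "confidence"] <= 1)).all()
        # routed neurons now carry the fine label
        assert (out.loc[out["tier1_label"] == "neuron", "final_label"]
                .isin(["neuron.f1", "doublet"])).all()
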