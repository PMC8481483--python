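"""Tests of SNN/Leiden clustering, robustness, and the hygiene rules."""

import numpy as np
import pandas as pd
import pytest

from cordatlas import clustering as clu


def _two_blobs(rng, n=60, sep=20.0, d=5):
    X = np.vstack([
        rng.normal(0, 1, size=(n // 2, d)),
        rng.normal(sep, 1, size=(n // 2, d)),
    ])
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, labels


class TestSNNGraph:
    def test_separated_blobs_have_no_cross_edges(self, rng):
        X, labels = _two_blobs(rng)
        g = clu.snn_graph(X, k=10)
        for e in g.es:
            assert labels[e.source] == labels[e.target]

    def test_matches_brute_force_jaccard(self, rng):
        X = rng.normal(size=(15, 3))
        k = 14
        g = clu.snn_graph(X, k=k, prune=0.0)
        D = np.linalg.norm(X[:, None] - X[None], axis=2)
        neigh = [set(np.argsort(D[i])[:k]) for i in range(15)]
        got = {(min(e.source, e.target), max(e.source, e.target)): w
               for e, w in zip(g.es, g.es["weight"])}
        for i in range(15):
            for j in range(i + 1, 15):
                inter = len(neigh[i] & neigh[j])
                jac = inter / len(neigh[i] | neigh[j])
                if jac > 0:
                    assert got[(i, j)] == pytest.approx(jac)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            clu.snn_graph(rng.normal(size=(5, 2)), k=5)

    def test_weights_symmetric_for_duplicate_points(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        g = clu.snn_graph(X, k=2, prune=0.0)
        w = {(e.source, e.target): x for e, x in zip(g.es, g.es["weight"])}
        assert all(v >= 0 for v in w.values())


class TestClusterGraph:
    def test_two_cliques_two_clusters(self):
        import igraph as ig

        g = ig.Graph.Full(10) + ig.Graph.Full(10)
        g.es["weight"] = [1.0] * g.ecount()
        labels = clu.cluster_graph(g, resolution=1.0, seed=0)
        assert len(set(labels.tolist())) == 2
        assert len(set(labels[:10].tolist())) == 1

    def test_low_resolution_one_cluster_per_component(self):
        import igraph as ig

        g = ig.Graph.Full(12)
        g.es["weight"] = [1.0] * g.ecount()
        labels = clu.cluster_graph(g, resolution=1e-3, seed=0)
        assert len(set(labels.tolist())) == 1

    def test_empty_graph_rejected(self):
        import igraph as ig

        with pytest.raises(ValueError):
            clu.cluster_graph(ig.Graph(), 1.0)

    def test_deterministic_in_seed(self, rng):
        X, _ = _two_blobs(rng, n=80, sep=4.0)
        g = clu.snn_graph(X, k=10)
        l1 = clu.cluster_graph(g, 1.0, seed=3)
        l2 = clu.cluster_graph(g, 1.0, seed=3)
        np.testing.assert_array_equal(l1, l2)


class TestResolutionSweep:
    def test_two_blobs_plateau_at_two(self, rng):
        X, _ = _two_blobs(rng, n=100)
        table = clu.resolution_sweep(X, [0.1, 0.5, 1.0], seed=0)
        assert list(table["n_clusters"]) == [2, 2, 2]

    def test_single_resolution_single_row(self, rng):
        X, _ = _two_blobs(rng, n=40)
        table = clu.resolution_sweep(X, [0.5], seed=0)
        assert len(table) == 1
        assert np.isnan(table["split_stability"].iloc[0])


class TestSilhouette:
    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(25, 4))
        labels = rng.integers(0, 3, size=25)
        got, _ = clu.silhouette_scores(X, labels)
        # brute force silhouette
        D = np.linalg.norm(X[:, None] - X[None], axis=2)
        svals = np.zeros(25)
        for i in range(25):
            same = (labels == labels[i]) & (np.arange(25) != i)
            if same.sum() == 0:
                svals[i] = 0
                continue
            a = D[i, same].mean()
            b = min(
                D[i, labels == c].mean() for c in set(labels.tolist()) - {labels[i]}
            )
            svals[i] = (b - a) / max(a, b)
        for c in set(labels.tolist()):
            assert got[str(c)] == pytest.approx(svals[labels == c].mean(), abs=1e-9)

    def test_far_separated_pairs_approach_one(self):
        X = np.array([[0.0, 0], [0.1, 0], [100, 0], [100.1, 0]])
        got, flagged = clu.silhouette_scores(X, np.array([0, 0, 1, 1]))
        assert got["0"] > 0.99 and got["1"] > 0.99
        assert flagged == []

    def test_single_cluster_rejected_and_singleton_flagged(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            clu.silhouette_scores(X, np.zeros(10))
        got, flagged = clu.silhouette_scores(X, np.array([0] * 9 + [1]))
        assert got["1"] == 0.0
        assert flagged == ["1"]


class TestCoclusteringRobustness:
    def test_identity_iteration_gives_frequency_one(self, rng):
        X, labels = _two_blobs(rng, n=40)
        fn = clu.make_matrix_cluster_fn(n_pcs=3, resolution=0.5, k=10)
        ref = fn(X, 0)
        rob = clu.coclustering_robustness(
            X, ref, fn, n_iter=1, subsample_frac=1.0, seed=0
        )
        for v in rob.frequency.values():
            assert v == pytest.approx(1.0)

    def test_separated_blobs_fully_robust(self, rng):
        X, labels = _two_blobs(rng, n=80)
        fn = clu.make_matrix_cluster_fn(n_pcs=3, resolution=0.5, k=10)
        rob = clu.coclustering_robustness(
            X, labels, fn, n_iter=10, subsample_frac=0.8, seed=0
        )
        assert all(v >= 0.99 for v in rob.frequency.values())

    def test_artificial_split_of_one_blob_is_fragile(self, rng):
        X = rng.normal(size=(80, 4))
        fake = np.array([0] * 40 + [1] * 40)  # one blob, arbitrary split
        fn = clu.make_matrix_cluster_fn(n_pcs=3, resolution=2.0, k=10)
        rob = clu.coclustering_robustness(
            X, fake, fn, n_iter=10, subsample_frac=0.8, seed=0
        )
        blobs, blob_labels = _two_blobs(rng, n=80)
        rob_real = clu.coclustering_robustness(
            blobs, blob_labels, fn, n_iter=10, subsample_frac=0.8, seed=0
        )
        assert max(rob.frequency.values()) < min(rob_real.frequency.values())

    def test_tiny_cluster_flagged(self, rng):
        X, labels = _two_blobs(rng, n=40)
        labels = labels.copy()
        labels[0] = 7  # singleton cluster
        fn = clu.make_matrix_cluster_fn(n_pcs=3, resolution=0.5, k=10)
        rob = clu.coclustering_robustness(X, labels, fn, n_iter=2,
                                          subsample_frac=0.9, seed=0)
        assert "7" in rob.flagged


class TestLowQualityRule:
    def _table(self, n_sig):
        return pd.DataFrame(
            {
                "log_fc": [1.0] * n_sig + [0.1] * 2,
                "pct_group": [0.5] * (n_sig + 2),
                "pct_rest": [0.1] * (n_sig + 2),
                "p": [1e-9] * n_sig + [0.5] * 2,
                "p_adj": [1e-6] * n_sig + [1.0] * 2,
            },
            index=[f"g{i}" for i in range(n_sig + 2)],
        )

    def test_two_markers_flagged(self):
        flagged, ev = clu.flag_low_quality(self._table(2))
        assert flagged and ev["n_significant_markers"] == 2

    def test_three_markers_kept(self):
        flagged, _ = clu.flag_low_quality(self._table(3))
        assert not flagged

    def test_empty_table_flagged(self):
        flagged, _ = clu.flag_low_quality(pd.DataFrame())
        assert flagged


class TestDoubletRule:
    def _setup(self, rng, mode):
        """Construct a dataset of two pure types plus a third cluster."""
        g = 40
        genes = pd.Index([f"g{i}" for i in range(g)])
        sig_a = [f"g{i}" for i in range(0, 10)]
        sig_b = [f"g{i}" for i in range(10, 20)]
        n = 60
        A = np.zeros((n, g))
        A[:, :10] = rng.poisson(5, (n, 10))
        B = np.zeros((n, g))
        B[:, 10:20] = rng.poisson(5, (n, 10))
        if mode == "doublet":
            C = A[:30] + B[:30]
        elif mode == "mixture":
            C = np.vstack([A[:15], B[:15]])
        else:  # pure
            C = A[30:]
        X = np.log1p(np.vstack([A, B, C]))
        mask = np.zeros(len(X), bool)
        mask[2 * n:] = True
        sigs = {"typeA": sig_a, "typeB": sig_b}
        markers = sig_a[:3] + sig_b[:3] if mode in ("doublet", "mixture") else sig_a[:3]
        return X, mask, markers, sigs, genes

    def test_doublet_cluster_flagged(self, rng):
        X, mask, markers, sigs, genes = self._setup(rng, "doublet")
        flagged, ev = clu.flag_doublet_cluster(X, mask, markers, sigs, genes)
        assert flagged and ev["dual_fraction"] >= 0.5

    def test_pure_cluster_not_flagged(self, rng):
        X, mask, markers, sigs, genes = self._setup(rng, "pure")
        flagged, _ = clu.flag_doublet_cluster(X, mask, markers, sigs, genes)
        assert not flagged

    def test_disjoint_mixture_not_flagged(self, rng):
        """Two pure subsets co-located in one cluster: condition (b) fails."""
        X, mask, markers, sigs, genes = self._setup(rng, "mixture")
        flagged, ev = clu.flag_doublet_cluster(X, mask, markers, sigs, genes)
        assert not flagged
        assert ev["dual_fraction"] < 0.5


class TestMergeRule:
    def _de_fn_factory(self, enriched_counts, marker_rank=None, marker="Classic1"):
        """Build a de_fn returning tables with the requested enriched counts."""

        def de_fn(mask_a, mask_b):
            key = (int(mask_a.sum()), int(mask_b.sum()))
            n = enriched_counts.get(key, 0)
            genes = [f"e{key}{i}" for i in range(n)]
            p_adj = [1e-6] * n
            if marker_rank is not None and key in marker_rank:
                genes.insert(marker_rank[key] - 1, marker)
                p_adj = [1e-6] * len(genes)
            return pd.DataFrame(
                {
                    "log_fc": [1.0] * len(genes),
                    "pct_group": [0.5] * len(genes),
                    "pct_rest": [0.0] * len(genes),
                    "p": [1e-9] * len(genes),
                    "p_adj": p_adj,
                },
                index=genes,
            )

        return de_fn

    def _embedding(self):
        # clusters of sizes 10 and 11 close together, a third far away
        X = np.vstack([
            np.zeros((10, 2)),
            np.ones((11, 2)) * 0.5,
            np.ones((12, 2)) * 50,
        ])
        labels = np.array(["a"] * 10 + ["b"] * 11 + ["c"] * 12)
        return X, labels

    def test_underpowered_pair_merges(self):
        X, labels = self._embedding()
        de_fn = self._de_fn_factory({(10, 11): 2, (11, 10): 2, (21, 12): 5, (12, 21): 5})
        out = clu.merge_pass(labels, X, de_fn)
        assert out.merge_provenance == {"b": "a"}
        assert set(out.labels.tolist()) == {"a", "c"}
        assert out.status["b"] == "merged"

    def test_classic_marker_in_top_five_blocks_merge(self):
        X, labels = self._embedding()
        de_fn = self._de_fn_factory(
            {(10, 11): 2, (11, 10): 2}, marker_rank={(10, 11): 4}
        )
        out = clu.merge_pass(
            labels, X, de_fn,
            clu.MergeRuleParams(classic_marker_list=("Classic1",)),
        )
        assert out.merge_provenance == {}
        assert set(out.labels.tolist()) == {"a", "b", "c"}

    def test_sufficiently_distinct_pair_kept(self):
        X, labels = self._embedding()
        de_fn = self._de_fn_factory({(10, 11): 3, (11, 10): 4})
        out = clu.merge_pass(labels, X, de_fn)
        assert out.merge_provenance == {}

    def test_merge_terminates_and_records_provenance_chain(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 0.1,
                       np.ones((5, 2)) * 0.2])
        labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)

        def de_fn(mask_a, mask_b):
            return pd.DataFrame(columns=["log_fc", "pct_group", "pct_rest", "p", "p_adj"])

        out = clu.merge_pass(labels, X, de_fn)
        assert set(out.labels.tolist()) == {"a"}
        assert out.merge_provenance["b"] == "a"
        assert out.merge_provenance["c"] == "a"


class TestMultiphase:
    def test_missing_parent_signature_skips_later_phase(self, small_norm):
        phases = [
            clu.PhaseParams("p1", n_pcs=10, resolution=0.8,
                            hvg=__import__("cordatlas.qc", fromlist=["HVGParams"]).HVGParams(n_top=150)),
            clu.PhaseParams("p2", n_pcs=10, resolution=1.0,
                            hvg=__import__("cordatlas.qc", fromlist=["HVGParams"]).HVGParams(n_top=150),
                            parent_signature=["not-a-gene"]),
        ]
        with pytest.warns(UserWarning):
            labeling, diag = clu.multiphase_cluster(
                small_norm, phases, seed=0, apply_flags=False
            )
        assert "p2" not in diag["phases"]
        # every cell got a phase-1 label
        assert all(l.startswith("p1") for l in labeling.labels)

    def test_phase_hierarchy_consistent(self, small_norm, small_hierarchy):
        from cordatlas.qc import HVGParams

        sig = [small_hierarchy.gene_names[i]
               for i in small_hierarchy.coarse_signature("neuron")]
        phases = [
            clu.PhaseParams("p1", n_pcs=10, resolution=0.8, hvg=HVGParams(n_top=150)),
            clu.PhaseParams("p2", n_pcs=10, resolution=1.0, hvg=HVGParams(n_top=150),
                            parent_signature=sig, min_cells=30),
        ]
        labeling, diag = clu.multiphase_cluster(small_norm, phases, seed=0,
                                                apply_flags=False)
        df = labeling.phase_labels
        sub = df[df["p2"].notna()]
        assert len(sub) >= 30  # the neuronal compartment was selected
        # final labels are single-valued: phase-2 cells carry p2 labels and
        # everyone else keeps their p1 label
        final = pd.Series(labeling.labels, index=df.index)
        assert (final[sub.index].str.startswith("p2")).all()
        rest = df.index.difference(sub.index)
        assert (final[rest].str.startswith("p1")).all()
        # phase-2 parents are a strict subset of phase-1 clusters
        assert set(sub["p1"].unique()) < set(df["p1"].unique())
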