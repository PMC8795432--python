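"""QC thresholds, normalization arithmetic, HVG ranking, clustering, doublets."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

from dlnatlas import io, qc_cluster, simdata


def _rna_matrix(counts, names=None):
    counts = np.asarray(counts)
    names = names or [f"g{i}" for i in range(counts.shape[0])]
    features = pd.DataFrame({"id": names, "name": names, "kind": "gene"})
    cells = pd.DataFrame({"barcode": [f"bc{i}" for i in range(counts.shape[1])]})
    return io.CellMatrix(values=sparse.csr_matrix(counts), features=features,
                         cells=cells, modality="RNA")


class TestQcFilter:
    def test_atac_thresholds_forced_cases(self):
        features = pd.DataFrame({"id": ["p0"], "name": ["p0"], "kind": "peak"})
        cells = pd.DataFrame({
            "barcode": ["a", "b", "c"],
            "n_fragments": [500, 1500, 1500],
            "tss_enrichment": [9.0, 7.0, 9.0],
        })
        cm = io.CellMatrix(values=sparse.csr_matrix(np.ones((1, 3))),
                           features=features, cells=cells, modality="ATAC")
        kept, report = qc_cluster.qc_filter(cm)
        assert kept.cells["barcode"].tolist() == ["c"]
        assert report["low_fragment_removed"] == 1
        assert report["low_tss_removed"] == 1

    def test_mito_fraction_exactly_at_threshold_retained(self):
        # removal is strict "greater than": a cell at exactly 20% stays
        counts = np.array([[20, 21, 80], [80, 79, 20]])
        cm = _rna_matrix(counts, names=["mt-g0", "g1"])
        kept, _ = qc_cluster.qc_filter(cm)
        assert kept.cells["barcode"].tolist() == ["bc0"]

    def test_all_pass_identity_and_idempotence(self):
        counts = np.vstack([np.full(100, 1), np.full(100, 99)])
        cm = _rna_matrix(counts, names=["mt-g0", "g1"])
        once, _ = qc_cluster.qc_filter(cm)
        assert once.n_cells == 100
        twice, _ = qc_cluster.qc_filter(once)
        assert twice.cells.equals(once.cells)

    def test_no_mito_genes_is_an_error(self):
        cm = _rna_matrix(np.ones((2, 3)))
        with pytest.raises(io.FormatError, match="mt-"):
            qc_cluster.qc_filter(cm)


class TestLognormalize:
    def test_stated_formula_value(self):
        # count 1 at depth 4 with scale 10000: ln(1 + 10000/4) = ln(2501)
        cm = _rna_matrix([[1], [3]])
        norm = qc_cluster.lognormalize(cm)
        assert norm[0, 0] == pytest.approx(np.log(2501.0), abs=1e-10)

    def test_zero_count_maps_to_zero(self):
        cm = _rna_matrix([[0], [5]])
        assert qc_cluster.lognormalize(cm)[0, 0] == 0.0

    def test_depth_scale_invariance(self):
        cm1 = _rna_matrix([[1], [3]])
        cm2 = _rna_matrix([[2], [6]])
        assert np.allclose(qc_cluster.lognormalize(cm1),
                           qc_cluster.lognormalize(cm2))

    def test_zero_depth_cell_lists_barcode(self):
        cm = _rna_matrix([[0, 1], [0, 3]])
        with pytest.raises(io.FormatError, match="bc0"):
            qc_cluster.lognormalize(cm)


class TestSelectHvg:
    def test_only_varying_genes_selected(self, rng):
        norm = np.vstack([
            rng.normal(1, 1, size=(5, 50)),          # varying
            np.ones((20, 50)) * 0.5,                 # constant
        ])
        norm = np.clip(norm, 0, None)
        ids = [f"v{i}" for i in range(5)] + [f"c{i}" for i in range(20)]
        top = qc_cluster.select_hvg(norm, ids, n=5)
        assert set(top) == {f"v{i}" for i in range(5)}

    def test_constant_matrix_ties_break_lexicographically(self):
        norm = np.ones((6, 10))
        ids = ["b", "a", "d", "c", "f", "e"]
        assert qc_cluster.select_hvg(norm, ids, n=3) == ["a", "b", "c"]

    def test_requesting_too_many_raises(self):
        with pytest.raises(ValueError):
            qc_cluster.select_hvg(np.ones((3, 4)), ["a", "b", "c"], n=5)

    def test_planted_high_dispersion_block_recovered(self, rng):
        # 50 genes with 10x dispersion among 500: all must rank in the top 100
        n_cells = 300
        mu = 2.0
        low = rng.gamma(shape=10.0, scale=mu / 10.0, size=(450, n_cells))
        high = rng.gamma(shape=0.5, scale=mu / 0.5, size=(50, n_cells))
        counts = rng.poisson(np.vstack([low, high]))
        cm = _rna_matrix(counts)
        norm = qc_cluster.lognormalize(cm)
        top = qc_cluster.select_hvg(norm, cm.features["id"], n=200)
        planted = {f"g{i}" for i in range(450, 500)}
        assert planted <= set(top)


class TestEmbedCluster:
    def _blobs(self, rng, n_per=200, sep=20.0):
        # centers 20 sigma apart, the separation spread over all features so
        # per-feature standardization cannot erase it
        a = rng.normal(0, 1, size=(n_per, 30))
        b = rng.normal(0, 1, size=(n_per, 30)) + sep / np.sqrt(30)
        x = np.vstack([a, b]).T  # features x cells
        labels = np.array([0] * n_per + [1] * n_per)
        return x, labels

    def test_two_separated_blobs_two_clusters(self, rng):
        x, truth = self._blobs(rng)
        labels, _ = qc_cluster.embed_cluster(
            x, qc_cluster.ClusterParams(n_hvg=30, n_pcs=10, seed=0))
        assert labels.max() + 1 == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_blob_one_cluster(self, rng):
        x = rng.normal(0, 1, size=(30, 300))
        labels, _ = qc_cluster.embed_cluster(
            x, qc_cluster.ClusterParams(n_hvg=30, n_pcs=10, seed=0))
        assert labels.max() + 1 == 1

    def test_cell_permutation_permutes_labels(self, rng):
        x, _ = self._blobs(rng, n_per=100)
        perm = rng.permutation(x.shape[1])
        params = qc_cluster.ClusterParams(n_hvg=30, n_pcs=10, seed=0)
        labels, _ = qc_cluster.embed_cluster(x, params)
        labels_perm, _ = qc_cluster.embed_cluster(x[:, perm], params)
        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_too_few_cells_raises(self, rng):
        x = rng.normal(size=(10, 15))
        with pytest.raises(ValueError):
            qc_cluster.embed_cluster(
                x, qc_cluster.ClusterParams(n_hvg=10, n_pcs=5, knn_k=20))


class TestDoubletFilter:
    def test_percentile_arithmetic_distinct_scores(self, rng):
        # 100 cells with distinct scores: percentile 95 removes exactly 5
        counts = rng.poisson(2.0, size=(300, 100))
        counts[0] = np.arange(100) * 10  # force distinct co-detection scores
        cm = _rna_matrix(counts)
        scores = qc_cluster.doublet_scores(cm)
        kept, removed = qc_cluster.doublet_score_and_filter(cm, 95.0)
        if len(np.unique(scores)) == len(scores):
            assert len(removed) == 5
        else:
            assert len(removed) >= 5
        assert kept.n_cells + len(removed) == 100

    def test_all_identical_cells_tie_rule_removes_all(self):
        counts = np.tile(np.arange(1, 11)[:, None], (1, 20))
        cm = _rna_matrix(counts)
        kept, removed = qc_cluster.doublet_score_and_filter(cm, 95.0)
        # every score ties at the threshold; the documented rule removes all
        assert kept.n_cells == 0
        assert len(removed) == 20

    def test_invalid_percentile(self):
        cm = _rna_matrix(np.ones((3, 5)))
        with pytest.raises(ValueError):
            qc_cluster.doublet_score_and_filter(cm, 0.0)

    def test_simulated_doublets_recovered(self):
        config = simdata.default_config(seed=11, doublet_rate=0.08)
        rna, truth = simdata.simulate_rna(config)
        cm, _ = qc_cluster.qc_filter(rna)
        _, removed = qc_cluster.doublet_score_and_filter(cm, 92.0)
        true_doublets = set(truth.cells.loc[truth.cells["doublet"],
                                            "barcode"]) & set(
            cm.cells["barcode"])
        recall = len(set(removed["barcode"]) & true_doublets) / len(
            true_doublets)
        assert recall > 0.5


class TestPipelineRecovery:
    def test_planted_cell_types_recovered(self, default_sim):
        config, rna, truth = default_sim
        cm, _ = qc_cluster.qc_filter(rna)
        cm, _ = qc_cluster.doublet_score_and_filter(cm, 95.0)
        norm = qc_cluster.lognormalize(cm)
        hvgs = qc_cluster.select_hvg(norm, cm.features["id"], n=500)
        idx = cm.features.set_index("id").index.get_indexer(hvgs)
        labels, _ = qc_cluster.embed_cluster(
            norm[idx], qc_cluster.ClusterParams(n_hvg=500, seed=0))
        tt = truth.cells.set_index("barcode").loc[cm.cells["barcode"]]
        singlet = ~tt["doublet"].to_numpy()
        ari = adjusted_rand_score(tt["cell_type"].to_numpy()[singlet],
                                  labels[singlet])
        assert ari >= 0.9

    def test_monocyte_subclusters_recovered(self, default_sim):
        config, rna, truth = default_sim
        cm, _ = qc_cluster.qc_filter(rna)
        cm, _ = qc_cluster.doublet_score_and_filter(cm, 95.0)
        tt = truth.cells.set_index("barcode").loc[cm.cells["barcode"]]
        mono = ((tt["cell_type"] == "monocyte")
                & tt["timepoint"].isin(["day0", "day28"])).to_numpy()
        cm_mono = cm.subset_cells(mono)
        norm = qc_cluster.lognormalize(cm_mono)
        hvgs = qc_cluster.select_hvg(norm, cm_mono.features["id"], n=300)
        idx = cm_mono.features.set_index("id").index.get_indexer(hvgs)
        labels, _ = qc_cluster.embed_cluster(
            norm[idx], qc_cluster.ClusterParams(n_hvg=300, seed=0))
        ttm = tt[mono]
        singlet = ~ttm["doublet"].to_numpy()
        ari = adjusted_rand_score(ttm["subcluster"].to_numpy()[singlet],
                                  labels[singlet])
        assert ari >= 0.8
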