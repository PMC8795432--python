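"""Deviation arithmetic vs a brute-force oracle; TSS scores; gene scores;
TF-gene correlation ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.metrics import roc_auc_score

from dlnatlas import io, motif_dev, simdata


def _atac_matrix(counts):
    counts = np.asarray(counts)
    n_peaks, n_cells = counts.shape
    features = pd.DataFrame({"id": [f"p{i}" for i in range(n_peaks)],
                             "name": [f"p{i}" for i in range(n_peaks)],
                             "kind": "peak"})
    cells = pd.DataFrame({"barcode": [f"bc{i}" for i in range(n_cells)]})
    return io.CellMatrix(values=sparse.csr_matrix(counts), features=features,
                         cells=cells, modality="ATAC")


def _peaks(n, gc=None, rng=None):
    gc = gc if gc is not None else (rng.random(n) if rng is not None
                                    else np.full(n, 0.5))
    return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 1000,
                         "end": np.arange(n) * 1000 + 400,
                         "peak_id": [f"p{i}" for i in range(n)], "gc": gc})


def _oracle_raw(counts, members):
    """Direct evaluation of the deviation expectation formula."""
    counts = np.asarray(counts, dtype=float)
    f = counts.sum(axis=1) / counts.sum()
    totals = counts.sum(axis=0)
    raw = np.empty((members.shape[0], counts.shape[1]))
    for m in range(members.shape[0]):
        idx = np.flatnonzero(members[m])
        observed = counts[idx].sum(axis=0)
        expected = f[idx].sum() * totals
        raw[m] = (observed - expected) / expected
    return raw


class TestDeviations:
    def test_two_by_two_worked_instance(self):
        # X = [[2,0],[0,2]], motif = {peak0}: f=0.5, T=(2,2), E=(1,1)
        counts = np.array([[2, 0], [0, 2]])
        hits = sparse.csr_matrix(np.array([[1, 0]]))
        dev = motif_dev.compute_deviations(_atac_matrix(counts), hits,
                                           _peaks(2), n_bg=5, seed=0)
        np.testing.assert_allclose(dev.raw[0], [1.0, -1.0], atol=1e-12)

    def test_all_peaks_motif_deviates_exactly_zero(self, rng):
        counts = rng.poisson(3.0, size=(8, 6)) + 1
        hits = sparse.csr_matrix(np.ones((1, 8)))
        dev = motif_dev.compute_deviations(_atac_matrix(counts), hits,
                                           _peaks(8, rng=rng), n_bg=5, seed=0)
        np.testing.assert_allclose(dev.raw[0], 0.0, atol=1e-10)

    def test_random_small_instances_match_oracle(self, rng):
        for _ in range(10):
            n_peaks = rng.integers(3, 11)
            n_cells = rng.integers(2, 6)
            counts = rng.poisson(2.0, size=(n_peaks, n_cells)) + 1
            members = (rng.random((3, n_peaks)) < 0.4).astype(int)
            members[members.sum(axis=1) == 0, 0] = 1
            dev = motif_dev.compute_deviations(
                _atac_matrix(counts), sparse.csr_matrix(members),
                _peaks(n_peaks, rng=rng), n_bg=3, seed=0)
            np.testing.assert_allclose(dev.raw, _oracle_raw(counts, members),
                                       atol=1e-12)

    def test_n_bg_below_two_rejected(self):
        counts = np.ones((3, 3))
        hits = sparse.csr_matrix(np.array([[1, 0, 0]]))
        with pytest.raises(ValueError):
            motif_dev.compute_deviations(_atac_matrix(counts), hits,
                                         _peaks(3), n_bg=1)

    def test_background_matching_beats_random_on_gc(self, paired_sim):
        _, _, atac, peaks, hits, _, _ = paired_sim
        counts = sparse.csr_matrix(atac.values, dtype=float)
        peak_totals = np.asarray(counts.sum(axis=1)).ravel()
        gc = peaks["gc"].to_numpy()
        space = np.column_stack([gc, np.log1p(peak_totals / counts.shape[1])])
        space = (space - space.mean(0)) / space.std(0)
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=251).fit(space)
        neighbors = nn.kneighbors(return_distance=False)
        rng = np.random.default_rng(0)
        sampled = neighbors[np.arange(len(gc)),
                            rng.integers(0, 250, size=len(gc))]
        random_pick = rng.permutation(len(gc))
        matched_err = np.abs(gc - gc[sampled]).mean()
        random_err = np.abs(gc - gc[random_pick]).mean()
        assert matched_err < random_err

    def test_null_motif_z_unit_scale_and_active_motif_separates(self,
                                                                paired_sim):
        config, _, atac, peaks, hits, motif_names, truth = paired_sim
        dev = motif_dev.compute_deviations(atac, hits, peaks, n_bg=50, seed=0)
        # null motifs: z sd across cells near 1
        for null_idx in (5, 10, 15):
            assert 0.7 <= np.nanstd(dev.z[null_idx]) <= 1.3
        # null motif group means near zero
        ac = truth.atac_cells
        day1 = (ac["timepoint"] == "day1").to_numpy()
        assert abs(np.nanmean(dev.z[5][day1])) < 0.15
        # planted Irf-like motif separates day1 from day0
        mask = ac["timepoint"].isin(["day0", "day1"]).to_numpy() & ~ac[
            "doublet"].to_numpy()
        y = (ac["timepoint"] == "day1").to_numpy()[mask]
        irf = motif_names.index("Irf2")
        assert roc_auc_score(y, dev.z[irf][mask]) > 0.9


class TestTssEnrichment:
    def test_boundary_arithmetic(self):
        # proximal density 16/bp, flanking 2/bp -> score 8
        score = motif_dev.tss_enrichment([1600], [400])
        assert score[0] == pytest.approx(8.0)

    def test_zero_proximal_is_zero(self):
        assert motif_dev.tss_enrichment([0], [400])[0] == 0.0

    def test_flanking_floor_prevents_blowup(self):
        assert motif_dev.tss_enrichment([100], [0])[0] == pytest.approx(10.0)

    def test_simulated_ratio_recovered_at_depth(self):
        config = simdata.default_config(
            seed=8, n_cell_types=2, cells_per_type_per_condition=40,
            n_genes=300, n_peaks=400, tss_ratio_mean=12.0,
            low_quality_fraction=0.0,
            atac_depth_lognormal_params=(np.log(8000.0), 0.2))
        _, truth = simdata.simulate_rna(config)
        _, _, _, truth = simdata.simulate_atac(config, truth)
        ac = truth.atac_cells
        deep = ac["n_fragments"].to_numpy() >= 5000
        score = motif_dev.tss_enrichment(ac["tss_proximal"].to_numpy(),
                                         ac["tss_flanking"].to_numpy())
        err = score[deep] - ac["true_tss_ratio"].to_numpy()[deep]
        assert np.abs(err).mean() < 1.5
        assert abs(score[deep].mean() - 12.0) < 1.5


class TestGeneScores:
    def _genes(self):
        return pd.DataFrame({
            "gene": ["gA", "gB"], "chrom": ["chr1", "chr1"],
            "strand": ["+", "+"], "tss": [1000, 1000],
            "start": [1000, 1000], "end": [2000, 2000],
        })

    def test_promoter_peak_weight_one(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [900],
                              "end": [1100], "peak_id": ["p0"], "gc": [0.5]})
        atac = _atac_matrix([[5]])
        gs = motif_dev.gene_scores(atac, peaks, self._genes().iloc[:1],
                                   normalize=False)
        assert gs.scores[0, 0] == pytest.approx(5.0)

    def test_distance_decay_weight(self):
        # peak 5000 bp beyond the promoter margin: weight e^-1
        genes = self._genes().iloc[:1]
        start = 2000 + 200 + 5000  # gene end + margin + decay distance
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [start],
                              "end": [start + 100], "peak_id": ["p0"],
                              "gc": [0.5]})
        gs = motif_dev.gene_scores(_atac_matrix([[10]]), peaks, genes,
                                   normalize=False)
        assert gs.scores[0, 0] == pytest.approx(10 * np.exp(-1.0), rel=1e-12)

    def test_shared_peak_counts_for_both_genes(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [900],
                              "end": [1100], "peak_id": ["p0"], "gc": [0.5]})
        gs = motif_dev.gene_scores(_atac_matrix([[4]]), peaks, self._genes(),
                                   normalize=False)
        assert gs.scores[0, 0] == gs.scores[1, 0] == pytest.approx(4.0)

    def test_gene_without_peaks_flagged(self):
        genes = self._genes().iloc[:1].assign(chrom="chr9")
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [900],
                              "end": [1100], "peak_id": ["p0"], "gc": [0.5]})
        gs = motif_dev.gene_scores(_atac_matrix([[4]]), peaks, genes)
        assert gs.no_peak_genes == ["gA"]
        assert (gs.scores[0] == 0).all()


class TestTfGeneCorrelation:
    def _dev(self, z, names):
        return motif_dev.DeviationMatrix(
            raw=z, corrected=z, z=z, motif_names=names,
            cell_barcodes=[f"bc{i}" for i in range(z.shape[1])],
            n_background=0, seed=0, flagged=np.zeros(len(names), dtype=bool))

    def test_affine_transform_gives_r_one(self, rng):
        z = rng.normal(size=(3, 40))
        gs = motif_dev.GeneScoreMatrix(
            scores=(2.0 * z[1] + 1.0)[None, :], gene_names=["gX"],
            cell_barcodes=[f"bc{i}" for i in range(40)],
            no_peak_genes=[], window=0, decay=0.0)
        ranking = motif_dev.tf_gene_correlation(
            self._dev(z, ["m0", "m1", "m2"]), gs, "gX")
        assert ranking["motif"].iloc[0] == "m1"
        assert ranking["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_motif_low_correlation(self, rng):
        z = rng.normal(size=(1, 500))
        gs = motif_dev.GeneScoreMatrix(
            scores=rng.normal(size=(1, 500)), gene_names=["gX"],
            cell_barcodes=[f"bc{i}" for i in range(500)],
            no_peak_genes=[], window=0, decay=0.0)
        ranking = motif_dev.tf_gene_correlation(self._dev(z, ["m0"]), gs, "gX")
        assert abs(ranking["r"].iloc[0]) < 0.15

    def test_zero_variance_gene_rejected(self, rng):
        z = rng.normal(size=(1, 30))
        gs = motif_dev.GeneScoreMatrix(
            scores=np.ones((1, 30)), gene_names=["gX"],
            cell_barcodes=[f"bc{i}" for i in range(30)],
            no_peak_genes=[], window=0, decay=0.0)
        with pytest.raises(ValueError, match="zero-variance"):
            motif_dev.tf_gene_correlation(self._dev(z, ["m0"]), gs, "gX")

    def test_too_few_cells_rejected(self, rng):
        z = rng.normal(size=(1, 10))
        gs = motif_dev.GeneScoreMatrix(
            scores=rng.normal(size=(1, 10)), gene_names=["gX"],
            cell_barcodes=[f"bc{i}" for i in range(10)],
            no_peak_genes=[], window=0, decay=0.0)
        with pytest.raises(ValueError, match="cells"):
            motif_dev.tf_gene_correlation(self._dev(z, ["m0"]), gs, "gX")

    def test_planted_irf_motif_ranks_first_for_mirrored_gene(self, paired_sim):
        config, _, atac, peaks, hits, motif_names, truth = paired_sim
        dev = motif_dev.compute_deviations(atac, hits, peaks, n_bg=50, seed=0)
        dev.motif_names = motif_names
        gs = motif_dev.gene_scores(atac, peaks, truth.gene_annotation)
        ranking = motif_dev.tf_gene_correlation(dev, gs,
                                                truth.mirrored_genes[0])
        assert ranking["motif"].iloc[0] == "Irf2"


class TestKnnSmooth:
    def test_constant_matrix_unchanged(self, rng):
        values = np.full((3, 50), 2.5)
        emb = rng.normal(size=(50, 5))
        np.testing.assert_allclose(motif_dev.knn_smooth(values, emb), 2.5)

    def test_noise_variance_reduced_signal_kept(self, rng):
        # two cell groups with distinct means: smoothing within groups keeps
        # the group difference but shrinks within-group noise
        group = np.repeat([0, 1], 100)
        emb = np.column_stack([group * 10 + rng.normal(0, 0.5, 200),
                               rng.normal(0, 0.5, 200)])
        values = (group * 3.0 + rng.normal(0, 1.0, 200))[None, :]
        smooth = motif_dev.knn_smooth(values, emb, k=20)
        assert smooth[0][group == 1].mean() - smooth[0][
            group == 0].mean() == pytest.approx(3.0, abs=0.3)
        assert smooth[0][group == 0].std() < values[0][group == 0].std() / 2
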