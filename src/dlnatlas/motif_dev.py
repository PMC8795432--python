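"""Per-cell TF motif deviations with GC-matched backgrounds; gene scores; TSS QC.

The deviation statistic follows the chromVAR idea: for motif m and cell c
the expected count is ``E_mc = (sum of member-peak count shares) * T_c``
where a peak's share ``f_i`` is its fraction of total counts over all cells
and ``T_c`` is the cell total; the raw deviation is ``(O_mc - E_mc)/E_mc``.
Bias correction resamples each member peak from its k nearest neighbors in
the standardized (GC, log1p mean accessibility) plane, ``n_bg`` times:
``corrected = raw - mean_bg(raw_bg)`` and ``z = corrected / sd_bg(raw_bg)``.

Gene activity scores are a simplified distance-decay model: peaks within
100 kb of a gene contribute their counts weighted 1 for body/promoter
overlap and ``exp(-distance/5000)`` otherwise, then per-cell depth
normalization to 10,000 and log1p.

TSS enrichment is the ratio of TSS-proximal to flanking fragment densities
(counts per bp of a 100 bp proximal window vs the outer 2x100 bp of a
+/-2 kb window), with the flanking density floored at 0.1 to avoid division
blowup in empty cells.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors


@dataclasses.dataclass
class DeviationMatrix:
    """Motif x cell deviations: raw, bias-corrected, and z-scores."""

    raw: np.ndarray
    corrected: np.ndarray
    z: np.ndarray
    motif_names: list[str]
    cell_barcodes: list[str]
    n_background: int
    seed: int
    flagged: np.ndarray  # motifs with undefined deviations (E == 0 everywhere)

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.motif_names,
                            columns=self.cell_barcodes)


def _raw_deviations(counts: sparse.csr_matrix, members: sparse.csr_matrix,
                    f: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """(O - E) / E for every motif x cell, given per-peak shares ``f``."""
    observed = np.asarray((members @ counts).todense(), dtype=float)
    expected = np.outer(np.asarray(members @ f).ravel(), totals)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(expected > 0, (observed - expected) / expected, np.nan)
    return raw


def compute_deviations(atac, hits: sparse.spmatrix, peaks: pd.DataFrame,
                       n_bg: int = 50, k_neighbors: int = 250,
                       seed: int = 0, binarize: bool = False
                       ) -> DeviationMatrix:
    """Bias-corrected motif deviation z-scores (deterministic given seed).

    Parameters
    ----------
    atac
        ATAC :class:`~dlnatlas.io.CellMatrix` (peaks x cells counts).
    hits
        Binary motif x peak incidence.
    peaks
        Peak table aligned with the matrix rows; must carry ``gc``.
    n_bg
        Number of background peak sets (>= 2).
    k_neighbors
        Neighborhood size for GC/accessibility-matched background sampling.
    """
    if n_bg < 2:
        raise ValueError("n_bg must be at least 2")
    counts = sparse.csr_matrix(atac.values, dtype=float)
    if binarize:
        counts = (counts > 0).astype(float)
    members = sparse.csr_matrix(hits, dtype=float)
    if members.shape[1] != counts.shape[0]:
        raise ValueError("motif-hit matrix does not match peak count matrix")

    peak_totals = np.asarray(counts.sum(axis=1)).ravel()
    grand = peak_totals.sum()
    f = peak_totals / grand
    totals = np.asarray(counts.sum(axis=0)).ravel()

    raw = _raw_deviations(counts, members, f, totals)
    flagged = np.asarray(members @ f).ravel() == 0

    # background peaks: k nearest neighbors in standardized (GC, log1p mean)
    gc = peaks["gc"].to_numpy()
    mean_acc = np.log1p(peak_totals / counts.shape[1])
    space = np.column_stack([gc, mean_acc])
    sd = space.std(axis=0)
    sd[sd == 0] = 1.0
    space = (space - space.mean(axis=0)) / sd
    n_peaks = space.shape[0]
    k = min(k_neighbors, n_peaks - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(space)
    neighbors = nn.kneighbors(return_distance=False)  # excludes self

    rng = np.random.default_rng(seed)
    bg_sum = np.zeros_like(raw)
    bg_sumsq = np.zeros_like(raw)
    for _ in range(n_bg):
        pick = neighbors[np.arange(n_peaks), rng.integers(0, k, size=n_peaks)]
        bg_counts = counts[pick, :]
        bg_f = f[pick]
        observed = np.asarray((members @ bg_counts).todense(), dtype=float)
        expected = np.outer(np.asarray(members @ bg_f).ravel(), totals)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw_b = np.where(expected > 0, (observed - expected) / expected,
                             np.nan)
        bg_sum += raw_b
        bg_sumsq += raw_b ** 2
    mean_bg = bg_sum / n_bg
    var_bg = np.maximum(bg_sumsq / n_bg - mean_bg ** 2, 0.0) * n_bg / (n_bg - 1)
    sd_bg = np.sqrt(var_bg)
    corrected = raw - mean_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_bg > 0, corrected / sd_bg, np.nan)
    z[flagged, :] = np.nan
    return DeviationMatrix(
        raw=raw, corrected=corrected, z=z,
        motif_names=list(getattr(hits, "motif_names", [])) or [
            f"motif{i}" for i in range(members.shape[0])],
        cell_barcodes=atac.cells["barcode"].tolist(),
        n_background=n_bg, seed=seed, flagged=flagged,
    )


def tss_enrichment(proximal: np.ndarray, flanking: np.ndarray,
                   proximal_bp: float = 100.0, flanking_bp: float = 200.0,
                   floor: float = 0.1) -> np.ndarray:
    """Per-cell TSS enrichment: proximal density over floored flanking density."""
    proximal = np.asarray(proximal, dtype=float)
    flanking = np.asarray(flanking, dtype=float)
    prox_density = proximal / proximal_bp
    flank_density = np.maximum(flanking / flanking_bp, floor)
    return prox_density / flank_density


@dataclasses.dataclass
class GeneScoreMatrix:
    scores: np.ndarray  # genes x cells
    gene_names: list[str]
    cell_barcodes: list[str]
    no_peak_genes: list[str]
    window: int
    decay: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gene_names,
                            columns=self.cell_barcodes)


def gene_scores(atac, peaks: pd.DataFrame, genes: pd.DataFrame,
                window: int = 100_000, decay: float = 5_000.0,
                normalize: bool = True, scale: float = 10_000.0
                ) -> GeneScoreMatrix:
    """Distance-decay gene activity scores from peak counts.

    A peak overlapping the gene body or promoter gets weight 1; otherwise
    ``exp(-distance/decay)`` with distance to the nearest gene-body edge,
    zero beyond ``window``.  A peak within range of several genes counts for
    each of them (no exclusivity).
    """
    counts = sparse.csr_matrix(atac.values, dtype=float)
    rows, cols, weights = [], [], []
    no_peak = []
    peak_by_chrom: dict[str, pd.DataFrame] = {
        str(c): grp for c, grp in peaks.reset_index().groupby("chrom")
    }
    for gi, grow in genes.reset_index(drop=True).iterrows():
        chrom_peaks = peak_by_chrom.get(str(grow.chrom))
        if chrom_peaks is None:
            no_peak.append(grow.gene)
            continue
        body_lo = min(grow.start, grow.tss) - 200  # promoter margin
        body_hi = max(grow.end, grow.tss) + 200
        starts = chrom_peaks["start"].to_numpy()
        ends = chrom_peaks["end"].to_numpy()
        dist = np.maximum.reduce([
            body_lo - ends, starts - body_hi, np.zeros(len(chrom_peaks))
        ])
        in_range = dist <= window
        if not in_range.any():
            no_peak.append(grow.gene)
            continue
        w = np.where(dist == 0, 1.0, np.exp(-dist / decay))
        sel = np.flatnonzero(in_range)
        rows.extend([gi] * len(sel))
        cols.extend(chrom_peaks["index"].to_numpy()[sel].tolist())
        weights.extend(w[sel].tolist())
    wmat = sparse.csr_matrix(
        (weights, (rows, cols)), shape=(len(genes), counts.shape[0])
    )
    scores = np.asarray((wmat @ counts).todense())
    if normalize:
        totals = scores.sum(axis=0)
        totals[totals == 0] = 1.0
        scores = np.log1p(scale * scores / totals[None, :])
    return GeneScoreMatrix(
        scores=scores, gene_names=genes["gene"].tolist(),
        cell_barcodes=atac.cells["barcode"].tolist(),
        no_peak_genes=no_peak, window=window, decay=decay,
    )


def tf_gene_correlation(dev: DeviationMatrix, gs: GeneScoreMatrix, gene: str,
                        cell_subset: np.ndarray | None = None,
                        min_cells: int = 20) -> pd.DataFrame:
    """Rank motifs by Pearson correlation of motif z with one gene's score.

    Ties break lexicographically on motif name; undefined correlations
    (zero-variance gene score, flagged motifs) are reported as NaN rows at
    the bottom.
    """
    gene_idx = gs.gene_names.index(gene)
    y = gs.scores[gene_idx]
    z = dev.z
    if cell_subset is not None:
        mask = np.asarray(cell_subset)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        y = y[mask]
        z = z[:, mask]
    if y.size < min_cells:
        raise ValueError(f"need >= {min_cells} cells, got {y.size}")
    if y.std() == 0:
        raise ValueError(f"gene {gene!r} has zero-variance accessibility score")
    yc = y - y.mean()
    ysd = y.std()
    zc = z - np.nanmean(z, axis=1, keepdims=True)
    zsd = np.nanstd(z, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.nanmean(zc * yc[None, :], axis=1) / (zsd * ysd)
    frame = pd.DataFrame({"motif": dev.motif_names, "r": r})
    frame["rank_key"] = -frame["r"]
    frame = frame.sort_values(["rank_key", "motif"], kind="stable",
                              na_position="last")
    return frame.drop(columns="rank_key").reset_index(drop=True)


def knn_smooth(values: np.ndarray, embedding: np.ndarray,
               k: int = 20) -> np.ndarray:
    """Average feature-by-cell values over each cell's k nearest neighbors.

    Per-cell accessibility summaries are sparse and noisy; correlation
    analyses (TF-gene ranking, network edges) conventionally run on
    neighbor-smoothed values.  ``embedding`` is cells x dims (e.g. PCs);
    the neighborhood includes the cell itself.
    """
    n = embedding.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    neighbors = nn.kneighbors(return_distance=False)
    neighbors = np.hstack([np.arange(n)[:, None], neighbors])
    return values[:, neighbors].mean(axis=2)
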