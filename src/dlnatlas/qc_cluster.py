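"""QC filtering, normalization, HVG selection, graph clustering, doublets.

The RNA QC applies two sequential mitochondrial-fraction cutoffs (25% on the
raw matrix, then 20%), both configurable, both strict "greater than" removal.
ATAC QC removes cells with fewer than ``atac_min_fragments`` unique fragments
or TSS enrichment strictly below ``atac_min_tss_enrichment``.

Clustering follows the Seurat-style recipe: log-normalization, top-N
variable features, z-scoring, PCA, kNN graph in PC space, SNN edge weights
by Jaccard overlap of neighborhoods pruned below ``snn_prune``, then seeded
resolution-parameterized modularity community detection.

The doublet score is a cxds-like binarized co-expression statistic: gene
pairs that are co-detected less often than their detection rates predict
("mutually exclusive" marker-like pairs) up-weight cells in which both genes
are nevertheless detected.  The contract is the percentile-removal behavior,
not parity with any particular published score.
"""

from __future__ import annotations

import dataclasses

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CellMatrix, FormatError


@dataclasses.dataclass
class QCParams:
    rna_mito_max_fraction: float = 0.20
    rna_mito_raw_max_fraction: float = 0.25
    atac_min_fragments: int = 1000
    atac_min_tss_enrichment: float = 8.0
    doublet_removal_percentile_rna: float = 95.0
    doublet_removal_percentile_atac: float = 90.0

    def __post_init__(self) -> None:
        for frac in (self.rna_mito_max_fraction, self.rna_mito_raw_max_fraction):
            if not 0 < frac <= 1:
                raise ValueError("mito fractions must be in (0, 1]")
        for pct in (self.doublet_removal_percentile_rna,
                    self.doublet_removal_percentile_atac):
            if not 0 < pct < 100:
                raise ValueError("percentiles must be in (0, 100)")


@dataclasses.dataclass
class ClusterParams:
    n_hvg: int = 2000
    n_pcs: int = 25
    knn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 0.4
    seed: int = 0


def mito_fraction(m: CellMatrix) -> np.ndarray:
    """Per-cell fraction of counts in ``mt-``-prefixed genes."""
    is_mito = m.features["name"].str.startswith("mt-").to_numpy()
    if not is_mito.any():
        raise FormatError("no mt- prefixed genes; mitochondrial fraction undefined")
    total = np.asarray(m.values.sum(axis=0)).ravel()
    mito = np.asarray(m.values[is_mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return frac


def qc_filter(m: CellMatrix, p: QCParams | None = None,
              tss_scores: np.ndarray | None = None
              ) -> tuple[CellMatrix, dict[str, int]]:
    """Keep cells passing all thresholds for their modality.

    Returns the filtered matrix and a report of cells removed per criterion
    (a cell failing several criteria is counted under each).
    """
    p = p or QCParams()
    n = m.n_cells
    report: dict[str, int] = {"n_input": n}
    if m.modality == "RNA":
        frac = mito_fraction(m)
        fail_raw = frac > p.rna_mito_raw_max_fraction
        fail = frac > p.rna_mito_max_fraction
        report["mito_raw_removed"] = int(fail_raw.sum())
        report["mito_removed"] = int((fail & ~fail_raw).sum())
        keep = ~fail & ~fail_raw
    elif m.modality == "ATAC":
        frags = m.cells["n_fragments"].to_numpy()
        if tss_scores is None:
            if "tss_enrichment" in m.cells.columns:
                tss_scores = m.cells["tss_enrichment"].to_numpy()
            else:
                from .motif_dev import tss_enrichment
                tss_scores = tss_enrichment(
                    m.cells["tss_proximal"].to_numpy(),
                    m.cells["tss_flanking"].to_numpy(),
                )
        fail_frag = frags < p.atac_min_fragments
        fail_tss = np.asarray(tss_scores) < p.atac_min_tss_enrichment
        report["low_fragment_removed"] = int(fail_frag.sum())
        report["low_tss_removed"] = int(fail_tss.sum())
        keep = ~fail_frag & ~fail_tss
    else:
        raise ValueError(f"unknown modality {m.modality!r}")
    report["n_kept"] = int(keep.sum())
    return m.subset_cells(keep), report


def lognormalize(m: CellMatrix, scale: float = 10_000.0) -> np.ndarray:
    """``ln(1 + scale * count / column_total)`` per entry (dense genes x cells)."""
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = m.cells["barcode"][totals == 0].tolist()
        raise FormatError(f"zero-depth cells: {bad[:10]}")
    dense = np.asarray(m.values.todense(), dtype=float)
    return np.log1p(scale * dense / totals[None, :])


def select_hvg(norm: np.ndarray, feature_ids: pd.Series | list[str],
               n: int = 2000) -> list[str]:
    """Top-``n`` variable features by variance of the log-normalized values.

    The log1p transform already stabilizes the count-depth mean-variance
    relation, so the variance of the normalized values is used directly as
    the dispersion statistic.  Ties break lexicographically on feature id,
    so the ranking is fully deterministic.
    """
    feature_ids = list(feature_ids)
    if n > norm.shape[0]:
        raise ValueError(f"requested {n} HVGs but only {norm.shape[0]} features")
    disp = norm.var(axis=1)
    frame = pd.DataFrame({"id": feature_ids, "disp": disp})
    frame = frame.sort_values(["disp", "id"], ascending=[False, True],
                              kind="stable")
    return frame["id"].head(n).tolist()


def snn_graph(pcs: np.ndarray, k: int = 20, prune: float = 1.0 / 15.0
              ) -> sparse.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN neighborhoods
    (self included, Seurat-style), edges below ``prune`` dropped."""
    n = pcs.shape[0]
    if n <= k:
        raise ValueError(f"need more than knn_k={k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    knn = nn.kneighbors(return_distance=False)
    knn = np.hstack([np.arange(n)[:, None], knn])  # include self
    rows = np.repeat(np.arange(n), knn.shape[1])
    adj = sparse.csr_matrix(
        (np.ones(rows.size), (rows, knn.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # |N(i) & N(j)|
    shared = shared.tocoo()
    ksize = knn.shape[1]
    jac = shared.data / (2 * ksize - shared.data)
    keep = jac >= prune
    snn = sparse.csr_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    snn.setdiag(0)
    snn.eliminate_zeros()
    return snn


def embed_cluster(norm: np.ndarray, p: ClusterParams | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """PCA -> SNN graph -> seeded modularity communities.

    ``norm`` is the HVG-subset log-normalized matrix (features x cells).
    Returns (labels, PC coordinates).
    """
    p = p or ClusterParams()
    x = norm.T  # cells x features
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    n_pcs = min(p.n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=p.seed)
    pcs = pca.fit_transform(x)
    snn = snn_graph(pcs, k=p.knn_k, prune=p.snn_prune)
    coo = snn.tocoo()
    mask = coo.row < coo.col
    g = ig.Graph(
        n=snn.shape[0],
        edges=list(zip(coo.row[mask].tolist(), coo.col[mask].tolist())),
        edge_attrs={"weight": coo.data[mask].tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=p.resolution,
        seed=p.seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership), pcs


def doublet_scores(m: CellMatrix, n_top: int = 500) -> np.ndarray:
    """cxds-like co-expression doublet score per cell.

    Counts are binarized at > 0; the ``n_top`` most informative genes (by
    binarized variance) are kept; for each gene pair the weight is the
    relative shortfall of observed co-detection versus the independence
    expectation, and a cell's score sums the weights of pairs it co-detects.
    """
    binary = (m.values > 0).astype(np.float64)
    det = np.asarray(binary.mean(axis=1)).ravel()
    # restrict to population-restricted genes (markers, not housekeeping):
    # broadly detected genes carry no co-expression signal for doublets
    informative = np.where((det > 0.02) & (det < 0.4), det * (1 - det), 0.0)
    top = np.argsort(-informative, kind="stable")[: min(n_top, m.n_features)]
    b = np.asarray(binary[top, :].todense())
    n = b.shape[1]
    pvec = b.mean(axis=1)
    obs = b @ b.T
    exp = np.outer(pvec, pvec) * n
    # deficit z-score: only pairs co-detected well below chance carry weight,
    # so background (independent) pairs contribute ~nothing
    deficit = (exp - obs) / np.sqrt(exp + 1.0)
    w = np.clip(deficit - 2.0, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return 0.5 * np.einsum("gc,gh,hc->c", b, w, b)


def doublet_score_and_filter(m: CellMatrix, percentile: float,
                             n_top: int = 500
                             ) -> tuple[CellMatrix, pd.DataFrame]:
    """Remove cells whose doublet score is at or above the given percentile.

    All cells tied at the threshold are removed.  Returns the filtered
    matrix and a table of removed barcodes with their scores.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    scores = doublet_scores(m, n_top=n_top)
    threshold = np.percentile(scores, percentile)
    remove = scores >= threshold
    removed = pd.DataFrame(
        {"barcode": m.cells["barcode"][remove].to_numpy(),
         "score": scores[remove]}
    )
    return m.subset_cells(~remove), removed
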