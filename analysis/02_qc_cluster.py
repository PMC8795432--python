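#!/usr/bin/env python
"""QC, doublet removal and graph clustering of the simulated RNA data.

Reproduces the clustering stage of the study: mitochondrial QC, cxds-like
doublet-score filtering at the 95th percentile, log-normalization, HVG
selection, PCA/SNN/modularity clustering at resolution 0.4, plus monocyte
sub-clustering at day 0 + day 28.  Reports recovery against the simulation
truth (ARI) under ``results/``.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from dlnatlas import io, qc_cluster

BUNDLE = Path("scratch/simdata")
RESULTS = Path("results")
SEED = 1


def cluster(cm, n_hvg):
    norm = qc_cluster.lognormalize(cm)
    hvgs = qc_cluster.select_hvg(norm, cm.features["id"], n=n_hvg)
    idx = cm.features.set_index("id").index.get_indexer(hvgs)
    labels, _ = qc_cluster.embed_cluster(
        norm[idx], qc_cluster.ClusterParams(n_hvg=n_hvg, seed=SEED))
    return labels


def main() -> None:
    rna = io.read_mtx_bundle(BUNDLE / "rna")
    truth = pd.read_csv(BUNDLE / "cells.tsv", sep="\t")

    cm, qc_report = qc_cluster.qc_filter(rna)
    cm, removed = qc_cluster.doublet_score_and_filter(cm, 95.0)
    print(f"QC: {qc_report}; doublet filter removed {len(removed)} cells")

    labels = cluster(cm, n_hvg=500)
    tt = truth.set_index("barcode").loc[cm.cells["barcode"]]
    singlet = ~tt["doublet"].to_numpy()
    ari = adjusted_rand_score(tt["cell_type"].to_numpy()[singlet],
                              labels[singlet])
    print(f"{labels.max() + 1} clusters over {cm.n_cells} cells; "
          f"cell-type ARI (singlets) = {ari:.3f}")

    mono = ((tt["cell_type"] == "monocyte")
            & tt["timepoint"].isin(["day0", "day28"])).to_numpy()
    labels_m = cluster(cm.subset_cells(mono), n_hvg=300)
    ttm = tt[mono]
    singlet_m = ~ttm["doublet"].to_numpy()
    ari_m = adjusted_rand_score(ttm["subcluster"].to_numpy()[singlet_m],
                                labels_m[singlet_m])
    print(f"monocyte day0+day28 sub-clustering: {labels_m.max() + 1} "
          f"subclusters, Ly6C subcluster ARI = {ari_m:.3f}")

    RESULTS.mkdir(exist_ok=True)
    io.write_table(RESULTS / "02_cluster_labels.tsv",
                   pd.DataFrame({"barcode": cm.cells["barcode"],
                                 "cluster": labels}))
    io.write_table(RESULTS / "02_cluster_metrics.tsv", pd.DataFrame({
        "metric": ["n_clusters", "cell_type_ari", "n_subclusters",
                   "ly6c_subcluster_ari", "doublets_removed"],
        "value": [labels.max() + 1, round(ari, 4), labels_m.max() + 1,
                  round(ari_m, 4), len(removed)],
    }))


if __name__ == "__main__":
    main()
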