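"""TF-gene accessibility correlation networks.

Nodes are differentially accessible genes and TF motifs from one cell
population (|logFC| > 0.2 and FDR < 0.005, strict inequalities).  Edges are
signed Pearson correlations across single cells: gene-gene pairs connect
above r = 0.9, gene-TF pairs above r = 0.8, TF-TF pairs are not created.
Communities come from greedy modularity maximization; communities smaller
than 4 nodes are pruned.  Hub TFs are TF nodes whose gene-degree reaches the
95th percentile of TF gene-degrees.  The Fruchterman-Reingold layout is
seeded and purely cosmetic.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd


@dataclasses.dataclass
class TFGeneNetwork:
    graph: nx.Graph  # node attrs: kind, logfc; edge attr: r
    communities: dict[str, int]
    hubs: set[str]
    layout: dict[str, tuple[float, float]]
    excluded_zero_variance: list[str]
    status: str = "ok"

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in self.graph.nodes(data=True):
            rows.append((node, data["kind"], data["logfc"],
                         self.graph.degree(node),
                         self.communities.get(node, -1),
                         node in self.hubs))
        return pd.DataFrame(rows, columns=["id", "kind", "logfc", "degree",
                                           "community", "hub"])

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["u", "v", "r"])


def select_network_features(dags: pd.DataFrame, dars: pd.DataFrame,
                            min_abs_logfc: float = 0.2,
                            max_fdr: float = 0.005) -> pd.DataFrame:
    """Nodes: genes and TF motifs with |logFC| > threshold and FDR < threshold.

    ``dags`` and ``dars`` are differential tables with columns
    ``feature, logfc, fdr``; returns a table with a ``kind`` column.
    """
    frames = []
    for table, kind in ((dags, "gene"), (dars, "TF")):
        if table is None or len(table) == 0:
            continue
        passing = table[(table["logfc"].abs() > min_abs_logfc)
                        & (table["fdr"] < max_fdr)]
        frames.append(pd.DataFrame({
            "feature": passing["feature"], "logfc": passing["logfc"],
            "kind": kind,
        }))
    if not frames:
        return pd.DataFrame(columns=["feature", "logfc", "kind"])
    return pd.concat(frames, ignore_index=True)


def build_network(feature_values: pd.DataFrame, nodes: pd.DataFrame,
                  r_gene_gene: float = 0.9, r_gene_tf: float = 0.8,
                  min_cells: int = 20) -> TFGeneNetwork:
    """Threshold the cross-cell Pearson correlations into a network.

    ``feature_values`` holds one row per node feature (index = feature id)
    and one column per cell: gene accessibility scores for gene nodes, motif
    z-scores for TF nodes.  Edges require signed r strictly above the
    kind-specific threshold (positive correlations only).
    """
    if feature_values.shape[1] < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells, got {feature_values.shape[1]}")
    nodes = nodes.drop_duplicates("feature").set_index("feature")
    present = [f for f in nodes.index if f in feature_values.index]
    values = feature_values.loc[present].to_numpy(dtype=float)
    sd = values.std(axis=1)
    excluded = [f for f, s in zip(present, sd) if s == 0]
    keep = [i for i, s in enumerate(sd) if s > 0]
    present = [present[i] for i in keep]
    values = values[keep]

    graph = nx.Graph()
    for f in present:
        graph.add_node(f, kind=nodes.loc[f, "kind"],
                       logfc=float(nodes.loc[f, "logfc"]))
    if len(present) >= 2:
        corr = np.corrcoef(values)
        kinds = [nodes.loc[f, "kind"] for f in present]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                pair = {kinds[i], kinds[j]}
                if pair == {"gene"}:
                    threshold = r_gene_gene
                elif pair == {"gene", "TF"}:
                    threshold = r_gene_tf
                else:
                    continue  # no TF-TF edges
                if corr[i, j] > threshold:
                    graph.add_edge(present[i], present[j],
                                   r=float(corr[i, j]))
    return TFGeneNetwork(graph=graph, communities={}, hubs=set(), layout={},
                         excluded_zero_variance=excluded)


def communities_and_hubs(net: TFGeneNetwork, min_community_size: int = 4,
                         hub_percentile: float = 95.0,
                         seed: int = 0) -> TFGeneNetwork:
    """Greedy modularity communities, <4-node pruning, hub TFs, FR layout."""
    graph = net.graph
    if graph.number_of_edges() == 0:
        return dataclasses.replace(net, status="edgeless network")
    comms = nx.algorithms.community.greedy_modularity_communities(graph)
    labels: dict[str, int] = {}
    kept_nodes: set[str] = set()
    label = 0
    for comm in sorted(comms, key=lambda c: (-len(c), sorted(c))):
        if len(comm) < min_community_size:
            continue
        for node in comm:
            labels[node] = label
        kept_nodes |= set(comm)
        label += 1
    pruned = graph.subgraph(kept_nodes).copy()
    tf_nodes = [n for n, d in pruned.nodes(data=True) if d["kind"] == "TF"]
    gene_degree = {
        n: sum(1 for nb in pruned.neighbors(n)
               if pruned.nodes[nb]["kind"] == "gene")
        for n in tf_nodes
    }
    hubs: set[str] = set()
    if gene_degree:
        cut = np.percentile(list(gene_degree.values()), hub_percentile)
        hubs = {n for n, d in gene_degree.items() if d >= cut and d > 0}
    layout = nx.spring_layout(pruned, seed=seed)
    layout = {n: (float(x), float(y)) for n, (x, y) in layout.items()}
    status = "ok" if kept_nodes else "all communities pruned"
    return TFGeneNetwork(graph=pruned, communities=labels, hubs=hubs,
                         layout=layout,
                         excluded_zero_variance=net.excluded_zero_variance,
                         status=status)
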