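"""Cross-species effect-size meta-analysis.

Per study and gene, the pre- vs post-vaccination change is summarized as
Hedges' g (small-sample-corrected standardized mean difference) with its
sampling variance; per-gene summary effect sizes across studies come from
DerSimonian-Laird random-effects inverse-variance meta-analysis.  Summary
effects are then compared to mouse per-cell-type log fold changes through a
homolog map.

Input expression matrices are assumed log2-transformed; paired subjects are
treated as independent groups (two-sample g, MetaIntegrator-style).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def hedges_g(pre: Sequence[float], post: Sequence[float]
             ) -> tuple[float, float]:
    """Bias-corrected standardized mean difference (post minus pre).

    ``d = (mean_post - mean_pre) / s_pooled``;
    ``J = 1 - 3 / (4(n1+n2) - 9)``; ``g = J d``;
    ``var_g = (n1+n2)/(n1 n2) + g^2 / (2(n1+n2))``.
    Raises on groups smaller than 2 or zero pooled variance.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n1, n2 = pre.size, post.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    s2 = ((n1 - 1) * pre.var(ddof=1) + (n2 - 1) * post.var(ddof=1)) / (
        n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("zero pooled standard deviation")
    d = (post.mean() - pre.mean()) / np.sqrt(s2)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = j * d
    var_g = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    return float(g), float(var_g)


@dataclasses.dataclass
class MetaEntry:
    es: float
    se: float
    tau2: float
    q: float
    k: int
    ci_low: float
    ci_high: float
    single_study: bool = False


def dersimonian_laird(effects: Sequence[tuple[float, float]]) -> MetaEntry:
    """DL random-effects summary of ``(g, var_g)`` pairs.

    Moment estimator: ``tau2 = max(0, (Q - (k-1)) / (S1 - S2/S1))`` with
    fixed-effect weights ``w = 1/var``, ``S1 = sum w``, ``S2 = sum w^2``;
    random-effect weights ``1/(var + tau2)``.
    """
    effects = list(effects)
    k = len(effects)
    if k == 0:
        raise ValueError("no studies")
    g = np.array([e[0] for e in effects], dtype=float)
    v = np.array([e[1] for e in effects], dtype=float)
    if (v <= 0).any():
        raise ValueError("variances must be positive")
    if k == 1:
        se = float(np.sqrt(v[0]))
        return MetaEntry(float(g[0]), se, 0.0, 0.0, 1,
                         float(g[0] - 1.96 * se), float(g[0] + 1.96 * se),
                         single_study=True)
    w = 1.0 / v
    g_fe = float((w * g).sum() / w.sum())
    q = float((w * (g - g_fe) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    es = float((w_star * g).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    return MetaEntry(es, se, float(tau2), q, k, es - 1.96 * se, es + 1.96 * se)


def study_effects(expression: pd.DataFrame, design: pd.DataFrame,
                  study_id: str) -> pd.DataFrame:
    """Per-gene Hedges' g for one study.

    ``expression``: genes x samples (log2 scale); ``design``: columns
    ``sample`` and ``phase`` in {pre, post}.  Genes with degenerate pooled
    variance are flagged and excluded from downstream meta-analysis.
    """
    pre_samples = design.loc[design["phase"] == "pre", "sample"]
    post_samples = design.loc[design["phase"] == "post", "sample"]
    pre = expression[pre_samples].to_numpy(dtype=float)
    post = expression[post_samples].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(expression.index):
        try:
            g, var_g = hedges_g(pre[i], post[i])
            rows.append((gene, study_id, g, var_g, pre.shape[1],
                         post.shape[1], False))
        except ValueError:
            rows.append((gene, study_id, np.nan, np.nan, pre.shape[1],
                         post.shape[1], True))
    return pd.DataFrame(rows, columns=["gene", "study", "g", "var_g",
                                       "n_pre", "n_post", "degenerate"])


def meta_analyze(per_study: pd.DataFrame) -> pd.DataFrame:
    """DL summary per gene over a concatenated :func:`study_effects` table."""
    rows = []
    for gene, grp in per_study[~per_study["degenerate"]].groupby("gene"):
        entry = dersimonian_laird(list(zip(grp["g"], grp["var_g"])))
        rows.append((gene, entry.es, entry.se, entry.tau2, entry.q, entry.k,
                     entry.ci_low, entry.ci_high))
    return pd.DataFrame(rows, columns=["gene", "es", "se", "tau2", "q", "k",
                                       "ci_low", "ci_high"])


@dataclasses.dataclass
class CrossSpeciesResult:
    r: float | None
    p: float | None
    n: int
    n_dropped_ambiguous: int
    status: str = "ok"


def cross_species_correlation(meta: pd.DataFrame,
                              mouse_fc: Mapping[str, float],
                              homologs: pd.DataFrame,
                              expression_means: Mapping[str, float] | None = None
                              ) -> CrossSpeciesResult:
    """Pearson correlation of per-gene summary ES against mouse logFC.

    ``homologs`` has two columns (query-species gene, mouse gene).  Homology
    groups that are not one-to-one are collapsed by keeping the
    highest-mean-expression representative when ``expression_means`` is
    given, and dropped (counted) otherwise.
    """
    homologs = homologs.copy()
    homologs.columns = ["query", "mouse"][: homologs.shape[1]]
    dup = homologs["query"].duplicated(keep=False) | homologs[
        "mouse"].duplicated(keep=False)
    n_dropped = 0
    if dup.any():
        if expression_means is not None:
            homologs["rank"] = homologs["query"].map(
                lambda g: expression_means.get(g, -np.inf))
            homologs = homologs.sort_values("rank", ascending=False,
                                            kind="stable")
            before = len(homologs)
            homologs = homologs.drop_duplicates("mouse").drop_duplicates(
                "query")
            n_dropped = before - len(homologs)
        else:
            n_dropped = int(dup.sum())
            homologs = homologs[~dup]
    es_by_gene = dict(zip(meta["gene"], meta["es"]))
    xs, ys = [], []
    for _, row in homologs.iterrows():
        if row["query"] in es_by_gene and row["mouse"] in mouse_fc:
            xs.append(es_by_gene[row["query"]])
            ys.append(mouse_fc[row["mouse"]])
    if len(xs) < 3:
        return CrossSpeciesResult(None, None, len(xs), n_dropped,
                                  status="too few matched pairs")
    x, y = np.asarray(xs), np.asarray(ys)
    if x.std() == 0 or y.std() == 0:
        return CrossSpeciesResult(None, None, len(xs), n_dropped,
                                  status="zero variance")
    r, p = stats.pearsonr(x, y)
    return CrossSpeciesResult(float(r), float(p), len(xs), n_dropped)
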