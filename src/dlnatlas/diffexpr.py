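"""Differential expression/accessibility between timepoints and stimuli.

P-values come from the two-sided Wilcoxon rank-sum test (exact enumeration
when the combined group size is at most 20 and there are no ties, normal
approximation with tie and continuity correction otherwise); a Student
t-test engine is available behind a flag.  Log fold changes are natural-log
ratios of pseudocounted de-logged group means (Seurat v3 convention):
``ln((mean(expm1(norm_A)) + 1) / (mean(expm1(norm_B)) + 1))``.

Two published significance regimes are exposed: the acute (day 1) regime
FDR < 0.05 and |logFC| > 0.25, and the late (day 28) regime FDR < 0.05 and
|logFC| >= 0.1, chosen to catch an attenuated residual response.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

REGIMES = {"day1": {"min_abs_logfc": 0.25, "strict": True},
           "day28": {"min_abs_logfc": 0.1, "strict": False}}


@dataclasses.dataclass
class Contrast:
    """Cell selection for one differential test within one cell type.

    ``group_a`` / ``group_b`` map cell-table columns to required values,
    e.g. ``{"timepoint": "day1", "stimulus": "3M"}``.
    """

    cell_type: str
    group_a: Mapping[str, str]
    group_b: Mapping[str, str]
    modality: str = "RNA"
    min_group_size: int = 3

    def masks(self, cells: pd.DataFrame,
              cell_type_col: str = "cell_type") -> tuple[np.ndarray, np.ndarray]:
        base = np.ones(len(cells), dtype=bool)
        if self.cell_type and cell_type_col in cells.columns:
            base = (cells[cell_type_col] == self.cell_type).to_numpy()
        mask_a, mask_b = base.copy(), base.copy()
        for col, val in self.group_a.items():
            mask_a &= (cells[col] == val).to_numpy()
        for col, val in self.group_b.items():
            mask_b &= (cells[col] == val).to_numpy()
        if (mask_a & mask_b).any():
            raise ValueError(f"groups overlap in contrast {self}")
        return mask_a, mask_b


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values, monotone in rank, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _logfc(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    mean_a = np.expm1(norm_a).mean(axis=1)
    mean_b = np.expm1(norm_b).mean(axis=1)
    return np.log((mean_a + 1.0) / (mean_b + 1.0))


def wilcoxon_de(norm: np.ndarray, feature_ids: list[str] | pd.Series,
                mask_a: np.ndarray, mask_b: np.ndarray,
                min_group_size: int = 3, min_detect_frac: float = 0.10,
                engine: str = "wilcoxon", regime: str = "day1",
                contrast_name: str = "") -> pd.DataFrame:
    """Per-feature differential test between two cell groups.

    ``norm`` is the log-normalized matrix (features x cells).  Features
    detected in fewer than ``min_detect_frac`` of both groups are not
    tested.  BH correction is applied within the call, over tested features.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < min_group_size or n_b < min_group_size:
        raise ValueError(
            f"contrast {contrast_name or '<unnamed>'}: group sizes "
            f"({n_a}, {n_b}) below minimum {min_group_size}"
        )
    a = norm[:, mask_a]
    b = norm[:, mask_b]
    det_a = (a > 0).mean(axis=1)
    det_b = (b > 0).mean(axis=1)
    tested = (det_a >= min_detect_frac) | (det_b >= min_detect_frac)

    logfc = _logfc(a, b)
    pvals = np.full(norm.shape[0], np.nan)
    ti = np.flatnonzero(tested)
    if ti.size:
        if engine == "wilcoxon":
            if n_a + n_b <= 20:
                for i in ti:
                    row_a, row_b = a[i], b[i]
                    has_ties = np.unique(np.concatenate([row_a, row_b])).size < (
                        n_a + n_b)
                    method = "asymptotic" if has_ties else "exact"
                    pvals[i] = stats.mannwhitneyu(
                        row_a, row_b, alternative="two-sided", method=method
                    ).pvalue
            else:
                res = stats.mannwhitneyu(
                    a[ti], b[ti], alternative="two-sided", axis=1,
                    method="asymptotic",
                )
                pvals[ti] = res.pvalue
        elif engine == "ttest":
            res = stats.ttest_ind(a[ti], b[ti], axis=1)
            pvals[ti] = res.pvalue
        else:
            raise ValueError(f"unknown engine {engine!r}")
    # identical groups yield p = 1 (no evidence), not NaN
    same = np.array([np.array_equal(a[i], b[i]) if n_a == n_b else False
                     for i in ti])
    if same.any():
        pvals[ti[same]] = 1.0

    result = pd.DataFrame({
        "feature": list(feature_ids),
        "logfc": logfc,
        "p_raw": pvals,
        "direction": np.where(logfc >= 0, "up", "down"),
        "n_a": n_a,
        "n_b": n_b,
        "regime": regime,
    })
    result = result[tested].reset_index(drop=True)
    result["fdr"] = benjamini_hochberg(result["p_raw"].to_numpy())
    return result


def significant(result: pd.DataFrame, regime: str | None = None,
                max_fdr: float = 0.05) -> pd.DataFrame:
    """Apply the regime's |logFC| threshold (strict > for day1, >= for day28)."""
    regime = regime or (result["regime"].iloc[0] if len(result) else "day1")
    spec = REGIMES[regime]
    abs_fc = result["logfc"].abs()
    if spec["strict"]:
        fc_ok = abs_fc > spec["min_abs_logfc"]
    else:
        fc_ok = abs_fc >= spec["min_abs_logfc"]
    return result[(result["fdr"] < max_fdr) & fc_ok].reset_index(drop=True)


@dataclasses.dataclass
class DirectionSharing:
    percent: float | None
    n_shared: int
    n_compared: int
    n_missing: int
    status: str = "ok"


def direction_sharing(degs_a: pd.DataFrame,
                      fc_b: Mapping[str, float]) -> DirectionSharing:
    """Percentage of A-significant features whose logFC sign matches in B.

    Features missing from ``fc_b`` are excluded and counted; a zero logFC in
    B is treated as a mismatch.  Returns an explicit no-DEGs status when
    ``degs_a`` is empty.
    """
    if len(degs_a) == 0:
        return DirectionSharing(None, 0, 0, 0, status="no DEGs")
    n_missing = 0
    n_shared = 0
    n_compared = 0
    for _, row in degs_a.iterrows():
        if row["feature"] not in fc_b:
            n_missing += 1
            continue
        n_compared += 1
        other = fc_b[row["feature"]]
        if other != 0 and np.sign(other) == np.sign(row["logfc"]):
            n_shared += 1
    if n_compared == 0:
        return DirectionSharing(None, 0, 0, n_missing, status="no shared features")
    return DirectionSharing(100.0 * n_shared / n_compared, n_shared,
                            n_compared, n_missing)


@dataclasses.dataclass
class CorrelationResult:
    r: float | None
    p: float | None
    n: int
    status: str = "ok"


def logfc_correlation(fc_a: Mapping[str, float], fc_b: Mapping[str, float],
                      feature_subset: list[str] | None = None
                      ) -> CorrelationResult:
    """Pearson correlation of two logFC maps over their shared features."""
    shared = sorted(set(fc_a) & set(fc_b))
    if feature_subset is not None:
        shared = [f for f in shared if f in set(feature_subset)]
    if len(shared) < 3:
        return CorrelationResult(None, None, len(shared), status="too few features")
    x = np.array([fc_a[f] for f in shared])
    y = np.array([fc_b[f] for f in shared])
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(None, None, len(shared),
                                 status="zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(shared))


def motif_differential(z: np.ndarray, motif_names: list[str],
                       mask_a: np.ndarray, mask_b: np.ndarray,
                       min_group_size: int = 3) -> pd.DataFrame:
    """Differentially accessible TF motifs between two cell groups.

    Motif deviation z-scores are already on a centered, bias-corrected
    scale, so the reported "logFC" is the difference of group mean z
    (labeled as such); p-values come from the two-sided rank-sum test with
    BH correction across motifs.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() < min_group_size or mask_b.sum() < min_group_size:
        raise ValueError("motif contrast groups below minimum size")
    za, zb = z[:, mask_a], z[:, mask_b]
    delta = np.nanmean(za, axis=1) - np.nanmean(zb, axis=1)
    pvals = np.full(z.shape[0], np.nan)
    for i in range(z.shape[0]):
        a = za[i][~np.isnan(za[i])]
        b = zb[i][~np.isnan(zb[i])]
        if a.size >= min_group_size and b.size >= min_group_size:
            pvals[i] = stats.mannwhitneyu(a, b,
                                          alternative="two-sided").pvalue
    result = pd.DataFrame({
        "feature": motif_names, "logfc": delta, "p_raw": pvals,
        "direction": np.where(delta >= 0, "up", "down"),
        "n_a": int(mask_a.sum()), "n_b": int(mask_b.sum()),
    })
    ok = ~result["p_raw"].isna()
    result = result[ok].reset_index(drop=True)
    result["fdr"] = benjamini_hochberg(result["p_raw"].to_numpy())
    return result


def match_background_cells(cov_a: np.ndarray, cov_b: np.ndarray,
                           seed: int = 0) -> np.ndarray:
    """Bias-matched subsampling of group B for ATAC differential tests.

    For each group-A cell, pick the nearest unused group-B cell in the
    standardized covariate space (log fragments, TSS enrichment), emulating
    differential testing "with correction for TSS enrichment and the number
    of unique fragments".  Returns indices into group B.
    """
    cov_a = np.asarray(cov_a, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    pooled = np.vstack([cov_a, cov_b])
    mean, sd = pooled.mean(axis=0), pooled.std(axis=0)
    sd[sd == 0] = 1.0
    za = (cov_a - mean) / sd
    zb = (cov_b - mean) / sd
    k = min(len(cov_b), max(10, len(cov_a)))
    nn = NearestNeighbors(n_neighbors=k).fit(zb)
    _, neighbors = nn.kneighbors(za)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cov_a))
    used: set[int] = set()
    chosen = np.empty(len(cov_a), dtype=int)
    for i in order:
        pick = next((int(j) for j in neighbors[i] if int(j) not in used), None)
        if pick is None:
            pick = int(neighbors[i][0])
        chosen[i] = pick
        used.add(pick)
    return chosen
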