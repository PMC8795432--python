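"""Paired scRNA/scATAC simulator for a vaccination time course in lymph nodes.

The generator emulates the statistical structure the downstream analyses
assume: ~10 innate cell types profiled at three timepoints (day0, day1,
day28) under two stimuli (an adjuvanted antigen, ``3M``, and a live
attenuated virus, ``YF``); a shared interferon-stimulated-gene (ISG) program
induced at day 1 with cell-type-specific magnitude; persistence of a residual
fraction of that program at day 28 in monocytes under the adjuvant stimulus;
three monocyte subclusters (Ly6Chi / Ly6Cint / Ly6Clo) with marker-gene
blocks; mirrored chromatin accessibility effects in gene-linked peaks; an
Irf-like motif whose hits are enriched in ISG-linked peaks; per-peak GC
content; per-cell sequencing-depth variation; and parent-sum doublets.

RNA counts are negative binomial (Gamma-Poisson), ATAC peak counts Poisson.
Planted effects are specified on the natural-log fold-change scale.  One RNG
stream per modality, derived from ``config.seed`` as
``default_rng([seed, k])`` with ``k = 0`` (RNA) and ``k = 1`` (ATAC), so the
two modalities are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .io import (
    CellMatrix,
    write_gene_annotation,
    write_motif_hits,
    write_mtx_bundle,
    write_peaks_bed,
)

MONOCYTE = "monocyte"
SUBCLUSTER_NAMES = ("Ly6Chi", "Ly6Cint", "Ly6Clo")


@dataclasses.dataclass
class SubclusterSpec:
    """Monocyte subcluster structure: marker blocks and mixing proportions."""

    marker_blocks: tuple[tuple[str, ...], ...]
    proportions: tuple[float, ...] = (0.5, 0.3, 0.2)
    names: tuple[str, ...] = SUBCLUSTER_NAMES
    marker_boost: float = 2.0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("subcluster proportions must sum to 1")
        if not (len(self.marker_blocks) == len(self.proportions) == len(self.names)):
            raise ValueError("subcluster spec fields must have equal length")


@dataclasses.dataclass
class SimConfig:
    """All knobs of the paired simulator.  Defaults are the study conditions.

    ``isg_genes`` carries the induced program; ``isg_induction_by_type`` its
    per-cell-type day-1 magnitude on the natural-log scale;
    ``persistence_map`` maps ``(cell_type, gene)`` to the day-28 residual
    fraction of that magnitude (applied under ``persistence_stimulus`` only,
    emulating adjuvant-specific persistence).
    """

    n_cell_types: int = 10
    cells_per_type_per_condition: int = 50
    n_genes: int = 1200
    n_peaks: int = 1500
    n_motifs: int = 25
    timepoints: tuple[str, ...] = ("day0", "day1", "day28")
    stimuli: tuple[str, ...] = ("3M", "YF")
    isg_genes: tuple[str, ...] = ()
    isg_induction_by_type: Mapping[str, float] = dataclasses.field(default_factory=dict)
    persistence_map: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=dict
    )
    persistence_stimulus: str = "3M"
    monocyte_subcluster_spec: SubclusterSpec | None = None
    nb_dispersion: float = 2.0
    depth_lognormal_params: tuple[float, float] = (np.log(2500.0), 0.3)
    atac_depth_lognormal_params: tuple[float, float] = (np.log(5000.0), 0.35)
    doublet_rate: float = 0.05
    gc_beta_params: tuple[float, float] = (10.0, 10.0)
    n_mito_genes: int = 13
    mito_base_boost: float = 2.0
    mito_high_fraction: float = 0.04
    mito_high_boost: float = 2.5
    type_marker_genes: int = 20
    type_marker_boost: float = 2.5
    isg_base_offset: float = -1.0
    atac_mirror_fraction: float = 0.8
    atac_effect_scale: float = 1.0
    irf_hit_rate_isg: float = 0.6
    background_hit_rate: float = 0.05
    tss_ratio_mean: float = 10.0
    low_quality_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "cells_per_type_per_condition", "n_genes",
                     "n_peaks", "n_motifs"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        unknown = set(self.isg_induction_by_type) - set(self.cell_type_names())
        if unknown:
            raise ValueError(f"isg_induction_by_type for unknown types: {unknown}")
        for frac in dict(self.persistence_map).values():
            if not 0 <= frac <= 1:
                raise ValueError("persistence fractions must be in [0, 1]")

    def cell_type_names(self) -> list[str]:
        names = [MONOCYTE, "macrophage", "migDC", "cDC1", "cDC2", "pDC", "tDC",
                 "NK", "ILC2", "gdT", "Treg", "CD8T", "B", "neutrophil", "mast"]
        if self.n_cell_types <= len(names):
            return names[: self.n_cell_types]
        return names + [f"type{i}" for i in range(len(names), self.n_cell_types)]

    def gene_names(self) -> list[str]:
        return _gene_names(self)

    @property
    def n_conditions(self) -> int:
        return len(self.timepoints) * len(self.stimuli)

    @property
    def n_cells(self) -> int:
        return self.n_cell_types * self.n_conditions * self.cells_per_type_per_condition


# Named ISGs / subcluster markers give the synthetic genes domain-recognizable
# labels (the first ISG is "Ifit3", the active motif "Irf2").
_ISG_SEED_NAMES = ("Ifit3", "Irf7", "Isg15", "Mx1", "Mx2", "Stat1", "Stat2",
                   "Ddx58", "Ifi44", "Oasl1", "Rsad2", "Cxcl10")
_LY6CHI_SEED = ("Ly6c2", "Ccr2")
_LY6CINT_SEED = ("Cd74", "H2-Aa", "Ciita")
_LY6CLO_SEED = ("Cx3cr1", "Nr4a1", "Pparg")


def _gene_names(config: SimConfig) -> list[str]:
    names = [f"g{i:04d}" for i in range(config.n_genes)]
    # mitochondrial genes first (QC needs the "mt-" prefix)
    cursor = min(config.n_mito_genes, config.n_genes)
    for i in range(cursor):
        names[i] = f"mt-g{i:02d}"
    # named ISG / subcluster-marker genes occupy the next slots unless the
    # caller referenced default-pattern ids directly
    existing = set(names)
    special = list(config.isg_genes)
    spec = config.monocyte_subcluster_spec
    if spec is not None:
        for block in spec.marker_blocks:
            special.extend(block)
    for g in special:
        if g in existing:
            continue
        if cursor >= config.n_genes:
            raise ValueError("n_genes too small for the named gene blocks")
        names[cursor] = g
        existing.add(g)
        cursor += 1
    return names


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Build the study-condition default configuration.

    Plants a 40-gene ISG program (induction logFC 1.5 in monocytes, 1.0 in
    DC-like types, 0.5 in lymphoid types), 40% day-28 persistence in
    monocytes under the adjuvant stimulus, per-type marker blocks, and three
    monocyte subclusters at 50/30/20% mixing.
    """
    base = SimConfig(seed=seed)
    n_genes = overrides.get("n_genes", base.n_genes)
    n_types = overrides.get("n_cell_types", base.n_cell_types)
    cfg0 = SimConfig(seed=seed, n_genes=n_genes, n_cell_types=n_types)
    n_isg = min(40, max(4, n_genes // 30))
    isg = [_ISG_SEED_NAMES[i] if i < len(_ISG_SEED_NAMES) else f"Isg{i:02d}"
           for i in range(n_isg)]
    blocks = []
    for bi, seedset in enumerate((_LY6CHI_SEED, _LY6CINT_SEED, _LY6CLO_SEED)):
        block = [seedset[j] if j < len(seedset) else f"sub{bi}_{j:02d}"
                 for j in range(15)]
        blocks.append(tuple(block))
    types = cfg0.cell_type_names()
    dc_like = {"migDC", "cDC1", "cDC2", "pDC", "tDC", "macrophage"}
    induction = {}
    for t in types:
        if t == MONOCYTE:
            induction[t] = 1.5
        elif t in dc_like:
            induction[t] = 1.0
        else:
            induction[t] = 0.5
    persistence = {(MONOCYTE, g): 0.4 for g in isg}
    defaults = dict(
        isg_genes=tuple(isg),
        isg_induction_by_type=induction,
        persistence_map=persistence,
        monocyte_subcluster_spec=SubclusterSpec(marker_blocks=tuple(blocks)),
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration with no planted effects (for calibration checks)."""
    cfg = default_config(seed=seed, **overrides)
    return dataclasses.replace(
        cfg,
        isg_induction_by_type={t: 0.0 for t in cfg.cell_type_names()},
        persistence_map={},
    )


@dataclasses.dataclass
class SimTruth:
    """Every planted parameter, for recovery tests."""

    cells: pd.DataFrame  # barcode, cell_type, subcluster, timepoint, stimulus,
    #                      doublet, depth (+ATAC columns once simulate_atac ran)
    de_table: pd.DataFrame  # cell_type, timepoint, stimulus, gene, true_logfc
    gene_names: list[str]
    base_log_expression: np.ndarray  # genes x types
    peak_table: pd.DataFrame | None = None
    motif_hits: sparse.csr_matrix | None = None
    motif_names: list[str] | None = None
    active_motifs: tuple[str, ...] = ()
    peak_effects: pd.DataFrame | None = None  # peak effects per type/condition
    atac_cells: pd.DataFrame | None = None
    gene_annotation: pd.DataFrame | None = None
    mirrored_genes: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="list"),
            "de_table": self.de_table.to_dict(orient="list"),
            "gene_names": self.gene_names,
            "active_motifs": list(self.active_motifs),
            "mirrored_genes": list(self.mirrored_genes),
        }
        if self.atac_cells is not None:
            payload["atac_cells"] = self.atac_cells.to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, sort_keys=True))


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _structure(config: SimConfig) -> dict:
    """Deterministic layout shared by both modalities: base expression,
    marker assignments, planted effect table."""
    rng = _rng_for(config, 2)
    genes = _gene_names(config)
    types = config.cell_type_names()
    name_to_idx = {g: i for i, g in enumerate(genes)}

    # shared baseline with per-type marker blocks on top
    shared = rng.normal(0.0, 1.0, size=config.n_genes)
    base = np.tile(shared[:, None], (1, len(types)))

    mito_idx = [i for i, g in enumerate(genes) if g.startswith("mt-")]
    base[mito_idx, :] += config.mito_base_boost

    # reserve gene blocks: walk from the end of the array so markers do not
    # collide with mito/ISG/subcluster names assigned from the front
    marker_of_type: dict[str, list[int]] = {}
    cursor = config.n_genes - 1
    for t in types:
        block = []
        for _ in range(config.type_marker_genes):
            block.append(cursor)
            cursor -= 1
        marker_of_type[t] = block
        # markers are population-restricted: suppressed everywhere, boosted
        # in their own type
        base[block, :] -= 3.0
        base[block, types.index(t)] += config.type_marker_boost + 3.0
    if cursor < config.n_mito_genes + len(config.isg_genes) + 45:
        raise ValueError("n_genes too small for marker/ISG/subcluster blocks")

    isg_idx = []
    for g in config.isg_genes:
        if g not in name_to_idx:
            raise ValueError(f"ISG gene {g!r} not in gene universe")
        isg_idx.append(name_to_idx[g])
    base[isg_idx, :] += config.isg_base_offset

    spec = config.monocyte_subcluster_spec
    sub_marker_idx: list[list[int]] = []
    if spec is not None:
        for block in spec.marker_blocks:
            idx = [name_to_idx[g] for g in block]
            sub_marker_idx.append(idx)
            base[idx, :] -= 1.5  # markers quiet outside their subcluster

    # planted DE table (natural-log fold changes)
    records = []
    for stim in config.stimuli:
        for t in types:
            amp = float(config.isg_induction_by_type.get(t, 0.0))
            for g in config.isg_genes:
                if amp != 0.0:
                    records.append((t, "day1", stim, g, amp))
                resid = float(dict(config.persistence_map).get((t, g), 0.0))
                if resid > 0 and stim == config.persistence_stimulus and amp != 0.0:
                    records.append((t, "day28", stim, g, amp * resid))
    de_table = pd.DataFrame(
        records, columns=["cell_type", "timepoint", "stimulus", "gene", "true_logfc"]
    )
    return {
        "genes": genes,
        "types": types,
        "base": base,
        "marker_of_type": marker_of_type,
        "sub_marker_idx": sub_marker_idx,
        "isg_idx": isg_idx,
        "mito_idx": mito_idx,
        "de_table": de_table,
        "name_to_idx": name_to_idx,
    }


def _effect_matrix(config: SimConfig, struct: dict, cell_type: str,
                   timepoint: str, stimulus: str) -> np.ndarray:
    """Per-gene planted log-fold-change for one (type, timepoint, stimulus)."""
    effect = np.zeros(config.n_genes)
    if timepoint == "day0" or not config.isg_genes:
        return effect
    amp = float(config.isg_induction_by_type.get(cell_type, 0.0))
    if amp == 0.0:
        return effect
    if timepoint == "day1":
        effect[struct["isg_idx"]] = amp
    elif timepoint == "day28" and stimulus == config.persistence_stimulus:
        pmap = dict(config.persistence_map)
        for g, gi in zip(config.isg_genes, struct["isg_idx"]):
            effect[gi] = amp * float(pmap.get((cell_type, g), 0.0))
    return effect


def _make_cell_table(config: SimConfig, rng: np.random.Generator,
                     struct: dict) -> pd.DataFrame:
    rows = []
    spec = config.monocyte_subcluster_spec
    for t in struct["types"]:
        for tp in config.timepoints:
            for stim in config.stimuli:
                n = config.cells_per_type_per_condition
                if t == MONOCYTE and spec is not None:
                    subs = rng.choice(
                        len(spec.proportions), size=n, p=list(spec.proportions)
                    )
                    subnames = [spec.names[s] for s in subs]
                else:
                    subnames = [""] * n
                for i in range(n):
                    rows.append((t, subnames[i], tp, stim))
    cells = pd.DataFrame(rows, columns=["cell_type", "subcluster", "timepoint",
                                        "stimulus"])
    cells.insert(0, "barcode", [f"cell{i:05d}" for i in range(len(cells))])
    return cells


def _plant_doublets(counts: np.ndarray, depths: np.ndarray, rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Replace round(rate*n) cells with parent-sum doublets, thinned back to
    the mean parental depth.  Returns the boolean doublet flag vector."""
    n = counts.shape[1]
    n_doub = int(round(rate * n))
    flags = np.zeros(n, dtype=bool)
    if n_doub == 0:
        return flags
    targets = rng.choice(n, size=n_doub, replace=False)
    for c in targets:
        p1, p2 = rng.choice(n, size=2, replace=False)
        combined = counts[:, p1] + counts[:, p2]
        total = combined.sum()
        target_depth = 0.5 * (counts[:, p1].sum() + counts[:, p2].sum())
        if total > 0:
            combined = rng.binomial(combined, min(1.0, target_depth / total))
        counts[:, c] = combined
        flags[c] = True
    return flags


def simulate_rna(config: SimConfig) -> tuple[CellMatrix, SimTruth]:
    """Simulate the scRNA-seq count matrix and its ground truth.

    Counts for cell c of group (type t, timepoint, stimulus) are negative
    binomial with mean ``depth_c * p_g`` where ``p`` is the softmax of the
    per-type base log-expression plus any planted log-fold-change active in
    that condition, and dispersion ``nb_dispersion`` (variance
    ``mu + mu^2/theta``).
    """
    struct = _structure(config)
    rng = _rng_for(config, 0)
    cells = _make_cell_table(config, rng, struct)
    n = len(cells)

    depths = np.round(
        rng.lognormal(*config.depth_lognormal_params, size=n)
    ).astype(np.int64).clip(min=100)

    # cells with pathological mito content, to exercise QC
    n_bad = int(round(config.mito_high_fraction * n))
    bad_idx = rng.choice(n, size=n_bad, replace=False) if n_bad else np.array([], int)
    bad_mask = np.zeros(n, dtype=bool)
    bad_mask[bad_idx] = True

    counts = np.zeros((config.n_genes, n), dtype=np.int64)
    spec = config.monocyte_subcluster_spec
    theta = config.nb_dispersion
    group_cols = ["cell_type", "subcluster", "timepoint", "stimulus"]
    for keys, grp in cells.groupby(group_cols, sort=True):
        t, sub, tp, stim = keys
        idx = grp.index.to_numpy()
        logmean = struct["base"][:, struct["types"].index(t)].copy()
        logmean += _effect_matrix(config, struct, t, tp, stim)
        if sub and spec is not None:
            block = struct["sub_marker_idx"][list(spec.names).index(sub)]
            logmean[block] += spec.marker_boost + 1.5
        w = np.exp(logmean)
        # high-mito cells handled per cell below; start from the group profile
        p = w / w.sum()
        mu = p[:, None] * depths[idx][None, :]
        if bad_mask[idx].any():
            sel = np.flatnonzero(bad_mask[idx])
            w_bad = w.copy()
            w_bad[struct["mito_idx"]] *= np.exp(config.mito_high_boost)
            p_bad = w_bad / w_bad.sum()
            mu[:, sel] = p_bad[:, None] * depths[idx][sel][None, :]
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts[:, idx] = rng.poisson(lam)

    flags = _plant_doublets(counts, depths, config.doublet_rate, rng)
    cells = cells.copy()
    cells["doublet"] = flags
    cells["depth"] = depths
    cells["high_mito"] = bad_mask

    features = pd.DataFrame(
        {"id": struct["genes"], "name": struct["genes"], "kind": "gene"}
    )
    cm = CellMatrix(
        values=sparse.csr_matrix(counts),
        features=features,
        cells=cells[["barcode", "timepoint", "stimulus"]].copy(),
        modality="RNA",
    )
    truth = SimTruth(
        cells=cells,
        de_table=struct["de_table"],
        gene_names=struct["genes"],
        base_log_expression=struct["base"],
    )
    return cm, truth


def gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Deterministic synthetic gene coordinates (no RNG): genes laid out on
    19 chromosomes, 8 kb bodies every 60 kb."""
    genes = _gene_names(config)
    rows = []
    for i, g in enumerate(genes):
        chrom = f"chr{1 + i % 19}"
        tss = 100_000 + (i // 19) * 60_000
        rows.append((g, chrom, "+", tss, tss, tss + 8_000))
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss", "start",
                                       "end"])


def simulate_atac(
    config: SimConfig, rna_truth: SimTruth
) -> tuple[CellMatrix, pd.DataFrame, tuple[sparse.csr_matrix, list[str]], SimTruth]:
    """Simulate the paired scATAC-seq data for the cells in ``rna_truth``.

    Peak counts are Poisson with per-peak propensity x per-cell fragment
    depth.  Every gene gets a promoter peak; a subset get a distal peak.
    For a configurable fraction of ISG genes the RNA effect is mirrored onto
    their linked peaks (scaled by ``atac_effect_scale``).  Motif hits are
    planted so the Irf-like motif is enriched in ISG-linked peaks.  Per-cell
    TSS-proximal/flanking fragment totals realize a planted enrichment ratio.
    """
    struct = _structure(config)
    rng = _rng_for(config, 1)
    genes_tbl = gene_annotation(config)
    cells = rna_truth.cells

    n_genes = config.n_genes
    if config.n_peaks < n_genes + 10:
        raise ValueError(
            "n_peaks must exceed n_genes (every gene needs a promoter peak)"
        )

    # --- peak layout -----------------------------------------------------
    rows = []
    linked_gene: list[str] = []
    kind: list[str] = []
    for i, grow in genes_tbl.iterrows():
        rows.append((grow.chrom, grow.tss - 200, grow.tss + 200))
        linked_gene.append(grow.gene)
        kind.append("promoter")
    n_extra = config.n_peaks - n_genes
    n_distal = min(n_extra // 2, n_genes)
    distal_genes = rng.choice(n_genes, size=n_distal, replace=False)
    for gi in distal_genes:
        grow = genes_tbl.iloc[int(gi)]
        offset = int(rng.integers(3_000, 40_000))
        rows.append((grow.chrom, grow.tss + offset, grow.tss + offset + 400))
        linked_gene.append(grow.gene)
        kind.append("distal")
    for j in range(config.n_peaks - len(rows)):
        chrom = f"chr{1 + j % 19}"
        start = 50_000_000 + (j // 19) * 10_000
        rows.append((chrom, start, start + 400))
        linked_gene.append("")
        kind.append("intergenic")
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks["peak_id"] = [f"peak{i:05d}" for i in range(len(peaks))]
    peaks["gc"] = rng.beta(*config.gc_beta_params, size=len(peaks))
    peaks["linked_gene"] = linked_gene
    peaks["kind"] = kind

    # --- per-peak propensities per group ---------------------------------
    types = struct["types"]
    name_to_idx = struct["name_to_idx"]
    base_peak = rng.normal(0.0, 0.8, size=len(peaks))
    # promoter peaks of type markers mirror the marker boost (cluster structure)
    gene_of_peak = np.array([name_to_idx.get(g, -1) for g in linked_gene])
    type_boost = np.zeros((len(peaks), len(types)))
    for ti, t in enumerate(types):
        for gi in struct["marker_of_type"][t]:
            type_boost[gene_of_peak == gi, ti] += 1.8
    spec = config.monocyte_subcluster_spec
    sub_boost = np.zeros((len(peaks), len(spec.names) if spec else 0))
    if spec is not None:
        for si in range(len(spec.names)):
            for gi in struct["sub_marker_idx"][si]:
                sub_boost[gene_of_peak == gi, si] += 1.5

    # mirrored condition effects on ISG-linked peaks
    isg_set = set(config.isg_genes)
    mirrored = [
        g for g in config.isg_genes
        if rng.random() < config.atac_mirror_fraction
    ]
    mirrored_set = set(mirrored)
    isg_linked_peak = np.array([g in isg_set for g in linked_gene])
    mirrored_peak = np.array([g in mirrored_set for g in linked_gene])

    # --- motif hits -------------------------------------------------------
    motif_names = ["Irf2"] + [f"TF{i:02d}" for i in range(1, config.n_motifs)]
    hits = np.zeros((config.n_motifs, len(peaks)), dtype=np.int8)
    hits[0] = np.where(
        isg_linked_peak,
        rng.random(len(peaks)) < config.irf_hit_rate_isg,
        rng.random(len(peaks)) < config.background_hit_rate / 2,
    )
    for mi in range(1, config.n_motifs):
        hits[mi] = rng.random(len(peaks)) < config.background_hit_rate
    for mi in range(config.n_motifs):  # every motif hits >= 1 peak
        if hits[mi].sum() == 0:
            hits[mi, int(rng.integers(len(peaks)))] = 1
    hits_sp = sparse.csr_matrix(hits)

    # --- depths, TSS enrichment truth ------------------------------------
    n = len(cells)
    frag_depth = np.round(
        rng.lognormal(*config.atac_depth_lognormal_params, size=n)
    ).astype(np.int64).clip(min=50)
    n_lq = int(round(config.low_quality_fraction * n))
    lq_idx = rng.choice(n, size=n_lq, replace=False) if n_lq else np.array([], int)
    lq = np.zeros(n, dtype=bool)
    lq[lq_idx] = True
    tss_ratio = rng.lognormal(np.log(config.tss_ratio_mean), 0.15, size=n)
    tss_ratio[lq] = rng.lognormal(np.log(4.0), 0.15, size=lq.sum())
    frag_depth[lq] = np.round(frag_depth[lq] * 0.15).astype(np.int64).clip(min=50)
    flank_bp, prox_bp, alpha = 200.0, 100.0, 0.05
    flank_counts = rng.poisson(frag_depth * alpha)
    prox_counts = rng.poisson(frag_depth * alpha * tss_ratio * (prox_bp / flank_bp))

    # --- counts -----------------------------------------------------------
    counts = np.zeros((len(peaks), n), dtype=np.int64)
    in_peak_fraction = 0.3
    group_cols = ["cell_type", "subcluster", "timepoint", "stimulus"]
    effect_records = []
    for keys, grp in cells.groupby(group_cols, sort=True):
        t, sub, tp, stim = keys
        idx = grp.index.to_numpy()
        logprop = base_peak + type_boost[:, types.index(t)]
        if sub and spec is not None:
            logprop = logprop + sub_boost[:, list(spec.names).index(sub)]
        gene_effect = _effect_matrix(config, struct, t, tp, stim)
        peak_effect = np.where(
            mirrored_peak,
            config.atac_effect_scale * gene_effect[gene_of_peak.clip(min=0)],
            0.0,
        )
        logprop = logprop + peak_effect
        if tp != "day0" and peak_effect.any():
            effect_records.append(
                pd.DataFrame({
                    "peak_id": peaks["peak_id"], "cell_type": t, "timepoint": tp,
                    "stimulus": stim, "true_logfc": peak_effect,
                })
            )
        w = np.exp(logprop)
        p = w / w.sum()
        mu = p[:, None] * (frag_depth[idx] * in_peak_fraction)[None, :]
        counts[:, idx] = rng.poisson(mu)

    atac_flags = _plant_doublets(counts, frag_depth, config.doublet_rate, rng)

    atac_cells = cells[["barcode", "cell_type", "subcluster", "timepoint",
                        "stimulus"]].copy()
    atac_cells["doublet"] = atac_flags
    atac_cells["n_fragments"] = frag_depth
    atac_cells["tss_proximal"] = prox_counts
    atac_cells["tss_flanking"] = flank_counts
    atac_cells["true_tss_ratio"] = tss_ratio

    features = pd.DataFrame(
        {"id": peaks["peak_id"], "name": peaks["peak_id"], "kind": "peak"}
    )
    cell_meta = atac_cells[["barcode", "timepoint", "stimulus", "n_fragments",
                            "tss_proximal", "tss_flanking"]].copy()
    cm = CellMatrix(
        values=sparse.csr_matrix(counts), features=features, cells=cell_meta,
        modality="ATAC",
    )
    truth = dataclasses.replace(
        rna_truth,
        peak_table=peaks,
        motif_hits=hits_sp,
        motif_names=motif_names,
        active_motifs=("Irf2",),
        peak_effects=(pd.concat(effect_records, ignore_index=True)
                      if effect_records else pd.DataFrame(
                          columns=["peak_id", "cell_type", "timepoint",
                                   "stimulus", "true_logfc"])),
        atac_cells=atac_cells,
        gene_annotation=genes_tbl,
        mirrored_genes=tuple(mirrored),
    )
    return cm, peaks, (hits_sp, motif_names), truth


def write_sim_bundle(directory: str | Path, rna: CellMatrix, atac: CellMatrix,
                     peaks: pd.DataFrame, motif_hits: sparse.spmatrix,
                     motif_names: list[str], truth: SimTruth) -> None:
    """Write the full simulated dataset: per-modality MTX bundles, peaks.bed,
    motif hits, gene annotation, cell metadata and truth.json."""
    directory = Path(directory)
    write_mtx_bundle(directory / "rna", rna)
    write_mtx_bundle(directory / "atac", atac)
    write_peaks_bed(directory / "peaks.bed", peaks)
    write_motif_hits(directory, motif_hits, motif_names)
    if truth.gene_annotation is not None:
        write_gene_annotation(directory / "genes.tsv", truth.gene_annotation)
    truth.cells.to_csv(directory / "cells.tsv", sep="\t", index=False)
    truth.to_json(directory / "truth.json")


@dataclasses.dataclass
class MetaSim:
    """Synthetic multi-study pre/post expression data with mouse truth.

    ``studies`` maps study id to (expression genes x samples, design table);
    ``mouse_fc`` is the noisy mouse per-gene logFC; ``homologs`` the
    query-species -> mouse gene map; ``true_query_effect`` /
    ``true_mouse_effect`` the planted correlated effect pair.
    """

    studies: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    mouse_fc: dict[str, float]
    homologs: pd.DataFrame
    true_query_effect: np.ndarray
    true_mouse_effect: np.ndarray


def simulate_meta_studies(n_genes: int = 200, n_studies: int = 4,
                          n_per_arm: int = 15, effect_sd: float = 0.5,
                          effect_corr: float = 0.6,
                          mouse_noise_sd: float = 0.1,
                          seed: int = 0) -> MetaSim:
    """Simulate the cross-species meta-analysis inputs.

    Per gene, a bivariate-normal (mouse logFC, human standardized effect)
    pair with correlation ``effect_corr``; per study, log2-scale expression
    with unit within-group variance and the human effect as the post-pre
    mean shift.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 3])
    var = effect_sd**2
    cov = np.array([[var, effect_corr * var], [effect_corr * var, var]])
    effects = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes)
    mouse_eff, query_eff = effects[:, 0], effects[:, 1]
    query_genes = [f"GENE{i:04d}" for i in range(n_genes)]
    mouse_genes = [f"Gene{i:04d}" for i in range(n_genes)]
    studies = {}
    for s in range(n_studies):
        pre = rng.normal(0.0, 1.0, size=(n_genes, n_per_arm))
        post = rng.normal(query_eff[:, None], 1.0, size=(n_genes, n_per_arm))
        samples = [f"s{s}_{j}" for j in range(2 * n_per_arm)]
        expr = pd.DataFrame(np.hstack([pre, post]), index=query_genes,
                            columns=samples)
        expr.index.name = "gene"
        design = pd.DataFrame({"sample": samples,
                               "phase": ["pre"] * n_per_arm + ["post"] * n_per_arm})
        studies[f"study{s}"] = (expr, design)
    mouse_fc = {
        g: float(mouse_eff[i] + rng.normal(0.0, mouse_noise_sd))
        for i, g in enumerate(mouse_genes)
    }
    homologs = pd.DataFrame({"query": query_genes, "mouse": mouse_genes})
    return MetaSim(studies=studies, mouse_fc=mouse_fc, homologs=homologs,
                   true_query_effect=query_eff, true_mouse_effect=mouse_eff)
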