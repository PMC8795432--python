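"""On-disk formats: MatrixMarket bundles, GMT gene sets, BED peak tables.

Conventions
-----------
MatrixMarket indices are 1-based on disk (format standard) and 0-based in
memory.  BED intervals are 0-based half-open.  All tables are tab-separated
with a header row except ``barcodes.tsv`` (bare barcode list, 10x style) and
``peaks.bed`` (standard headerless BED with ``peak_id`` and ``gc`` in columns
4-5).  Readers validate and raise rather than silently coercing malformed
input.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """Base class for malformed on-disk inputs."""


class DimensionMismatchError(FormatError):
    """Matrix dimensions disagree with the feature/barcode tables."""


class DuplicateIdError(FormatError):
    """Duplicate feature ids or cell barcodes."""


class GmtParseError(FormatError):
    """Malformed GMT line."""


@dataclasses.dataclass
class CellMatrix:
    """Sparse feature x cell count matrix with aligned annotation tables.

    Parameters
    ----------
    values
        Nonnegative counts, shape ``(n_features, n_cells)``.
    features
        One row per feature; must contain columns ``id``, ``name``, ``kind``
        (``gene`` or ``peak``).  Extra per-modality columns are preserved.
    cells
        One row per cell; must contain ``barcode``; typically also
        ``timepoint`` and ``stimulus`` plus any truth/annotation labels.
    modality
        ``"RNA"`` or ``"ATAC"``.
    """

    values: sparse.spmatrix
    features: pd.DataFrame
    cells: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        if self.values.shape != (len(self.features), len(self.cells)):
            raise DimensionMismatchError(
                f"matrix is {self.values.shape} but tables have "
                f"{len(self.features)} features and {len(self.cells)} cells"
            )
        if self.features["id"].duplicated().any():
            dups = self.features["id"][self.features["id"].duplicated()].tolist()
            raise DuplicateIdError(f"duplicate feature ids: {dups[:5]}")
        if self.cells["barcode"].duplicated().any():
            dups = self.cells["barcode"][self.cells["barcode"].duplicated()].tolist()
            raise DuplicateIdError(f"duplicate barcodes: {dups[:5]}")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellMatrix(
            values=self.values[:, idx],
            features=self.features,
            cells=self.cells.iloc[idx].reset_index(drop=True),
            modality=self.modality,
        )

    def subset_features(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellMatrix(
            values=self.values[idx, :],
            features=self.features.iloc[idx].reset_index(drop=True),
            cells=self.cells,
            modality=self.modality,
        )


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (BTM-style, TF-target-style)."""

    sets: dict[str, frozenset[str]]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def write_mtx_bundle(directory: str | Path, cm: CellMatrix) -> None:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` + ``cells.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(cm.values)
    field = "integer" if np.issubdtype(mat.dtype, np.integer) else "real"
    spio.mmwrite(str(directory / "matrix.mtx"), mat, field=field)
    cm.features.to_csv(directory / "features.tsv", sep="\t", index=False)
    cm.cells[["barcode"]].to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )
    cm.cells.to_csv(directory / "cells.tsv", sep="\t", index=False)
    (directory / "modality.txt").write_text(cm.modality + "\n")


def read_mtx_bundle(directory: str | Path, modality: str | None = None) -> CellMatrix:
    """Read a bundle written by :func:`write_mtx_bundle`.

    Round-trip write -> read is exact on values and tables.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    try:
        values = sparse.csr_matrix(spio.mmread(str(mtx_path)))
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    features = pd.read_csv(directory / "features.tsv", sep="\t", dtype={"id": str})
    cells_path = directory / "cells.tsv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path, sep="\t", dtype={"barcode": str})
    else:
        cells = pd.read_csv(
            directory / "barcodes.tsv", sep="\t", header=None, names=["barcode"],
            dtype=str,
        )
    if values.shape[0] != len(features):
        raise DimensionMismatchError(
            f"matrix declares {values.shape[0]} features but features.tsv has "
            f"{len(features)} rows"
        )
    if values.shape[1] != len(cells):
        raise DimensionMismatchError(
            f"matrix declares {values.shape[1]} cells but cell table has "
            f"{len(cells)} rows"
        )
    if modality is None:
        mod_path = directory / "modality.txt"
        modality = mod_path.read_text().strip() if mod_path.exists() else "RNA"
    return CellMatrix(values=values, features=features, cells=cells, modality=modality)


def read_gmt(path: str | Path, provenance: str = "custom") -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are deduplicated; empty lines skipped.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            name = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets=sets, provenance=provenance)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w") as handle:
        for name, genes in collection.sets.items():
            handle.write("\t".join([name, collection.provenance, *sorted(genes)]) + "\n")


PEAK_COLUMNS = ["chrom", "start", "end", "peak_id", "gc"]


def write_peaks_bed(path: str | Path, peaks: pd.DataFrame) -> None:
    """Write peaks as headerless BED: chrom, start, end, peak_id, gc."""
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    peaks = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS)
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks.loc[peaks["start"] >= peaks["end"], "peak_id"].tolist()
        raise FormatError(f"peaks with start >= end: {bad[:5]}")
    if ((peaks["gc"] < 0) | (peaks["gc"] > 1)).any():
        raise FormatError("GC fraction outside [0, 1]")
    if peaks["peak_id"].duplicated().any():
        raise DuplicateIdError("duplicate peak ids")
    return peaks


def write_motif_hits(directory: str | Path, hits: sparse.spmatrix,
                     motif_names: list[str]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / "motif_hits.mtx"), sparse.coo_matrix(hits),
                 field="integer")
    pd.DataFrame({"motif": motif_names}).to_csv(
        directory / "motifs.tsv", sep="\t", index=False
    )


def read_motif_hits(directory: str | Path) -> tuple[sparse.csr_matrix, list[str]]:
    directory = Path(directory)
    hits = sparse.csr_matrix(spio.mmread(str(directory / "motif_hits.mtx")))
    motifs = pd.read_csv(directory / "motifs.tsv", sep="\t")["motif"].tolist()
    if hits.shape[0] != len(motifs):
        raise DimensionMismatchError(
            f"motif matrix has {hits.shape[0]} rows but motifs.tsv {len(motifs)}"
        )
    return hits, motifs


GENE_COLUMNS = ["gene", "chrom", "strand", "tss", "start", "end"]


def write_gene_annotation(path: str | Path, genes: pd.DataFrame) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise FormatError(f"gene annotation missing columns: {sorted(missing)}")
    if genes["gene"].duplicated().any():
        raise DuplicateIdError("duplicate gene ids in annotation")
    return genes


def read_homolog_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV mapping e.g. human gene -> mouse gene."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise FormatError("homolog map needs two columns")
    return table


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Deterministic TSV writer used by every CLI stage (6-digit floats)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def validate_config(config: Mapping, schema: Mapping[str, type]) -> dict:
    """Validate a flat-key mapping against ``{key: type}``; unknown keys raise."""
    out = {}
    for key, value in config.items():
        if key not in schema:
            raise FormatError(f"unknown configuration key {key!r}")
        expected = schema[key]
        if expected is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, expected):
            raise FormatError(
                f"configuration key {key!r} expects {expected.__name__}, "
                f"got {type(value).__name__}"
            )
        out[key] = value
    return out
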