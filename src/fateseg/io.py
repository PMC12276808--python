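"""Readers and writers for the formats the pipeline touches.

The annotated expression matrix is held as an :class:`anndata.AnnData` with
cells as ``obs`` and genes as ``var``; values are log-normalized CPM-scale
(non-negative, sparse).  Side formats are MatrixMarket ``.mtx`` plus TSV id
files, an annotation TSV (``cell_id, stage, celltype, sample``) and GMT gene
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "FormatError",
    "GeneSet",
    "DEFAULT_STAGES",
    "stage_sort_key",
    "load_expression",
    "write_expression",
    "load_annotation",
    "write_annotation",
    "attach_annotation",
    "load_gene_sets",
    "write_gene_sets",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


#: Gastrulation stages covered by the atlas, ordered by embryonic day.
DEFAULT_STAGES: tuple[str, ...] = (
    "E6.5", "E6.75", "E7.0", "E7.25", "E7.5", "E7.75", "E8.0", "E8.25", "E8.5",
)


def stage_sort_key(stage: str) -> float:
    """Numeric embryonic day of a stage label such as ``'E7.25'``."""
    return float(str(stage).lstrip("Ee"))


@dataclass
class GeneSet:
    """A named signature: an ordered, duplicate-free list of gene symbols."""

    name: str
    genes: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        dupes = []
        for g in self.genes:
            if g in seen:
                dupes.append(g)
            seen[g] = None
        if dupes:
            warnings.warn(
                f"gene set {self.name!r}: dropping duplicate genes {sorted(set(dupes))}"
            )
            self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Sequence[str]) -> list[str]:
        present = set(universe)
        return [g for g in self.genes if g in present]


def _read_ids(path: str | Path) -> list[str]:
    """First column of a headerless one/two-column TSV id file."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def load_expression(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    *,
    cells_axis: int | None = None,
) -> AnnData:
    """Load an MTX + id-file triple into an AnnData (cells × genes).

    The on-disk matrix may store cells on either axis; the orientation is
    auto-detected against the id-file lengths.  A square matrix is ambiguous
    and requires ``cells_axis`` (0 = rows are cells).

    Raises
    ------
    FormatError
        If neither orientation matches the id files, or the matrix is square
        and ``cells_axis`` is not given.
    """
    genes = _read_ids(genes_path)
    cells = _read_ids(barcodes_path)
    mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
    n_r, n_c = mat.shape

    if n_r == n_c:
        if cells_axis is None:
            if len(cells) != n_r or len(genes) != n_r:
                raise FormatError(
                    f"matrix is {n_r}×{n_c} but id files have "
                    f"{len(cells)} barcodes / {len(genes)} genes"
                )
            raise FormatError(
                "square matrix: orientation is ambiguous, pass cells_axis=0 or 1"
            )
        if cells_axis not in (0, 1):
            raise ValueError("cells_axis must be 0 or 1")
        if cells_axis == 1:
            mat = sp.csr_matrix(mat.T)
    elif (n_r, n_c) == (len(cells), len(genes)):
        pass
    elif (n_r, n_c) == (len(genes), len(cells)):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"matrix is {n_r}×{n_c} but id files have "
            f"{len(cells)} barcodes / {len(genes)} genes"
        )

    if mat.nnz and mat.data.min() < 0:
        raise FormatError("expression matrix contains negative values")
    if len(set(genes)) != len(genes):
        raise FormatError("gene ids are not unique")

    adata = AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    return adata


def write_expression(
    adata: AnnData,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write AnnData to MTX (cells as rows) plus gene/barcode TSVs."""
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(X))
    Path(genes_path).write_text("".join(f"{g}\n" for g in adata.var_names))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in adata.obs_names))


_ANNOTATION_COLUMNS = ("cell_id", "stage", "celltype", "sample")


def load_annotation(
    tsv_path: str | Path,
    alias_map: Mapping[str, str] | None = None,
    *,
    stages: Sequence[str] = DEFAULT_STAGES,
) -> pd.DataFrame:
    """Read the per-cell annotation TSV.

    Cell-type labels are rewritten through ``alias_map`` (the atlas label
    ``'mesenchyme'`` is conventionally aliased to ``'LPM'``).  Stages outside
    the declared vocabulary and duplicated cell ids are format errors.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file missing columns: {missing}")
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise FormatError(f"duplicate cell_id rows: {dupes[:5]}")
    unknown = sorted(set(df["stage"]) - set(stages))
    if unknown:
        raise FormatError(f"unknown stage labels: {unknown}")
    if alias_map:
        df["celltype"] = df["celltype"].map(lambda c: alias_map.get(c, c))
    df = df.set_index("cell_id")
    df["stage"] = pd.Categorical(df["stage"], categories=list(stages), ordered=True)
    return df[["stage", "celltype", "sample"]]


def write_annotation(annotation: pd.DataFrame, tsv_path: str | Path) -> None:
    annotation.to_csv(tsv_path, sep="\t", index=True, index_label="cell_id")


def attach_annotation(adata: AnnData, annotation: pd.DataFrame) -> AnnData:
    """Join annotation into ``adata.obs``; every matrix cell must be annotated."""
    missing = adata.obs_names.difference(annotation.index)
    if len(missing):
        raise FormatError(
            f"{len(missing)} matrix cells lack annotation, e.g. {list(missing[:3])}"
        )
    joined = annotation.loc[adata.obs_names]
    for col in joined.columns:
        adata.obs[col] = joined[col].values
    return adata


def load_gene_sets(gmt_path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name <tab> description <tab> gene...`` per line."""
    sets: list[GeneSet] = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description "
                    f"and at least one gene ({len(fields)} fields found)"
                )
            sets.append(GeneSet(name=fields[0], genes=fields[2:], source=fields[1]))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], gmt_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "."] + list(s.genes)) + "\n")
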