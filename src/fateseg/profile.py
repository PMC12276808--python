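"""Focal-gene expression profiling.

Identifies cells expressing a focal gene (strictly above a threshold, by
default 0 on the log-CPM scale) and summarises their prevalence, expression
level and cell-type composition per embryonic stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CellSubset",
    "identify_focal_cells",
    "stage_expression_summary",
    "celltype_distribution",
    "normalize_counts_per_sample",
    "marker_panel_profile",
]


def gene_vector(adata: AnnData, gene: str) -> np.ndarray:
    """Dense expression vector of one gene across all cells."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    col = adata[:, gene].X
    if sp.issparse(col):
        col = col.toarray()
    return np.asarray(col).ravel()


@dataclass
class CellSubset:
    """Cells whose focal-gene expression exceeds ``positivity_threshold``."""

    focal_gene: str
    positivity_threshold: float
    cell_ids: pd.Index

    def __len__(self) -> int:
        return len(self.cell_ids)

    def mask(self, adata: AnnData) -> np.ndarray:
        return adata.obs_names.isin(self.cell_ids)


def identify_focal_cells(
    adata: AnnData, gene: str, threshold: float = 0.0
) -> CellSubset:
    """Cells with focal expression strictly greater than ``threshold``."""
    expr = gene_vector(adata, gene)
    members = adata.obs_names[expr > threshold]
    return CellSubset(focal_gene=gene, positivity_threshold=threshold, cell_ids=members)


def stage_expression_summary(subset: CellSubset, adata: AnnData) -> pd.DataFrame:
    """Per-stage prevalence and mean expression of the focal-positive cells.

    ``percent_positive`` uses all cells of the stage as denominator;
    ``mean_expression`` averages over positive cells only and is NaN for
    stages without positives.
    """
    expr = gene_vector(adata, subset.focal_gene)
    member = subset.mask(adata)
    df = pd.DataFrame(
        {"stage": adata.obs["stage"].values, "positive": member, "expr": expr}
    )
    rows = []
    for stage, grp in df.groupby("stage", observed=False, sort=True):
        n_total = len(grp)
        n_pos = int(grp["positive"].sum())
        mean = float(grp.loc[grp["positive"], "expr"].mean()) if n_pos else float("nan")
        pct = 100.0 * n_pos / n_total if n_total else float("nan")
        rows.append((stage, n_total, n_pos, pct, mean))
    return pd.DataFrame(
        rows, columns=["stage", "n_total", "n_positive", "percent_positive", "mean_expression"]
    )


def celltype_distribution(subset: CellSubset, adata: AnnData) -> pd.DataFrame:
    """Per-stage cell-type counts and proportions among focal-positive cells."""
    obs = adata.obs.loc[subset.mask(adata), ["stage", "celltype"]]
    rows = []
    for stage, grp in obs.groupby("stage", observed=True, sort=True):
        counts = grp["celltype"].value_counts()
        total = counts.sum()
        for celltype, n in counts.items():
            rows.append((stage, celltype, int(n), n / total))
    return pd.DataFrame(rows, columns=["stage", "celltype", "count", "proportion"])


def normalize_counts_per_sample(
    counts: Mapping[str, float] | pd.Series, sample_sizes: Mapping[str, float] | pd.Series
) -> pd.Series:
    """Cell counts divided by sample size, rounded up to the nearest integer."""
    counts = pd.Series(counts, dtype=float)
    sizes = pd.Series(sample_sizes, dtype=float).reindex(counts.index)
    if sizes.isna().any():
        missing = list(counts.index[sizes.isna()])
        raise KeyError(f"no sample size for {missing}")
    if (sizes <= 0).any():
        raise ValueError("sample sizes must be positive")
    return (counts / sizes).map(math.ceil).astype(int)


def marker_panel_profile(
    adata: AnnData, markers: Sequence[str], tissues: Sequence[str]
) -> pd.DataFrame:
    """Mean expression and fraction-positive per (tissue, marker).

    Means are over all cells of the tissue; fraction-positive uses strict
    ``> 0`` positivity.  Unknown tissue labels raise.
    """
    known = set(adata.obs["celltype"])
    unknown = [t for t in tissues if t not in known]
    if unknown:
        raise KeyError(f"unknown tissue labels: {unknown}")
    rows = []
    for tissue in tissues:
        in_tissue = (adata.obs["celltype"] == tissue).values
        for marker in markers:
            expr = gene_vector(adata, marker)[in_tissue]
            rows.append(
                (tissue, marker, float(expr.mean()), float((expr > 0).mean()))
            )
    return pd.DataFrame(
        rows, columns=["tissue", "marker", "mean_expression", "fraction_positive"]
    )
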