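"""Per-stage correlation of focal-gene expression with signature genes.

Correlations are Pearson, computed among the focal-positive cells of each
stage ("within expressing cells"), with explicit data-sufficiency masking:
a (stage, marker) pair with no contributing cells is ``absent``, one with
fewer than three is ``insufficient``, and a zero-variance vector is
``zero_variance`` — reported, never silently dropped.  Significance tiers
follow the conventional 0.001 / 0.01 / 0.05 cutoffs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

from .io import GeneSet
from .profile import CellSubset, gene_vector

__all__ = [
    "significance_tier",
    "pairwise_correlation",
    "count_significant_markers",
]

TIER_CUTOFFS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    """Star label for a p-value: *** < 0.001, ** < 0.01, * < 0.05, else ns."""
    if np.isnan(p):
        return ""
    for cutoff, label in TIER_CUTOFFS:
        if p < cutoff:
            return label
    return "ns"


def pairwise_correlation(
    adata: AnnData,
    subset: CellSubset,
    gene_sets: Sequence[GeneSet],
    *,
    nonzero_only: bool = False,
    fdr: bool = True,
) -> pd.DataFrame:
    """Correlate focal expression with each signature gene, per stage.

    For each stage, ``r`` and the two-sided ``p`` are computed over the
    focal-positive cells of that stage (all of them by default; with
    ``nonzero_only`` only cells where the marker itself is non-zero count
    toward ``n``).  Returns a tidy table with columns ``stage, gene_set,
    gene, n, r, p, tier, mask`` and, when ``fdr`` is set, a
    Benjamini–Hochberg ``q`` over the unmasked tests.
    """
    all_genes = [g for s in gene_sets for g in s.genes]
    missing = [g for g in all_genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"marker genes absent from matrix: {missing}")

    member = subset.mask(adata)
    focal = gene_vector(adata, subset.focal_gene)
    stages = adata.obs["stage"]
    stage_levels = (
        stages.cat.categories if hasattr(stages, "cat") else pd.unique(stages)
    )

    rows = []
    for stage in stage_levels:
        in_stage = member & (stages == stage).values
        x_all = focal[in_stage]
        for gset in gene_sets:
            for gene in gset.genes:
                y_all = gene_vector(adata, gene)[in_stage]
                if nonzero_only:
                    keep = y_all > 0
                    x, y = x_all[keep], y_all[keep]
                else:
                    x, y = x_all, y_all
                n = len(x)
                r = p = np.nan
                if n == 0:
                    mask = "absent"
                elif n < 3:
                    mask = "insufficient"
                elif np.ptp(x) == 0 or np.ptp(y) == 0:
                    mask = "zero_variance"
                else:
                    mask = "none"
                    res = stats.pearsonr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
                rows.append((stage, gset.name, gene, n, r, p,
                             significance_tier(p), mask))

    table = pd.DataFrame(
        rows, columns=["stage", "gene_set", "gene", "n", "r", "p", "tier", "mask"]
    )
    if fdr:
        table["q"] = np.nan
        ok = table["mask"] == "none"
        if ok.any():
            table.loc[ok, "q"] = stats.false_discovery_control(
                table.loc[ok, "p"].to_numpy(), method="bh"
            )
    return table


def count_significant_markers(
    table: pd.DataFrame, direction: str = "positive", alpha: float = 0.05
) -> pd.DataFrame:
    """Number of markers significantly correlated with the focal gene.

    ``direction='positive'`` counts markers with ``p < alpha`` and ``r > 0``
    (the convention for tracking positively co-regulated signature genes);
    ``direction='any'`` ignores the sign.  Masked pairs never count.
    """
    if direction not in ("positive", "any"):
        raise ValueError("direction must be 'positive' or 'any'")
    ok = (table["mask"] == "none") & (table["p"] < alpha)
    if direction == "positive":
        ok &= table["r"] > 0
    counts = (
        table.assign(significant=ok)
        .groupby(["stage", "gene_set"], observed=False, sort=True)["significant"]
        .sum()
        .astype(int)
        .reset_index(name="n_significant")
    )
    return counts
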