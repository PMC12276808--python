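"""Co-expression fate classification of focal-positive cells.

A focal-positive cell belongs to a signature's class when it expresses at
least ``min_genes`` (default 3) of that signature's genes above 0.  Cells
reaching the threshold for both signatures are ``both``; for neither,
``neither``.  The classifier is deterministic — membership is a plain count
of positive signature genes — with an optional mode additionally gating
membership on a per-set signature-score threshold.

Exposed as a scikit-learn style estimator (:class:`CoexpressionFateClassifier`)
whose :meth:`predict` returns the class label per cell; the module functions
wrap it and add the per-stage summaries (class intersection counts, tissue
distribution with an LPM share, focal expression by class).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import GeneSet
from .profile import CellSubset, gene_vector

__all__ = [
    "CLASS_LABELS",
    "CoexpressionFateClassifier",
    "classify_cells",
    "intersect_summary",
    "tissue_distribution",
    "lpm_share",
    "expression_by_class",
]

CLASS_LABELS = ("A-only", "B-only", "both", "neither")


class CoexpressionFateClassifier(BaseEstimator, ClassifierMixin):
    """Assign cells to fate classes by signature co-expression counts.

    Parameters
    ----------
    set_a, set_b : GeneSet
        The two signatures (e.g. smooth-muscle and mesothelium).
    min_genes : int, default 3
        Minimum number of positive (> 0) signature genes for membership.
    focal_gene : str, optional
        Excluded from both signatures even if listed in one.

    Attributes
    ----------
    classes_ : ndarray of str
        The four class labels.
    idx_a_, idx_b_ : ndarray of int
        Column indices of each signature's genes in the fitted universe.
    """

    def __init__(
        self,
        set_a: GeneSet | None = None,
        set_b: GeneSet | None = None,
        min_genes: int = 3,
        focal_gene: str | None = None,
    ):
        self.set_a = set_a
        self.set_b = set_b
        self.min_genes = min_genes
        self.focal_gene = focal_gene

    def fit(self, X, y=None, *, gene_names: Sequence[str] | None = None):
        if isinstance(X, AnnData):
            gene_names = np.asarray(X.var_names)
            X = X.X
        if gene_names is None:
            raise ValueError("gene_names required when X is a plain array")
        if self.set_a is None or self.set_b is None:
            raise ValueError("both gene sets are required")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        genes_a = [g for g in self.set_a.genes if g != self.focal_gene]
        genes_b = [g for g in self.set_b.genes if g != self.focal_gene]
        shared = set(genes_a) & set(genes_b)
        if shared and len(shared) > 0.5 * min(len(genes_a), len(genes_b)):
            warnings.warn(
                f"gene sets share {len(shared)} genes (> 50%): "
                "classification is confounded"
            )
        index = {g: j for j, g in enumerate(gene_names)}
        self.idx_a_ = np.array([index[g] for g in genes_a if g in index], dtype=int)
        self.idx_b_ = np.array([index[g] for g in genes_b if g in index], dtype=int)
        self.classes_ = np.array(CLASS_LABELS)
        return self

    def _counts(self, X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, AnnData):
            X = X.X
        if sp.issparse(X):
            X = X.tocsc()
            n_a = np.asarray((X[:, self.idx_a_] > 0).sum(axis=1)).ravel()
            n_b = np.asarray((X[:, self.idx_b_] > 0).sum(axis=1)).ravel()
        else:
            X = np.asarray(X)
            n_a = (X[:, self.idx_a_] > 0).sum(axis=1)
            n_b = (X[:, self.idx_b_] > 0).sum(axis=1)
        return n_a.astype(int), n_b.astype(int)

    def count_table(self, X) -> pd.DataFrame:
        """Per-cell positive-gene counts for both signatures."""
        n_a, n_b = self._counts(X)
        return pd.DataFrame({"n_expressed_A": n_a, "n_expressed_B": n_b})

    def predict(self, X) -> np.ndarray:
        """Class label per cell in {A-only, B-only, both, neither}."""
        n_a, n_b = self._counts(X)
        in_a = n_a >= self.min_genes
        in_b = n_b >= self.min_genes
        out = np.where(
            in_a & in_b, "both",
            np.where(in_a, "A-only", np.where(in_b, "B-only", "neither")),
        )
        return out.astype(object)


def classify_cells(
    adata: AnnData,
    subset: CellSubset,
    set_a: GeneSet,
    set_b: GeneSet,
    min_genes: int = 3,
    *,
    score_gate: Mapping[str, float] | None = None,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify the focal-positive cells by signature co-expression.

    Returns a table indexed by cell id with columns ``n_expressed_A``,
    ``n_expressed_B``, ``class``, plus ``stage`` / ``celltype`` carried over
    from the annotation.  With ``score_gate`` (set name → AUC threshold) and
    a ``scores`` table, membership additionally requires the cell's
    signature score to exceed the gate — the alternative reading in which
    the count threshold is combined with enrichment-score selection.
    """
    clf = CoexpressionFateClassifier(
        set_a, set_b, min_genes=min_genes, focal_gene=subset.focal_gene
    ).fit(adata)
    member = subset.mask(adata)
    sub = adata[member]
    table = clf.count_table(sub)
    table.index = sub.obs_names
    in_a = table["n_expressed_A"].to_numpy() >= min_genes
    in_b = table["n_expressed_B"].to_numpy() >= min_genes
    if score_gate is not None:
        if scores is None:
            raise ValueError("score_gate requires the scores table")
        s = scores.loc[table.index]
        in_a &= s[set_a.name].to_numpy() > score_gate[set_a.name]
        in_b &= s[set_b.name].to_numpy() > score_gate[set_b.name]
    table["class"] = np.where(
        in_a & in_b, "both",
        np.where(in_a, "A-only", np.where(in_b, "B-only", "neither")),
    )
    for col in ("stage", "celltype"):
        if col in adata.obs:
            table[col] = adata.obs.loc[table.index, col].values
    return table


def intersect_summary(classification: pd.DataFrame) -> pd.DataFrame:
    """Per-stage counts of the four classes; rows sum to the subset size."""
    rows = []
    for stage, grp in classification.groupby("stage", observed=True, sort=True):
        counts = grp["class"].value_counts()
        rows.append(
            (stage, *[int(counts.get(c, 0)) for c in CLASS_LABELS], len(grp))
        )
    return pd.DataFrame(
        rows, columns=["stage", "A_only", "B_only", "both", "neither", "n_subset"]
    )


def tissue_distribution(
    classification: pd.DataFrame, *, min_tissue_count: int = 0
) -> pd.DataFrame:
    """Per (stage, class, tissue) counts and within-class percentages.

    Tissues with fewer than ``min_tissue_count`` cells in a (stage, class)
    stratum are collapsed into ``'other'``, following the figure-legend
    convention for small tissues.
    """
    rows = []
    grouped = classification.groupby(["stage", "class"], observed=True, sort=True)
    for (stage, cls), grp in grouped:
        counts = grp["celltype"].value_counts()
        if min_tissue_count > 0:
            small = counts[counts < min_tissue_count]
            if len(small):
                counts = counts[counts >= min_tissue_count]
                counts["other"] = small.sum()
        total = counts.sum()
        for tissue, n in counts.items():
            rows.append((stage, cls, tissue, int(n), 100.0 * n / total))
    return pd.DataFrame(
        rows, columns=["stage", "class", "tissue", "count", "percent_within_class"]
    )


def lpm_share(
    tissue_table: pd.DataFrame, stage: str, cls: str, lpm_label: str = "LPM"
) -> float:
    """Percentage of a class's cells located in the LPM-like tissue."""
    sel = tissue_table[
        (tissue_table["stage"] == stage)
        & (tissue_table["class"] == cls)
        & (tissue_table["tissue"] == lpm_label)
    ]
    return float(sel["percent_within_class"].iloc[0]) if len(sel) else 0.0


def expression_by_class(
    classification: pd.DataFrame,
    adata: AnnData,
    focal_gene: str,
    *,
    exclude_dual: bool = False,
) -> pd.DataFrame:
    """Focal-gene expression per class per stage: n and median.

    ``exclude_dual`` removes the ``both`` class, the convention used when
    comparing the two single-signature populations.
    """
    expr = pd.Series(gene_vector(adata, focal_gene), index=adata.obs_names)
    table = classification.copy()
    table["focal_expression"] = expr.loc[table.index].values
    if exclude_dual:
        table = table[table["class"] != "both"]
    rows = []
    for (stage, cls), grp in table.groupby(["stage", "class"], observed=True, sort=True):
        vals = grp["focal_expression"].to_numpy()
        rows.append((stage, cls, len(vals), float(np.median(vals))))
    return pd.DataFrame(rows, columns=["stage", "class", "n", "median_expression"])
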