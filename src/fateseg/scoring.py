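"""Rank-based recovery-curve signature scoring (the AUCell statistic).

For each cell, genes are ranked by decreasing expression (ties broken by a
seeded shuffle).  A signature's score is the area under the step "recovery
curve" — the cumulative count of signature genes encountered while
descending the ranking — evaluated over the top ``top_fraction`` of the
ranking and normalized so a perfectly front-loaded signature scores 1.

The scorer is exposed as a scikit-learn style transformer
(:class:`AUCellScorer`) mapping a cells × genes matrix to a cells × sets
score matrix; the module functions are thin wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

from .io import GeneSet

__all__ = [
    "AUCellScorer",
    "rank_cells",
    "auc_score",
    "ThresholdSuggestion",
    "suggest_thresholds",
    "enrichment_summary",
]


def _as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        return X.toarray()
    return np.asarray(X, dtype=float)


class AUCellScorer(BaseEstimator, TransformerMixin):
    """Recovery-curve AUC scoring of gene signatures per cell.

    Parameters
    ----------
    gene_sets : sequence of GeneSet
        Signatures to score.
    top_fraction : float, default 0.05
        Fraction of the ranking over which the recovery curve is integrated.
    tie_seed : int, default 0
        Seed of the uniform shuffle breaking expression ties within a cell.

    Attributes
    ----------
    gene_names_ : ndarray of str
        Gene universe seen at fit time.
    max_rank_ : int
        ``floor(top_fraction * n_genes)``, the integration limit.
    set_indices_ : dict of str -> ndarray of int
        Column indices of each signature's genes present in the universe.

    Notes
    -----
    The AUC depends only on each cell's ranking, not on the expression
    values themselves.  With signature gene ranks :math:`r_1 < r_2 < \\dots`
    and integration limit :math:`R`, the rectangle area under the step curve
    is :math:`\\sum_{r_i \\le R} (R - r_i + 1)`, normalized by the area of a
    signature occupying ranks :math:`1..k`.
    """

    def __init__(
        self,
        gene_sets: Sequence[GeneSet] = (),
        top_fraction: float = 0.05,
        tie_seed: int = 0,
    ):
        self.gene_sets = gene_sets
        self.top_fraction = top_fraction
        self.tie_seed = tie_seed

    def _validate(self, X, gene_names):
        if isinstance(X, AnnData):
            gene_names = np.asarray(X.var_names)
            X = X.X
        if gene_names is None:
            raise ValueError("gene_names required when X is a plain array")
        gene_names = np.asarray(gene_names)
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        return X, gene_names

    def fit(self, X, y=None, *, gene_names: Sequence[str] | None = None):
        X, gene_names = self._validate(X, gene_names)
        n_genes = X.shape[1]
        if n_genes != len(gene_names):
            raise ValueError("gene_names length does not match matrix width")
        self.gene_names_ = gene_names
        self.n_genes_ = n_genes
        self.max_rank_ = int(np.floor(self.top_fraction * n_genes))
        if self.max_rank_ < 1:
            raise ValueError(
                f"top_fraction {self.top_fraction} leaves no ranks over {n_genes} genes"
            )
        index = {g: j for j, g in enumerate(gene_names)}
        self.set_indices_ = {}
        for gset in self.gene_sets:
            idx = np.array([index[g] for g in gset.genes if g in index], dtype=int)
            if idx.size == 0:
                raise ValueError(
                    f"gene set {gset.name!r} shares no genes with the matrix"
                )
            if idx.size < len(gset.genes):
                warnings.warn(
                    f"gene set {gset.name!r}: {len(gset.genes) - idx.size} genes "
                    "absent from the matrix"
                )
            self.set_indices_[gset.name] = idx
        return self

    def rank(self, X, *, gene_names: Sequence[str] | None = None) -> np.ndarray:
        """Per-cell 1-based rank of every gene by decreasing expression."""
        X, _ = self._validate(X, gene_names if gene_names is not None
                              else getattr(self, "gene_names_", None))
        dense = _as_dense(X)
        rng = np.random.default_rng(self.tie_seed)
        tie_keys = rng.random(dense.shape)
        # lexsort: primary key -expression, secondary the random tie key
        order = np.lexsort((tie_keys, -dense), axis=1)
        ranks = np.empty_like(order)
        n = dense.shape[1]
        rows = np.arange(dense.shape[0])[:, None]
        ranks[rows, order] = np.arange(1, n + 1)[None, :]
        return ranks

    def transform(self, X) -> np.ndarray:
        """Score matrix of shape (n_cells, n_gene_sets), values in [0, 1]."""
        ranks = self.rank(X)
        R = self.max_rank_
        out = np.zeros((ranks.shape[0], len(self.set_indices_)))
        for j, (name, idx) in enumerate(self.set_indices_.items()):
            set_ranks = ranks[:, idx]
            area = np.where(set_ranks <= R, R - set_ranks + 1, 0).sum(axis=1)
            k = min(idx.size, R)
            max_area = k * R - k * (k - 1) // 2  # ranks 1..k
            out[:, j] = area / max_area
        return out

    def score_table(self, adata: AnnData) -> pd.DataFrame:
        """Scores as a cells × sets DataFrame indexed like ``adata.obs``."""
        self.fit(adata)
        scores = self.transform(adata)
        return pd.DataFrame(scores, index=adata.obs_names,
                            columns=list(self.set_indices_))


def rank_cells(adata: AnnData, tie_seed: int = 0) -> np.ndarray:
    """Per-cell gene ranking by decreasing expression (1-based)."""
    return AUCellScorer(tie_seed=tie_seed).rank(adata)


def auc_score(
    adata: AnnData,
    gene_sets: Sequence[GeneSet],
    top_fraction: float = 0.05,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Recovery-curve AUC per (cell, gene set)."""
    return AUCellScorer(gene_sets, top_fraction, tie_seed).score_table(adata)


@dataclass
class ThresholdSuggestion:
    """Candidate score thresholds for one gene set and the selected one."""

    candidates: dict[str, float]
    selected: float
    mode: str  # "auto" | "manual"


def _mixture_boundary(scores: np.ndarray, seed: int = 0) -> float:
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(scores.reshape(-1, 1))
    means = np.sort(gm.means_.ravel())
    grid = np.linspace(means[0], means[1], 512)
    post = gm.predict_proba(grid.reshape(-1, 1))
    lo_comp = int(np.argmin(gm.means_.ravel()))
    crossing = np.argmin(np.abs(post[:, lo_comp] - 0.5))
    return float(grid[crossing])


def _density_inflection(scores: np.ndarray) -> float:
    kde = stats.gaussian_kde(scores)
    grid = np.linspace(scores.min(), scores.max(), 512)
    dens = kde(grid)
    # deepest local minimum between the outermost modes
    maxima = [i for i in range(1, 511) if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1]]
    if len(maxima) >= 2:
        lo, hi = maxima[0], maxima[-1]
        inner = slice(lo, hi + 1)
        return float(grid[inner][np.argmin(dens[inner])])
    return float(np.median(scores))


def suggest_thresholds(
    scores: np.ndarray | pd.Series,
    mode: str = "auto",
    manual_value: float | None = None,
    seed: int = 0,
) -> ThresholdSuggestion:
    """Candidate AUC thresholds for one gene set.

    Candidates: the top-1% quantile of a global normal fit, the density
    inflection between modes, and the 2-component Gaussian-mixture boundary.
    ``mode='auto'`` selects the mixture boundary; ``mode='manual'`` requires
    an explicit ``manual_value`` inside the observed score range.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 10:
        raise ValueError("need at least 10 scored cells to suggest thresholds")
    lo, hi = float(scores.min()), float(scores.max())
    if np.isclose(lo, hi):
        warnings.warn("constant scores: single degenerate threshold candidate")
        candidates = {"constant": lo}
        selected = lo if mode == "auto" else _check_manual(manual_value, lo, hi)
        return ThresholdSuggestion(candidates, selected, mode)
    candidates = {
        "global_q99": float(scores.mean() + stats.norm.ppf(0.99) * scores.std(ddof=1)),
        "density_inflection": _density_inflection(scores),
        "mixture_boundary": _mixture_boundary(scores, seed),
    }
    if mode == "auto":
        selected = candidates["mixture_boundary"]
        selected = float(np.clip(selected, lo, hi))
    elif mode == "manual":
        selected = _check_manual(manual_value, lo, hi)
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return ThresholdSuggestion(candidates, selected, mode)


def _check_manual(value: float | None, lo: float, hi: float) -> float:
    if value is None:
        raise ValueError("manual threshold mode requires an explicit value")
    if not lo <= value <= hi:
        raise ValueError(f"manual threshold {value} outside observed range [{lo}, {hi}]")
    return float(value)


def enrichment_summary(
    scores: pd.DataFrame,
    adata: AnnData,
    thresholds: dict[str, float],
    cell_ids: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-stage proportion of cells above threshold and mean score per set.

    ``scores`` is a cells × sets table; ``cell_ids`` restricts to a subset
    (e.g. the focal-positive cells).
    """
    if cell_ids is not None:
        scores = scores.loc[scores.index.intersection(cell_ids)]
    stage = adata.obs.loc[scores.index, "stage"]
    rows = []
    for st, idx in scores.groupby(stage, observed=True, sort=True).groups.items():
        block = scores.loc[idx]
        for set_name in scores.columns:
            thr = thresholds[set_name]
            vals = block[set_name].to_numpy()
            rows.append(
                (st, set_name, len(vals), float((vals > thr).mean()),
                 float(vals.mean()))
            )
    return pd.DataFrame(
        rows, columns=["stage", "gene_set", "n", "proportion_above", "mean_score"]
    )
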