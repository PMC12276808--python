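"""Recovery-curve AUC scoring against brute-force step-curve integration."""

import itertools

import numpy as np
import pytest

from fateseg import AUCellScorer, GeneSet, auc_score, suggest_thresholds
from tests.conftest import make_adata


def brute_force_auc(positions, n_genes, top_fraction):
    """Literal step-curve integration: cumulative hit count over ranks 1..R."""
    R = int(np.floor(top_fraction * n_genes))
    hits = np.zeros(n_genes + 1)
    for p in positions:
        hits[p] = 1
    curve = np.cumsum(hits)[1 : R + 1]
    best = np.cumsum([1] * min(len(positions), n_genes))[: R]
    best = np.concatenate([best, np.full(max(0, R - len(best)), min(len(positions), R))])
    return curve.sum() / best.sum()


def adata_with_ranking(order, genes):
    """One cell whose expression strictly decreases along ``order``."""
    vals = np.zeros((1, len(genes)))
    for rank, gi in enumerate(order):
        vals[0, gi] = len(genes) - rank
    return make_adata(vals, genes)


def test_toy_ranking_matches_oracle():
    """Signature at ranks {1,3,5} of 10 genes, top half: AUC = 9/12."""
    genes = [f"g{i}" for i in range(10)]
    order = list(range(10))  # g0 highest ... g9 lowest
    adata = adata_with_ranking(order, genes)
    sig = GeneSet("S", ["g0", "g2", "g4"])  # ranks 1, 3, 5
    scores = auc_score(adata, [sig], top_fraction=0.5)
    expected = brute_force_auc([1, 3, 5], 10, 0.5)
    assert expected == pytest.approx(0.75)
    assert scores.iloc[0, 0] == pytest.approx(expected)


@pytest.mark.parametrize("top_fraction", [0.3, 0.5, 1.0])
def test_all_3gene_signatures_of_10_match_oracle(top_fraction):
    """Exhaustive check over every 3-gene signature placement in 10 ranks."""
    genes = [f"g{i}" for i in range(10)]
    adata = adata_with_ranking(list(range(10)), genes)
    for positions in itertools.combinations(range(1, 11), 3):
        sig = GeneSet("S", [genes[p - 1] for p in positions])
        got = auc_score(adata, [sig], top_fraction=top_fraction).iloc[0, 0]
        want = brute_force_auc(list(positions), 10, top_fraction)
        assert got == pytest.approx(want), positions


def test_front_loaded_signature_scores_one_and_absent_scores_zero():
    genes = [f"g{i}" for i in range(20)]
    adata = adata_with_ranking(list(range(20)), genes)
    top = GeneSet("top", genes[:3])
    bottom = GeneSet("bottom", genes[-3:])
    scores = auc_score(adata, [top, bottom], top_fraction=0.25)
    assert scores["top"].iloc[0] == pytest.approx(1.0)
    assert scores["bottom"].iloc[0] == pytest.approx(0.0)


def test_auc_depends_only_on_ranking():
    """Doubling all expression values leaves every score unchanged."""
    rng = np.random.default_rng(0)
    vals = rng.random((5, 40))
    genes = [f"g{i}" for i in range(40)]
    sig = GeneSet("S", genes[::7])
    a = auc_score(make_adata(vals, genes), [sig], top_fraction=0.25)
    b = auc_score(make_adata(3.5 * vals, genes), [sig], top_fraction=0.25)
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


def test_gene_order_permutation_invariance():
    rng = np.random.default_rng(1)
    vals = rng.random((4, 30))
    genes = [f"g{i}" for i in range(30)]
    sig = GeneSet("S", ["g3", "g11", "g25"])
    perm = rng.permutation(30)
    a = auc_score(make_adata(vals, genes), [sig], top_fraction=0.3)
    b = auc_score(make_adata(vals[:, perm], [genes[j] for j in perm]), [sig],
                  top_fraction=0.3)
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


def test_tie_break_is_seeded_and_deterministic():
    vals = np.zeros((3, 50))  # all ties
    genes = [f"g{i}" for i in range(50)]
    r1 = AUCellScorer(tie_seed=5).rank(make_adata(vals, genes))
    r2 = AUCellScorer(tie_seed=5).rank(make_adata(vals, genes))
    r3 = AUCellScorer(tie_seed=6).rank(make_adata(vals, genes))
    np.testing.assert_array_equal(r1, r2)
    assert not np.array_equal(r1, r3)
    # each cell's ranks are a permutation of 1..n
    for row in r1:
        assert sorted(row) == list(range(1, 51))


def test_strictly_decreasing_cell_gets_identity_ranking():
    genes = [f"g{i}" for i in range(8)]
    adata = adata_with_ranking(list(range(8)), genes)
    ranks = AUCellScorer(tie_seed=0).rank(adata)
    np.testing.assert_array_equal(ranks[0], np.arange(1, 9))


def test_empty_intersection_raises():
    genes = [f"g{i}" for i in range(10)]
    adata = adata_with_ranking(list(range(10)), genes)
    with pytest.raises(ValueError, match="no genes"):
        auc_score(adata, [GeneSet("S", ["absent1", "absent2", "absent3"])],
                  top_fraction=0.5)


def test_threshold_between_separated_modes():
    """Two well-separated Gaussians: auto threshold falls between the means."""
    rng = np.random.default_rng(3)
    scores = np.concatenate([rng.normal(0.1, 0.02, 400), rng.normal(0.7, 0.05, 100)])
    sug = suggest_thresholds(scores, seed=0)
    assert 0.1 < sug.selected < 0.7
    assert set(sug.candidates) == {"global_q99", "density_inflection", "mixture_boundary"}


def test_constant_scores_single_candidate():
    with pytest.warns(UserWarning, match="constant"):
        sug = suggest_thresholds(np.full(50, 0.3))
    assert sug.candidates == {"constant": pytest.approx(0.3)}
    assert sug.selected == pytest.approx(0.3)


def test_manual_threshold_outside_range_rejected():
    rng = np.random.default_rng(4)
    scores = rng.random(100)
    with pytest.raises(ValueError, match="outside observed range"):
        suggest_thresholds(scores, mode="manual", manual_value=2.0)


def test_enrichment_summary_proportions():
    from fateseg import enrichment_summary
    import pandas as pd

    scores = pd.DataFrame(
        {"SMC": [0.1, 0.4, 0.9, 0.8], "MC": [0.0, 0.1, 0.2, 0.1]},
        index=["c0", "c1", "c2", "c3"],
    )
    adata = make_adata(np.zeros((4, 1)), ["Wt1"], cells=list(scores.index),
                       obs={"stage": ["E8.5"] * 4, "celltype": ["LPM"] * 4})
    # threshold above the max -> proportion 0; below the min -> proportion 1
    table = enrichment_summary(scores, adata, {"SMC": 1.5, "MC": -0.1})
    by = table.set_index("gene_set")
    assert by.loc["SMC", "proportion_above"] == 0.0
    assert by.loc["MC", "proportion_above"] == 1.0


def test_planted_majority_set_more_enriched(atlas):
    """With more A-only than B-only cells planted, the A set is expressed
    above threshold in a larger proportion of focal cells."""
    from fateseg import enrichment_summary, identify_focal_cells

    adata, truth = atlas
    subset = identify_focal_cells(adata, truth.focal_gene)
    scores = auc_score(adata[subset.mask(adata)], list(truth.gene_sets))
    thr = {s.name: 0.2 for s in truth.gene_sets}
    table = enrichment_summary(scores, adata, thr)
    pooled = table.groupby("gene_set").apply(
        lambda g: np.average(g["proportion_above"], weights=g["n"]),
        include_groups=False)
    assert pooled["SMC"] > pooled["MC"]
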