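"""Synthetic data with known ground truth.

Two generators back the test suite and the worked examples:

* :func:`generate_atlas` — an annotated cell × gene log-CPM expression matrix
  emulating the statistical structure of a gastrulation-stage single-cell
  atlas: a rare focal-gene-positive population (fraction rising across
  stages), stage-dependent cell-type composition with a designated LPM-like
  tissue, and planted subclasses of focal-positive cells co-expressing genes
  of one, both, or neither of two 15-gene signatures.

* :func:`generate_vessel_volume` — a 3-D intensity stack containing a
  rasterized random branching tree of tubes over a smooth background gradient
  with additive Gaussian noise, with the centerline voxels and the
  end-point / junction counts recorded as ground truth.

Positive expression values are drawn zero-inflated log-normal on the log-CPM
scale; signature genes of a member cell are multiplicatively coupled to the
cell's focal-gene level so that within-class correlations are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.sparse as sp
from anndata import AnnData

from .io import DEFAULT_STAGES, GeneSet

__all__ = [
    "ConfigurationError",
    "AtlasConfig",
    "AtlasGroundTruth",
    "generate_atlas",
    "VesselGroundTruth",
    "generate_vessel_volume",
    "rasterize_tree",
    "y_tree",
    "straight_tube",
]

CLASS_LABELS = ("A-only", "B-only", "both", "neither")


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


def _default_composition(n_stages: int) -> np.ndarray:
    # epiblast-dominated early, LPM-dominated late; primitive streak peaks
    # mid-gastrulation.  Columns: epiblast, primitive_streak, LPM,
    # paraxial_mesoderm, ExE_ectoderm.
    t = np.linspace(0.0, 1.0, n_stages)
    epi = 0.65 - 0.55 * t
    ps = 0.15 + 0.25 * np.sin(np.pi * t) * (1 - t)
    lpm = 0.05 + 0.50 * t
    pm = 0.05 + 0.10 * t
    exe = np.full(n_stages, 0.10)
    comp = np.stack([epi, ps, lpm, pm, exe], axis=1)
    return comp / comp.sum(axis=1, keepdims=True)


@dataclass
class AtlasConfig:
    """Parameters of the synthetic atlas.

    ``focal_fraction`` defaults to a linear ramp over 0.65%–1.66% across the
    stages; ``focal_mean`` is the mean log-CPM level of focal-positive cells;
    ``class_probs`` governs how focal-positive cells split over the four
    co-expression classes; ``sig_gene_expr_prob`` / ``background_expr_prob``
    set how often an "on" signature gene of a member / non-member exceeds 0.
    """

    n_cells_per_stage: int = 3000
    stages: Sequence[str] = DEFAULT_STAGES
    celltypes: Sequence[str] = (
        "epiblast", "primitive_streak", "LPM", "paraxial_mesoderm", "ExE_ectoderm",
    )
    composition: np.ndarray | None = None  # (n_stages, n_celltypes) weights
    lpm_celltype: str = "LPM"
    focal_gene: str = "Wt1"
    focal_fraction: Sequence[float] | None = None  # per stage
    focal_mean: float = 1.0
    focal_sigma: float = 0.25
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"A-only": 0.10, "B-only": 0.08, "both": 0.02, "neither": 0.80}
    )
    classed_lpm_prob: float = 0.8  # classed focal cells relocated to the LPM-like tissue
    n_signature_genes: int = 15
    sig_gene_expr_prob: float = 0.9
    background_expr_prob: float = 0.02
    n_noise_genes: int = 400
    noise_expr_prob: float = 0.05
    samples_per_stage: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_stage <= 0:
            raise ConfigurationError("n_cells_per_stage must be positive")
        if self.composition is None:
            self.composition = _default_composition(len(self.stages))
        self.composition = np.asarray(self.composition, dtype=float)
        if self.composition.shape != (len(self.stages), len(self.celltypes)):
            raise ConfigurationError(
                "composition must be (n_stages, n_celltypes) "
                f"= {(len(self.stages), len(self.celltypes))}, got {self.composition.shape}"
            )
        if (self.composition < 0).any():
            raise ConfigurationError("composition weights must be non-negative")
        if self.lpm_celltype not in self.celltypes:
            raise ConfigurationError(f"lpm_celltype {self.lpm_celltype!r} not in celltypes")
        if self.focal_fraction is None:
            self.focal_fraction = np.linspace(0.0065, 0.0166, len(self.stages))
        self.focal_fraction = np.asarray(self.focal_fraction, dtype=float)
        if self.focal_fraction.shape != (len(self.stages),):
            raise ConfigurationError("focal_fraction must give one value per stage")
        if ((self.focal_fraction < 0) | (self.focal_fraction >= 1)).any():
            raise ConfigurationError("focal_fraction values must lie in [0, 1)")
        if set(self.class_probs) - set(CLASS_LABELS):
            raise ConfigurationError(f"class_probs keys must be among {CLASS_LABELS}")
        p = np.array([self.class_probs.get(c, 0.0) for c in CLASS_LABELS], dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ConfigurationError("class_probs must be non-negative and sum to 1")
        for name in ("sig_gene_expr_prob", "background_expr_prob", "noise_expr_prob",
                     "classed_lpm_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_signature_genes < 1 or self.n_noise_genes < 0:
            raise ConfigurationError("invalid gene counts")


@dataclass
class AtlasGroundTruth:
    """Planted truth for one synthetic atlas."""

    cells: pd.DataFrame  # index cell_id; columns focal_positive, true_class
    gene_sets: tuple[GeneSet, GeneSet]
    focal_gene: str

    def to_json_dict(self) -> dict:
        return {
            "focal_gene": self.focal_gene,
            "gene_sets": {s.name: list(s.genes) for s in self.gene_sets},
            "cells": {
                "cell_id": self.cells.index.tolist(),
                "focal_positive": self.cells["focal_positive"].astype(bool).tolist(),
                "true_class": self.cells["true_class"].tolist(),
            },
        }


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    """Log-normal values with arithmetic mean ``mean``."""
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size)


def generate_atlas(config: AtlasConfig) -> tuple[AnnData, AtlasGroundTruth]:
    """Draw one synthetic annotated atlas.

    Returns an AnnData whose ``obs`` carries ``stage``, ``celltype`` and
    ``sample``, plus the planted ground truth.  Fixing ``config.seed`` fixes
    the output bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n_sig = config.n_signature_genes
    set_a = GeneSet("SMC", [f"SmcSig{i:02d}" for i in range(1, n_sig + 1)], "synthetic")
    set_b = GeneSet("MC", [f"McSig{i:02d}" for i in range(1, n_sig + 1)], "synthetic")
    noise_genes = [f"Gene{i:04d}" for i in range(1, config.n_noise_genes + 1)]
    genes = [config.focal_gene] + set_a.genes + set_b.genes + noise_genes
    gene_index = {g: j for j, g in enumerate(genes)}

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    obs_records: list[tuple[str, str, str, str]] = []
    truth_records: list[tuple[str, bool, str]] = []

    def emit(cell_row: int, gene_names: Sequence[str], values: np.ndarray) -> None:
        if len(gene_names) == 0:
            return
        rows.append(np.full(len(gene_names), cell_row))
        cols.append(np.array([gene_index[g] for g in gene_names]))
        vals.append(np.asarray(values, dtype=float))

    n_total = 0
    for si, stage in enumerate(config.stages):
        n = config.n_cells_per_stage
        comp = config.composition[si] / config.composition[si].sum()
        celltypes = rng.choice(config.celltypes, size=n, p=comp)
        samples = rng.integers(1, config.samples_per_stage + 1, size=n)
        focal_pos = rng.random(n) < config.focal_fraction[si]
        classes = np.full(n, "", dtype=object)
        p = np.array([config.class_probs.get(c, 0.0) for c in CLASS_LABELS])
        classes[focal_pos] = rng.choice(CLASS_LABELS, size=int(focal_pos.sum()), p=p)
        # classed focal cells preferentially sit in the LPM-like tissue
        classed = focal_pos & (classes != "neither") & (classes != "")
        relocate = classed & (rng.random(n) < config.classed_lpm_prob)
        celltypes[relocate] = config.lpm_celltype

        focal_vals = np.zeros(n)
        npos = int(focal_pos.sum())
        focal_vals[focal_pos] = _lognormal(rng, config.focal_mean, config.focal_sigma, npos)

        for i in range(n):
            row = n_total + i
            cell_id = f"cell_{stage}_{i:05d}"
            obs_records.append((cell_id, stage, celltypes[i], f"{stage}_s{samples[i]}"))
            truth_records.append(
                (cell_id, bool(focal_pos[i]), classes[i] if focal_pos[i] else "")
            )
            if focal_pos[i]:
                emit(row, [config.focal_gene], np.array([focal_vals[i]]))
                cls = classes[i]
                for gset, member in ((set_a, cls in ("A-only", "both")),
                                     (set_b, cls in ("B-only", "both"))):
                    p_on = config.sig_gene_expr_prob if member else config.background_expr_prob
                    on = rng.random(len(gset)) < p_on
                    if member:
                        # couple to the focal level -> positive within-class correlation
                        v = focal_vals[i] * rng.lognormal(0.0, 0.2, int(on.sum()))
                    else:
                        v = _lognormal(rng, 0.5, 0.5, int(on.sum()))
                    emit(row, list(np.asarray(gset.genes)[on]), v)
            else:
                for gset in (set_a, set_b):
                    on = rng.random(len(gset)) < config.background_expr_prob
                    v = _lognormal(rng, 0.5, 0.5, int(on.sum()))
                    emit(row, list(np.asarray(gset.genes)[on]), v)
            on = rng.random(len(noise_genes)) < config.noise_expr_prob
            v = _lognormal(rng, 0.8, 0.6, int(on.sum()))
            emit(row, list(np.asarray(noise_genes)[on]), v)
        n_total += n

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        v = np.concatenate(vals)
    else:  # pragma: no cover - n_cells_per_stage >= 1 always
        r = c = v = np.empty(0)
    X = sp.coo_matrix((v, (r, c)), shape=(n_total, len(genes))).tocsr()

    obs = pd.DataFrame(
        obs_records, columns=["cell_id", "stage", "celltype", "sample"]
    ).set_index("cell_id")
    obs["stage"] = pd.Categorical(obs["stage"], categories=list(config.stages), ordered=True)
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))

    truth = pd.DataFrame(
        truth_records, columns=["cell_id", "focal_positive", "true_class"]
    ).set_index("cell_id")
    return adata, AtlasGroundTruth(cells=truth, gene_sets=(set_a, set_b),
                                   focal_gene=config.focal_gene)


# ---------------------------------------------------------------------------
# 3-D vessel volumes


@dataclass
class VesselGroundTruth:
    """Planted truth for one synthetic vessel volume."""

    centerline: np.ndarray  # boolean, same shape as the volume
    n_endpoints: int
    n_junctions: int
    n_segments: int

    def to_json_dict(self) -> dict:
        zz, yy, xx = np.nonzero(self.centerline)
        return {
            "n_endpoints": self.n_endpoints,
            "n_junctions": self.n_junctions,
            "n_segments": self.n_segments,
            "shape": list(self.centerline.shape),
            "centerline_voxels": np.stack([zz, yy, xx], axis=1).tolist(),
        }


def _segment_voxels(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    length = float(np.linalg.norm(p1 - p0))
    n = max(2, int(np.ceil(length * 4)))
    pts = p0[None, :] + np.linspace(0, 1, n)[:, None] * (p1 - p0)[None, :]
    return np.unique(np.rint(pts).astype(int), axis=0)


def rasterize_tree(
    graph: nx.Graph,
    shape: tuple[int, int, int],
    radius: float,
    noise_sd: float,
    seed: int,
    *,
    amplitude: float = 100.0,
    background_scale: float = 0.15,
) -> tuple[np.ndarray, VesselGroundTruth]:
    """Rasterize a tube tree into an intensity volume.

    Nodes of ``graph`` carry a ``pos`` attribute (z, y, x).  A voxel is tube
    foreground iff its Euclidean distance to the centerline polyline is
    ``<= radius``.  A smooth linear background gradient and additive Gaussian
    noise are superimposed.  End-points are nodes of degree ≤ 1, junctions
    nodes of degree ≥ 3.
    """
    if radius < 1:
        raise ConfigurationError("radius must be >= 1 voxel")
    rng = np.random.default_rng(seed)
    center = np.zeros(shape, dtype=bool)
    for u, v in graph.edges():
        p0 = np.asarray(graph.nodes[u]["pos"], dtype=float)
        p1 = np.asarray(graph.nodes[v]["pos"], dtype=float)
        vox = _segment_voxels(p0, p1)
        ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        vox = vox[ok]
        center[vox[:, 0], vox[:, 1], vox[:, 2]] = True

    if center.any():
        dist = ndi.distance_transform_edt(~center)
        tube = dist <= radius
    else:
        tube = center

    zz = np.linspace(0.0, 1.0, shape[0])[:, None, None]
    yy = np.linspace(0.0, 1.0, shape[1])[None, :, None]
    background = amplitude * background_scale * (0.5 * zz + 0.5 * yy)
    volume = tube * amplitude + background
    if noise_sd > 0:
        volume = volume + rng.normal(0.0, noise_sd, shape)

    degrees = dict(graph.degree())
    truth = VesselGroundTruth(
        centerline=center,
        n_endpoints=sum(1 for d in degrees.values() if d <= 1),
        n_junctions=sum(1 for d in degrees.values() if d >= 3),
        n_segments=graph.number_of_edges(),
    )
    return volume.astype(np.float32), truth


def _random_tree(n_branches: int, shape: tuple[int, int, int],
                 rng: np.random.Generator) -> nx.Graph:
    g: nx.Graph = nx.Graph()
    if n_branches == 0:
        return g
    lo = np.array(shape) * 0.25
    hi = np.array(shape) * 0.75
    start = rng.uniform(lo, hi)
    g.add_node(0, pos=tuple(start))
    seg_len = min(shape) * 0.28
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    g.add_node(1, pos=tuple(np.clip(start + direction * seg_len, 1, np.array(shape) - 2)))
    g.add_edge(0, 1)
    next_id = 2
    for _ in range(n_branches - 1):
        # attach at the far node of a random existing segment
        u, v = list(g.edges())[rng.integers(g.number_of_edges())]
        anchor = np.asarray(g.nodes[v]["pos"])
        parent = np.asarray(g.nodes[u]["pos"])
        d = anchor - parent
        d = d / (np.linalg.norm(d) + 1e-9)
        perturb = rng.normal(size=3)
        perturb -= perturb.dot(d) * d
        perturb /= np.linalg.norm(perturb) + 1e-9
        angle = rng.uniform(np.pi / 6, np.pi / 3)
        new_dir = np.cos(angle) * d + np.sin(angle) * perturb
        end = np.clip(anchor + new_dir * seg_len * rng.uniform(0.6, 1.0),
                      1, np.array(shape) - 2)
        g.add_node(next_id, pos=tuple(end))
        g.add_edge(v, next_id)
        next_id += 1
    return g


def generate_vessel_volume(
    n_branches: int,
    radius: float = 2.0,
    noise_sd: float = 3.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
) -> tuple[np.ndarray, VesselGroundTruth]:
    """Random branching tube tree rasterized into a noisy intensity volume.

    ``n_branches`` is the number of tube segments; 0 yields pure
    background + noise with an empty ground-truth skeleton.
    """
    if n_branches < 0:
        raise ConfigurationError("n_branches must be >= 0")
    rng = np.random.default_rng(seed)
    graph = _random_tree(n_branches, shape, rng)
    return rasterize_tree(graph, shape, radius, noise_sd, seed + 1)


def straight_tube(
    shape: tuple[int, int, int] = (48, 48, 48),
    radius: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, VesselGroundTruth]:
    """A single axis-aligned tube: 2 end-points, 0 junctions by construction."""
    g: nx.Graph = nx.Graph()
    z = shape[0] // 2
    y = shape[1] // 2
    g.add_node(0, pos=(z, y, 6))
    g.add_node(1, pos=(z, y, shape[2] - 7))
    g.add_edge(0, 1)
    return rasterize_tree(g, shape, radius, noise_sd, seed)


def y_tree(
    shape: tuple[int, int, int] = (56, 56, 56),
    radius: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, VesselGroundTruth]:
    """A Y-shaped tree of three segments: 3 end-points, 1 junction."""
    g: nx.Graph = nx.Graph()
    z = shape[0] // 2
    mid = (z, shape[1] // 2, shape[2] // 2)
    g.add_node(0, pos=(z, shape[1] - 8, shape[2] // 2))
    g.add_node(1, pos=mid)
    g.add_node(2, pos=(z, 8, 10))
    g.add_node(3, pos=(z, 8, shape[2] - 11))
    g.add_edge(0, 1)
    g.add_edge(1, 2)
    g.add_edge(1, 3)
    return rasterize_tree(g, shape, radius, noise_sd, seed)
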