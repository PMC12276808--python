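"""3-D vascular network morphometry.

The processing chain mirrors the standard whole-mount workflow: rolling-ball
background subtraction (applied slice-wise, the convention of the ImageJ
family), 3-D median filtering, thresholding (explicit value, or Otsu),
volume density per region of interest, topology-preserving 3-D thinning
(Lee-style), and skeleton-voxel classification under 26-connectivity:
a voxel with fewer than 2 skeleton neighbors is an end-point, exactly 2 a
slab, more than 2 a junction.  Adjacent junction voxels are merged into
single junction nodes before node counting, so a thick crossing counts once.

Group-level outputs are the per-embryo mean density, the group standard
deviation (n−1 denominator) and the coefficient of variation
CV% = 100·s.d./mean, plus a PCA-based batch check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import ball, skeletonize
from skimage.restoration import rolling_ball
from sklearn.decomposition import PCA

__all__ = [
    "ROI",
    "preprocess",
    "density",
    "SkeletonVolume",
    "skeletonize3d",
    "classify_voxels",
    "group_variability",
    "batch_pca",
]

VOXEL_CLASSES = {0: "background", 1: "end-point", 2: "slab", 3: "junction"}


@dataclass(frozen=True)
class ROI:
    """Axis-aligned half-open box in 0-based (z, y, x) voxel coordinates."""

    name: str
    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def slices(self) -> tuple[slice, slice, slice]:
        return slice(self.z0, self.z1), slice(self.y0, self.y1), slice(self.x0, self.x1)

    def validate(self, shape: tuple[int, int, int]) -> None:
        bounds = ((self.z0, self.z1, shape[0]), (self.y0, self.y1, shape[1]),
                  (self.x0, self.x1, shape[2]))
        for lo, hi, n in bounds:
            if not (0 <= lo < hi <= n):
                raise ValueError(f"ROI {self.name!r} out of bounds for shape {shape}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ROI":
        return cls(**{k: d[k] for k in ("name", "z0", "z1", "y0", "y1", "x0", "x1")})


def preprocess(
    volume: np.ndarray,
    bg_radius: int = 15,
    median_radius: int = 1,
    threshold: float | str = "auto",
) -> np.ndarray:
    """Background-subtract, median-filter and binarize an intensity volume.

    ``threshold`` is an explicit intensity value (must lie inside the
    filtered intensity range) or ``'auto'`` for Otsu.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if bg_radius < 1 or median_radius < 1:
        raise ValueError("radii must be >= 1")
    subtracted = np.empty_like(volume)
    for z in range(volume.shape[0]):
        background = rolling_ball(volume[z], radius=bg_radius)
        subtracted[z] = volume[z] - background
    # ball footprint: a radius-1 median is near-identity on tubes >= 2 voxels
    # thick, unlike a full 3x3x3 cube which erodes their surface
    filtered = ndi.median_filter(subtracted, footprint=ball(median_radius))
    if threshold == "auto":
        thr = threshold_otsu(filtered)
    else:
        thr = float(threshold)
        # manual thresholds are chosen on the raw intensity scale
        lo, hi = min(0.0, float(volume.min())), float(volume.max())
        if not lo <= thr <= hi:
            raise ValueError(
                f"threshold {thr} outside intensity range [{lo:.3g}, {hi:.3g}]"
            )
    return filtered > thr


def density(binary: np.ndarray, roi: ROI | None = None) -> float:
    """Percentage of foreground voxels within the ROI (whole volume if None)."""
    binary = np.asarray(binary, dtype=bool)
    if roi is not None:
        roi.validate(binary.shape)
        binary = binary[roi.slices()]
    if binary.size == 0:
        raise ValueError("empty ROI")
    return 100.0 * float(binary.sum()) / binary.size


def _neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3, 3), dtype=int)
    kernel[1, 1, 1] = 0
    return ndi.convolve(skeleton.astype(int), kernel, mode="constant", cval=0)


@dataclass
class SkeletonVolume:
    """A one-voxel-thick skeleton with per-voxel classes.

    ``classes`` holds 0 background, 1 end-point, 2 slab, 3 junction;
    ``n_junction_nodes`` counts 26-connected clusters of junction voxels
    (merged junctions); ``branch_lengths`` are voxel counts of the maximal
    slab/end-point runs between junction clusters.
    """

    skeleton: np.ndarray
    classes: np.ndarray
    n_endpoint_voxels: int
    n_slab_voxels: int
    n_junction_voxels: int
    n_junction_nodes: int
    branch_lengths: list[int]

    @property
    def n_voxels(self) -> int:
        return int(self.skeleton.sum())


def skeletonize3d(binary: np.ndarray) -> SkeletonVolume:
    """Medial-axis skeleton via topology-preserving 3-D thinning.

    Voxels are then classified by their 26-neighbor count and adjacent
    junction voxels merged into junction nodes.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 3:
        raise ValueError("expected a 3-D binary volume")
    if not binary.any():
        empty = np.zeros_like(binary)
        return SkeletonVolume(empty, empty.astype(np.uint8), 0, 0, 0, 0, [])
    skel = skeletonize(binary, method="lee").astype(bool)
    return _classify_skeleton(skel)


def _classify_skeleton(skel: np.ndarray) -> SkeletonVolume:
    nbrs = _neighbor_counts(skel)
    classes = np.zeros(skel.shape, dtype=np.uint8)
    classes[skel & (nbrs < 2)] = 1
    classes[skel & (nbrs == 2)] = 2
    classes[skel & (nbrs > 2)] = 3
    junction_mask = classes == 3
    _, n_nodes = cc_label(junction_mask, connectivity=3, return_num=True)
    branch_mask = skel & ~junction_mask
    branch_labels, n_branches = cc_label(branch_mask, connectivity=3, return_num=True)
    lengths = sorted(
        int((branch_labels == i).sum()) for i in range(1, n_branches + 1)
    )
    return SkeletonVolume(
        skeleton=skel,
        classes=classes,
        n_endpoint_voxels=int((classes == 1).sum()),
        n_slab_voxels=int((classes == 2).sum()),
        n_junction_voxels=int((classes == 3).sum()),
        n_junction_nodes=n_nodes,
        branch_lengths=lengths,
    )


def classify_voxels(skeleton: np.ndarray | SkeletonVolume) -> dict[str, int]:
    """End-point / slab / junction voxel counts of a skeleton mask.

    Counts follow the 26-neighbor rule and always sum to the skeleton size.
    """
    if isinstance(skeleton, SkeletonVolume):
        sv = skeleton
    else:
        sv = _classify_skeleton(np.asarray(skeleton, dtype=bool))
    return {
        "end_point": sv.n_endpoint_voxels,
        "slab": sv.n_slab_voxels,
        "junction": sv.n_junction_voxels,
        "junction_nodes": sv.n_junction_nodes,
        "total": sv.n_voxels,
    }


def group_variability(
    values: Sequence[float] | pd.Series, groups: Sequence[str]
) -> pd.DataFrame:
    """Per-group mean, sample s.d. and CV% of per-embryo measurements.

    CV% = 100·s.d./mean, computed only for groups with positive mean.
    Groups with fewer than 2 embryos are rejected.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    rows = []
    for group, grp in df.groupby("group", sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"group {group!r} has {n} embryo(s); need >= 2")
        mean = float(grp["value"].mean())
        sd = float(grp["value"].std(ddof=1))
        cv = 100.0 * sd / mean if mean > 0 else float("nan")
        rows.append((group, n, mean, sd, cv))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd", "cv_percent"])


def batch_pca(
    density_table: pd.DataFrame, batches: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centered PCA of the embryo × ROI-density table, with a batch check.

    Returns the PC coordinates per embryo and a per-batch dispersion summary
    including the ratio of between-batch centroid spread to mean within-batch
    spread; a ratio near or below 1 indicates negligible batch structure.
    """
    X = density_table.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 embryos for a batch check")
    if np.allclose(X, X[0]):
        raise ValueError("constant density table: PCA undefined")
    n_comp = min(X.shape[0] - 1, X.shape[1], 2)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    coord_df = pd.DataFrame(
        coords,
        index=density_table.index,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    coord_df["batch"] = list(batches)
    coord_df["explained_variance_ratio"] = np.nan
    coord_df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()

    centroids = coord_df.groupby("batch", sort=True)[coord_df.columns[:n_comp]].mean()
    overall = coords.mean(axis=0)
    between = float(
        np.mean([np.linalg.norm(c - overall) for c in centroids.to_numpy()])
    )
    within_terms = []
    for batch, grp in coord_df.groupby("batch", sort=True):
        pts = grp[coord_df.columns[:n_comp]].to_numpy()
        within_terms.extend(np.linalg.norm(pts - centroids.loc[batch].to_numpy(), axis=1))
    within = float(np.mean(within_terms)) if within_terms else float("nan")
    summary = pd.DataFrame(
        {
            "batch": centroids.index,
            "n": coord_df.groupby("batch", sort=True).size().values,
        }
    )
    summary.attrs["between_within_ratio"] = (
        between / within if within and within > 0 else float("inf")
    )
    summary["between_within_ratio"] = summary.attrs["between_within_ratio"]
    return coord_df.drop(columns="explained_variance_ratio"), summary
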