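"""Supra-threshold cluster extraction and cluster-level FWE inference.

Connected components of the voxel-thresholded ALE map are the reporting unit
of the meta-analysis.  Cluster-level family-wise error control keeps only the
components whose extent exceeds the empirical (1 - alpha) quantile of the
max-cluster-extent permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .ale import GridSpec, ScalarMap, ThresholdSpec, connectivity_structure
from .coords import Focus, Space

__all__ = ["Cluster", "ClusterSet", "label_clusters", "apply_cluster_fwe", "cluster_peaks"]


@dataclass
class Cluster:
    """One connected supra-threshold component."""

    id: int
    voxels: np.ndarray  # (n, 3) int voxel indices
    extent_mm3: float
    peak_mni: Focus | None = None
    peak_ale: float | None = None
    fwe_survivor: bool | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    grid: GridSpec
    threshold: ThresholdSpec

    def __len__(self) -> int:
        return len(self.clusters)

    def largest(self) -> Cluster | None:
        return self.clusters[0] if self.clusters else None

    def label_volume(self) -> np.ndarray:
        """Integer volume with each voxel carrying its cluster id (0 = none)."""
        vol = np.zeros(self.grid.shape, dtype=np.int32)
        for c in self.clusters:
            vol[tuple(c.voxels.T)] = c.id
        return vol

    def to_table(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append(
                {
                    "cluster_id": c.id,
                    "n_voxels": c.n_voxels,
                    "extent_mm3": c.extent_mm3,
                    "peak_x": c.peak_mni.x if c.peak_mni else np.nan,
                    "peak_y": c.peak_mni.y if c.peak_mni else np.nan,
                    "peak_z": c.peak_mni.z if c.peak_mni else np.nan,
                    "peak_ale": c.peak_ale if c.peak_ale is not None else np.nan,
                    "fwe_survivor": c.fwe_survivor,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "n_voxels",
                "extent_mm3",
                "peak_x",
                "peak_y",
                "peak_z",
                "peak_ale",
                "fwe_survivor",
            ],
        )

    def save_table(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def label_clusters(
    supra: np.ndarray, g: GridSpec, connectivity: int = 26, threshold: ThresholdSpec | None = None
) -> ClusterSet:
    """Partition a boolean volume into maximal connected components.

    Ids are assigned by first-encountered voxel in raster (linear) order and
    clusters are reported sorted by extent descending (ties by id), so the
    labeling is deterministic across runs.
    """
    supra = np.asarray(supra, dtype=bool)
    if supra.shape != g.shape:
        raise ValueError(f"volume shape {supra.shape} != grid shape {g.shape}")
    t = threshold or ThresholdSpec(connectivity=connectivity)
    if not supra.any():
        return ClusterSet(clusters=[], grid=g, threshold=t)
    labels, n_lab = ndimage.label(supra, structure=connectivity_structure(connectivity))
    vsize = g.voxel_size**3
    clusters = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        clusters.append(Cluster(id=lab, voxels=vox, extent_mm3=vox.shape[0] * vsize))
    clusters.sort(key=lambda c: (-c.n_voxels, c.id))
    return ClusterSet(clusters=clusters, grid=g, threshold=t)


def fwe_extent_threshold(cluster_extent_null: list[int] | np.ndarray, alpha: float) -> float:
    """Empirical (1 - alpha) quantile of the max-cluster-extent null.

    The 'higher' order statistic is used so that survivors strictly exceed a
    null extent attained with probability >= alpha.
    """
    null = np.asarray(cluster_extent_null)
    if null.size == 0:
        raise ValueError("cluster extent null is empty")
    return float(np.quantile(null, 1.0 - alpha, method="higher"))


def apply_cluster_fwe(
    cs: ClusterSet, cluster_extent_null: list[int] | np.ndarray, alpha: float = 0.05
) -> ClusterSet:
    """Keep clusters whose voxel count exceeds the null (1 - alpha) extent quantile."""
    crit = fwe_extent_threshold(cluster_extent_null, alpha)
    survivors = [replace(c, fwe_survivor=True) for c in cs.clusters if c.n_voxels > crit]
    return ClusterSet(clusters=survivors, grid=cs.grid, threshold=cs.threshold)


def cluster_peaks(cs: ClusterSet, ale: ScalarMap) -> ClusterSet:
    """Attach each cluster's ALE peak (mm, MNI) to the cluster set.

    The peak is the member voxel of maximal ALE; exact ties are broken by the
    lowest linear (raster) voxel index.
    """
    if not cs.grid.same_geometry(ale.grid):
        raise ValueError("cluster set and ALE map live on different grids")
    out = []
    shape = cs.grid.shape
    for c in cs.clusters:
        vals = ale.values[tuple(c.voxels.T)]
        lin = np.ravel_multi_index(tuple(c.voxels.T), shape)
        best = np.lexsort((lin, -vals))[0]
        mm = cs.grid.voxel_to_mm(c.voxels[best])
        peak = Focus(float(mm[0]), float(mm[1]), float(mm[2]), Space.MNI)
        out.append(replace(c, peak_mni=peak, peak_ale=float(vals[best])))
    return ClusterSet(clusters=out, grid=cs.grid, threshold=cs.threshold)
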