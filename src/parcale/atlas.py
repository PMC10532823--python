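"""Parcellation atlases, cluster-parcel volumetric overlap, network rollups.

A parcellation atlas is an integer label volume (0 = unlabeled) plus a table
mapping each label to a hemisphere-tagged parcel name (e.g. ``L_FOP4``,
``R_8BM``) and a large-scale functional network (the seven-network scheme:
salience, dorsal attention, limbic, central executive, default mode, visual,
sensorimotor).  Clusters from the meta-analysis are matched to parcels by
voxel-count overlap, and parcels roll up to networks for the contrast stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ale import GridSpec
from .clusters import ClusterSet

__all__ = [
    "NETWORKS",
    "ParcelInfo",
    "ParcellationAtlas",
    "AtlasIntegrityError",
    "read_atlas",
    "resample_labels_nearest",
    "cluster_parcel_overlap",
    "parcels_to_networks",
]

logger = logging.getLogger(__name__)

NETWORKS = (
    "salience",
    "dorsal_attention",
    "limbic",
    "CEN",
    "DMN",
    "visual",
    "sensorimotor",
    "unassigned",
)

_TABLE_COLUMNS = ["label_id", "parcel_name", "hemisphere", "network"]


class AtlasIntegrityError(ValueError):
    """Label volume and label table disagree."""


@dataclass(frozen=True)
class ParcelInfo:
    parcel_name: str
    hemisphere: str  # "L" | "R"
    network: str

    @property
    def tagged_name(self) -> str:
        return f"{self.hemisphere}_{self.parcel_name}"


@dataclass
class ParcellationAtlas:
    """Integer label volume on a grid plus the label lookup table."""

    grid: GridSpec
    labels: np.ndarray
    table: dict[int, ParcelInfo]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.shape != self.grid.shape:
            raise ValueError("label volume shape does not match grid shape")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = sorted(present - set(self.table))
        if missing:
            raise AtlasIntegrityError(
                f"labels present in volume but absent from table: {missing}"
            )
        seen: set[str] = set()
        for info in self.table.values():
            if info.hemisphere not in ("L", "R"):
                raise AtlasIntegrityError(f"bad hemisphere tag {info.hemisphere!r}")
            if info.tagged_name in seen:
                raise AtlasIntegrityError(f"duplicate parcel name {info.tagged_name!r}")
            seen.add(info.tagged_name)

    def by_tagged_name(self) -> dict[str, int]:
        return {info.tagged_name: lab for lab, info in self.table.items()}

    def parcel_sizes(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel())
        return {lab: int(counts[lab]) if lab < counts.size else 0 for lab in self.table}

    def table_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label_id": lab,
                "parcel_name": info.parcel_name,
                "hemisphere": info.hemisphere,
                "network": info.network,
            }
            for lab, info in sorted(self.table.items())
        ]
        return pd.DataFrame(rows, columns=_TABLE_COLUMNS)

    def save(self, volume_path: str | Path, table_path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.grid.affine), str(volume_path))
        self.table_frame().to_csv(table_path, sep="\t", index=False)


def _table_from_frame(df: pd.DataFrame) -> dict[int, ParcelInfo]:
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasIntegrityError(f"label table missing columns: {missing}")
    table: dict[int, ParcelInfo] = {}
    for r in df.itertuples(index=False):
        lab = int(r.label_id)
        if lab in table:
            raise AtlasIntegrityError(f"duplicate label id {lab} in table")
        table[lab] = ParcelInfo(str(r.parcel_name), str(r.hemisphere), str(r.network))
    return table


def resample_labels_nearest(
    labels: np.ndarray, src_affine: np.ndarray, dst: GridSpec
) -> np.ndarray:
    """Nearest-neighbor resampling of an integer label volume onto a grid.

    Each destination voxel center is mapped through the source affine; the
    nearest source voxel (rounded index) supplies the label, 0 outside the
    source field of view.  Nearest-neighbor keeps the label inventory intact.
    """
    labels = np.asarray(labels)
    inv = np.linalg.inv(np.asarray(src_affine, dtype=float))
    ijk = np.argwhere(np.ones(dst.shape, dtype=bool))
    mm = np.asarray(dst.voxel_to_mm(ijk))
    src_idx = np.rint(mm @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    ok = np.all((src_idx >= 0) & (src_idx < np.array(labels.shape)), axis=1)
    out = np.zeros(dst.shape, dtype=labels.dtype)
    flat = out.ravel()
    lin = np.ravel_multi_index(tuple(ijk[ok].T), dst.shape)
    flat[lin] = labels[tuple(src_idx[ok].T)]
    return flat.reshape(dst.shape)


def read_atlas(
    label_volume: str | Path, table: str | Path, grid: GridSpec | None = None
) -> ParcellationAtlas:
    """Load a NIfTI label volume plus TSV label table.

    If ``grid`` is given and differs geometrically from the volume, labels are
    resampled onto it by nearest neighbor (logged).
    """
    img = nib.load(str(label_volume))
    labels = np.asarray(img.dataobj).astype(np.int32)
    affine = img.affine
    df = pd.read_csv(table, sep="\t")
    tbl = _table_from_frame(df)
    if grid is None:
        lin = affine[:3, :3]
        vox = float(np.abs(np.diag(lin)).mean())
        grid = GridSpec(
            shape=labels.shape,
            affine=affine,
            voxel_size=vox,
            mask=labels > 0,
        )
        return ParcellationAtlas(grid=grid, labels=labels, table=tbl)
    if labels.shape != grid.shape or not np.allclose(affine, grid.affine):
        logger.info(
            "resampling atlas %s from shape %s onto analysis grid %s (nearest neighbor)",
            label_volume,
            labels.shape,
            grid.shape,
        )
        labels = resample_labels_nearest(labels, affine, grid)
    return ParcellationAtlas(grid=grid, labels=labels, table=tbl)


def cluster_parcel_overlap(
    cs: ClusterSet, atlas: ParcellationAtlas, principal_pct: float = 10.0
) -> pd.DataFrame:
    """Volumetric overlap of each cluster with each parcel.

    Returns one row per (cluster, parcel) pair sharing at least one voxel,
    with the share of the cluster inside the parcel (``pct_of_cluster``) and
    the share of the parcel covered (``pct_of_parcel``); the unlabeled
    remainder of each cluster is reported under parcel ``<unlabeled>``.
    Parcels covering at least ``principal_pct`` percent of the cluster are
    flagged ``principal``.  Rows sort by cluster then pct_of_cluster
    descending (ties by parcel name).
    """
    if not cs.grid.same_geometry(atlas.grid):
        raise ValueError("cluster set and atlas live on different grids")
    sizes = atlas.parcel_sizes()
    rows = []
    for c in cs.clusters:
        labs = atlas.labels[tuple(c.voxels.T)]
        counts = np.bincount(labs)
        for lab in np.nonzero(counts)[0]:
            n = int(counts[lab])
            pct_cluster = 100.0 * n / c.n_voxels
            if lab == 0:
                name, pct_parcel = "<unlabeled>", np.nan
            else:
                name = atlas.table[int(lab)].tagged_name
                pct_parcel = 100.0 * n / sizes[int(lab)]
            rows.append(
                {
                    "cluster_id": c.id,
                    "parcel": name,
                    "pct_of_cluster": pct_cluster,
                    "pct_of_parcel": pct_parcel,
                    "n_voxels": n,
                    "principal": lab != 0 and pct_cluster >= principal_pct,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["cluster_id", "parcel", "pct_of_cluster", "pct_of_parcel", "n_voxels", "principal"],
    )
    if len(df):
        df = df.sort_values(
            ["cluster_id", "pct_of_cluster", "parcel"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return df


def overlap_parcel_set(overlap: pd.DataFrame, min_voxels: int = 1) -> set[str]:
    """Hemisphere-tagged parcels a cluster set engages, per the reporting rule."""
    if not len(overlap):
        return set()
    keep = (overlap["parcel"] != "<unlabeled>") & (overlap["n_voxels"] >= min_voxels)
    return set(overlap.loc[keep, "parcel"])


def parcels_to_networks(
    parcels: set[str] | list[str], atlas: ParcellationAtlas
) -> dict[str, dict[str, list[str]]]:
    """Group hemisphere-tagged parcels by functional network, split by hemisphere.

    Returns ``{network: {"L": [...], "R": [...]}}`` with parcel lists sorted;
    networks with no member parcels are omitted.
    """
    lookup = {info.tagged_name: info for info in atlas.table.values()}
    out: dict[str, dict[str, list[str]]] = {}
    for p in sorted(set(parcels)):
        info = lookup.get(p)
        if info is None:
            raise KeyError(f"parcel {p!r} not found in atlas table")
        out.setdefault(info.network, {"L": [], "R": []})[info.hemisphere].append(p)
    return out
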