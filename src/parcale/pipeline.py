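"""End-to-end orchestration: convert -> ALE -> threshold -> overlap -> contrast.

A single structured config drives the full analysis over one or more named
study sets.  Every stochastic stage takes an explicit seed, and a manifest
recording the config hash, seeds, stage runtimes and output checksums is
written alongside the results, so a run is reproducible bit-for-bit from its
config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .ale import (
    GridSpec,
    KernelModel,
    NullModel,
    ThresholdSpec,
    ale_union,
    build_null,
    make_mni_grid,
    modeled_activation_map,
    supra_threshold,
    voxel_p_map,
)
from .atlas import ParcellationAtlas, cluster_parcel_overlap, overlap_parcel_set, read_atlas
from .clusters import apply_cluster_fwe, cluster_peaks, label_clusters
from .contrast import contrast_parcel_sets, network_coactivation, network_uniqueness
from .coords import StudySet, parse_foci, to_mni, validate_studyset, write_foci
from .similarity import ExperimentDatabase, rank_similarity

__all__ = ["PipelineConfig", "PipelineError", "AleResult", "analyze_studyset", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AleResult:
    """Everything one study set's ALE stage produces."""

    studyset: StudySet
    mas: list  # per-experiment MA ScalarMaps
    ale: Any  # ALE ScalarMap
    null: Any  # NullTables
    pmap: Any  # p-value ScalarMap
    clusters_all: Any  # ClusterSet before cluster-level FWE
    clusters: Any  # FWE-surviving ClusterSet with peaks attached


def analyze_studyset(
    s: StudySet,
    grid: GridSpec,
    kernel: KernelModel | None = None,
    null_model: NullModel | None = None,
    thresholds: ThresholdSpec | None = None,
) -> AleResult:
    """MA maps -> ALE -> permutation null -> voxel threshold -> cluster FWE.

    The single-study-set core of the pipeline, usable directly from scripts.
    """
    kernel = kernel or KernelModel()
    null_model = null_model or NullModel()
    thresholds = thresholds or ThresholdSpec()
    mas = [modeled_activation_map(e, grid, kernel) for e in s.experiments]
    ale = ale_union(mas)
    null = build_null(s, grid, kernel, null_model, thresholds)
    pmap = voxel_p_map(ale, null)
    supra = supra_threshold(ale, null, thresholds)
    cs_all = cluster_peaks(
        label_clusters(supra, grid, thresholds.connectivity, thresholds), ale
    )
    cs = cluster_peaks(
        apply_cluster_fwe(cs_all, null.cluster_extent_null, thresholds.cluster_alpha), ale
    )
    return AleResult(
        studyset=s, mas=mas, ale=ale, null=null, pmap=pmap, clusters_all=cs_all, clusters=cs
    )


@dataclass
class PipelineConfig:
    """Validated configuration for one full run."""

    out_dir: Path
    studysets: dict[str, dict[str, str]]  # name -> {path, dialect}
    grid_voxel_size: float = 4.0
    kernel: KernelModel = field(default_factory=KernelModel)
    n_permutations: int = 1000
    seed: int = 0
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)
    min_subjects: int = 8
    atlas_volume: Path | None = None
    atlas_table: Path | None = None
    toy_atlas_parcels: int = 4
    similarity_db: Path | None = None
    similarity_radius: float = 10.0
    similarity_top_k: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def respath(v: str | None) -> Path | None:
            if v is None:
                return None
            p = Path(v)
            return p if p.is_absolute() else base / p

        studysets = {}
        for name, block in raw.get("studysets", {}).items():
            studysets[name] = {
                "path": str(respath(block["path"])),
                "dialect": block.get("dialect", "tsv"),
            }
        kern = raw.get("kernel", {})
        thr = raw.get("thresholds", {})
        cfg = cls(
            out_dir=respath(raw["out_dir"]),  # type: ignore[arg-type]
            studysets=studysets,
            grid_voxel_size=float(raw.get("grid", {}).get("voxel_size", 4.0)),
            kernel=KernelModel(
                fwhm_template=float(kern.get("fwhm_template", 5.7)),
                fwhm_subject=float(kern.get("fwhm_subject", 11.6)),
            ),
            n_permutations=int(raw.get("null", {}).get("n_permutations", 1000)),
            seed=int(raw.get("null", {}).get("seed", raw.get("seed", 0))),
            thresholds=ThresholdSpec(
                voxel_p=float(thr.get("voxel_p", 0.001)),
                cluster_alpha=float(thr.get("cluster_alpha", 0.05)),
                connectivity=int(thr.get("connectivity", 26)),
            ),
            min_subjects=int(raw.get("min_subjects", 8)),
            atlas_volume=respath(raw.get("atlas", {}).get("volume")),
            atlas_table=respath(raw.get("atlas", {}).get("table")),
            toy_atlas_parcels=int(raw.get("atlas", {}).get("toy_parcels", 4)),
            similarity_db=respath(raw.get("similarity", {}).get("db")),
            similarity_radius=float(raw.get("similarity", {}).get("radius", 10.0)),
            similarity_top_k=int(raw.get("similarity", {}).get("top_k", 10)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.studysets:
            raise PipelineError("config: no studysets declared")
        for name, block in self.studysets.items():
            if not Path(block["path"]).exists():
                raise PipelineError(f"config: foci file for {name!r} not found: {block['path']}")
        for label, p in (("atlas volume", self.atlas_volume), ("atlas table", self.atlas_table)):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {label} not found: {p}")
        if (self.atlas_volume is None) != (self.atlas_table is None):
            raise PipelineError("config: atlas volume and table must be given together")
        if self.similarity_db is not None and not Path(self.similarity_db).exists():
            raise PipelineError(f"config: similarity db not found: {self.similarity_db}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "studysets": cfg.studysets,
            "grid_voxel_size": cfg.grid_voxel_size,
            "kernel": [cfg.kernel.fwhm_template, cfg.kernel.fwhm_subject],
            "n_permutations": cfg.n_permutations,
            "seed": cfg.seed,
            "thresholds": [
                cfg.thresholds.voxel_p,
                cfg.thresholds.cluster_alpha,
                cfg.thresholds.connectivity,
            ],
            "min_subjects": cfg.min_subjects,
            "atlas": [str(cfg.atlas_volume), str(cfg.atlas_table), cfg.toy_atlas_parcels],
            "similarity": [str(cfg.similarity_db), cfg.similarity_radius, cfg.similarity_top_k],
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def _stage(manifest: dict, name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        manifest["failed_stage"] = name
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    manifest["stage_runtimes_s"][name] = round(time.perf_counter() - t0, 4)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage for every study set; returns the manifest dict.

    Outputs per study set: normalized MNI foci TSV, ALE / p-value NIfTI maps,
    cluster table TSV, cluster-label NIfTI, overlap TSV, null tables; plus one
    cross-set contrast report, network co-activation matrix, and (if a
    database is configured) similarity rankings.  Stage failures abort with
    the stage named; partial outputs stay under a `failed` marker file.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_permutations": cfg.n_permutations,
        "stage_runtimes_s": {},
        "study_counts": {},
        "outputs": {},
    }
    failed_marker = out / "FAILED"
    try:
        grid = make_mni_grid(cfg.grid_voxel_size)
        if cfg.atlas_volume is not None:
            atlas = _stage(
                manifest, "read_atlas", read_atlas, cfg.atlas_volume, cfg.atlas_table, grid
            )
        else:
            from .simulate import make_toy_atlas

            atlas = _stage(manifest, "toy_atlas", make_toy_atlas, grid, cfg.toy_atlas_parcels)

        parcel_sets: dict[str, set[str]] = {}
        peak_tables: dict[str, Any] = {}
        for idx, (name, block) in enumerate(sorted(cfg.studysets.items())):
            sdir = out / name
            sdir.mkdir(exist_ok=True)
            with open(block["path"]) as fh:
                raw_set = _stage(
                    manifest, f"{name}.parse", parse_foci, fh, block["dialect"], name
                )
            s: StudySet = _stage(manifest, f"{name}.convert", to_mni, raw_set)
            report = validate_studyset(s, min_subjects=cfg.min_subjects)
            manifest["study_counts"][name] = {
                "n_experiments": len(s.experiments),
                "n_foci": sum(len(e.foci) for e in s.experiments),
                "n_validation_violations": len(report.violations),
            }
            with open(sdir / "foci_mni.tsv", "w") as fh:
                write_foci(s, fh, dialect="tsv")

            nm = NullModel(n_permutations=cfg.n_permutations, seed=cfg.seed + idx)
            res = _stage(
                manifest,
                f"{name}.ale",
                analyze_studyset,
                s,
                grid,
                cfg.kernel,
                nm,
                cfg.thresholds,
            )
            cs = res.clusters
            res.ale.save(sdir / "ale.nii")
            res.pmap.save(sdir / "p.nii")
            import nibabel as nib

            nib.save(
                nib.Nifti1Image(cs.label_volume(), grid.affine), str(sdir / "clusters.nii")
            )
            cs.save_table(sdir / "clusters.tsv")
            res.null.save(sdir / "null")

            overlap = cluster_parcel_overlap(cs, atlas)
            overlap.to_csv(sdir / "overlap.tsv", sep="\t", index=False)
            pset = overlap_parcel_set(overlap)
            parcel_sets[name] = pset
            (sdir / "parcels.json").write_text(
                json.dumps(sorted(pset), indent=2) + "\n"
            )
            peak_tables[name] = cs

        if len(parcel_sets) >= 2:
            contrast = _stage(manifest, "contrast", contrast_parcel_sets, parcel_sets)
            contrast.save(out / "contrast.json")
            coact = network_coactivation(parcel_sets, atlas)
            coact.to_csv(out / "network_coactivation.tsv", sep="\t", index=False)
            uniq = network_uniqueness(parcel_sets, atlas)
            uniq.to_csv(out / "network_uniqueness.tsv", sep="\t", index=False)

        if cfg.similarity_db is not None:
            db = ExperimentDatabase.from_tsv(cfg.similarity_db)
            for name, cs in peak_tables.items():
                peaks = [c.peak_mni for c in cs.clusters if c.peak_mni is not None]
                if not peaks:
                    continue
                res = rank_similarity(
                    peaks, db, radius=cfg.similarity_radius, k=cfg.similarity_top_k
                )
                res.rows.to_csv(out / name / "similarity.tsv", sep="\t", index=False)
    except Exception:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        raise
    if failed_marker.exists():
        failed_marker.unlink()

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
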