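"""Synthetic study sets, toy parcellation atlases and experiment databases.

Real coordinate corpora are assembled from published tables and the standard
volumetric atlases are distributed under their own licenses, so every stage
of the pipeline is exercised here against generated data with known ground
truth: experiments that report jittered copies of planted convergence centers
mixed with spatially unstructured noise foci, a slab-parcel atlas with
cyclically assigned networks, and a foci database for the similarity search.

Default simulation parameters mirror a typical judgement-meta-analysis
corpus: 8-20 experiments per sub-analysis, 8-30 subjects each, a few foci per
experiment, millimetre-scale jitter around shared true centers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ale import GridSpec
from .atlas import NETWORKS, ParcelInfo, ParcellationAtlas
from .coords import Experiment, Focus, Space, StudySet, write_foci
from .similarity import DbExperiment, ExperimentDatabase

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_studyset",
    "make_toy_atlas",
    "simulate_database",
    "write_fixtures",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study set.

    Each simulated experiment reports each planted true center with
    probability ``report_prob``, displaced by isotropic Gaussian jitter of SD
    ``jitter_sd`` mm, plus a Poisson(``noise_foci_mean``) number of uniform
    in-mask noise foci.  Subject counts are drawn uniformly from
    ``subjects_range`` (inclusive), honoring the >= 8 participants inclusion
    convention by default.
    """

    n_experiments: int = 10
    subjects_range: tuple[int, int] = (8, 30)
    true_centers: tuple[tuple[float, float, float], ...] = ((-42.0, 22.0, 18.0),)
    report_prob: float = 0.9
    jitter_sd: float = 6.0
    noise_foci_mean: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if not (0.0 <= self.report_prob <= 1.0):
            raise ValueError("report_prob must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.noise_foci_mean < 0:
            raise ValueError("noise_foci_mean must be >= 0")
        lo, hi = self.subjects_range
        if lo < 1 or hi < lo:
            raise ValueError("subjects_range must satisfy 1 <= lo <= hi")


@dataclass
class GroundTruth:
    """Which simulated foci are signal, and where the truth lies."""

    true_centers: list[tuple[float, float, float]]
    # per experiment id: list of (focus_index, center_index) for signal foci
    signal_foci: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_centers": [list(c) for c in self.true_centers],
                "signal_foci": {k: [list(t) for t in v] for k, v in self.signal_foci.items()},
            },
            indent=2,
            sort_keys=True,
        )


def _in_mask(g: GridSpec, xyz: np.ndarray) -> bool:
    idx = np.rint(g.mm_to_voxel(xyz)).astype(int)[0]
    if np.any(idx < 0) or np.any(idx >= np.array(g.shape)):
        return False
    return bool(g.mask[tuple(idx)])


def simulate_studyset(
    c: SimulationConfig, g: GridSpec, name: str = "SIM"
) -> tuple[StudySet, GroundTruth]:
    """Draw a seeded study set with known convergence structure.

    Deterministic given (config, grid): the same config always yields the
    same study set.  Experiments that would end up with no foci at all
    receive one fallback noise focus, keeping every experiment non-empty
    (including in the pure-null regime report_prob = 0, noise_foci_mean = 0).
    """
    for ctr in c.true_centers:
        if not _in_mask(g, np.asarray(ctr, dtype=float)):
            raise ValueError(f"true center {ctr} lies outside the mask")
    rng = np.random.default_rng(c.seed)
    centers = g.mask_voxel_centers()
    truth = GroundTruth(true_centers=[tuple(map(float, ctr)) for ctr in c.true_centers])
    experiments = []
    lo, hi = c.subjects_range
    for i in range(c.n_experiments):
        eid = f"{name}_exp{i + 1:02d}"
        n_subj = int(rng.integers(lo, hi + 1))
        foci: list[Focus] = []
        signal: list[tuple[int, int]] = []
        for ci, ctr in enumerate(c.true_centers):
            if rng.random() < c.report_prob:
                xyz = np.asarray(ctr, dtype=float) + rng.normal(0.0, c.jitter_sd, size=3)
                signal.append((len(foci), ci))
                foci.append(Focus(float(xyz[0]), float(xyz[1]), float(xyz[2]), Space.MNI))
        n_noise = int(rng.poisson(c.noise_foci_mean))
        if not foci and n_noise == 0:
            n_noise = 1  # fallback: every experiment reports something
        picks = rng.integers(0, centers.shape[0], size=n_noise)
        for p in picks:
            xyz = centers[p]
            foci.append(Focus(float(xyz[0]), float(xyz[1]), float(xyz[2]), Space.MNI))
        experiments.append(
            Experiment(id=eid, n_subjects=n_subj, foci=foci, space=Space.MNI, source_ref="synthetic")
        )
        truth.signal_foci[eid] = signal
    return StudySet(name=name, experiments=experiments), truth


def make_toy_atlas(
    g: GridSpec,
    parcels_per_hemisphere: int = 4,
    networks: tuple[str, ...] = NETWORKS[:7],
) -> ParcellationAtlas:
    """Slab-parcel toy atlas covering the grid mask.

    Each hemisphere's in-mask voxels (left: x < 0 mm; right: x >= 0 mm) are
    cut into ``parcels_per_hemisphere`` contiguous slabs of roughly equal
    voxel count along the posterior-anterior axis, named ``L_P01``...,
    ``R_P01``..., with networks assigned cyclically from ``networks``.
    Deterministic; a geometric stand-in for real multimodal parcellations,
    not an anatomical model.
    """
    if parcels_per_hemisphere < 1:
        raise ValueError("parcels_per_hemisphere must be >= 1")
    ax_x, ax_y, _ = g.axis_coords()
    labels = np.zeros(g.shape, dtype=np.int32)
    table: dict[int, ParcelInfo] = {}
    next_label = 1
    for hemi, sel in (("L", ax_x < 0), ("R", ax_x >= 0)):
        hemi_mask = np.zeros(g.shape, dtype=bool)
        hemi_mask[sel, :, :] = True
        hemi_mask &= g.mask
        vox = np.argwhere(hemi_mask)
        if vox.shape[0] < parcels_per_hemisphere:
            raise ValueError(
                f"hemisphere {hemi}: {vox.shape[0]} in-mask voxels < "
                f"{parcels_per_hemisphere} requested parcels"
            )
        # slabs along y: sort by y index and split into near-equal runs
        order = np.lexsort((vox[:, 2], vox[:, 0], vox[:, 1]))
        vox = vox[order]
        bounds = np.linspace(0, vox.shape[0], parcels_per_hemisphere + 1).astype(int)
        for pi in range(parcels_per_hemisphere):
            chunk = vox[bounds[pi] : bounds[pi + 1]]
            labels[tuple(chunk.T)] = next_label
            table[next_label] = ParcelInfo(
                parcel_name=f"P{pi + 1:02d}",
                hemisphere=hemi,
                network=networks[(pi if hemi == "L" else pi + parcels_per_hemisphere) % len(networks)],
            )
            next_label += 1
    return ParcellationAtlas(grid=g, labels=labels, table=table)


def simulate_database(
    n_records: int,
    g: GridSpec,
    seed: int = 0,
    foci_range: tuple[int, int] = (3, 12),
    tags: tuple[str, ...] = ("reward", "social", "risk", "memory", "emotion"),
) -> ExperimentDatabase:
    """Random foci database for exercising the similarity search."""
    rng = np.random.default_rng(seed)
    centers = g.mask_voxel_centers()
    records = []
    for i in range(n_records):
        nf = int(rng.integers(foci_range[0], foci_range[1] + 1))
        picks = rng.integers(0, centers.shape[0], size=nf)
        foci = [Focus(*map(float, centers[p])) for p in picks]
        records.append(
            DbExperiment(
                experiment_id=f"db{i + 1:04d}",
                behavioral_tag=str(tags[int(rng.integers(0, len(tags)))]),
                n_subjects=int(rng.integers(8, 40)),
                foci=foci,
            )
        )
    return ExperimentDatabase(records)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(
    out_dir: str | Path,
    c: SimulationConfig,
    g: GridSpec,
    parcels_per_hemisphere: int = 4,
    n_db_records: int = 20,
) -> dict[str, str]:
    """Emit a complete fixture bundle and return a {path: sha256} manifest.

    Writes Sleuth-format foci, the equivalent TSV foci table, the toy atlas
    (NIfTI labels + TSV table), an experiment-database TSV, the ground-truth
    JSON, and a manifest JSON listing every file with its checksum.
    """
    if c.n_experiments < 1:
        raise ValueError("refusing to write fixtures for an empty configuration")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s, truth = simulate_studyset(c, g)
    with open(out / "foci.txt", "w") as fh:
        write_foci(s, fh, dialect="sleuth")
    with open(out / "foci.tsv", "w") as fh:
        write_foci(s, fh, dialect="tsv")
    atlas = make_toy_atlas(g, parcels_per_hemisphere)
    atlas.save(out / "atlas.nii", out / "atlas_labels.tsv")
    db = simulate_database(n_db_records, g, seed=c.seed + 1)
    db.to_tsv(out / "experiment_db.tsv")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")
    files = sorted(
        p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {p.name: _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
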