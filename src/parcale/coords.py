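"""Stereotaxic coordinates, experiments and study sets.

Reported peak-activation coordinates (foci) arrive in one of two standard
spaces, Talairach or MNI, and must be harmonized before pooling.  This
module holds the coordinate containers, the foci-table parsers (Sleuth-style
text and plain TSV) and the affine Talairach<->MNI conversion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import TextIO

import numpy as np
import pandas as pd

__all__ = [
    "Space",
    "Focus",
    "Experiment",
    "StudySet",
    "PlausibilityBounds",
    "FociParseError",
    "WrongSpaceError",
    "TAL2MNI_DEFAULT",
    "parse_foci",
    "write_foci",
    "tal_to_mni",
    "mni_to_tal",
    "validate_studyset",
]


class Space(str, Enum):
    """Stereotaxic reference space of a coordinate."""

    TAL = "TAL"
    MNI = "MNI"


class FociParseError(ValueError):
    """Raised when a foci table cannot be parsed."""


class WrongSpaceError(ValueError):
    """Raised when a coordinate is in the wrong space for an operation."""


# Affine mapping Talairach coordinates into ICBM/MNI space (SPM variant) from
# Lancaster et al., Hum Brain Mapp 28:1194-1205 (2007), "tal2icbm_spm".
# Stored explicitly so the conversion applied to pooled coordinates is
# inspectable and replaceable by any user-supplied 4x4 affine.
TAL2MNI_DEFAULT = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass(frozen=True)
class Focus:
    """One reported peak coordinate, in mm (RAS: +x right, +y anterior, +z superior)."""

    x: float
    y: float
    z: float
    space: Space = Space.MNI

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not np.isfinite(v):
                raise ValueError(f"focus coordinate not finite: {(self.x, self.y, self.z)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class PlausibilityBounds:
    """Absolute mm bounds beyond which a coordinate is implausible for a human brain."""

    x: float = 100.0
    y: float = 120.0
    z: float = 100.0

    def check(self, f: Focus) -> bool:
        return abs(f.x) <= self.x and abs(f.y) <= self.y and abs(f.z) <= self.z


@dataclass
class Experiment:
    """One study's reported foci plus its subject count.

    The subject count N drives the spatial-uncertainty kernel width
    downstream: larger samples localize peaks more precisely.
    """

    id: str
    n_subjects: int
    foci: list[Focus]
    space: Space
    source_ref: str = field(default="", compare=False)  # provenance only

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"experiment {self.id!r}: n_subjects must be >= 1")
        if not self.foci:
            raise ValueError(f"experiment {self.id!r}: foci list is empty")
        for f in self.foci:
            if f.space != self.space:
                raise ValueError(
                    f"experiment {self.id!r}: focus space {f.space} != experiment space {self.space}"
                )


@dataclass
class StudySet:
    """A named group of experiments meta-analyzed together (one sub-analysis)."""

    name: str
    experiments: list[Experiment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate experiment ids in study set {self.name!r}: {dupes}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudySet):
            return NotImplemented
        return self.name == other.name and self.experiments == other.experiments


def _parse_space(tag: str, *, context: str) -> Space:
    t = tag.strip().upper()
    if t in ("TAL", "TALAIRACH"):
        return Space.TAL
    if t in ("MNI", "ICBM", "MNI152"):
        return Space.MNI
    raise FociParseError(f"{context}: unknown space tag {tag!r}")


def _parse_sleuth(stream: TextIO, name: str) -> StudySet:
    """Parse a Sleuth-style foci file.

    Experiment header lines begin with ``//``; a ``Subjects=`` field is
    required per experiment; a ``Reference=`` field (usually on the first
    line) sets the space, and may be restated per block.  Blank lines
    separate experiments; coordinate lines are whitespace-separated x y z.
    """
    default_space: Space | None = None
    experiments: list[Experiment] = []
    header_lines: list[str] = []
    coords: list[tuple[float, float, float]] = []
    block_space: Space | None = None
    block_subjects: int | None = None
    any_content = False
    counter = 0
    lineno = 0

    def flush(lineno: int) -> None:
        nonlocal header_lines, coords, block_space, block_subjects, counter
        if not header_lines and not coords:
            return
        counter += 1
        names = [h for h in header_lines if "=" not in h]
        exp_id = names[0] if names else f"experiment_{counter}"
        if block_subjects is None:
            raise FociParseError(
                f"line {lineno}: experiment {exp_id!r} has no Subjects= field"
            )
        space = block_space or default_space
        if space is None:
            raise FociParseError(
                f"line {lineno}: experiment {exp_id!r} has no Reference= space tag"
            )
        if not coords:
            raise FociParseError(f"line {lineno}: experiment {exp_id!r} has no coordinates")
        foci = [Focus(x, y, z, space) for x, y, z in coords]
        experiments.append(
            Experiment(id=exp_id, n_subjects=block_subjects, foci=foci, space=space)
        )
        header_lines, coords, block_space, block_subjects = [], [], None, None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            flush(lineno)
            continue
        any_content = True
        if line.startswith("//"):
            body = line[2:].strip()
            low = body.lower()
            if low.startswith("reference="):
                sp = _parse_space(body.split("=", 1)[1], context=f"line {lineno}")
                block_space = sp
                if default_space is None:
                    default_space = sp
            elif low.startswith("subjects="):
                try:
                    block_subjects = int(body.split("=", 1)[1].strip())
                except ValueError as exc:
                    raise FociParseError(f"line {lineno}: bad Subjects= value {body!r}") from exc
            else:
                header_lines.append(body)
        else:
            parts = line.split()
            if len(parts) < 3:
                raise FociParseError(f"line {lineno}: expected 'x y z', got {line!r}")
            try:
                x, y, z = (float(p) for p in parts[:3])
            except ValueError as exc:
                raise FociParseError(f"line {lineno}: non-numeric coordinate in {line!r}") from exc
            coords.append((x, y, z))
    flush(lineno)

    if not any_content:
        raise FociParseError("empty foci file")
    if not experiments:
        raise FociParseError("foci file contains no experiments")
    return StudySet(name=name, experiments=experiments)


_TSV_COLUMNS = ["study_id", "n_subjects", "space", "x", "y", "z"]


def _parse_tsv(stream: TextIO, name: str) -> StudySet:
    df = pd.read_csv(stream, sep="\t", dtype={"study_id": str}, float_precision="round_trip")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FociParseError(f"TSV foci table missing columns: {missing}")
    if len(df) == 0:
        raise FociParseError("TSV foci table has no data rows")
    experiments: list[Experiment] = []
    for sid, grp in df.groupby("study_id", sort=False):
        n_vals = grp["n_subjects"].unique()
        if len(n_vals) != 1:
            raise FociParseError(f"experiment {sid!r}: inconsistent n_subjects {sorted(n_vals)}")
        if pd.isna(n_vals[0]):
            raise FociParseError(f"experiment {sid!r}: missing subject count")
        sp_vals = grp["space"].unique()
        if len(sp_vals) != 1:
            raise FociParseError(f"experiment {sid!r}: inconsistent space tags {sorted(sp_vals)}")
        space = _parse_space(str(sp_vals[0]), context=f"experiment {sid!r}")
        foci = [
            Focus(float(r.x), float(r.y), float(r.z), space)
            for r in grp.itertuples(index=False)
        ]
        experiments.append(
            Experiment(id=str(sid), n_subjects=int(n_vals[0]), foci=foci, space=space)
        )
    return StudySet(name=name, experiments=experiments)


def parse_foci(source: TextIO | str, dialect: str = "tsv", name: str = "studyset") -> StudySet:
    """Parse a foci table into a :class:`StudySet`.

    Parameters
    ----------
    source
        Open text stream, or a string containing the file contents.
    dialect
        ``"sleuth"`` for Sleuth/BrainMap-style text, ``"tsv"`` for a
        tab-separated table with columns study_id, n_subjects, space, x, y, z.
    name
        Name given to the returned study set.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    if dialect == "sleuth":
        return _parse_sleuth(stream, name)
    if dialect == "tsv":
        return _parse_tsv(stream, name)
    raise ValueError(f"unknown foci dialect {dialect!r}")


def write_foci(s: StudySet, stream: TextIO, dialect: str = "tsv") -> None:
    """Write a StudySet in a format :func:`parse_foci` reads back identically."""
    if dialect == "tsv":
        stream.write("\t".join(_TSV_COLUMNS) + "\n")
        for e in s.experiments:
            for f in e.foci:
                stream.write(
                    f"{e.id}\t{e.n_subjects}\t{e.space.value}\t{f.x!r}\t{f.y!r}\t{f.z!r}\n"
                )
    elif dialect == "sleuth":
        for e in s.experiments:
            stream.write(f"// Reference={e.space.value}\n")
            stream.write(f"// {e.id}\n")
            stream.write(f"// Subjects={e.n_subjects}\n")
            for f in e.foci:
                stream.write(f"{f.x!r}\t{f.y!r}\t{f.z!r}\n")
            stream.write("\n")
    else:
        raise ValueError(f"unknown foci dialect {dialect!r}")


def _apply_affine(affine: np.ndarray, f: Focus, out_space: Space) -> Focus:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    v = affine @ np.array([f.x, f.y, f.z, 1.0])
    if not np.all(np.isfinite(v)):
        raise ValueError("affine transform produced non-finite coordinates")
    return Focus(float(v[0]), float(v[1]), float(v[2]), out_space)


def tal_to_mni(f: Focus, affine: np.ndarray = TAL2MNI_DEFAULT) -> Focus:
    """Convert a Talairach focus to MNI via homogeneous affine multiplication."""
    if f.space != Space.TAL:
        raise WrongSpaceError(f"tal_to_mni expects a TAL focus, got {f.space}")
    return _apply_affine(affine, f, Space.MNI)


def mni_to_tal(f: Focus, affine: np.ndarray = TAL2MNI_DEFAULT) -> Focus:
    """Exact inverse of :func:`tal_to_mni` under the same affine."""
    if f.space != Space.MNI:
        raise WrongSpaceError(f"mni_to_tal expects an MNI focus, got {f.space}")
    return _apply_affine(np.linalg.inv(np.asarray(affine, dtype=float)), f, Space.TAL)


def to_mni(s: StudySet, affine: np.ndarray = TAL2MNI_DEFAULT) -> StudySet:
    """Return a copy of the study set with every experiment in MNI space."""
    out: list[Experiment] = []
    for e in s.experiments:
        if e.space == Space.MNI:
            out.append(e)
        else:
            foci = [tal_to_mni(f, affine) for f in e.foci]
            out.append(replace(e, foci=foci, space=Space.MNI))
    return StudySet(name=s.name, experiments=out)


@dataclass
class Violation:
    experiment_id: str
    kind: str  # "n_subjects" | "plausibility"
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_studyset(
    s: StudySet,
    min_subjects: int = 8,
    bounds: PlausibilityBounds = PlausibilityBounds(),
    strict: bool = False,
) -> ValidationReport:
    """Check the sample-size inclusion rule and coordinate plausibility.

    Meta-analytic inclusion conventionally requires at least ``min_subjects``
    participants per experiment (default 8).  Coordinates outside ``bounds``
    are flagged as implausible.  With ``strict=True`` any violation raises.
    """
    violations: list[Violation] = []
    for e in s.experiments:
        if e.n_subjects < min_subjects:
            violations.append(
                Violation(e.id, "n_subjects", f"N={e.n_subjects} < {min_subjects}")
            )
        for i, f in enumerate(e.foci):
            if not bounds.check(f):
                violations.append(
                    Violation(e.id, "plausibility", f"focus {i} at ({f.x}, {f.y}, {f.z}) out of bounds")
                )
    report = ValidationReport(violations)
    if strict and violations:
        raise ValueError(
            "study set failed validation: "
            + "; ".join(f"{v.experiment_id}: {v.detail}" for v in violations)
        )
    return report
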