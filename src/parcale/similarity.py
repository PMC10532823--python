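"""Coordinate-similarity search over an experiment database.

A local emulation of experiment-wise activation-coordinate search services:
given a query set of peak coordinates (e.g. the significant peaks of a
meta-analysis), every database experiment is scored by the fraction of query
foci lying within a match radius of at least one of its foci, and the top-k
experiments are returned.  The metric is a deliberately simple, documented
within-radius matching fraction — an emulation of proprietary ranking, not a
reproduction of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .coords import Focus

__all__ = ["DbExperiment", "ExperimentDatabase", "SimilarityResult", "rank_similarity"]


@dataclass
class DbExperiment:
    experiment_id: str
    behavioral_tag: str
    n_subjects: int
    foci: list[Focus]

    def __post_init__(self) -> None:
        if not self.foci:
            raise ValueError(f"database experiment {self.experiment_id!r} has no foci")


@dataclass
class ExperimentDatabase:
    records: list[DbExperiment]

    def __post_init__(self) -> None:
        ids = [r.experiment_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate experiment ids in database")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExperimentDatabase":
        """Read a TSV with one row per focus:
        experiment_id, behavioral_tag, n_subjects, x, y, z."""
        df = pd.read_csv(path, sep="\t", dtype={"experiment_id": str, "behavioral_tag": str})
        needed = ["experiment_id", "behavioral_tag", "n_subjects", "x", "y", "z"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"experiment database TSV missing columns: {missing}")
        records = []
        for eid, grp in df.groupby("experiment_id", sort=False):
            foci = [Focus(float(r.x), float(r.y), float(r.z)) for r in grp.itertuples()]
            records.append(
                DbExperiment(
                    experiment_id=str(eid),
                    behavioral_tag=str(grp["behavioral_tag"].iloc[0]),
                    n_subjects=int(grp["n_subjects"].iloc[0]),
                    foci=foci,
                )
            )
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for r in self.records:
            for f in r.foci:
                rows.append(
                    {
                        "experiment_id": r.experiment_id,
                        "behavioral_tag": r.behavioral_tag,
                        "n_subjects": r.n_subjects,
                        "x": f.x,
                        "y": f.y,
                        "z": f.z,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SimilarityResult:
    """Ranked matches, sorted by similarity descending, ties by experiment id."""

    rows: pd.DataFrame  # experiment_id, behavioral_tag, n_subjects, n_matching, similarity_pct


def rank_similarity(
    query: Sequence[Focus],
    db: ExperimentDatabase,
    radius: float = 10.0,
    k: int = 10,
) -> SimilarityResult:
    """Rank database experiments by coordinate similarity to the query foci.

    ``n_matching`` counts query foci within ``radius`` mm of at least one of
    the record's foci (query -> record direction only);
    ``similarity_pct = 100 * n_matching / len(query)``.
    """
    if not query:
        raise ValueError("query foci list is empty")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if k <= 0:
        raise ValueError("k must be positive")
    q = np.array([[f.x, f.y, f.z] for f in query], dtype=float)
    rows = []
    for r in db.records:
        pts = np.array([[f.x, f.y, f.z] for f in r.foci], dtype=float)
        d = cdist(q, pts)
        n_match = int((d.min(axis=1) <= radius).sum())
        rows.append(
            {
                "experiment_id": r.experiment_id,
                "behavioral_tag": r.behavioral_tag,
                "n_subjects": r.n_subjects,
                "n_matching": n_match,
                "similarity_pct": 100.0 * n_match / q.shape[0],
            }
        )
    df = pd.DataFrame(
        rows, columns=["experiment_id", "behavioral_tag", "n_subjects", "n_matching", "similarity_pct"]
    )
    if len(df):
        df = df.sort_values(
            ["similarity_pct", "experiment_id"], ascending=[False, True]
        ).head(k).reset_index(drop=True)
    return SimilarityResult(rows=df)
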