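"""Core/accessory contrast between sub-analyses and network co-activation.

After each sub-analysis (e.g. moral, social, risk, interpersonal judgement)
has been reduced to the hemisphere-tagged parcels its significant clusters
overlap, this module performs the symbolic set contrast: parcels engaged by
two or more sub-analyses are *core* regions, parcels engaged by exactly one
are *accessory*.  A separate network-level rollup captures convergence that
set intersection misses — two tasks may engage disjoint parcels of the same
large-scale network.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .atlas import ParcellationAtlas, parcels_to_networks

__all__ = ["PairContrast", "ContrastReport", "contrast_parcel_sets", "network_coactivation"]


@dataclass
class PairContrast:
    first: str
    second: str
    shared: list[str]
    unique_to_first: list[str]
    unique_to_second: list[str]


@dataclass
class ContrastReport:
    sets: dict[str, list[str]]
    pairs: list[PairContrast]
    core: list[str] = field(default_factory=list)  # parcels shared by >= 2 sub-analyses
    accessory: dict[str, list[str]] = field(default_factory=dict)  # name -> parcels unique to it

    def pair(self, a: str, b: str) -> PairContrast:
        for p in self.pairs:
            if {p.first, p.second} == {a, b}:
                return p
        raise KeyError(f"no pair ({a}, {b}) in report")

    def to_json(self) -> str:
        obj = {
            "sets": self.sets,
            "pairs": [
                {
                    "first": p.first,
                    "second": p.second,
                    "shared": p.shared,
                    "unique_to_first": p.unique_to_first,
                    "unique_to_second": p.unique_to_second,
                }
                for p in self.pairs
            ],
            "core": self.core,
            "accessory": self.accessory,
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def contrast_parcel_sets(sets: dict[str, set[str] | list[str]]) -> ContrastReport:
    """Exact set algebra over named parcel sets.

    For every unordered pair of sub-analyses the shared and unique parcels are
    listed; globally, parcels appearing in two or more sets are *core* and
    parcels appearing in exactly one are *accessory* to that sub-analysis.
    All output lists are sorted lexicographically for determinism.
    """
    if len(sets) < 2:
        raise ValueError("contrast requires at least two named parcel sets")
    norm = {name: set(p) for name, p in sets.items()}
    names = sorted(norm)
    pairs = []
    for a, b in itertools.combinations(names, 2):
        sa, sb = norm[a], norm[b]
        pairs.append(
            PairContrast(
                first=a,
                second=b,
                shared=sorted(sa & sb),
                unique_to_first=sorted(sa - sb),
                unique_to_second=sorted(sb - sa),
            )
        )
    membership: dict[str, list[str]] = {}
    for name in names:
        for p in norm[name]:
            membership.setdefault(p, []).append(name)
    core = sorted(p for p, owners in membership.items() if len(owners) >= 2)
    accessory = {
        name: sorted(
            p for p, owners in membership.items() if owners == [name]
        )
        for name in names
    }
    return ContrastReport(
        sets={n: sorted(norm[n]) for n in names}, pairs=pairs, core=core, accessory=accessory
    )


def network_coactivation(
    sets: dict[str, set[str] | list[str]], atlas: ParcellationAtlas
) -> pd.DataFrame:
    """Network-by-pair co-activation matrix.

    For each functional network and each unordered pair of sub-analyses the
    matrix records whether *both* members engage the network, overall and per
    hemisphere.  Engagement means at least one of the sub-analysis's parcels
    belongs to the network; co-activation therefore does not require any
    shared parcel (though a shared parcel always implies it).
    """
    norm = {name: set(p) for name, p in sets.items()}
    names = sorted(norm)
    engagement: dict[str, dict[tuple[str, str], bool]] = {}
    nets: set[str] = set()
    for name in names:
        summary = parcels_to_networks(norm[name], atlas)
        eng = {}
        for net, hemi in summary.items():
            nets.add(net)
            eng[(net, "L")] = bool(hemi["L"])
            eng[(net, "R")] = bool(hemi["R"])
        engagement[name] = eng
    rows = []
    for net in sorted(nets):
        for a, b in itertools.combinations(names, 2):
            ea, eb = engagement[a], engagement[b]
            both_l = ea.get((net, "L"), False) and eb.get((net, "L"), False)
            both_r = ea.get((net, "R"), False) and eb.get((net, "R"), False)
            any_a = ea.get((net, "L"), False) or ea.get((net, "R"), False)
            any_b = eb.get((net, "L"), False) or eb.get((net, "R"), False)
            rows.append(
                {
                    "network": net,
                    "first": a,
                    "second": b,
                    "coactive": any_a and any_b,
                    "coactive_L": both_l,
                    "coactive_R": both_r,
                }
            )
    return pd.DataFrame(
        rows, columns=["network", "first", "second", "coactive", "coactive_L", "coactive_R"]
    )


def network_uniqueness(
    sets: dict[str, set[str] | list[str]], atlas: ParcellationAtlas
) -> pd.DataFrame:
    """Per (network, hemisphere): which sub-analyses engage it, and whether
    exactly one does (uniqueness among the contrasted tasks)."""
    norm = {name: set(p) for name, p in sets.items()}
    names = sorted(norm)
    rows = []
    cells: dict[tuple[str, str], list[str]] = {}
    for name in names:
        summary = parcels_to_networks(norm[name], atlas)
        for net, hemi in summary.items():
            for h in ("L", "R"):
                if hemi[h]:
                    cells.setdefault((net, h), []).append(name)
    for (net, h), engaged in sorted(cells.items()):
        rows.append(
            {
                "network": net,
                "hemisphere": h,
                "engaged_by": ",".join(engaged),
                "unique": len(engaged) == 1,
            }
        )
    return pd.DataFrame(rows, columns=["network", "hemisphere", "engaged_by", "unique"])
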