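"""Spatial relations between connectivity maps and stimulation coordinates.

Distances are Euclidean in template mm space between map centers of gravity
and named stimulation sites; membership asks whether a site's mm coordinate
falls on a voxel of a thresholded map (nearest-voxel rounding — sites are
points and the masks binary). Reports bundle the full distance matrix, the
membership matrix, and a per-site ranking of maps by COG distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group_maps import MPMask, center_of_gravity


@dataclass(frozen=True)
class CoordinateMM:
    """A named point in template mm space with a provenance tag."""

    name: str
    x: float
    y: float
    z: float
    source: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"non-finite coordinate for {self.name!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ProximityReport:
    distances: pd.DataFrame          # rows = maps, columns = sites, mm
    membership: pd.DataFrame         # "inside" / "outside"
    ranking: dict[str, list[str]]    # site -> map names by increasing distance
    nearest: dict[str, str] = field(default_factory=dict)


def euclidean_distance(p: CoordinateMM, q: CoordinateMM) -> float:
    """L2 distance in mm between two template-space points."""
    return float(np.linalg.norm(p.xyz - q.xyz))


def site_membership(site: CoordinateMM, mask: MPMask) -> str:
    """``"inside"`` iff the site's nearest voxel is within the grid and the mask."""
    inv = np.linalg.inv(mask.affine)
    vox = inv[:3, :3] @ site.xyz + inv[:3, 3]
    idx = np.round(vox).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.mask.shape)):
        warnings.warn(f"site {site.name!r} falls outside the grid of {mask.label_name!r}")
        return "outside"
    return "inside" if mask.mask[tuple(idx)] else "outside"


def load_site_table(table: pd.DataFrame) -> list[CoordinateMM]:
    """Coordinates from a table with columns name, x, y, z [, source]."""
    sites = []
    for _, row in table.iterrows():
        sites.append(
            CoordinateMM(
                name=str(row["name"]),
                x=float(row["x"]),
                y=float(row["y"]),
                z=float(row["z"]),
                source=str(row.get("source", "")),
            )
        )
    return sites


def proximity_report(
    cogs: list[CoordinateMM],
    sites: list[CoordinateMM],
    masks: list[MPMask] | None = None,
) -> ProximityReport:
    """Distance and membership matrices plus a nearest-map ranking per site.

    ``cogs`` carry the map names; ``masks`` (optional, matched to COGs by
    name) provide the membership test.
    """
    if not cogs or not sites:
        raise ValueError("need at least one COG and one site")
    for group in (cogs, sites):
        names = [c.name for c in group]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate names: {sorted(names)}")

    dist = pd.DataFrame(
        {s.name: [euclidean_distance(c, s) for c in cogs] for s in sites},
        index=[c.name for c in cogs],
    )

    mask_by_name = {m.label_name: m for m in masks} if masks else {}
    member = pd.DataFrame(
        {
            s.name: [
                site_membership(s, mask_by_name[c.name]) if c.name in mask_by_name else "unknown"
                for c in cogs
            ]
            for s in sites
        },
        index=[c.name for c in cogs],
    )

    ranking = {
        s.name: list(dist[s.name].sort_values(kind="stable").index) for s in sites
    }
    nearest = {site: maps[0] for site, maps in ranking.items()}
    return ProximityReport(distances=dist, membership=member, ranking=ranking, nearest=nearest)


def cogs_from_masks(masks: list[MPMask]) -> list[CoordinateMM]:
    """Centers of gravity of thresholded maps as named coordinates."""
    out = []
    for m in masks:
        c = center_of_gravity(m)
        out.append(CoordinateMM(name=m.label_name, x=c[0], y=c[1], z=c[2], source="cog"))
    return out
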