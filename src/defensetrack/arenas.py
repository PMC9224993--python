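"""Arena geometry and named behavioral zones.

Every assay is scored against a :class:`ZoneMap`: the arena footprint plus a
dictionary of named zone polygons (corners, center, burrow, arms, threat/safe
zones ...) in centimetre coordinates with the origin at the arena lower-left
corner and y pointing up.  Default geometries follow the published assay
dimensions: 34x34 cm open field, 47x47 cm latency-to-enter (LTE) box with a
13x7 cm burrow, 70x25 cm predator corridor, elevated plus maze with 30x7 cm
arms, and a 42x20 cm two-chamber place-test context.

Zone membership is point-in-(closed)-polygon on the head centroid; points on a
zone boundary count as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "ARENA_DIMS_CM",
    "ZoneMap",
    "make_zonemap",
    "read_zonemap",
    "write_zonemap",
]

#: (length_x, length_y) footprint of each supported arena, cm.
ARENA_DIMS_CM: dict[str, tuple[float, float]] = {
    "open_field": (34.0, 34.0),
    "lte": (47.0, 47.0),
    "corridor": (70.0, 25.0),
    "epm": (67.0, 67.0),  # two 30-cm arms plus a 7-cm hub on each axis
    "rtpt": (42.0, 20.0),
}

# Fractions used for default zone construction (configurable via custom maps).
_CORNER_FRAC = 0.25  # corner squares span 25% of the side length
_CENTER_FRAC = 0.50  # center square spans the middle 50%
_SAFE_FRAC = 1.0 / 3.0  # safe zone = third of the corridor nearest safe wall

_EPM_ARM_LEN = 30.0
_EPM_ARM_W = 7.0


@dataclass
class ZoneMap:
    """Arena polygon, named zone polygons, and threat/safe reference geometry.

    ``threat_point`` is the midpoint of the rat-end wall for the corridor and
    ``None`` for arenas without a defined threat.  ``safe_wall`` / ``rat_wall``
    are wall segments ((x1, y1), (x2, y2)) when defined.
    """

    arena_name: str
    arena: Polygon
    zones: dict[str, Polygon] = field(default_factory=dict)
    threat_point: tuple[float, float] | None = None
    safe_wall: tuple[tuple[float, float], tuple[float, float]] | None = None
    rat_wall: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for name, poly in self.zones.items():
            if not self.arena.buffer(1e-9).covers(poly):
                raise ValueError(f"zone {name!r} is not contained in the arena polygon")

    def zone_names(self) -> list[str]:
        return list(self.zones)

    def contains(self, zone: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed zone polygon."""
        if zone not in self.zones:
            raise KeyError(f"unknown zone {zone!r}; available: {sorted(self.zones)}")
        return shapely.intersects_xy(self.zones[zone], np.asarray(x), np.asarray(y))

    def in_arena(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return shapely.intersects_xy(self.arena, np.asarray(x), np.asarray(y))

    @property
    def safe_wall_x(self) -> float:
        """x-coordinate of the safe wall (corridor scoring)."""
        if self.safe_wall is None:
            raise ValueError(f"arena {self.arena_name!r} defines no safe wall")
        return 0.5 * (self.safe_wall[0][0] + self.safe_wall[1][0])

    def to_dict(self) -> dict:
        def ring(p: Polygon) -> list[list[float]]:
            return [[float(x), float(y)] for x, y in p.exterior.coords[:-1]]

        return {
            "arena_name": self.arena_name,
            "arena": ring(self.arena),
            "zones": {k: ring(v) for k, v in self.zones.items()},
            "threat_point": list(self.threat_point) if self.threat_point else None,
            "safe_wall": [list(p) for p in self.safe_wall] if self.safe_wall else None,
            "rat_wall": [list(p) for p in self.rat_wall] if self.rat_wall else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZoneMap":
        return cls(
            arena_name=d["arena_name"],
            arena=Polygon(d["arena"]),
            zones={k: Polygon(v) for k, v in d["zones"].items()},
            threat_point=tuple(d["threat_point"]) if d.get("threat_point") else None,
            safe_wall=tuple(tuple(p) for p in d["safe_wall"]) if d.get("safe_wall") else None,
            rat_wall=tuple(tuple(p) for p in d["rat_wall"]) if d.get("rat_wall") else None,
        )


def _rect(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def _square_zones(side_x: float, side_y: float) -> dict[str, Polygon]:
    """Corner + center zones for a rectangular open arena."""
    cx, cy = _CORNER_FRAC * side_x, _CORNER_FRAC * side_y
    zones = {
        "corner_sw": _rect(0, 0, cx, cy),
        "corner_se": _rect(side_x - cx, 0, side_x, cy),
        "corner_nw": _rect(0, side_y - cy, cx, side_y),
        "corner_ne": _rect(side_x - cx, side_y - cy, side_x, side_y),
    }
    mx, my = _CENTER_FRAC * side_x / 2, _CENTER_FRAC * side_y / 2
    zones["center"] = _rect(side_x / 2 - mx, side_y / 2 - my, side_x / 2 + mx, side_y / 2 + my)
    return zones


def _epm_polygon() -> Polygon:
    c0 = _EPM_ARM_LEN  # hub lower edge
    c1 = _EPM_ARM_LEN + _EPM_ARM_W  # hub upper edge
    ext = 2 * _EPM_ARM_LEN + _EPM_ARM_W
    return Polygon(
        [
            (c0, 0), (c1, 0), (c1, c0), (ext, c0), (ext, c1), (c1, c1),
            (c1, ext), (c0, ext), (c0, c1), (0, c1), (0, c0), (c0, c0),
        ]
    )


def make_zonemap(arena_name: str, burrow_corner: str = "sw") -> ZoneMap:
    """Build the default :class:`ZoneMap` for a named arena.

    Parameters
    ----------
    arena_name:
        One of ``open_field``, ``lte``, ``corridor``, ``epm``, ``rtpt``.
    burrow_corner:
        LTE only - which corner holds the dark burrow (default ``sw``).
    """
    if arena_name not in ARENA_DIMS_CM:
        raise ValueError(f"unknown arena {arena_name!r}; expected one of {sorted(ARENA_DIMS_CM)}")
    lx, ly = ARENA_DIMS_CM[arena_name]

    if arena_name == "open_field":
        return ZoneMap(arena_name, _rect(0, 0, lx, ly), _square_zones(lx, ly))

    if arena_name == "lte":
        zones = _square_zones(lx, ly)
        zones.pop("center")
        if burrow_corner != "sw":
            raise NotImplementedError("default LTE map places the burrow in the SW corner")
        zones.pop("corner_sw")  # burrow replaces its corner zone
        zones["burrow"] = _rect(0, 0, 13.0, 7.0)
        hz = _CORNER_FRAC * lx
        zones["holding_zone"] = _rect(lx - hz, ly - hz, lx, ly)
        return ZoneMap(arena_name, _rect(0, 0, lx, ly), zones)

    if arena_name == "corridor":
        safe_x = _SAFE_FRAC * lx
        zones = {
            "safe_zone": _rect(0, 0, safe_x, ly),
            "threat_zone": _rect(lx - safe_x, 0, lx, ly),
            "threat_two_thirds": _rect(safe_x, 0, lx, ly),
        }
        return ZoneMap(
            arena_name,
            _rect(0, 0, lx, ly),
            zones,
            threat_point=(lx, ly / 2),
            safe_wall=((0.0, 0.0), (0.0, ly)),
            rat_wall=((lx, 0.0), (lx, ly)),
        )

    if arena_name == "epm":
        c0, c1 = _EPM_ARM_LEN, _EPM_ARM_LEN + _EPM_ARM_W
        ext = 2 * _EPM_ARM_LEN + _EPM_ARM_W
        zones = {
            # open arms run along x, closed arms along y (walled)
            "open_arm_west": _rect(0, c0, c0, c1),
            "open_arm_east": _rect(c1, c0, ext, c1),
            "closed_arm_south": _rect(c0, 0, c1, c0),
            "closed_arm_north": _rect(c0, c1, c1, ext),
            "epm_center": _rect(c0, c0, c1, c1),
        }
        return ZoneMap(arena_name, _epm_polygon(), zones)

    # rtpt: two identical chambers split across the long axis
    zones = {
        "stim_chamber": _rect(0, 0, lx / 2, ly),
        "nostim_chamber": _rect(lx / 2, 0, lx, ly),
    }
    return ZoneMap(arena_name, _rect(0, 0, lx, ly), zones)


def write_zonemap(zonemap: ZoneMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(zonemap.to_dict(), fh, indent=1)


def read_zonemap(path) -> ZoneMap:
    with open(path) as fh:
        return ZoneMap.from_dict(json.load(fh))
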