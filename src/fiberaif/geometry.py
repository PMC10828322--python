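"""Geometric primitives, analytic ray tracing, and the study's scene builders.

Coordinate convention: the tail / wrist / fiber / vessel axes all run along
``z``; the fiber sits on the ``-y`` side of the anatomy, so vessel "depth" is
measured along ``+y`` from the skin surface down to the vessel surface.

A :class:`Scene` is an ordered set of :class:`Volume` (finite cylinders and
axis-aligned boxes) inside one large enclosing air cylinder.  Point location
is by priority: the highest-priority volume containing the point wins, which
lets vessels and bone sit inside the tail, and the tail inside air, without
boolean CSG.  Surfaces belong to the inner (higher-priority) volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .materials import MATERIALS, get_material

ROLES = (
    "air",
    "tissue",
    "bone",
    "wall",
    "fiber",
    "source_artery",
    "source_vein",
    "source_body",
)

_BOUNDARY_EPS = 1e-9  # mm


@dataclass(frozen=True)
class Volume:
    """A finite cylinder or axis-aligned box with a material and a role."""

    name: str
    shape: str  # "cylinder" | "box"
    center: Tuple[float, float, float]
    material: str
    role: str
    priority: int
    # cylinder fields
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius: float = 0.0
    length: float = 0.0
    # box fields (full edge lengths)
    edges: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.shape == "cylinder":
            if self.radius <= 0.0 or self.length <= 0.0:
                raise ValueError("cylinder needs radius > 0 and length > 0")
            ax = np.asarray(self.axis, dtype=float)
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValueError("cylinder axis must be unit-norm")
        elif self.shape == "box":
            if any(e <= 0.0 for e in self.edges):
                raise ValueError("box needs positive edge lengths")
        else:
            raise ValueError(f"unknown shape {self.shape!r}")
        get_material(self.material)  # validate

    def contains(self, point: Sequence[float]) -> bool:
        p = np.asarray(point, dtype=float) - np.asarray(self.center)
        if self.shape == "cylinder":
            ax = np.asarray(self.axis)
            za = float(p @ ax)
            if abs(za) > self.length / 2.0 + _BOUNDARY_EPS:
                return False
            r2 = float(p @ p) - za * za
            return r2 <= (self.radius + _BOUNDARY_EPS) ** 2
        h = np.asarray(self.edges) / 2.0
        return bool(np.all(np.abs(p) <= h + _BOUNDARY_EPS))

    def volume_mm3(self) -> float:
        if self.shape == "cylinder":
            return float(np.pi * self.radius**2 * self.length)
        return float(np.prod(self.edges))

    def ray_interval(
        self, origin: np.ndarray, direction: np.ndarray
    ) -> Optional[Tuple[float, float]]:
        """[t_in, t_out] of the ray with this solid, or None if it misses."""
        o = np.asarray(origin, dtype=float) - np.asarray(self.center)
        d = np.asarray(direction, dtype=float)
        if self.shape == "box":
            h = np.asarray(self.edges) / 2.0
            t0, t1 = -np.inf, np.inf
            for i in range(3):
                if abs(d[i]) < 1e-300:
                    if abs(o[i]) > h[i]:
                        return None
                    continue
                ta = (-h[i] - o[i]) / d[i]
                tb = (h[i] - o[i]) / d[i]
                if ta > tb:
                    ta, tb = tb, ta
                t0, t1 = max(t0, ta), min(t1, tb)
            return (t0, t1) if t1 > t0 else None
        ax = np.asarray(self.axis)
        oz, dz = float(o @ ax), float(d @ ax)
        op, dp = o - oz * ax, d - dz * ax
        a = float(dp @ dp)
        b = 2.0 * float(op @ dp)
        c = float(op @ op) - self.radius**2
        if a < 1e-300:
            if c > 0.0:
                return None
            t0, t1 = -np.inf, np.inf
        else:
            disc = b * b - 4.0 * a * c
            if disc <= 0.0:
                return None
            sq = np.sqrt(disc)
            t0, t1 = (-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)
        hl = self.length / 2.0
        if abs(dz) < 1e-300:
            if abs(oz) > hl:
                return None
        else:
            ta, tb = (-hl - oz) / dz, (hl - oz) / dz
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
        return (t0, t1) if t1 > t0 else None


@dataclass
class Scene:
    """Ordered volumes inside an enclosing air cylinder, plus source levels.

    ``activity`` maps a source volume name either to a concentration in
    kBq/mL (vessels) or a total activity in Bq (body backgrounds); the
    ``activity_kind`` companion says which.
    """

    name: str
    volumes: List[Volume]
    activity: Dict[str, float] = field(default_factory=dict)
    activity_kind: Dict[str, str] = field(default_factory=dict)
    meta: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.volumes or self.volumes[0].role != "air":
            raise ValueError("volumes[0] must be the enclosing air volume")
        names = [v.name for v in self.volumes]
        if len(set(names)) != len(names):
            raise ValueError("volume names must be unique")

    @property
    def world(self) -> Volume:
        return self.volumes[0]

    def volume(self, name: str) -> Volume:
        for v in self.volumes:
            if v.name == name:
                return v
        raise KeyError(name)

    def volumes_by_role(self, role: str) -> List[Volume]:
        return [v for v in self.volumes if v.role == role]

    def locate(self, point: Sequence[float]) -> Volume:
        """Highest-priority volume containing ``point``; error outside world."""
        if not self.world.contains(point):
            raise ValueError("point outside the enclosing air volume")
        best = self.world
        for v in self.volumes[1:]:
            if v.priority > best.priority and v.contains(point):
                best = v
        return best

    def ray_segments(
        self, origin: Sequence[float], direction: Sequence[float], max_length: float
    ) -> List[Tuple[Volume, float, float]]:
        """Partition [0, max_length] along the ray into per-volume segments.

        Segments are contiguous and non-overlapping; each is classified by
        point location at its midpoint.
        """
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be unit-norm")
        cuts = [0.0, float(max_length)]
        for v in self.volumes:
            iv = v.ray_interval(o, d)
            if iv is None:
                continue
            for t in iv:
                if _BOUNDARY_EPS < t < max_length - _BOUNDARY_EPS:
                    cuts.append(float(t))
        cuts = sorted(set(cuts))
        segs: List[Tuple[Volume, float, float]] = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = o + 0.5 * (a + b) * d
            vol = self.locate(mid)
            if segs and segs[-1][0] is vol:
                segs[-1] = (vol, segs[-1][1], b)
            else:
                segs.append((vol, a, b))
        return segs

    def sample_in_volume(
        self, volume: Volume, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Uniform points inside ``volume``, shape (n, 3)."""
        c = np.asarray(volume.center)
        if volume.shape == "box":
            h = np.asarray(volume.edges) / 2.0
            return c + rng.uniform(-h, h, size=(n, 3))
        ax = np.asarray(volume.axis)
        # orthonormal frame around the axis
        t = np.array([1.0, 0.0, 0.0]) if abs(ax[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(ax, t)
        u /= np.linalg.norm(u)
        w = np.cross(ax, u)
        r = volume.radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        za = rng.uniform(-volume.length / 2.0, volume.length / 2.0, n)
        return (
            c
            + np.outer(r * np.cos(phi), u)
            + np.outer(r * np.sin(phi), w)
            + np.outer(za, ax)
        )

    # serialization -------------------------------------------------------
    def to_config(self) -> str:
        doc = {
            "name": self.name,
            "volumes": [dataclasses.asdict(v) for v in self.volumes],
            "activity": dict(self.activity),
            "activity_kind": dict(self.activity_kind),
            "meta": dict(self.meta),
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_config(cls, text: str) -> "Scene":
        doc = yaml.safe_load(text)
        vols = []
        for v in doc["volumes"]:
            v = dict(v)
            for k in ("center", "axis", "edges"):
                if k in v:
                    v[k] = tuple(v[k])
            vols.append(Volume(**v))
        return cls(
            name=doc["name"],
            volumes=vols,
            activity=doc.get("activity", {}),
            activity_kind=doc.get("activity_kind", {}),
            meta=doc.get("meta", {}),
        )

    def geometry_table(self):
        import pandas as pd

        return pd.DataFrame([dataclasses.asdict(v) for v in self.volumes])


def _world(radius_mm: float = 1000.0, length_mm: float = 2000.0) -> Volume:
    return Volume(
        "world_air", "cylinder", (0.0, 0.0, 0.0), "air", "air", 0,
        radius=radius_mm, length=length_mm,
    )


def build_mouse_tail_scene(
    isotope_name: str = "F18",
    body_activity_mbq: float = 10.0,
    bone_material: str = "water",
) -> Scene:
    """Mouse-tail scene: 3.2 mm water tail with a 1 mm bone insert, one
    ventral artery (0.1 mm), three veins (0.2 mm, lateral x2 + dorsal), a
    25 x 70 mm body cylinder, and a 1 mm round fiber 30 mm long with a
    0.1 mm air gap to the skin and 30 mm clearance to the body.

    All vessels sit 0.1 mm below the tail surface.  The two lateral veins
    are at +-90 degrees and the dorsal vein opposite the ventral artery.
    """
    tail_r = 1.6
    tail_len = 60.0
    artery_r = 0.05
    vein_r = 0.1
    depth = 0.1  # surface-to-vessel-surface
    vols = [
        _world(),
        Volume("tail", "cylinder", (0.0, 0.0, 0.0), "water", "tissue", 1,
               radius=tail_r, length=tail_len),
        Volume("bone", "cylinder", (0.0, 0.0, 0.0), bone_material, "bone", 2,
               radius=0.5, length=tail_len),
        Volume("artery", "cylinder", (0.0, -(tail_r - depth - artery_r), 0.0),
               "water", "source_artery", 3, radius=artery_r, length=tail_len),
        Volume("vein_lateral_left", "cylinder",
               (-(tail_r - depth - vein_r), 0.0, 0.0), "water", "source_vein", 3,
               radius=vein_r, length=tail_len),
        Volume("vein_lateral_right", "cylinder",
               ((tail_r - depth - vein_r), 0.0, 0.0), "water", "source_vein", 3,
               radius=vein_r, length=tail_len),
        Volume("vein_dorsal", "cylinder", (0.0, (tail_r - depth - vein_r), 0.0),
               "water", "source_vein", 3, radius=vein_r, length=tail_len),
        Volume("fiber", "cylinder", (0.0, -(tail_r + 0.1 + 0.5), 0.0),
               "polystyrene", "fiber", 3, radius=0.5, length=30.0),
        # body: coaxial with the tail, its near face 30 mm beyond the
        # fiber's near end (fiber spans z in [-15, 15])
        Volume("body", "cylinder", (0.0, 0.0, -45.0 - 35.0), "water",
               "source_body", 1, radius=12.5, length=70.0),
    ]
    return Scene(
        name="mouse_tail",
        volumes=vols,
        activity={"artery": 1.0, "vein_lateral_left": 1.0,
                  "vein_lateral_right": 1.0, "vein_dorsal": 1.0,
                  "body": body_activity_mbq * 1e6},
        activity_kind={"artery": "concentration_kBq_mL",
                       "vein_lateral_left": "concentration_kBq_mL",
                       "vein_lateral_right": "concentration_kBq_mL",
                       "vein_dorsal": "concentration_kBq_mL",
                       "body": "total_Bq"},
        meta={"isotope": isotope_name, "fiber_overlap_mm": 30.0},
    )


def build_human_wrist_scene(
    isotope_name: str = "Ga68",
    vessel_depth_mm: float = 2.0,
    n_fibers: int = 1,
    fiber_shape: str = "round",
    include_background: bool = False,
    background_activity_mbq: float = 176.0,
) -> Scene:
    """Human-wrist scene: 8 cm water cylinder, one 2.3 mm artery at the
    given depth, and 1-4 scintillating fibers 10 cm long at 0.1 mm from
    the skin (round: 1 mm diameter; square: 1 x 1 mm, tiled side by side).

    ``include_background`` adds the 20 x 70 cm body cylinder 30 cm from
    the detector, filled with 176 MBq.
    """
    if not (0.0 <= vessel_depth_mm):
        raise ValueError("depth must be >= 0")
    if n_fibers not in (1, 2, 3, 4):
        raise ValueError("n_fibers must be 1..4")
    if fiber_shape not in ("round", "square"):
        raise ValueError("fiber_shape must be 'round' or 'square'")
    wrist_r = 40.0
    artery_r = 1.15
    vols = [
        _world(),
        Volume("wrist", "cylinder", (0.0, 0.0, 0.0), "water", "tissue", 1,
               radius=wrist_r, length=120.0),
        Volume("artery", "cylinder",
               (0.0, -(wrist_r - vessel_depth_mm - artery_r), 0.0),
               "water", "source_artery", 2, radius=artery_r, length=100.0),
    ]
    fiber_y = -(wrist_r + 0.1 + 0.5)
    if fiber_shape == "round":
        if n_fibers != 1:
            raise ValueError("multi-fiber detectors use square fibers")
        vols.append(
            Volume("fiber_1", "cylinder", (0.0, fiber_y, 0.0), "polystyrene",
                   "fiber", 3, radius=0.5, length=100.0)
        )
    else:
        for i in range(n_fibers):
            x = (i - (n_fibers - 1) / 2.0) * 1.0
            vols.append(
                Volume(f"fiber_{i + 1}", "box", (x, fiber_y, 0.0),
                       "polystyrene", "fiber", 3, edges=(1.0, 1.0, 100.0))
            )
    activity = {"artery": 1.0}
    kind = {"artery": "concentration_kBq_mL"}
    if include_background:
        # body cylinder, axis parallel to the fiber, near surface 30 cm
        # below the detector
        vols.append(
            Volume("body", "cylinder", (0.0, fiber_y - 300.0 - 100.0, 0.0),
                   "water", "source_body", 1, radius=100.0, length=700.0)
        )
        activity["body"] = background_activity_mbq * 1e6
        kind["body"] = "total_Bq"
    return Scene(
        name="human_wrist",
        volumes=vols,
        activity=activity,
        activity_kind=kind,
        meta={"isotope": isotope_name, "vessel_depth_mm": vessel_depth_mm,
              "n_fibers": float(n_fibers), "fiber_overlap_mm": 100.0},
    )


def build_validation_tube_scene(isotope_name: str = "F18") -> Scene:
    """Bench validation scene: a 1 x 1 x 70 mm water tube (70 uL) facing the
    fiber through a 200 um plastic wall and a 200 um air gap.

    The fiber is 7 cm long, square section for F18 and round for Ga68
    (mirroring the two fiber types used on the bench).
    """
    if isotope_name not in ("F18", "Ga68"):
        raise ValueError("validation tube is defined for F18 and Ga68")
    vols = [_world()]
    if isotope_name == "F18":
        vols.append(Volume("fiber", "box", (0.0, 0.0, 0.0), "polystyrene",
                           "fiber", 3, edges=(1.0, 1.0, 70.0)))
        fiber_top = 0.5
    else:
        vols.append(Volume("fiber", "cylinder", (0.0, 0.0, 0.0), "polystyrene",
                           "fiber", 3, radius=0.5, length=70.0))
        fiber_top = 0.5
    wall_y = fiber_top + 0.2 + 0.1  # 200 um air gap then 200 um wall
    vols.append(Volume("wall", "box", (0.0, wall_y, 0.0), "polystyrene",
                       "wall", 2, edges=(1.4, 0.2, 70.0)))
    src_y = wall_y + 0.1 + 0.5
    vols.append(Volume("tube", "box", (0.0, src_y, 0.0), "water",
                       "source_artery", 2, edges=(1.0, 1.0, 70.0)))
    return Scene(
        name="validation_tube",
        volumes=vols,
        activity={"tube": 1.0},
        activity_kind={"tube": "concentration_kBq_mL"},
        meta={"isotope": isotope_name, "fiber_overlap_mm": 70.0},
    )


def subtended_source_volume_ml(scene: Scene) -> float:
    """Source volume subtended by the detector, in mL.

    Vessel cross-section times the axial overlap with the fiber (the full
    tube for the bench scene).
    """
    src = (scene.volumes_by_role("source_artery") or scene.volumes_by_role("source_vein"))[0]
    overlap = scene.meta.get("fiber_overlap_mm")
    if overlap is None:
        overlap = min(v.length if v.shape == "cylinder" else v.edges[2]
                      for v in scene.volumes_by_role("fiber"))
    if src.shape == "cylinder":
        area = np.pi * src.radius**2
    else:
        area = src.edges[0] * src.edges[1]
    return float(area * overlap) / 1000.0
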