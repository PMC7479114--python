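"""Ray-traceable constructive geometry for the neighbourhood world.

The world is a set of axis-aligned boxes (house wall layers, window panes
and their cut-out openings, interior partitions, floor slabs, roofs, ground
slabs) immersed in air, plus planar source regions at z = 0 and detector
spheres.  Two query paths are provided:

* :meth:`Scenario.ray_trace` — exact ordered (length, material) segments
  along a ray, resolved by solid priority (used by the Monte-Carlo engine);
* :meth:`Scenario.optical_depth` — vectorised total optical depth from many
  ground points to one target, using a signed-box formulation in which each
  solid contributes ``(mu_solid - mu_displaced) * chord`` on top of the
  baseline air attenuation (used by the point-kernel engine and the
  next-event estimator).

Coordinates are right-handed, metres, z up, ground plane z = 0.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, mapping

from suburbdose.materials import Material, SOURCE_ENERGY_MEV

__all__ = [
    "GeometryError",
    "Solid",
    "SourceRegion",
    "DetectorSphere",
    "Scenario",
    "region_area",
    "sample_point_in_region",
]

M_TO_CM = 100.0


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Solid:
    """Axis-aligned box of one material.

    ``displaces`` names the material the box is carved out of (air for
    ordinary solids; the wall material for window openings).  ``priority``
    resolves nesting in exact ray tracing: higher wins.
    """

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    material: str
    displaces: str = "air"
    priority: int = 1

    def __post_init__(self) -> None:
        if not all(h > l for l, h in zip(self.lo, self.hi)):
            raise GeometryError(f"degenerate box {self.lo}..{self.hi}")


@dataclass
class SourceRegion:
    """Planar source region at z = 0 with uniform areal activity.

    ``kind`` is "polygon" for gardens/street, "rect_annulus" for the
    far-field region between the neighbourhood bounding rectangle and the
    truncation circle (centre/radius in ``annulus``), or "disk" for a
    circular open-field source (centre/radius in ``disk``); the analytic
    kinds store exact areas since their polygon form is only approximate.
    """

    label: str
    polygon: Polygon
    areal_activity: float = 1.0
    kind: str = "polygon"
    annulus: tuple[float, float, float, float, float, float, float] | None = None
    # annulus = (rect_xmin, rect_ymin, rect_xmax, rect_ymax, cx, cy, radius)
    disk: tuple[float, float, float] | None = None  # (cx, cy, radius)

    def __post_init__(self) -> None:
        if self.kind == "polygon":
            if self.polygon.is_empty or self.polygon.area <= 0:
                raise GeometryError(f"region {self.label}: zero-area polygon")
            if not self.polygon.is_valid:
                raise GeometryError(f"region {self.label}: invalid polygon")

    @property
    def area(self) -> float:
        if self.kind == "rect_annulus":
            x0, y0, x1, y1, cx, cy, r = self.annulus
            return math.pi * r * r - (x1 - x0) * (y1 - y0)
        if self.kind == "disk":
            return math.pi * self.disk[2] ** 2
        return self.polygon.area

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points on the region, shape (n, 2)."""
        if self.kind == "rect_annulus":
            return self._sample_annulus(n, rng)
        if self.kind == "disk":
            cx, cy, r = self.disk
            rad = r * np.sqrt(rng.random(n))
            phi = rng.uniform(0, 2 * math.pi, n)
            return np.c_[cx + rad * np.cos(phi), cy + rad * np.sin(phi)]
        minx, miny, maxx, maxy = self.polygon.bounds
        pts = np.empty((n, 2))
        got = 0
        while got < n:
            m = max(2 * (n - got), 64)
            xs = rng.uniform(minx, maxx, m)
            ys = rng.uniform(miny, maxy, m)
            inside = shapely.contains_xy(self.polygon, xs, ys)
            k = min(int(inside.sum()), n - got)
            pts[got : got + k] = np.c_[xs[inside], ys[inside]][:k]
            got += k
        return pts

    def _sample_annulus(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x0, y0, x1, y1, cx, cy, r = self.annulus
        pts = np.empty((n, 2))
        got = 0
        while got < n:
            m = max(2 * (n - got), 64)
            u = rng.random(m)
            rad = r * np.sqrt(u)
            phi = rng.uniform(0, 2 * math.pi, m)
            xs = cx + rad * np.cos(phi)
            ys = cy + rad * np.sin(phi)
            keep = ~((xs >= x0) & (xs <= x1) & (ys >= y0) & (ys <= y1))
            k = min(int(keep.sum()), n - got)
            pts[got : got + k] = np.c_[xs[keep], ys[keep]][:k]
            got += k
        return pts

    def contains(self, x: float, y: float) -> bool:
        if self.kind == "disk":
            cx, cy, r = self.disk
            return (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        if self.kind == "rect_annulus":
            x0, y0, x1, y1, cx, cy, r = self.annulus
            inside_rect = x0 <= x <= x1 and y0 <= y <= y1
            return (not inside_rect) and (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        return bool(shapely.contains_xy(self.polygon, x, y))


@dataclass(frozen=True)
class DetectorSphere:
    label: str
    center: tuple[float, float, float]
    diameter: float = 0.30

    def __post_init__(self) -> None:
        if abs(self.center[2] - 1.0) > 1e-9:
            raise GeometryError(f"detector {self.label}: centre must be at z = 1 m")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def region_area(region: SourceRegion) -> float:
    """Region area in m^2 (analytic for the far-field annulus)."""
    return region.area


def sample_point_in_region(
    region: SourceRegion, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Uniform sample of n ground points (x, y) on the region at z = 0."""
    if region.area <= 0:
        raise GeometryError(f"region {region.label}: cannot sample zero area")
    return region.sample_points(n, rng)


class Scenario:
    """The assembled 3-D world: solids, source regions and detectors."""

    def __init__(
        self,
        materials: dict[str, Material],
        solids: list[Solid],
        regions: dict[str, SourceRegion],
        detectors: dict[str, DetectorSphere],
        world_radius: float,
        z_range: tuple[float, float] = (-0.5, 60.0),
        metadata: dict | None = None,
    ) -> None:
        self.materials = materials
        self.solids = solids
        self.regions = regions
        self.detectors = detectors
        self.world_radius = float(world_radius)
        self.z_range = z_range
        self.metadata = dict(metadata or {})
        if "air" not in materials:
            raise GeometryError("material library must provide 'air'")
        self._mat_names = sorted(materials)
        self._mat_index = {m: i for i, m in enumerate(self._mat_names)}
        for s in solids:
            if s.material not in materials or s.displaces not in materials:
                raise GeometryError(f"solid references unknown material: {s}")
        if solids:
            self._lo = np.array([s.lo for s in solids])
            self._hi = np.array([s.hi for s in solids])
            self._mat = np.array([self._mat_index[s.material] for s in solids])
            self._disp = np.array([self._mat_index[s.displaces] for s in solids])
            self._prio = np.array([s.priority for s in solids])
        else:
            self._lo = np.zeros((0, 3))
            self._hi = np.zeros((0, 3))
            self._mat = np.zeros(0, dtype=int)
            self._disp = np.zeros(0, dtype=int)
            self._prio = np.zeros(0, dtype=int)
        self._mu_cache: dict[float, np.ndarray] = {}

    # -- material helpers --------------------------------------------------

    @property
    def material_names(self) -> list[str]:
        return list(self._mat_names)

    def mu_vector(self, energy_mev: float) -> np.ndarray:
        """Linear attenuation (1/cm) for every material, indexed like solids."""
        key = round(float(energy_mev), 9)
        if key not in self._mu_cache:
            self._mu_cache[key] = np.array(
                [self.materials[m].linear_attenuation(energy_mev)
                 for m in self._mat_names]
            )
        return self._mu_cache[key]

    # -- world boundary ----------------------------------------------------

    def _world_exit(self, origin: np.ndarray, direction: np.ndarray) -> float:
        """Distance to world escape (cylinder radius R, slab in z)."""
        zmin, zmax = self.z_range
        ts = [np.inf]
        if direction[2] > 1e-12:
            ts.append((zmax - origin[2]) / direction[2])
        elif direction[2] < -1e-12:
            ts.append((zmin - origin[2]) / direction[2])
        # cylinder x^2+y^2=R^2
        a = direction[0] ** 2 + direction[1] ** 2
        if a > 1e-16:
            b = origin[0] * direction[0] + origin[1] * direction[1]
            c = origin[0] ** 2 + origin[1] ** 2 - self.world_radius**2
            disc = b * b - a * c
            if disc > 0:
                t = (-b + math.sqrt(disc)) / a
                if t > 0:
                    ts.append(t)
        return max(min(ts), 0.0)

    def inside_world(self, point: np.ndarray) -> bool:
        zmin, zmax = self.z_range
        return (
            zmin <= point[2] <= zmax
            and point[0] ** 2 + point[1] ** 2 <= self.world_radius**2
        )

    # -- exact ray trace ---------------------------------------------------

    def ray_trace(
        self, origin, direction, max_length: float | None = None
    ) -> list[tuple[float, str]]:
        """Ordered (length m, material name) segments until world escape."""
        origin = np.asarray(origin, dtype=float)
        direction = np.asarray(direction, dtype=float)
        norm = np.linalg.norm(direction)
        if abs(norm - 1.0) > 1e-9:
            raise GeometryError(f"|direction| = {norm}, expected a unit vector")
        if not self.inside_world(origin):
            return []
        t_end = self._world_exit(origin, direction)
        if max_length is not None:
            t_end = min(t_end, max_length)
        if t_end <= 0:
            return []
        if len(self.solids) == 0:
            return [(t_end, "air")]
        with np.errstate(divide="ignore"):
            inv = np.where(np.abs(direction) > 1e-300, 1.0 / direction, np.inf)
        t1 = (self._lo - origin) * inv
        t2 = (self._hi - origin) * inv
        tmin = np.minimum(t1, t2)
        tmax = np.maximum(t1, t2)
        # boxes with zero-direction axes: inside test on that axis
        for ax in range(3):
            if abs(direction[ax]) <= 1e-300:
                ok = (origin[ax] >= self._lo[:, ax]) & (origin[ax] <= self._hi[:, ax])
                tmin[:, ax] = np.where(ok, -np.inf, np.inf)
                tmax[:, ax] = np.where(ok, np.inf, -np.inf)
        t_in = np.clip(tmin.max(axis=1), 0.0, t_end)
        t_out = np.clip(tmax.min(axis=1), 0.0, t_end)
        hit = t_out > t_in + 1e-12
        cuts = np.unique(
            np.concatenate([[0.0, t_end], t_in[hit], t_out[hit]])
        )
        segments: list[tuple[float, str]] = []
        air_idx = self._mat_index["air"]
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a <= 1e-12:
                continue
            mid = (a + b) / 2.0
            covering = hit & (t_in <= mid) & (t_out >= mid)
            if covering.any():
                idx = np.nonzero(covering)[0]
                best = idx[np.argmax(self._prio[idx])]
                mat = int(self._mat[best])
            else:
                mat = air_idx
            name = self._mat_names[mat]
            if segments and segments[-1][1] == name:
                segments[-1] = (segments[-1][0] + (b - a), name)
            else:
                segments.append((b - a, name))
        return segments

    # -- vectorised optical depth -------------------------------------------

    def _chords(self, starts: np.ndarray, end: np.ndarray) -> tuple[np.ndarray, ...]:
        """Chord length of each (start -> end) segment in every box.

        Returns (chords (N, M) in metres, lengths (N,))."""
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
        end = np.asarray(end, dtype=float)
        d = end[None, :] - starts  # (N,3)
        lengths = np.linalg.norm(d, axis=1)
        if len(self.solids) == 0:
            return np.zeros((len(starts), 0)), lengths
        # accumulate entry/exit per axis to avoid (N, M, 3) temporaries;
        # parametrise t in [0, 1]
        tmin = np.full((len(starts), len(self.solids)), -np.inf)
        tmax = np.full_like(tmin, np.inf)
        for ax in range(3):
            dax = d[:, ax:ax + 1]  # (N,1)
            deg = np.abs(dax) <= 1e-300
            inv = 1.0 / np.where(deg, 1e-300, dax)
            t1 = (self._lo[None, :, ax] - starts[:, ax:ax + 1]) * inv
            t2 = (self._hi[None, :, ax] - starts[:, ax:ax + 1]) * inv
            np.maximum(tmin, np.minimum(t1, t2), out=tmin)
            np.minimum(tmax, np.maximum(t1, t2), out=tmax)
            if deg.any():
                inside = (
                    (starts[:, ax][:, None] >= self._lo[None, :, ax])
                    & (starts[:, ax][:, None] <= self._hi[None, :, ax])
                )
                bad = deg & ~inside
                tmin[bad] = np.inf
                tmax[bad] = -np.inf
        np.clip(tmin, 0.0, 1.0, out=tmin)
        np.clip(tmax, 0.0, 1.0, out=tmax)
        chords = np.maximum(tmax - tmin, 0.0) * lengths[:, None]
        return chords, lengths

    def optical_depth(
        self, starts, end, energy_mev: float = SOURCE_ENERGY_MEV,
        chunk: int = 4096,
    ) -> np.ndarray:
        """Total optical depth (dimensionless) from each start to ``end``."""
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
        mu = self.mu_vector(energy_mev)
        air_mu = mu[self._mat_index["air"]]
        coeff = mu[self._mat] - mu[self._disp]  # (M,)
        out = np.empty(len(starts))
        for i in range(0, len(starts), chunk):
            ch, lengths = self._chords(starts[i : i + chunk], np.asarray(end, float))
            out[i : i + chunk] = air_mu * lengths * M_TO_CM + (
                ch @ coeff
            ) * M_TO_CM
        return out

    def optical_depth_multi(
        self, point, targets, energies
    ) -> np.ndarray:
        """Optical depth from one point to many targets at per-target energies.

        Used by the next-event estimator, where the scattered energy (and
        hence every material's attenuation coefficient) differs per detector.
        """
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        energies = np.atleast_1d(np.asarray(energies, dtype=float))
        ch, lengths = self._chords(targets, np.asarray(point, float))
        K = len(self._mat_names)
        mu = np.empty((len(targets), K))
        loge = np.log(energies)
        for i, name in enumerate(self._mat_names):
            tab = self.materials[name].table
            mu[:, i] = self.materials[name].density * np.exp(
                np.interp(loge, np.log(tab.energy), np.log(tab.total))
            )
        air_idx = self._mat_index["air"]
        coeff = mu[:, self._mat] - mu[:, self._disp]  # (N, M)
        return (mu[:, air_idx] * lengths + (ch * coeff).sum(axis=1)) * M_TO_CM

    def material_path_lengths(
        self, starts, end, chunk: int = 4096
    ) -> tuple[np.ndarray, np.ndarray]:
        """Net path length (m) per material for each ray; (N, K) and (N,).

        Column order follows :attr:`material_names`; the air column includes
        the remainder of the ray outside all solids."""
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
        K = len(self._mat_names)
        air_idx = self._mat_index["air"]
        onehot = np.zeros((len(self.solids), K))
        if len(self.solids):
            onehot[np.arange(len(self.solids)), self._mat] += 1.0
            onehot[np.arange(len(self.solids)), self._disp] -= 1.0
        per_mat = np.zeros((len(starts), K))
        lengths_all = np.empty(len(starts))
        for i in range(0, len(starts), chunk):
            ch, lengths = self._chords(starts[i : i + chunk], np.asarray(end, float))
            lengths_all[i : i + chunk] = lengths
            block = ch @ onehot if len(self.solids) else np.zeros((len(lengths), K))
            block[:, air_idx] += lengths - block.sum(axis=1)
            per_mat[i : i + chunk] = block
        return per_mat, lengths_all

    # -- bookkeeping ---------------------------------------------------------

    def digest(self) -> str:
        """Stable hash of the geometry (solids, regions, detectors)."""
        payload = {
            "solids": [
                [list(np.round(s.lo, 9)), list(np.round(s.hi, 9)),
                 s.material, s.displaces, s.priority]
                for s in self.solids
            ],
            "regions": {
                lbl: {
                    "kind": r.kind,
                    "wkt": shapely.to_wkt(r.polygon, rounding_precision=6)
                    if r.kind == "polygon" else None,
                    "annulus": list(np.round(r.annulus, 6)) if r.annulus else None,
                    "areal_activity": r.areal_activity,
                }
                for lbl, r in sorted(self.regions.items())
            },
            "detectors": {
                lbl: [list(np.round(d.center, 9)), d.diameter]
                for lbl, d in sorted(self.detectors.items())
            },
            "world_radius": self.world_radius,
            "z_range": list(self.z_range),
            "materials": {
                m: [self.materials[m].density,
                    dict(sorted(self.materials[m].composition.items()))]
                for m in self._mat_names
            },
        }
        raw = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(raw).hexdigest()

    def to_geojson(self) -> dict:
        """Source regions and house footprints as a GeoJSON FeatureCollection."""
        feats = []
        for lbl, r in sorted(self.regions.items()):
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"label": lbl, "kind": r.kind,
                                   "area_m2": round(r.area, 3)},
                    "geometry": mapping(r.polygon),
                }
            )
        for fp in self.metadata.get("footprints", []):
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"label": fp["label"], "kind": "footprint"},
                    "geometry": mapping(Polygon(fp["coords"])),
                }
            )
        return {"type": "FeatureCollection", "features": feats}


def point_region_membership(
    scenario: Scenario, x: float, y: float
) -> list[str]:
    """Labels of source regions (or footprints) covering ground point (x, y)."""
    hits = [lbl for lbl, r in scenario.regions.items() if r.contains(x, y)]
    for fp in scenario.metadata.get("footprints", []):
        if Polygon(fp["coords"]).contains(Point(x, y)):
            hits.append(fp["label"] + ":footprint")
    return hits
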