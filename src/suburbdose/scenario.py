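"""Neighbourhood scenario: configuration schema and world builder.

The default scenario mimics a Northern European suburban block: 15
rectangular properties (875-1050 m^2 each) in three rows of five, flanking
an L-shaped asphalt street, every property carrying a 150 m^2 single-storey
house of brick or wooden construction.  Properties and street together
cover 16,250 m^2; the far field is a ground annulus out to a truncation
radius.  Gardens (lot minus house footprint), the street and the far field
are the uniform planar source regions; properties P12-P15 carry twelve
30 cm detector spheres each (OP1-OP11 at room centres, OP_OUT at the
garden centre, all 1 m above ground).

Exact lot coordinates of the original block are not published; this builder
reproduces the printed areal constraints with a parameterised layout, and
exposes house placement/orientation per property through the configuration.
House construction build-ups are representative defaults (flagged in the
scenario metadata), not surveyed drawings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import shapely
from pydantic import BaseModel, Field, field_validator
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from suburbdose.geometry import (
    DetectorSphere,
    GeometryError,
    Scenario,
    Solid,
    SourceRegion,
)
from suburbdose.materials import material_library

__all__ = ["ScenarioConfig", "build_neighborhood", "load_config", "save_config"]

NEIGHBORHOOD_AREA = 16250.0  # m^2, properties + street
LOT_AREA_BOUNDS = (875.0, 1050.0)
HOUSE_AREA = 150.0

# default geometric parameters; row-1 depth closes the area bookkeeping so
# that 5 lots x 3 rows + L-shaped street total exactly 16,250 m^2
_LOT_W = 31.0
_STREET_W = 6.0
_D3, _D2 = 30.0, 32.0
_D1 = (NEIGHBORHOOD_AREA - 5 * _LOT_W * _STREET_W - _STREET_W**2) / (
    5 * _LOT_W + _STREET_W
) - _D3 - _D2

_ROW3_LABELS = ["P6", "P8", "P9", "P7", "P10"]  # west to east
_ROW2_LABELS = ["P11", "P12", "P13", "P14", "P15"]
_ROW1_LABELS = ["P1", "P2", "P3", "P4", "P5"]

_BUILD_ORDER = [
    "P12", "P13", "P14", "P15", "P11", "P2", "P3", "P7", "P10",
    "P1", "P4", "P5", "P6", "P8", "P9",
]

WALL_LAYERS = {
    "brick": [("brick", 0.25)],
    "wood": [("wood", 0.022), ("insulation", 0.15), ("wood", 0.013)],
}

DEFAULT_OCCUPANCY = {"OP1": 8.0, "OP2": 0.5, "OP9": 1.0, "OP10": 3.5, "OP11": 1.0}


class WindowSpec(BaseModel):
    width: float = 1.2
    height: float = 1.2
    sill: float = 0.9
    glass_thickness: float = 0.006


class HouseSpec(BaseModel):
    length: float = 15.0
    width: float = 10.0
    height: float = 2.5
    partition_material: str = "wood"
    partition_thickness: float = 0.07
    floor_material: str = "concrete"
    floor_thickness: float = 0.10
    roof_material: str = "wood"
    roof_thickness: float = 0.02
    window: WindowSpec = Field(default_factory=WindowSpec)


class ScenarioConfig(BaseModel):
    """Validated scenario configuration (JSON-serialisable)."""

    flavour: Literal["brick", "wood"] = "brick"
    seed: int = 0
    n_properties: int = Field(default=15, ge=1, le=15)
    truncation_radius: float = 500.0
    include_street: bool = True
    include_surrounding: bool = True
    lot_width: float = _LOT_W
    street_width: float = _STREET_W
    row_depths: tuple[float, float, float] = (_D1, _D2, _D3)  # rows 1..3
    house: HouseSpec = Field(default_factory=HouseSpec)
    wall_layers: dict[str, list[tuple[str, float]]] = Field(
        default_factory=lambda: {k: list(v) for k, v in WALL_LAYERS.items()}
    )
    occupancy_hours: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY)
    )
    instrumented: list[str] = Field(
        default_factory=lambda: ["P12", "P13", "P14", "P15"]
    )
    # label -> (house x0, house y0, orientation in {0, 90, 180, 270})
    placement: dict[str, tuple[float, float, int]] = Field(default_factory=dict)
    material_overrides: dict[str, tuple[float, dict[str, float]]] = Field(
        default_factory=dict
    )

    @field_validator("occupancy_hours")
    @classmethod
    def _check_hours(cls, v):
        if any(h < 0 for h in v.values()):
            raise ValueError("occupancy hours must be non-negative")
        if sum(v.values()) > 24 + 1e-9:
            raise ValueError("occupancy hours exceed 24 h/day")
        return v

    @field_validator("truncation_radius")
    @classmethod
    def _check_radius(cls, v):
        if v < 50:
            raise ValueError("truncation radius must be at least 50 m")
        return v


def load_config(path: str | Path) -> ScenarioConfig:
    return ScenarioConfig.model_validate_json(Path(path).read_text())


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.model_dump(mode="json"), indent=2))


# --------------------------------------------------------------------------
# layout


def _layout(config: ScenarioConfig):
    """Lot rectangles, default house placements and street rectangles."""
    w = config.lot_width
    sw = config.street_width
    d1, d2, d3 = config.row_depths
    H = d1 + d2 + d3 + sw
    lots: dict[str, tuple[float, float, float, float]] = {}
    for j in range(5):
        x0 = j * w
        lots[_ROW3_LABELS[j]] = (x0, 0.0, x0 + w, d3)
        lots[_ROW2_LABELS[j]] = (x0, d3, x0 + w, d3 + d2)
        lots[_ROW1_LABELS[j]] = (x0, d3 + d2 + sw, x0 + w, H)
    streets = [
        (0.0, d3 + d2, 5 * w, d3 + d2 + sw),  # east-west arm
        (5 * w, 0.0, 5 * w + sw, H),  # north-south arm
    ]

    L, W = config.house.length, config.house.width
    placements: dict[str, tuple[float, float, int]] = {}
    # rows are staggered sideways so that window lines do not align across
    # the neighbourhood (a perfectly periodic grid would create artificial
    # window-to-window streaming corridors for distant sources)
    for lbl, (x0, y0, x1, y1) in lots.items():
        cx = x0 + ((x1 - x0) - L) / 2.0
        cy = y0 + ((y1 - y0) - W) / 2.0
        if lbl in _ROW1_LABELS:  # north of street: house toward street (south)
            placements[lbl] = (cx + 2.0, y0 + 4.0, 0)
        elif lbl in _ROW2_LABELS:  # south of street: house toward street (north)
            placements[lbl] = (cx, y1 - W - 4.0, 0)
        else:
            placements[lbl] = (cx - 2.0, cy, 0)
    # P14 sits centrally in its garden; P15 is drawn back from both streets
    x0, y0, x1, y1 = lots["P14"]
    placements["P14"] = (x0 + ((x1 - x0) - L) / 2.0, y0 + ((y1 - y0) - W) / 2.0, 0)
    x0, y0, x1, y1 = lots["P15"]
    placements["P15"] = (x0 + 3.0, y0 + 8.0, 0)
    placements.update(config.placement)
    return lots, placements, streets, (0.0, 0.0, 5 * w + sw, H)


def _rect_transform(u0, v0, u1, v1, place, dims):
    """Axis-aligned local rectangle -> world rectangle under 90-degree turns."""
    hx, hy, orient = place
    L, W = dims
    corners = [(u0, v0), (u1, v0), (u1, v1), (u0, v1)]
    out = []
    for u, v in corners:
        uu, vv, ll, ww = u, v, L, W
        for _ in range((orient // 90) % 4):
            uu, vv = ww - vv, uu
            ll, ww = ww, ll
        out.append((hx + uu, hy + vv))
    xs = [p[0] for p in out]
    ys = [p[1] for p in out]
    return min(xs), min(ys), max(xs), max(ys)


# room plan: (op label, band, u0, u1); bands at v in [5,10] (N) / [0,5] (S)
_NORTH_ROOMS = [("OP1", 0.0, 2.5), ("OP2", 2.5, 5.0), ("OP3", 5.0, 7.5),
                ("OP4", 7.5, 10.0), ("OP5", 10.0, 12.5), ("OP6", 12.5, 15.0)]
_SOUTH_ROOMS = [("OP7", 0.0, 3.0), ("OP8", 3.0, 6.0), ("OP9", 6.0, 9.0),
                ("OP10", 9.0, 12.0), ("OP11", 12.0, 15.0)]


def _build_house(label, place, config: ScenarioConfig, solids, detectors,
                 instrumented: bool):
    h = config.house
    L, W, Hh = h.length, h.width, h.height
    dims = (L, W)
    layers = config.wall_layers[config.flavour]
    t_wall = sum(t for _, t in layers)

    def add(u0, v0, u1, v1, z0, z1, mat, disp="air", prio=3):
        x0, y0, x1, y1 = _rect_transform(u0, v0, u1, v1, place, dims)
        solids.append(Solid((x0, y0, z0), (x1, y1, z1), mat, disp, prio))

    # exterior wall layers, outermost first
    off = 0.0
    for mat, t in layers:
        add(0, off, L, off + t, 0, Hh, mat)  # south strip (v = 0 side)
        add(0, W - off - t, L, W - off, 0, Hh, mat)  # north strip
        add(off, off + t, off + t, W - off - t, 0, Hh, mat)  # west
        add(L - off - t, off + t, L - off, W - off - t, 0, Hh, mat)  # east
        off += t

    # windows: one per room on its exterior-facing wall (N or S)
    win = h.window
    z0w, z1w = win.sill, win.sill + win.height
    glass_v = {}
    for op, u0, u1 in _NORTH_ROOMS:
        glass_v[op] = ("N", (u0 + u1) / 2.0)
    for op, u0, u1 in _SOUTH_ROOMS:
        glass_v[op] = ("S", (u0 + u1) / 2.0)
    for op, (side, uc) in glass_v.items():
        uw0, uw1 = uc - win.width / 2.0, uc + win.width / 2.0
        off = 0.0
        for mat, t in layers:  # per-layer cut-outs
            if side == "N":
                v0, v1 = W - off - t, W - off
            else:
                v0, v1 = off, off + t
            add(uw0, v0, uw1, v1, z0w, z1w, "air", disp=mat, prio=4)
            off += t
        gt = win.glass_thickness
        if side == "N":
            vg = W - t_wall / 2.0
        else:
            vg = t_wall / 2.0
        add(uw0, vg - gt / 2.0, uw1, vg + gt / 2.0, z0w, z1w,
            "glass", disp="air", prio=5)

    # interior partitions on top of the floor slab
    pt = h.partition_thickness / 2.0
    pm = h.partition_material
    zf = h.floor_thickness
    add(t_wall, 5 - pt, L - t_wall, 5 + pt, zf, Hh, pm, prio=2)
    for u in (2.5, 5.0, 7.5, 10.0, 12.5):
        add(u - pt, 5 + pt, u + pt, W - t_wall, zf, Hh, pm, prio=2)
    for u in (3.0, 6.0, 9.0, 12.0):
        add(u - pt, t_wall, u + pt, 5 - pt, zf, Hh, pm, prio=2)

    # floor slab inside the walls, roof over the full footprint
    add(t_wall, t_wall, L - t_wall, W - t_wall, 0, zf, h.floor_material, prio=2)
    add(0, 0, L, W, Hh, Hh + h.roof_thickness, h.roof_material, prio=2)

    # indoor observation points at room centres
    if instrumented:
        for rooms, v0, v1 in ((_NORTH_ROOMS, 5.0, 10.0), (_SOUTH_ROOMS, 0.0, 5.0)):
            for op, u0, u1 in rooms:
                x0, y0, x1, y1 = _rect_transform(
                    (u0 + u1) / 2 - 1e-9, (v0 + v1) / 2 - 1e-9,
                    (u0 + u1) / 2 + 1e-9, (v0 + v1) / 2 + 1e-9, place, dims)
                detectors[f"{label}:{op}"] = DetectorSphere(
                    f"{label}:{op}", ((x0 + x1) / 2, (y0 + y1) / 2, 1.0))

    x0, y0, x1, y1 = _rect_transform(0, 0, L, W, place, dims)
    return shapely_box(x0, y0, x1, y1)


# --------------------------------------------------------------------------


def build_neighborhood(config: ScenarioConfig | None = None) -> Scenario:
    """Assemble the full neighbourhood scenario from a configuration."""
    config = config or ScenarioConfig()
    materials = material_library(
        {k: (d, c) for k, (d, c) in config.material_overrides.items()}
    )
    lots, placements, streets, rect = _layout(config)

    labels = [l for l in _BUILD_ORDER if l in lots][: config.n_properties]
    solids: list[Solid] = []
    detectors: dict[str, DetectorSphere] = {}
    regions: dict[str, SourceRegion] = {}
    footprints = []

    R = config.truncation_radius
    # ground: soil slab under the whole world, asphalt inset in the street
    pad = R + 20.0
    solids.append(Solid((-pad, -pad, -0.5), (pad, pad, 0.0), "soil",
                        displaces="air", priority=1))

    street_polys = []
    if config.include_street:
        for x0, y0, x1, y1 in streets:
            solids.append(Solid((x0, y0, -0.18), (x1, y1, 0.0), "asphalt",
                                displaces="soil", priority=2))
            street_polys.append(shapely_box(x0, y0, x1, y1))

    areas = {}
    for lbl in labels:
        x0, y0, x1, y1 = lots[lbl]
        lot_poly = shapely_box(x0, y0, x1, y1)
        fp = _build_house(lbl, placements[lbl], config, solids, detectors,
                          instrumented=lbl in config.instrumented)
        if not lot_poly.contains(fp):
            raise GeometryError(f"{lbl}: house footprint extends beyond the lot")
        garden = lot_poly.difference(fp)
        regions[lbl] = SourceRegion(lbl, garden)
        areas[lbl] = lot_poly.area
        footprints.append({"label": lbl, "coords": list(fp.exterior.coords)})
        if abs(fp.area - HOUSE_AREA) > 0.5:
            raise GeometryError(f"{lbl}: footprint area {fp.area:.2f} != 150 m^2")
        if lbl in config.instrumented:
            gc = garden.centroid
            if not garden.contains(gc):
                gc = garden.representative_point()
            detectors[f"{lbl}:OP_OUT"] = DetectorSphere(
                f"{lbl}:OP_OUT", (gc.x, gc.y, 1.0))

    if config.include_street and street_polys:
        regions["STREET"] = SourceRegion("STREET", unary_union(street_polys))

    for lbl, a in areas.items():
        if not (LOT_AREA_BOUNDS[0] - 1e-6 <= a <= LOT_AREA_BOUNDS[1] + 1e-6):
            raise GeometryError(
                f"property {lbl} area {a:.1f} m^2 outside {LOT_AREA_BOUNDS}: "
                + ", ".join(f"{k}={v:.1f}" for k, v in areas.items())
            )

    if config.n_properties == 15 and config.include_street:
        total = sum(areas.values()) + regions["STREET"].polygon.area
        if abs(total - NEIGHBORHOOD_AREA) > 1.0:
            raise GeometryError(
                f"neighbourhood area {total:.2f} m^2 != {NEIGHBORHOOD_AREA}: "
                + ", ".join(f"{k}={v:.1f}" for k, v in areas.items())
            )

    if config.include_surrounding:
        x0, y0, x1, y1 = rect
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        circle = shapely.Point(cx, cy).buffer(R, quad_segs=64)
        ann_poly = circle.difference(shapely_box(x0, y0, x1, y1))
        regions["SURROUNDING"] = SourceRegion(
            "SURROUNDING", ann_poly, kind="rect_annulus",
            annulus=(x0, y0, x1, y1, cx, cy, R))

    scenario = Scenario(
        materials=materials,
        solids=solids,
        regions=regions,
        detectors=detectors,
        world_radius=R + 20.0,
        z_range=(-0.5, 60.0),
        metadata={
            "config": config.model_dump(mode="json"),
            "footprints": footprints,
            "property_areas": areas,
            "construction_defaults": "representative (not surveyed drawings)",
            "neighborhood_rect": rect,
        },
    )
    return scenario
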