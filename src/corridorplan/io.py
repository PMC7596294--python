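"""Interchange-format readers and writers.

Rasters travel as ESRI ASCII grids (``.asc``, NODATA honored); refuge
networks as GeoJSON FeatureCollections in projected km; tabular inputs as
CSV with declared headers; ecosystem and scenario definitions as YAML.
Reports are written as JSON (schema-versioned) and CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, mapping, shape

from corridorplan.landscape import CostLayer, FeatureLayer, Landscape
from corridorplan.refuges import RefugePolygon
from corridorplan.simulate import BoxPolygon, Ecosystem, FunctionalGroup, Scenario

REPORT_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending content."""


# ---------------------------------------------------------------------------
# ESRI ASCII grid

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (grid, header).

    NODATA cells come back as NaN; the header dict carries ncols, nrows,
    xllcorner, yllcorner, cellsize and nodata_value.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise FormatError(f"{path}: malformed header line {i + 1}: {line!r}") from None
            data_start = i + 1
        else:
            break
    for key in _ASC_HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing required header key {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    except ValueError as e:
        raise FormatError(f"{path}: malformed data section: {e}") from None
    if values.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: data shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, header


def write_raster(
    grid: np.ndarray,
    path: str | Path,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata_value: float = -9999.0,
) -> None:
    """Write a 2-D grid as an ESRI ASCII raster; NaN becomes NODATA."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise FormatError("raster grids must be 2-D")
    out = np.where(np.isnan(grid), nodata_value, grid)
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {xllcorner}\n"
        f"yllcorner {yllcorner}\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {nodata_value}\n"
    )
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def landscape_from_config(config_path: str | Path) -> Landscape:
    """Build a Landscape from a YAML criteria-stack config.

    The config lists layers with ``path``, ``role`` (feature | cost |
    exclusion) and, for features, ``weight`` or ``rank``; optional top-level
    ``cell_area`` (km²). All rasters must be co-registered.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    allowed = {"layers", "cell_area"}
    unknown = set(cfg) - allowed
    if unknown:
        raise FormatError(f"{config_path}: unknown config keys {sorted(unknown)}")
    base = config_path.parent
    features: list[FeatureLayer] = []
    cost = None
    valid = None
    shape_seen = None
    georef = None
    ranked = [ly for ly in cfg["layers"] if ly.get("role") == "feature" and "weight" not in ly]
    big_r = max((ly.get("rank", i + 1) for i, ly in enumerate(ranked)), default=0)
    for i, ly in enumerate(cfg["layers"]):
        grid, header = read_raster(base / ly["path"])
        ref = (header["xllcorner"], header["yllcorner"], header["cellsize"])
        if shape_seen is None:
            shape_seen, georef = grid.shape, ref
        elif grid.shape != shape_seen or ref != georef:
            raise FormatError(f"{ly['path']}: georeferencing conflicts with previous layers")
        role = ly.get("role", "feature")
        if role == "feature":
            if "weight" in ly:
                w = float(ly["weight"])
            else:
                w = float(2 ** (big_r - ly.get("rank", ranked.index(ly) + 1)))
            features.append(FeatureLayer(ly.get("name", ly["path"]), w, np.nan_to_num(grid)))
            mask = ~np.isnan(grid)
            valid = mask if valid is None else (valid & mask)
        elif role == "cost":
            cost = np.where(np.isnan(grid), 1.0, grid)
        elif role == "exclusion":
            excl = np.nan_to_num(grid) > 0
            valid = ~excl if valid is None else (valid & ~excl)
        else:
            raise FormatError(f"{config_path}: unknown layer role {role!r}")
    cellsize = georef[2] if georef else 1.0
    return Landscape(
        features=features,
        cost=CostLayer(cost) if cost is not None else None,
        valid_mask=valid,
        cell_area=float(cfg.get("cell_area", cellsize**2)),
        origin=(georef[0], georef[1]) if georef else (0.0, 0.0),
        resolution=cellsize,
    )


# ---------------------------------------------------------------------------
# GeoJSON refuges

_REQUIRED_REFUGE_PROPS = ("refuge_id",)


def read_refuges(path: str | Path) -> tuple[list[RefugePolygon], LineString | None]:
    """Read a refuge network (and optional corridor baseline) from GeoJSON.

    Polygon features need a ``refuge_id`` property; ``category``,
    ``subregion_id``, ``habitats`` (list), ``duration_years`` and
    ``whole_ecological_unit`` are honored when present. A LineString
    feature with property ``role: baseline`` supplies the corridor
    baseline.
    """
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    refuges: list[RefugePolygon] = []
    baseline = None
    for feat in fc.get("features", []):
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        if geom.geom_type == "LineString":
            if props.get("role") == "baseline":
                baseline = geom
            continue
        for key in _REQUIRED_REFUGE_PROPS:
            if key not in props:
                raise FormatError(f"{path}: refuge feature missing property {key!r}")
        refuges.append(RefugePolygon(
            refuge_id=str(props["refuge_id"]),
            geometry=geom,
            category=props.get("category", "total_permanent"),
            habitats_present=set(props.get("habitats", [])),
            subregion_id=int(props.get("subregion_id", 0)),
            duration_years=(
                np.inf if props.get("duration_years") is None
                else float(props["duration_years"])
            ),
            whole_ecological_unit=bool(props.get("whole_ecological_unit", False)),
        ))
    return refuges, baseline


def write_refuges(
    refuges: list[RefugePolygon],
    path: str | Path,
    baseline: LineString | None = None,
) -> None:
    """Write a refuge network (plus optional baseline) as GeoJSON."""
    features = []
    for r in refuges:
        features.append({
            "type": "Feature",
            "geometry": mapping(r.geometry),
            "properties": {
                "refuge_id": r.refuge_id,
                "category": r.category,
                "subregion_id": r.subregion_id,
                "habitats": sorted(r.habitats_present),
                "duration_years": None if np.isinf(r.duration_years) else r.duration_years,
                "whole_ecological_unit": r.whole_ecological_unit,
            },
        })
    if baseline is not None:
        features.append({
            "type": "Feature",
            "geometry": mapping(baseline),
            "properties": {"role": "baseline"},
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


# ---------------------------------------------------------------------------
# CSV tables


def read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    """Read a CSV and verify its required columns, naming any missing one."""
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_lengths(path: str | Path) -> pd.DataFrame:
    df = read_table(path, ("species_id", "length_cm"))
    if (df["length_cm"] <= 0).any():
        bad = df.loc[df["length_cm"] <= 0].index[0]
        raise FormatError(f"{path}: non-positive length_cm at row {bad}")
    return df


def read_psa_attributes(path: str | Path) -> pd.DataFrame:
    return read_table(path, ("species_id", "attribute", "axis", "score", "weight", "data_quality"))


def read_life_history(path: str | Path) -> pd.DataFrame:
    return read_table(path, ("species_id",))


def read_seasalt(path: str | Path) -> pd.DataFrame:
    return read_table(path, ("species_id", "attribute", "criterion", "state", "trend"))


# ---------------------------------------------------------------------------
# YAML ecosystem / scenario


def read_ecosystem(path: str | Path) -> Ecosystem:
    """Read an ecosystem definition (groups, boxes, fleets, F) from YAML."""
    cfg = yaml.safe_load(Path(path).read_text())
    groups = [
        FunctionalGroup(
            group_id=g["group_id"], guild=g["guild"], trophic_level=float(g["trophic_level"]),
            carrying_capacity=np.asarray(g["carrying_capacity"], dtype=float),
            intrinsic_growth=float(g["intrinsic_growth"]),
            mean_weight_kg=float(g.get("mean_weight_kg", 1.0)),
            price=float(g.get("price", 0.0)), commercial=bool(g.get("commercial", False)),
            juvenile_fraction=float(g.get("juvenile_fraction", 0.0)),
        )
        for g in cfg["groups"]
    ]
    boxes = [
        BoxPolygon(box_id=int(b["box_id"]), area_km2=float(b["area_km2"]),
                   inside_corridor=bool(b.get("inside_corridor", False)))
        for b in cfg["boxes"]
    ]
    base_f = {
        (e["group_id"], e["fleet"]): float(e["f"]) for e in cfg.get("base_f", [])
    }
    return Ecosystem(
        groups=groups, boxes=boxes, fleets=list(cfg.get("fleets", [])), base_f=base_f,
        adjacency=[tuple(p) for p in cfg.get("adjacency", [])],
        movement_rate=float(cfg.get("movement_rate", 0.1)),
        initial_depletion=float(cfg.get("initial_depletion", 0.5)),
    )


def write_ecosystem(eco: Ecosystem, path: str | Path) -> None:
    cfg = {
        "groups": [
            {
                "group_id": g.group_id, "guild": g.guild, "trophic_level": g.trophic_level,
                "carrying_capacity": [float(v) for v in g.carrying_capacity],
                "intrinsic_growth": g.intrinsic_growth, "mean_weight_kg": g.mean_weight_kg,
                "price": g.price, "commercial": g.commercial,
                "juvenile_fraction": g.juvenile_fraction,
            }
            for g in eco.groups
        ],
        "boxes": [
            {"box_id": b.box_id, "area_km2": b.area_km2, "inside_corridor": b.inside_corridor}
            for b in eco.boxes
        ],
        "fleets": list(eco.fleets),
        "base_f": [
            {"group_id": g, "fleet": f, "f": v} for (g, f), v in eco.base_f.items()
        ],
        "adjacency": [list(p) for p in eco.adjacency],
        "movement_rate": eco.movement_rate,
        "initial_depletion": eco.initial_depletion,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_scenario(path: str | Path) -> Scenario:
    """Read a scenario (reductions, closures, implementation years) from YAML."""
    cfg = yaml.safe_load(Path(path).read_text())
    reductions = {}
    for e in cfg.get("f_reductions", []):
        reductions[(e.get("group_id", "*"), e.get("fleet", "*"))] = float(e["reduction"])
    closures = {}
    for e in cfg.get("refuge_network", []):
        closures[int(e["box_id"])] = e.get("closure", "full")
    horizon = cfg.get("horizon", [2008, 2033])
    return Scenario(
        name=str(cfg.get("name", Path(path).stem)),
        f_reductions=reductions,
        reduction_start_year=cfg.get("reduction_start_year"),
        refuge_network=closures,
        refuge_start_year=cfg.get("refuge_start_year"),
        horizon=(int(horizon[0]), int(horizon[1])),
    )


def write_scenario(s: Scenario, path: str | Path) -> None:
    cfg = {
        "name": s.name,
        "f_reductions": [
            {"group_id": g, "fleet": f, "reduction": v} for (g, f), v in s.f_reductions.items()
        ],
        "reduction_start_year": s.reduction_start_year,
        "refuge_network": [
            {"box_id": b, "closure": c} for b, c in s.refuge_network.items()
        ],
        "refuge_start_year": s.refuge_start_year,
        "horizon": list(s.horizon),
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# ---------------------------------------------------------------------------
# reports


def write_report(obj: dict, path: str | Path) -> None:
    """Write a JSON report with the schema version stamped in."""
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"cannot serialize {type(o)!r}")
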