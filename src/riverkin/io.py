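"""File formats: genotype CSV, river GeoJSON/WKT, report tables.

Genotype CSV dialect (one row per fecal sample):

    sample_id, x, y, year, Y1..Y4, X1..X3, <locus columns>

Coordinates are projected planar metres (x = easting, y = northing). Sexing
marker columns hold 0/1 amplification flags. Each autosomal locus column
holds an unordered call like ``A/T`` or the empty string for missing.

Rivers are read from a GeoJSON FeatureCollection of LineString /
MultiLineString features (each with a ``name`` property) or from a WKT file
(one LINESTRING per line, optionally prefixed ``name:``). Coordinates must
share the samples' CRS; a bounding-box overlap check guards against obvious
CRS mixups.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.wkt
from shapely.geometry import LineString, mapping, shape
from shapely.ops import linemerge

from .geometry import RiverSet
from .records import MISSING, Dyad, Individual, Panel, SampleRecord

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_rivers_geojson",
    "read_rivers",
    "write_individuals_table",
    "write_dyads_table",
    "json_default",
]


def _marker_columns(panel: Panel) -> tuple[list[str], list[str]]:
    y_cols = [f"Y{i + 1}" for i in range(panel.n_y_markers)]
    x_cols = [f"X{i + 1}" for i in range(panel.n_x_markers)]
    return y_cols, x_cols


def write_genotypes(records: list[SampleRecord], panel: Panel, path) -> None:
    """Write sample records in the genotype CSV dialect."""
    y_cols, x_cols = _marker_columns(panel)
    header = ["sample_id", "x", "y", "year"] + y_cols + x_cols + list(panel.locus_names)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for r in records:
            row = [
                r.sample_id,
                repr(float(r.x)),
                repr(float(r.y)),
                "" if r.collection_year is None else r.collection_year,
            ]
            row += [int(v) for v in r.y_calls]
            row += [int(v) for v in r.x_calls]
            row += [panel.code_to_call(l, c) for l, c in enumerate(r.genotype)]
            w.writerow(row)


def read_genotypes(path, panel: Panel) -> list[SampleRecord]:
    """Read and validate the genotype CSV dialect; errors carry line numbers."""
    y_cols, x_cols = _marker_columns(panel)
    expected = ["sample_id", "x", "y", "year"] + y_cols + x_cols + list(panel.locus_names)
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        if header != expected:
            unknown = set(header) - set(expected)
            missing = set(expected) - set(header)
            raise ValueError(
                f"{path}: header mismatch (unknown columns {sorted(unknown)}, "
                f"missing {sorted(missing)})"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(expected):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(expected)} fields, got {len(row)}"
                )
            try:
                x, y = float(row[1]), float(row[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates {row[1:3]}")
            year = int(row[3]) if row[3] else None
            ny, nx = panel.n_y_markers, panel.n_x_markers
            y_calls = [bool(int(v)) for v in row[4 : 4 + ny]]
            x_calls = [bool(int(v)) for v in row[4 + ny : 4 + ny + nx]]
            base = 4 + ny + nx
            try:
                geno = [
                    panel.call_to_code(l, row[base + l]) for l in range(panel.n_loci)
                ]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from e
            records.append(
                SampleRecord(
                    sample_id=row[0],
                    x=x,
                    y=y,
                    genotype=np.array(geno, dtype=np.int8),
                    y_calls=np.array(y_calls),
                    x_calls=np.array(x_calls),
                    collection_year=year,
                )
            )
    return records


def write_rivers_geojson(rivers: RiverSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(line),
        }
        for name, line in rivers
    ]
    doc = {
        "type": "FeatureCollection",
        "properties": {"reference_azimuth_deg": rivers.reference_azimuth_deg},
        "features": features,
    }
    if rivers.extent is not None:
        doc["properties"]["extent"] = list(rivers.extent)
    Path(path).write_text(json.dumps(doc))


def _coerce_linestring(geom, name: str) -> LineString:
    if geom.geom_type == "LineString":
        return geom
    if geom.geom_type == "MultiLineString":
        merged = linemerge(geom)
        if merged.geom_type == "LineString":
            return merged
        raise ValueError(f"river {name!r}: MultiLineString parts do not join end-to-end")
    raise ValueError(f"river {name!r}: unsupported geometry {geom.geom_type}")


def read_rivers(
    path,
    reference_azimuth_deg: float | None = None,
    sample_bounds: tuple[float, float, float, float] | None = None,
) -> RiverSet:
    """Read a RiverSet from GeoJSON or WKT, in file order.

    ``reference_azimuth_deg`` overrides any value stored in the file; if
    neither is present it defaults to the mean river-segment azimuth + 90
    degrees (the line orthogonal to the mean course). ``sample_bounds``
    enables a CRS sanity check: river and sample bounding boxes must overlap.
    """
    path = Path(path)
    text = path.read_text()
    names: list[str] = []
    lines: list[LineString] = []
    stored_azimuth = None
    extent = None
    if text.lstrip().startswith("{"):
        doc = json.loads(text)
        if doc.get("type") != "FeatureCollection":
            raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
        props = doc.get("properties") or {}
        stored_azimuth = props.get("reference_azimuth_deg")
        if "extent" in props:
            extent = tuple(props["extent"])
        for i, feat in enumerate(doc.get("features", [])):
            name = (feat.get("properties") or {}).get("name", f"River {i + 1}")
            geom = shape(feat["geometry"])
            names.append(name)
            lines.append(_coerce_linestring(geom, name))
    else:
        for i, raw in enumerate(l for l in text.splitlines() if l.strip()):
            if ":" in raw.split("(")[0]:
                name, wkt_text = raw.split(":", 1)
                name = name.strip()
            else:
                name, wkt_text = f"River {i + 1}", raw
            geom = shapely.wkt.loads(wkt_text.strip())
            names.append(name)
            lines.append(_coerce_linestring(geom, name))
    if reference_azimuth_deg is None:
        reference_azimuth_deg = (
            float(stored_azimuth)
            if stored_azimuth is not None
            else _default_reference_azimuth(lines)
        )
    rs = RiverSet(
        names=names,
        lines=lines,
        reference_azimuth_deg=float(reference_azimuth_deg),
        extent=extent,
    )
    if sample_bounds is not None and len(lines):
        rb = np.array([l.bounds for l in lines])
        rxmin, rymin = rb[:, 0].min(), rb[:, 1].min()
        rxmax, rymax = rb[:, 2].max(), rb[:, 3].max()
        sxmin, symin, sxmax, symax = sample_bounds
        if rxmax < sxmin or sxmax < rxmin or rymax < symin or symax < rymin:
            import warnings

            warnings.warn(
                "river and sample bounding boxes do not overlap; are both in "
                "the same projected CRS?",
                stacklevel=2,
            )
    return rs


def _default_reference_azimuth(lines: list[LineString]) -> float:
    """Mean river-segment azimuth + 90 degrees (orthogonal reference line)."""
    if not lines:
        return 0.0
    vx = vy = 0.0
    for line in lines:
        c = np.asarray(line.coords)
        seg = np.diff(c, axis=0)
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        # undirected mean via doubled-angle averaging
        ang = np.arctan2(seg[:, 1], seg[:, 0])
        vx += float((lengths * np.cos(2 * ang)).sum())
        vy += float((lengths * np.sin(2 * ang)).sum())
    mean_ang = 0.5 * np.arctan2(vy, vx)  # math convention, radians
    # convert math angle (ccw from +x) to compass azimuth (cw from +y), +90°
    river_azimuth = (90.0 - np.degrees(mean_ang)) % 180.0
    return (river_azimuth + 90.0) % 180.0


def write_individuals_table(individuals: list[Individual], path) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "individual_id": [i.individual_id for i in individuals],
            "sex": [i.sex for i in individuals],
            "n_samples": [i.n_samples for i in individuals],
            "center_x": [i.center[0] for i in individuals],
            "center_y": [i.center[1] for i in individuals],
            "member_sample_ids": [";".join(i.member_sample_ids) for i in individuals],
        }
    )
    df.to_csv(path, index=False)
    return df


def write_dyads_table(dyads: list[Dyad], path) -> pd.DataFrame:
    df = pd.DataFrame([asdict(d) for d in dyads])
    df.to_csv(path, index=False)
    return df


def json_default(obj):
    """JSON encoder hook for numpy scalars/arrays and dataclasses."""
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
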