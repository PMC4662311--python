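"""Readers and writers for the tabular and geometric dialects.

Formats (all plain text, documented in the README):

* genotype CSV — GenAlEx-like wide layout: ``sample_id`` then two
  columns per locus named ``<locus>_1`` / ``<locus>_2``; missing
  genotype coded ``0,0``; a half-missing pair is a format error.
* replicate CSV — long layout ``scat_id,pcr_id,locus_id,allele_a,allele_b``
  with ``0,0`` meaning the reaction failed.
* detections CSV — ``scat_id,x,y,occasion`` (planar meters, 1-based
  occasions).
* transects / habitat — GeoJSON (LineString / Polygon features), with a
  CSV fallback for transects (``transect_id,x,y`` vertex rows in order).

All writers are bit-stable given fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from shapely.geometry import LineString, MultiPolygon, Polygon, mapping, shape

from .dtypes import (
    FormatError,
    GenotypeTable,
    Genotype,
    ReplicateRecord,
    ReplicateSet,
    SurveyGeometry,
    ValidationError,
)


# ---------------------------------------------------------------- genotypes

def _parse_allele(value, where: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"non-numeric allele {value!r} at {where}")
    if f != int(f):
        raise FormatError(f"non-integer allele {value!r} at {where}")
    a = int(f)
    if a < 0:
        raise FormatError(f"negative allele {a} at {where}")
    return a


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Read a GenAlEx-dialect wide genotype CSV."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if not cols or cols[0] != "sample_id":
        raise FormatError("first column must be 'sample_id'")
    allele_cols = cols[1:]
    if len(allele_cols) % 2 != 0:
        raise FormatError("odd number of allele columns; need two per locus")
    loci = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        base1 = c1.rsplit("_", 1)[0]
        base2 = c2.rsplit("_", 1)[0]
        if base1 != base2:
            raise FormatError(f"columns {c1!r}/{c2!r} do not form a locus pair")
        loci.append(base1)
    samples = [str(s) for s in df["sample_id"]]
    calls: dict[tuple[str, str], Optional[Genotype]] = {}
    for row_i, row in df.iterrows():
        s = str(row["sample_id"])
        for j, locus in enumerate(loci):
            a = _parse_allele(row[allele_cols[2 * j]], f"row {row_i}, locus {locus}")
            b = _parse_allele(row[allele_cols[2 * j + 1]], f"row {row_i}, locus {locus}")
            if a == 0 and b == 0:
                calls[(s, locus)] = None
            elif a == 0 or b == 0:
                raise FormatError(
                    f"half-missing genotype ({a},{b}) for sample {s}, locus {locus}"
                )
            else:
                calls[(s, locus)] = (a, b)
    return GenotypeTable(samples, loci, calls)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    cols = ["sample_id"]
    for l in table.loci:
        cols += [f"{l}_1", f"{l}_2"]
    rows = []
    for s in table.samples:
        row = [s]
        for l in table.loci:
            g = table.genotype(s, l)
            row += [0, 0] if g is None else [g[0], g[1]]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------- replicates

def read_replicates(path: str | Path) -> ReplicateSet:
    df = pd.read_csv(path)
    req = ["scat_id", "pcr_id", "locus_id", "allele_a", "allele_b"]
    if list(df.columns) != req:
        raise FormatError(f"replicate CSV needs columns {req}, got {list(df.columns)}")
    records = []
    for i, row in df.iterrows():
        a = _parse_allele(row["allele_a"], f"row {i}")
        b = _parse_allele(row["allele_b"], f"row {i}")
        if a == 0 and b == 0:
            call = None
        elif a == 0 or b == 0:
            raise FormatError(f"half-missing replicate call ({a},{b}) at row {i}")
        else:
            call = (min(a, b), max(a, b))
        records.append(
            ReplicateRecord(str(row["scat_id"]), str(row["pcr_id"]), str(row["locus_id"]), call)
        )
    return ReplicateSet(records)


def write_replicates(reps: ReplicateSet, path: str | Path) -> None:
    rows = []
    for r in reps.records:
        a, b = (0, 0) if r.call is None else r.call
        rows.append((r.scat_id, r.pcr_id, r.locus_id, a, b))
    pd.DataFrame(
        rows, columns=["scat_id", "pcr_id", "locus_id", "allele_a", "allele_b"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- geometry

def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    req = {"scat_id", "x", "y", "occasion"}
    if not req.issubset(df.columns):
        raise FormatError(f"detections CSV needs columns {sorted(req)}")
    if df["occasion"].isna().any():
        raise FormatError("missing occasion in detections CSV")
    df = df.copy()
    df["scat_id"] = df["scat_id"].astype(str)
    df["occasion"] = df["occasion"].astype(int)
    return df


def write_detections(det: pd.DataFrame, path: str | Path) -> None:
    det[["scat_id", "x", "y", "occasion"]].to_csv(path, index=False)


def _geojson_geoms(path: str | Path) -> list:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in gj["features"]]
    if gj.get("type") == "Feature":
        return [shape(gj["geometry"])]
    return [shape(gj)]


def read_transects(path: str | Path) -> list[LineString]:
    """Transect polylines from GeoJSON, or from a transect_id,x,y CSV."""
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        geoms = _geojson_geoms(path)
        lines = [g for g in geoms if isinstance(g, LineString)]
        if len(lines) != len(geoms):
            raise FormatError("transect GeoJSON must contain only LineStrings")
        return lines
    df = pd.read_csv(path)
    req = {"transect_id", "x", "y"}
    if not req.issubset(df.columns):
        raise FormatError(f"transect CSV needs columns {sorted(req)}")
    lines = []
    for _, grp in df.groupby("transect_id", sort=True):
        if len(grp) < 2:
            raise FormatError("a transect needs at least 2 vertices")
        lines.append(LineString(grp[["x", "y"]].to_numpy(float)))
    return lines


def write_transects(lines: list[LineString], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"transect_id": i}, "geometry": mapping(l)}
        for i, l in enumerate(lines)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_habitat(path: str | Path) -> Polygon | MultiPolygon:
    geoms = _geojson_geoms(path)
    polys = [g for g in geoms if isinstance(g, (Polygon, MultiPolygon))]
    if not polys:
        raise FormatError("habitat GeoJSON contains no Polygon")
    if len(polys) == 1:
        return polys[0]
    flat = []
    for g in polys:
        flat.extend(g.geoms if isinstance(g, MultiPolygon) else [g])
    return MultiPolygon(flat)


def write_habitat(poly: Polygon | MultiPolygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"type": "Feature", "properties": {}, "geometry": mapping(poly)}, fh, indent=1
        )


def read_survey(
    path_transects: str | Path,
    path_habitat: Optional[str | Path],
    path_detections: str | Path,
) -> SurveyGeometry:
    """Assemble a validated :class:`SurveyGeometry` from files."""
    transects = read_transects(path_transects)
    habitat = read_habitat(path_habitat) if path_habitat else None
    detections = read_detections(path_detections)
    return SurveyGeometry(transects=transects, habitat=habitat, detections=detections)
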