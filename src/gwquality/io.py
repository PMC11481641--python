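"""File I/O: monitoring CSVs, index tables, GeoJSON points, ASCII rasters.

The monitoring table schema is long-format CSV with columns
``well_id, year, x, y, pH, EC, NH4, NO2, NO3, PO4, COD, Na`` — one row per
well x sampling year, comma delimited, dot decimal, empty cells meaning a
missing measurement. Rasters are written as ESRI ASCII grids with a ``.prj``
sidecar carrying the coordinate-system identifier, a plain-text format every
GIS reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .indices import IndexResult, WellSample
from .spatial import RasterGrid

__all__ = [
    "MonitoringDataset",
    "SchemaError",
    "PARAMETER_COLUMNS",
    "read_samples_csv",
    "write_samples_csv",
    "write_index_csv",
    "read_index_csv",
    "write_geojson_points",
    "write_raster",
    "read_raster",
]

PARAMETER_COLUMNS = ["pH", "EC", "NH4", "NO2", "NO3", "PO4", "COD", "Na"]
_MANDATORY = ["well_id", "year", "x", "y", *PARAMETER_COLUMNS]


class SchemaError(ValueError):
    """Monitoring table violates the expected schema."""


@dataclass
class MonitoringDataset:
    """A well x year sample collection with study metadata."""

    samples: list[WellSample]
    boundary_year: int = 2014
    crs: str = ""
    provenance: str = "measured"  # 'measured' | 'synthetic seed=<n>'

    def __post_init__(self) -> None:
        seen = set()
        for s in self.samples:
            key = (s.well_id, s.year)
            if key in seen:
                raise SchemaError(f"duplicate record for well {key[0]}, year {key[1]}")
            seen.add(key)

    @property
    def years(self) -> list[int]:
        return sorted({s.year for s in self.samples})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {"well_id": s.well_id, "year": s.year, "x": s.x, "y": s.y,
                   "period": s.period}
            for c in PARAMETER_COLUMNS:
                row[c] = s.values.get(c, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def read_samples_csv(
    path: str | Path, boundary_year: int = 2014, crs: str = ""
) -> MonitoringDataset:
    """Read a long-format monitoring CSV, validating every row.

    Periods are derived from ``boundary_year``. Schema violations raise
    :class:`SchemaError` naming the missing column; row-level problems
    (unparseable numbers, out-of-range values) are collected and reported
    together with their 1-based data row numbers.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    samples: list[WellSample] = []
    problems: list[str] = []
    for i, row in frame.iterrows():
        rowno = int(i) + 1
        try:
            values: dict[str, float] = {}
            for c in PARAMETER_COLUMNS:
                cell = row[c]
                if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                        or str(cell).strip() == "":
                    continue
                values[c] = float(cell)
            year = int(row["year"])
            samples.append(
                WellSample(
                    well_id=str(row["well_id"]),
                    year=year,
                    x=float(row["x"]),
                    y=float(row["y"]),
                    values=values,
                    period="pre_sewerage" if year < boundary_year else "post_sewerage",
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {rowno}: {exc}")
    if problems:
        raise SchemaError("invalid rows:\n" + "\n".join(problems))
    return MonitoringDataset(samples, boundary_year=boundary_year, crs=crs)


def write_samples_csv(dataset: MonitoringDataset, path: str | Path) -> None:
    frame = dataset.to_frame().drop(columns=["period"])
    frame.to_csv(path, index=False)


def write_index_csv(results: list[IndexResult], path: str | Path) -> None:
    """Index table: both indices, ranks, labels, and the Qn/Cfi breakdown."""
    if not results:
        raise ValueError("no index results to write")
    rows = []
    for r in results:
        row = {
            "well_id": r.well_id,
            "year": r.year,
            "wqi": r.wqi,
            "rank_wqs": r.rank_wqs,
            "wqs_label": r.wqs_label,
            "cd": r.cd,
            "rank_cds": r.rank_cds,
            "cds_label": r.cds_label,
        }
        for c, q in r.breakdown.qn.items():
            row[f"Qn_{c}"] = q
        for c in r.breakdown.wn:
            row[f"Cfi_{c}"] = r.breakdown.cfi.get(c, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_index_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_geojson_points(
    results: list[IndexResult],
    coordinates: dict[str, tuple[float, float]],
    path: str | Path,
    crs: str = "",
) -> None:
    """Write index results as a GeoJSON FeatureCollection of well points."""
    if not results:
        raise ValueError("no index results to write")
    features = []
    for r in results:
        x, y = coordinates[r.well_id]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {
                    "well_id": r.well_id,
                    "year": r.year,
                    "wqi": r.wqi,
                    "rank_wqs": r.rank_wqs,
                    "wqs_label": r.wqs_label,
                    "cd": r.cd,
                    "rank_cds": r.rank_cds,
                    "cds_label": r.cds_label,
                },
            }
        )
    doc: dict = {"type": "FeatureCollection", "features": features}
    if crs:
        doc["crs_id"] = crs
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (+ ``.prj`` sidecar with the CRS id).

    Values are written with ``repr`` round-trip precision so read-back is
    bit-exact.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {grid.origin[1]!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    if grid.crs:
        path.with_suffix(".prj").write_text(grid.crs + "\n")


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    crs = ""
    prj = path.with_suffix(".prj")
    if prj.exists():
        crs = prj.read_text().strip()
    return RasterGrid(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        values=np.array(rows),
        crs=crs,
        nodata=header.get("nodata_value", -9999.0),
    )
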