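"""Readers and writers for the screen's plain-text formats.

All tables are UTF-8 comma-separated files with '.' decimals:

* plate readings — long format, columns ``plate_id,well,channel,value``;
* plate layouts — ``plate_id,well,role,gene_id,topography,library,replicate``;
* library manifest — ``gene_id,library,display_name``;
* hit table — one row per gene per topography with scores, filter status,
  category, test results and the secondary-candidate flag.

A grid importer is provided as a convenience for 8x12 plate-reader dumps;
it converts to long form immediately (grids are ambiguous about plate and
channel identity, so long form is the canonical representation).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .plate import (
    CHANNELS,
    Library,
    LayoutError,
    PlateLayout,
    ROWS,
    ScreenDataset,
    Topography,
    WellAddress,
    WellAssignment,
    WellRole,
    validate_layout,
)

__all__ = [
    "read_plate_table",
    "write_plate_table",
    "read_layout_table",
    "write_layout_table",
    "read_plate_grid",
    "read_library_manifest",
    "write_hit_table",
    "read_hit_table",
]

logger = logging.getLogger("osteoscreen")

HIT_TABLE_COLUMNS = [
    "gene_id",
    "library",
    "topography",
    "viability_score",
    "osteo_score",
    "fold_change",
    "filter_status",
    "category",
    "t_stat",
    "p_perm",
    "p_bonferroni",
    "secondary_candidate",
]


def read_plate_table(path, layouts: Mapping[str, PlateLayout]) -> ScreenDataset:
    """Read a long-format readings CSV against already-loaded layouts.

    Every row must reference a known plate, a valid well and a known
    channel; duplicate (plate, well, channel) keys are rejected.  Negative
    raw values are accepted with a warning (instrument exports occasionally
    carry negative baselines).
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "channel": str})
    required = {"plate_id", "well", "channel", "value"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if row.plate_id not in layouts:
            raise LayoutError(f"{path} line {i}: unknown plate_id {row.plate_id!r}")
        addr = WellAddress.parse(row.well)  # raises with the address echoed
        if addr not in layouts[row.plate_id].wells:
            raise LayoutError(f"{path} line {i}: well {row.well} not in layout")
        if row.channel not in CHANNELS:
            raise LayoutError(
                f"{path} line {i}: unknown channel {row.channel!r} "
                f"(expected one of {CHANNELS})"
            )
    if (df["value"] < 0).any():
        n = int((df["value"] < 0).sum())
        warnings.warn(
            f"{path}: {n} negative raw values (accepting; possibly "
            "background-subtracted export)",
            stacklevel=2,
        )
    dataset = ScreenDataset(layouts=dict(layouts), readings=df)
    dataset.validate()
    return dataset


def write_plate_table(dataset: ScreenDataset, path) -> Path:
    path = Path(path)
    dataset.readings.to_csv(path, index=False, float_format="%.12g")
    return path


def read_layout_table(path) -> dict[str, PlateLayout]:
    """Read plate layouts from the layout CSV format."""
    df = pd.read_csv(
        path,
        dtype={"plate_id": str, "well": str, "role": str, "gene_id": str},
        keep_default_na=False,
    )
    layouts: dict[str, PlateLayout] = {}
    for pid, sub in df.groupby("plate_id", sort=True):
        topo = Topography(sub["topography"].iloc[0])
        lib = Library(sub["library"].iloc[0])
        rep = int(sub["replicate"].iloc[0])
        wells = {}
        for row in sub.itertuples(index=False):
            addr = WellAddress.parse(row.well)
            role = WellRole(row.role)
            gene = row.gene_id or None
            wells[addr] = WellAssignment(role, gene)
        layout = PlateLayout(pid, topo, lib, rep, wells)
        bad = validate_layout(layout)
        if bad:
            raise LayoutError(f"{path}: plate {pid}: " + "; ".join(bad))
        layouts[pid] = layout
    if not layouts:
        raise LayoutError(f"{path}: no layouts found")
    return layouts


def write_layout_table(layouts: Mapping[str, PlateLayout], path) -> Path:
    path = Path(path)
    frames = [layouts[p].to_frame() for p in sorted(layouts)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_plate_grid(path, plate_id: str, channel: str) -> pd.DataFrame:
    """Convert an 8x12 grid dump (rows A-H x columns 1-12) to long form.

    The grid must carry the row letters as its index column and column
    numbers as header.  Returns a long table ready to concatenate into a
    readings CSV.
    """
    grid = pd.read_csv(path, index_col=0)
    if list(grid.index) != list(ROWS) or len(grid.columns) != 12:
        raise LayoutError(
            f"{path}: expected an 8x12 grid with index A-H and 12 columns"
        )
    rows = []
    for r in ROWS:
        for ci, col in enumerate(grid.columns, start=1):
            rows.append(
                {
                    "plate_id": plate_id,
                    "well": f"{r}{ci}",
                    "channel": channel,
                    "value": float(grid.loc[r, col]),
                }
            )
    return pd.DataFrame(rows)


def read_library_manifest(path) -> pd.DataFrame:
    """Read the gene manifest (``gene_id,library,display_name``).

    Gene ids must be unique; per-library counts are logged (the screened
    collections held 636 kinase and 237 phosphatase genes).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"gene_id", "library"}
    if df.empty:
        if not required <= set(df.columns):
            logger.warning("%s: empty manifest", path)
            return pd.DataFrame(columns=["gene_id", "library", "display_name"])
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"{path}: missing columns {sorted(missing)}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise LayoutError(
            f"{path}: duplicate gene_id {df.loc[dup, 'gene_id'].iloc[0]!r}"
        )
    bad_lib = set(df["library"]) - {l.value for l in Library}
    if bad_lib:
        raise LayoutError(f"{path}: unknown libraries {sorted(bad_lib)}")
    counts = df.groupby("library").size().to_dict()
    if df.empty:
        logger.warning("%s: empty manifest", path)
    else:
        logger.info("%s: manifest counts %s", path, counts)
    if "display_name" not in df.columns:
        df["display_name"] = df["gene_id"]
    return df


def write_hit_table(genes: pd.DataFrame, path) -> Path:
    """Write the finalized hit table (one row per gene per topography)."""
    df = genes.copy()
    if "fold_change" not in df.columns and "osteo_raw" in df.columns:
        df["fold_change"] = df["osteo_raw"]
    for col in HIT_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[HIT_TABLE_COLUMNS]
    path = Path(path)
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise LayoutError(f"cannot write hit table to {path}: {exc}") from exc
    return path


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene_id": str})
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise LayoutError(f"{path}: missing columns {sorted(missing)}")
    return df
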