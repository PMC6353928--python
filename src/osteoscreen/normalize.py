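"""Plate normalization chain for the screen readouts.

The chain, applied per channel in this fixed order:

1. background subtraction — per plate, the mean of the BACKGROUND-well
   readings is subtracted from every well of that plate;
2. edge-effect correction — per plate, a correction factor
   ``trimmed_mean(interior) / trimmed_mean(edge)`` (20% trimmed from each
   tail) multiplies every edge well, flattening the evaporation-driven bias
   of the outer well ring;
3. plate-scale normalization — every well is divided by the 20% trimmed
   mean of the plate's wells excluding assay (positive) controls, absorbing
   plate-to-plate drift;
4. fold change versus mock — every well is divided by the median of all
   normalized mock-transfection wells across plates, so a fold change of 1
   means "like a mock-transfected well".

Negative values can appear after background subtraction; they are handled
later by the outlier filter, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plate import CHANNELS, WellRole

__all__ = [
    "NormalizationError",
    "trimmed_mean",
    "subtract_background",
    "edge_correct",
    "plate_normalize",
    "fold_change_vs_mock",
    "normalize_readings",
    "POSITIVE_CONTROL_ROLES",
]


class NormalizationError(ValueError):
    pass


#: Roles excluded from the plate-scale trimmed mean.  Mock and scrambled
#: wells behave like null samples and stay in; the assay controls
#: (cell-death, media-only, secondary-only, background) do not.
POSITIVE_CONTROL_ROLES = (
    WellRole.CELL_DEATH.value,
    WellRole.MEDIA_GROWTH.value,
    WellRole.MEDIA_MINERALIZATION.value,
    WellRole.CELLS_SECONDARY_ONLY.value,
    WellRole.BACKGROUND.value,
)


def trimmed_mean(values: Sequence[float], trim_fraction: float = 0.2) -> float:
    """Mean after dropping ``floor(trim_fraction*n)`` values from each tail.

    With ``trim_fraction=0`` this is the plain mean.  Matches
    ``scipy.stats.trim_mean``'s truncation rule.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise NormalizationError("trimmed_mean of empty sequence")
    if not (0 <= trim_fraction < 0.5):
        raise NormalizationError(
            f"trim_fraction must be in [0, 0.5), got {trim_fraction}"
        )
    k = int(math.floor(trim_fraction * arr.size))
    if 2 * k >= arr.size:
        raise NormalizationError(
            f"trimming {k} from each tail of {arr.size} values leaves nothing"
        )
    arr = np.sort(arr)
    return float(arr[k : arr.size - k].mean())


def _require_columns(df: pd.DataFrame, cols: Iterable[str], stage: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise NormalizationError(f"{stage}: missing columns {sorted(missing)}")


def subtract_background(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract the per-plate, per-channel mean of BACKGROUND wells.

    Parameters
    ----------
    df : annotated readings (``ScreenDataset.annotated()`` columns).

    Returns the corrected table and a record table with columns
    ``plate_id, channel, background_value``.
    """
    _require_columns(df, ("plate_id", "channel", "value", "role"), "subtract_background")
    df = df.copy()
    is_bg = df["role"] == WellRole.BACKGROUND.value
    bg = (
        df[is_bg]
        .groupby(["plate_id", "channel"], sort=True)["value"]
        .mean()
        .rename("background_value")
    )
    groups = df.groupby(["plate_id", "channel"], sort=True).size()
    missing = groups.index.difference(bg.index)
    if len(missing):
        pid, ch = missing[0]
        raise NormalizationError(
            f"plate {pid} channel {ch} has no BACKGROUND reading"
        )
    key = pd.MultiIndex.from_frame(df[["plate_id", "channel"]])
    df["value"] = df["value"].to_numpy() - bg.reindex(key).to_numpy()
    return df, bg.reset_index()


def edge_correct(
    df: pd.DataFrame, trim_fraction: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multiply edge wells by ``tm(interior)/tm(edge)`` per plate/channel.

    Trimmed means are computed over cell-containing wells (every role except
    BACKGROUND); the factor is applied to all edge wells.  After correction
    the trimmed means of edge and interior cell wells agree to floating
    precision, because a positive scale factor commutes with trimming.
    """
    _require_columns(df, ("plate_id", "channel", "value", "role", "is_edge"), "edge_correct")
    df = df.copy()
    cells = df["role"] != WellRole.BACKGROUND.value
    records = []
    values = df["value"].to_numpy(dtype=float, copy=True)
    for (pid, ch), idx in df.groupby(["plate_id", "channel"], sort=True).groups.items():
        sub = df.loc[idx]
        inner = sub.loc[cells.loc[idx] & ~sub["is_edge"], "value"]
        edge = sub.loc[cells.loc[idx] & sub["is_edge"], "value"]
        if len(inner) < 5 or len(edge) < 5:
            raise NormalizationError(
                f"plate {pid} channel {ch}: need >=5 interior and >=5 edge "
                f"cell wells, got {len(inner)}/{len(edge)}"
            )
        tm_edge = trimmed_mean(edge, trim_fraction)
        tm_inner = trimmed_mean(inner, trim_fraction)
        if tm_edge <= 0:
            raise NormalizationError(
                f"plate {pid} channel {ch}: trimmed mean of edge wells is "
                f"{tm_edge:.4g} <= 0; edge correction factor undefined"
            )
        factor = tm_inner / tm_edge
        mask = df.index.isin(idx) & df["is_edge"].to_numpy()
        values[mask] *= factor
        records.append(
            {"plate_id": pid, "channel": ch, "edge_correction_factor": factor}
        )
    df["value"] = values
    return df, pd.DataFrame(records)


def plate_normalize(
    df: pd.DataFrame,
    trim_fraction: float = 0.2,
    positive_control_roles: Sequence[str] = POSITIVE_CONTROL_ROLES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide every well by the plate's 20% trimmed mean of eligible wells.

    Eligible wells are those whose role is not a positive control; after
    this step their trimmed mean is 1.  Control wells are still divided.
    """
    _require_columns(df, ("plate_id", "channel", "value", "role"), "plate_normalize")
    df = df.copy()
    eligible = ~df["role"].isin(positive_control_roles)
    records = []
    values = df["value"].to_numpy(dtype=float, copy=True)
    for (pid, ch), idx in df.groupby(["plate_id", "channel"], sort=True).groups.items():
        elig_vals = df.loc[idx][eligible.loc[idx]]["value"]
        if len(elig_vals) < 5:
            raise NormalizationError(
                f"plate {pid} channel {ch}: only {len(elig_vals)} eligible "
                "wells for plate normalization"
            )
        scale = trimmed_mean(elig_vals, trim_fraction)
        if scale <= 0:
            raise NormalizationError(
                f"plate {pid} channel {ch}: plate scale {scale:.4g} <= 0"
            )
        values[df.index.isin(idx)] /= scale
        records.append({"plate_id": pid, "channel": ch, "plate_scale": scale})
    df["value"] = values
    return df, pd.DataFrame(records)


def fold_change_vs_mock(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide by the per-channel median of all normalized MOCK wells.

    The median is taken across all plates, so the resulting fold changes are
    relative to the screen-wide mock-transfection behaviour; by construction
    the median mock fold change is exactly 1.
    """
    _require_columns(df, ("channel", "value", "role"), "fold_change_vs_mock")
    df = df.copy()
    mock = df[df["role"] == WellRole.MOCK.value]
    if mock.empty:
        raise NormalizationError("no MOCK wells in dataset")
    records = []
    values = df["value"].to_numpy(dtype=float, copy=True)
    for ch, idx in df.groupby("channel", sort=True).groups.items():
        mvals = mock.loc[mock["channel"] == ch, "value"]
        if mvals.empty:
            raise NormalizationError(f"channel {ch}: no MOCK wells")
        med = float(np.median(mvals))
        if med <= 0:
            raise NormalizationError(
                f"channel {ch}: mock median {med:.4g} <= 0"
            )
        values[df.index.isin(idx)] /= med
        records.append({"channel": ch, "mock_median": med})
    df["value"] = values
    return df, pd.DataFrame(records)


def normalize_readings(
    df: pd.DataFrame,
    trim_fraction: float = 0.2,
    positive_control_roles: Sequence[str] = POSITIVE_CONTROL_ROLES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full chain: background -> edge -> plate scale -> fold change.

    Returns the table with ``value`` now holding mock-relative fold changes,
    and a per-plate/channel record table merging the background value, edge
    correction factor, plate scale and mock median.
    """
    df, bg = subtract_background(df)
    df, edge = edge_correct(df, trim_fraction)
    df, scale = plate_normalize(df, trim_fraction, positive_control_roles)
    df, mock = fold_change_vs_mock(df)
    records = bg.merge(edge, on=["plate_id", "channel"]).merge(
        scale, on=["plate_id", "channel"]
    )
    records = records.merge(mock, on="channel", how="left")
    return df, records
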