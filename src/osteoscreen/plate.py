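"""96-well plate geometry, well roles and layout validation.

Every downstream stage keys on the objects defined here: a
:class:`WellAddress` on the 8x12 grid, the :class:`WellRole` a well plays in
the screen (library sample or one of the internal controls), the
:class:`PlateLayout` mapping wells to roles/genes for one physical plate, and
the :class:`ScreenDataset` bundling layouts with raw per-well readings.

The edge/interior distinction used by the edge-effect correction is the
outermost well ring (rows A/H, columns 1/12): 36 edge wells, 60 interior.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "ROWS",
    "N_COLS",
    "WellAddress",
    "WellRole",
    "Topography",
    "Library",
    "CHANNELS",
    "WellAssignment",
    "PlateLayout",
    "ScreenDataset",
    "LayoutError",
    "is_edge_well",
    "all_wells",
    "default_layout",
    "validate_layout",
    "SAMPLE_CAPACITY",
]

ROWS = "ABCDEFGH"
N_COLS = 12

#: Readout channels of the screen: resazurin viability dye and the RUNX2
#: in-cell-western signal.
CHANNELS = ("alamar_blue", "runx2")

_ADDR_RE = re.compile(r"^([A-Ha-h])([1-9]|1[0-2])$")


class LayoutError(ValueError):
    """Raised for invalid well addresses or malformed plate layouts."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well on the 96-well grid, e.g. ``WellAddress('H', 12)`` == "H12"."""

    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in ROWS or not (1 <= int(self.col) <= N_COLS):
            raise LayoutError(f"invalid well address: {self.row}{self.col!r}")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _ADDR_RE.match(str(text).strip())
        if not m:
            raise LayoutError(f"invalid well address: {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.col}"

    @property
    def is_edge(self) -> bool:
        return self.row in ("A", "H") or self.col in (1, N_COLS)


def is_edge_well(addr: "WellAddress | str") -> bool:
    """True iff the well sits on the outermost ring (rows A/H, columns 1/12)."""
    if not isinstance(addr, WellAddress):
        addr = WellAddress.parse(addr)
    return addr.is_edge


def all_wells() -> list[WellAddress]:
    """All 96 well addresses in row-major order (A1..A12, B1.., .., H12)."""
    return [WellAddress(r, c) for r in ROWS for c in range(1, N_COLS + 1)]


class WellRole(str, enum.Enum):
    """What a well holds.

    ``SAMPLE`` wells carry one library gene (pooled siRNA); the remaining
    roles are the per-plate internal controls: mock transfection (reagent
    only, the fold-change reference), scrambled siRNA (the categorization
    reference), a universal cell-death siRNA, untreated cells in growth and
    in mineralization media, cells stained with secondary antibody only, and
    the no-cell background well used for background subtraction.
    """

    SAMPLE = "SAMPLE"
    MOCK = "MOCK"
    SCRAMBLED = "SCRAMBLED"
    CELL_DEATH = "CELL_DEATH"
    MEDIA_GROWTH = "MEDIA_GROWTH"
    MEDIA_MINERALIZATION = "MEDIA_MINERALIZATION"
    CELLS_SECONDARY_ONLY = "CELLS_SECONDARY_ONLY"
    BACKGROUND = "BACKGROUND"


class Topography(str, enum.Enum):
    FIBER = "fiber"
    SMOOTH = "smooth"


class Library(str, enum.Enum):
    KINASE = "kinase"
    PHOSPHATASE = "phosphatase"


#: Control-well template. The source figure prints only the background well's
#: coordinate (H12); the other controls are placed in column 12 by
#: convention, since the analysis keys on roles rather than coordinates.
CONTROL_TEMPLATE: dict[str, WellRole] = {
    "A12": WellRole.MOCK,
    "B12": WellRole.SCRAMBLED,
    "C12": WellRole.CELL_DEATH,
    "D12": WellRole.MEDIA_GROWTH,
    "E12": WellRole.MEDIA_MINERALIZATION,
    "F12": WellRole.CELLS_SECONDARY_ONLY,
    "H12": WellRole.BACKGROUND,
}

#: Number of wells available for library genes on the default template.
SAMPLE_CAPACITY = 96 - len(CONTROL_TEMPLATE)


class WellAssignment(NamedTuple):
    role: WellRole
    gene_id: Optional[str] = None


@dataclass
class PlateLayout:
    """Well -> role/gene assignment for one 96-well plate.

    Invariants (checked by :func:`validate_layout`): exactly 96 wells, at
    least one BACKGROUND and one MOCK well, and ``gene_id`` present iff the
    role is SAMPLE.
    """

    plate_id: str
    topography: Topography
    library: Library
    replicate: int
    wells: dict[WellAddress, WellAssignment] = field(default_factory=dict)

    def role_wells(self, role: WellRole) -> list[WellAddress]:
        return sorted(a for a, w in self.wells.items() if w.role is role)

    def sample_genes(self) -> dict[WellAddress, str]:
        """SAMPLE wells that actually carry a gene."""
        return {
            a: w.gene_id
            for a, w in sorted(self.wells.items())
            if w.role is WellRole.SAMPLE and w.gene_id is not None
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": self.plate_id,
                "well": str(a),
                "role": w.role.value,
                "gene_id": "" if w.gene_id is None else w.gene_id,
                "topography": self.topography.value,
                "library": self.library.value,
                "replicate": self.replicate,
            }
            for a, w in sorted(self.wells.items())
        ]
        return pd.DataFrame(rows)


def default_layout(
    topography: "Topography | str",
    library: "Library | str",
    replicate: int,
    gene_ids: Sequence[str],
    plate_id: Optional[str] = None,
) -> PlateLayout:
    """Build a plate layout with the standard control pattern.

    Controls occupy column 12 per :data:`CONTROL_TEMPLATE` (background at
    H12); ``gene_ids`` fill the remaining wells in row-major order.  Unused
    sample slots are left as empty SAMPLE wells (no gene).  Deterministic in
    its inputs.
    """
    topography = Topography(topography)
    library = Library(library)
    if replicate < 1:
        raise LayoutError(f"replicate must be >= 1, got {replicate}")
    gene_ids = list(gene_ids)
    if len(gene_ids) > SAMPLE_CAPACITY:
        raise LayoutError(
            f"{len(gene_ids)} genes exceed plate capacity of "
            f"{SAMPLE_CAPACITY} sample wells"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise LayoutError("duplicate gene_ids in layout request")
    if plate_id is None:
        plate_id = f"{library.value[:3]}-{topography.value}-r{replicate}"

    wells: dict[WellAddress, WellAssignment] = {}
    controls = {WellAddress.parse(k): v for k, v in CONTROL_TEMPLATE.items()}
    queue = iter(gene_ids)
    for addr in all_wells():
        if addr in controls:
            wells[addr] = WellAssignment(controls[addr])
        else:
            wells[addr] = WellAssignment(WellRole.SAMPLE, next(queue, None))
    return PlateLayout(plate_id, topography, library, int(replicate), wells)


def validate_layout(layout: PlateLayout) -> list[str]:
    """Return violation messages (empty list means the layout is valid)."""
    violations: list[str] = []
    if len(layout.wells) != 96:
        violations.append(f"layout has {len(layout.wells)} wells, expected 96")
    roles = [w.role for w in layout.wells.values()]
    if WellRole.BACKGROUND not in roles:
        violations.append("no BACKGROUND well in layout")
    if WellRole.MOCK not in roles:
        violations.append("no MOCK well in layout")
    seen_genes: dict[str, WellAddress] = {}
    for addr, w in sorted(layout.wells.items()):
        if w.role is WellRole.SAMPLE:
            if w.gene_id is not None:
                if w.gene_id in seen_genes:
                    violations.append(
                        f"gene {w.gene_id} assigned to both "
                        f"{seen_genes[w.gene_id]} and {addr}"
                    )
                seen_genes[w.gene_id] = addr
        elif w.gene_id is not None:
            violations.append(
                f"well {addr} has role {w.role.value} but carries gene "
                f"{w.gene_id}"
            )
    return violations


@dataclass
class ScreenDataset:
    """All raw per-well readings across plates, channels and topographies.

    ``readings`` is a tidy table with columns ``plate_id, well, channel,
    value``; ``layouts`` maps plate_id to its :class:`PlateLayout`.
    """

    layouts: dict[str, PlateLayout]
    readings: pd.DataFrame

    def validate(self) -> None:
        """Check readings against layouts; raise LayoutError on violations."""
        req = {"plate_id", "well", "channel", "value"}
        missing = req - set(self.readings.columns)
        if missing:
            raise LayoutError(f"readings table missing columns: {sorted(missing)}")
        bad_channel = set(self.readings["channel"]) - set(CHANNELS)
        if bad_channel:
            raise LayoutError(f"unknown channels: {sorted(bad_channel)}")
        for pid in self.readings["plate_id"].unique():
            if pid not in self.layouts:
                raise LayoutError(f"readings reference unknown plate {pid!r}")
        for layout in self.layouts.values():
            bad = validate_layout(layout)
            if bad:
                raise LayoutError(
                    f"plate {layout.plate_id}: " + "; ".join(bad)
                )
        keys = self.readings[["plate_id", "well", "channel"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise LayoutError(
                f"duplicate reading for plate {dup.plate_id} well {dup.well} "
                f"channel {dup.channel}"
            )

    def annotated(self) -> pd.DataFrame:
        """Readings joined with layout metadata.

        Adds columns ``role, gene_id, topography, library, replicate,
        is_edge``; the result is the working table for the normalization
        chain.
        """
        meta = pd.concat(
            [la.to_frame() for la in self.layouts.values()], ignore_index=True
        )
        df = self.readings.merge(meta, on=["plate_id", "well"], how="left", validate="many_to_one")
        if df["role"].isna().any():
            bad = df[df["role"].isna()].iloc[0]
            raise LayoutError(
                f"reading for plate {bad.plate_id} well {bad.well} has no "
                "layout entry"
            )
        df["gene_id"] = df["gene_id"].fillna("").replace({"": None})
        df["is_edge"] = [is_edge_well(w) for w in df["well"]]
        return df

    def layout_frame(self) -> pd.DataFrame:
        return pd.concat(
            [la.to_frame() for la in self.layouts.values()], ignore_index=True
        )
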