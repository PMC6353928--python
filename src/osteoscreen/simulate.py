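"""Synthetic screen data with known ground truth.

No raw plate data from the original screen is public, so every pipeline
stage is exercised against simulated datasets that emulate its structure:
triplicate 96-well plates per substrate topography (fiber, smooth), the
standard control-well pattern, a multiplicative edge attenuation on the
outer well ring, lognormal plate-to-plate scale drift, additive assay
background, lognormal per-well noise, and planted per-gene effects on the
RUNX2 and viability channels.

The generative model for a cell-containing well is

    value = base * plate_drift * edge^(is_edge) * viability * effect * eps
            + background * eps_b

with ``eps`` lognormal, mean 1, coefficient of variation ``noise_cv``.
Multiplicative lognormal noise (rather than additive Gaussian) reflects
plate fluorescence being strictly positive and right-skewed; negative
values then arise only downstream, from background subtraction.  Planted
effects: upregulating genes multiply the RUNX2 channel by ``effect_ur``
(default 2), downregulating by ``effect_dr`` (default 0.5), lethal genes
multiply the viability of the well (both channels) by
``lethal_viability`` (default 0.2, i.e. well under the 0.5 filter
threshold).  A configurable subset of genes additionally carries a
fiber-specific differential so the permutation test has true positives to
find.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .morphology import CellMask
from .plate import (
    CHANNELS,
    Library,
    PlateLayout,
    SAMPLE_CAPACITY,
    ScreenDataset,
    Topography,
    WellRole,
    default_layout,
)

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "simulate_screen",
    "simulate_null_screen",
    "score_recovery",
    "Disk",
    "Ellipse",
    "Rectangle",
    "Star",
    "generate_cell_masks",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Library sizes and replicate count mirror the screened collections (636
    kinases, 237 phosphatases, triplicate plates); the planted-effect
    fractions and noise scales are chosen as representative of a kinome
    screen: ~8% of genes up- or down-modulate the readout twofold, ~5% are
    lethal knockdowns, wells vary with a 10% CV, plates drift with a 10%
    lognormal SD and edge wells read ~20% low.
    """

    n_kinase: int = 636
    n_phosphatase: int = 237
    n_replicates: int = 3
    frac_ur: float = 0.08
    frac_dr: float = 0.08
    frac_lethal: float = 0.05
    effect_ur: float = 2.0
    effect_dr: float = 0.5
    lethal_viability: float = 0.2
    edge_factor: float = 0.8
    plate_scale_sd: float = 0.1
    background_level: float = 50.0
    noise_cv: float = 0.1
    topography_shift: float = 1.5
    frac_topography: float = 0.05
    base_alamar: float = 1000.0
    base_runx2: float = 600.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_kinase", "n_phosphatase", "n_replicates"):
            if getattr(self, name) < 0 or (
                name == "n_replicates" and self.n_replicates < 1
            ):
                problems.append(f"{name} must be non-negative (replicates >= 1)")
        for name in ("frac_ur", "frac_dr", "frac_lethal", "frac_topography"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                problems.append(f"{name}={v} outside [0, 1]")
        if self.frac_ur + self.frac_dr + self.frac_lethal > 1:
            problems.append("frac_ur + frac_dr + frac_lethal > 1")
        for name in (
            "effect_ur",
            "effect_dr",
            "lethal_viability",
            "edge_factor",
            "base_alamar",
            "base_runx2",
        ):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("plate_scale_sd", "noise_cv", "background_level"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if problems:
            raise SimulationError("invalid config: " + "; ".join(problems))


#: (viability multiplier, RUNX2-specific multiplier) for control roles.
#: Cell-death wells are nearly dead; secondary-only wells lack the primary
#: antibody so their RUNX2 signal is residual; mineralization media boosts
#: RUNX2.  Unused sample slots hold untransfected cells (effect 1).
_CONTROL_EFFECTS = {
    WellRole.MOCK.value: (1.0, 1.0),
    WellRole.SCRAMBLED.value: (1.0, 1.0),
    WellRole.CELL_DEATH.value: (0.05, 1.0),
    WellRole.MEDIA_GROWTH.value: (1.0, 1.0),
    WellRole.MEDIA_MINERALIZATION.value: (1.0, 1.5),
    WellRole.CELLS_SECONDARY_ONLY.value: (1.0, 0.05),
}


def _gene_ids(library: Library, n: int) -> list[str]:
    prefix = {"kinase": "KIN", "phosphatase": "PHO"}[library.value]
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _plant_truth(config: SimulationConfig, rng: np.random.Generator, null: bool) -> pd.DataFrame:
    rows = []
    for library, n in (
        (Library.KINASE, config.n_kinase),
        (Library.PHOSPHATASE, config.n_phosphatase),
    ):
        genes = _gene_ids(library, n)
        classes = np.full(n, "NC", dtype=object)
        if not null:
            n_ur = int(round(config.frac_ur * n))
            n_dr = int(round(config.frac_dr * n))
            n_lethal = int(round(config.frac_lethal * n))
            order = rng.permutation(n)
            classes[order[:n_ur]] = "UR"
            classes[order[n_ur : n_ur + n_dr]] = "DR"
            classes[order[n_ur + n_dr : n_ur + n_dr + n_lethal]] = "LETHAL"
        runx2 = np.where(
            classes == "UR",
            config.effect_ur,
            np.where(classes == "DR", config.effect_dr, 1.0),
        )
        viability = np.where(classes == "LETHAL", config.lethal_viability, 1.0)
        diff = np.ones(n)
        if not null and config.frac_topography > 0:
            n_diff = int(round(config.frac_topography * n))
            diff_idx = rng.permutation(n)[:n_diff]
            diff[diff_idx] = config.topography_shift
        for g, c, r, v, d in zip(genes, classes, runx2, viability, diff):
            rows.append(
                {
                    "gene_id": g,
                    "library": library.value,
                    "class": c,
                    "runx2_effect": float(r),
                    "viability_effect": float(v),
                    "topography_differential": float(d),
                }
            )
    return pd.DataFrame(rows)


def _build_layouts(config: SimulationConfig) -> dict[str, PlateLayout]:
    layouts: dict[str, PlateLayout] = {}
    for library, n in (
        (Library.KINASE, config.n_kinase),
        (Library.PHOSPHATASE, config.n_phosphatase),
    ):
        genes = _gene_ids(library, n)
        chunks = [
            genes[i : i + SAMPLE_CAPACITY]
            for i in range(0, len(genes), SAMPLE_CAPACITY)
        ] or [[]]
        for topo in (Topography.FIBER, Topography.SMOOTH):
            for ci, chunk in enumerate(chunks, start=1):
                for rep in range(1, config.n_replicates + 1):
                    pid = f"{library.value[:3]}-{topo.value}-c{ci:02d}-r{rep}"
                    layouts[pid] = default_layout(
                        topo, library, rep, chunk, plate_id=pid
                    )
    return layouts


def _lognormal_mult(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Lognormal multipliers with mean 1 and the given CV (exactly 1 if cv=0)."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def simulate_screen(
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    _null: bool = False,
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate a full two-topography screen.

    Returns the dataset and a truth table with one row per gene:
    ``gene_id, library, class (UR/DR/NC/LETHAL), runx2_effect,
    viability_effect, topography_differential``.
    """
    config = config or SimulationConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    truth = _plant_truth(config, rng, null=_null)
    effects = truth.set_index("gene_id")
    layouts = _build_layouts(config)

    meta = pd.concat(
        [la.to_frame() for la in sorted(layouts.values(), key=lambda l: l.plate_id)],
        ignore_index=True,
    )
    # one row per well per channel, in deterministic order
    wells = pd.concat(
        [meta.assign(channel=ch) for ch in CHANNELS], ignore_index=True
    ).sort_values(["plate_id", "channel", "well"], kind="stable").reset_index(drop=True)

    # per-plate/channel drift, drawn in sorted order
    plate_keys = (
        wells[["plate_id", "channel"]].drop_duplicates().reset_index(drop=True)
    )
    drift = _lognormal_mult(rng, 0, len(plate_keys)) if config.plate_scale_sd == 0 else np.exp(
        rng.normal(0.0, config.plate_scale_sd, size=len(plate_keys))
    )
    drift_map = dict(zip(map(tuple, plate_keys.to_numpy()), drift))
    wells["drift"] = [
        drift_map[(p, c)] for p, c in zip(wells["plate_id"], wells["channel"])
    ]

    is_edge = wells["well"].map(
        lambda w: w[0] in "AH" or int(w[1:]) in (1, 12)
    ).to_numpy()
    edge_mult = np.where(is_edge, config.edge_factor, 1.0)

    role = wells["role"].to_numpy()
    gene = wells["gene_id"].to_numpy()
    topo = wells["topography"].to_numpy()
    channel = wells["channel"].to_numpy()

    viability = np.ones(len(wells))
    readout = np.ones(len(wells))
    for r, (v, rx) in _CONTROL_EFFECTS.items():
        m = role == r
        viability[m] = v
        readout[np.logical_and(m, channel == "runx2")] = rx
    sample = np.logical_and(role == WellRole.SAMPLE.value, gene != "")
    gidx = effects.reindex(pd.Index(gene[sample]))
    viability[sample] = gidx["viability_effect"].to_numpy()
    rx_eff = gidx["runx2_effect"].to_numpy() * np.where(
        topo[sample] == Topography.FIBER.value,
        gidx["topography_differential"].to_numpy(),
        1.0,
    )
    sample_runx2 = np.logical_and(sample, channel == "runx2")
    readout[sample_runx2] = rx_eff[channel[sample] == "runx2"]

    base = np.where(channel == "alamar_blue", config.base_alamar, config.base_runx2)
    signal = base * wells["drift"].to_numpy() * edge_mult * viability * readout
    signal[role == WellRole.BACKGROUND.value] = 0.0

    noise = _lognormal_mult(rng, config.noise_cv, len(wells))
    bg_noise = _lognormal_mult(rng, config.noise_cv, len(wells))
    value = signal * noise + config.background_level * bg_noise

    readings = pd.DataFrame(
        {
            "plate_id": wells["plate_id"],
            "well": wells["well"],
            "channel": wells["channel"],
            "value": value,
        }
    )
    dataset = ScreenDataset(layouts=layouts, readings=readings)
    return dataset, truth


def simulate_null_screen(
    config: Optional[SimulationConfig] = None, seed: Optional[int] = None
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate a screen with no planted effects: all genes NC, effects 1.

    Supports type-I-error calibration of the downstream permutation test.
    """
    return simulate_screen(config, seed=seed, _null=True)


def score_recovery(genes: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Compare pipeline output with planted truth.

    ``genes`` is the hit-calling gene table (columns gene_id, topography,
    filter_status, category).  Returns per-class recovery fractions:
    planted UR/DR genes assigned the same category (per topography
    membership counted over both topographies), and the fraction of planted
    lethal genes flagged ``low_viability``.
    """
    merged = genes.merge(
        truth[["gene_id", "class"]], on="gene_id", how="left", validate="many_to_one"
    )
    out = {}
    for cls in ("UR", "DR"):
        sub = merged[merged["class"] == cls]
        out[f"{cls.lower()}_recovery"] = (
            float((sub["category"] == cls).mean()) if len(sub) else float("nan")
        )
    lethal = merged[merged["class"] == "LETHAL"]
    out["lethal_removed"] = (
        float((lethal["filter_status"] == "low_viability").mean())
        if len(lethal)
        else float("nan")
    )
    return out


# ---------------------------------------------------------------------------
# synthetic cell masks


@dataclass(frozen=True)
class Disk:
    radius: float


@dataclass(frozen=True)
class Ellipse:
    a: float  # semi-major, px
    b: float  # semi-minor, px


@dataclass(frozen=True)
class Rectangle:
    width: int
    height: int


@dataclass(frozen=True)
class Star:
    points: int
    r_inner: float
    r_outer: float


def _expected(shape, scale: float) -> dict:
    """Closed-form area/perimeter/extent/form-factor for a scaled shape."""
    if isinstance(shape, Disk):
        r = shape.radius * scale
        area, perim, ext = math.pi * r**2, 2 * math.pi * r, math.pi / 4
    elif isinstance(shape, Ellipse):
        a, b = shape.a * scale, shape.b * scale
        area = math.pi * a * b
        # Ramanujan's approximation
        perim = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
        ext = math.pi / 4
    elif isinstance(shape, Rectangle):
        w, h = round(shape.width * scale), round(shape.height * scale)
        area, perim, ext = w * h, 2 * (w + h), 1.0
    elif isinstance(shape, Star):
        k = shape.points
        ri, ro = shape.r_inner * scale, shape.r_outer * scale
        area = k * ri * ro * math.sin(math.pi / k)
        side = math.sqrt(ri**2 + ro**2 - 2 * ri * ro * math.cos(math.pi / k))
        perim = 2 * k * side
        ext = float("nan")  # depends on orientation
    else:
        raise SimulationError(f"unknown shape spec {shape!r}")
    return {
        "area": float(area),
        "perimeter": float(perim),
        "extent": float(ext),
        "form_factor": 4 * math.pi * area / perim**2,
    }


def _min_radius(shape) -> float:
    if isinstance(shape, Disk):
        return shape.radius
    if isinstance(shape, Ellipse):
        return min(shape.a, shape.b)
    if isinstance(shape, Rectangle):
        return min(shape.width, shape.height) / 2
    if isinstance(shape, Star):
        return shape.r_inner
    raise SimulationError(f"unknown shape spec {shape!r}")


def _rasterize(shape, scale: float, angle: float) -> np.ndarray:
    if isinstance(shape, Disk):
        r = shape.radius * scale
        n = int(2 * math.ceil(r) + 7)
        c = n // 2
        yy, xx = np.mgrid[:n, :n]
        return (yy - c) ** 2 + (xx - c) ** 2 <= r**2
    if isinstance(shape, Ellipse):
        a, b = shape.a * scale, shape.b * scale
        n = int(2 * math.ceil(max(a, b)) + 7)
        c = n // 2
        yy, xx = np.mgrid[:n, :n]
        return ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0
    if isinstance(shape, Rectangle):
        w, h = round(shape.width * scale), round(shape.height * scale)
        mask = np.zeros((h + 6, w + 6), dtype=bool)
        mask[3 : 3 + h, 3 : 3 + w] = True
        return mask
    if isinstance(shape, Star):
        k, ri, ro = shape.points, shape.r_inner * scale, shape.r_outer * scale
        n = int(2 * math.ceil(ro) + 7)
        c = n // 2
        theta = angle + np.arange(2 * k) * math.pi / k
        radii = np.where(np.arange(2 * k) % 2 == 0, ro, ri)
        rows = c + radii * np.sin(theta)
        cols = c + radii * np.cos(theta)
        mask = np.zeros((n, n), dtype=bool)
        rr, cc = skdraw.polygon(rows, cols, shape=mask.shape)
        mask[rr, cc] = True
        return mask
    raise SimulationError(f"unknown shape spec {shape!r}")


def generate_cell_masks(
    shape,
    n_cells: int,
    seed: Optional[int] = None,
    size_jitter: float = 0.1,
    pixel_size: float = 1.0,
) -> tuple[list[CellMask], pd.DataFrame]:
    """Rasterize ``n_cells`` jittered copies of a shape with known geometry.

    Each cell gets a lognormal size multiplier (SD ``size_jitter`` on the
    log scale) and, for stars, a random orientation.  Returns the masks and
    a table of closed-form expectations (area, perimeter, extent, form
    factor) per cell for tolerance testing.  Shapes whose smallest radius
    falls below 3 px are rejected: discretization is unreliable there.
    """
    if n_cells < 1:
        raise SimulationError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(seed)
    masks, rows = [], []
    for i in range(n_cells):
        scale = float(np.exp(rng.normal(0.0, size_jitter))) if size_jitter else 1.0
        if _min_radius(shape) * scale < 3:
            raise SimulationError(
                f"shape {shape!r} at scale {scale:.3f} has min radius < 3 px"
            )
        angle = float(rng.uniform(0, 2 * math.pi)) if isinstance(shape, Star) else 0.0
        mask = _rasterize(shape, scale, angle)
        masks.append(CellMask(label_id=i + 1, mask=mask, pixel_size=pixel_size))
        exp = _expected(shape, scale)
        exp["label"] = i + 1
        # convert to physical units
        exp["area"] *= pixel_size**2
        exp["perimeter"] *= pixel_size
        rows.append(exp)
    table = pd.DataFrame(rows)[
        ["label", "area", "perimeter", "extent", "form_factor"]
    ]
    return masks, table
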