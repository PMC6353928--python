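"""Gene-level aggregation and the two viability filtering passes.

After normalization each library gene has one viability (Alamar Blue) and
one RUNX2 fold change per replicate plate.  This module aggregates those to
per-gene scores and applies, in the fixed order the screen used:

1. the outlier filter — within each (library, topography) stratum, genes
   with negative viability fold change are dropped, then the top 10% (by
   count, ``floor(0.10*m)`` over the m non-negative genes) of the highest
   viability scores;
2. the viability filter — genes whose viability score is strictly below
   0.5, i.e. wells where the knockdown killed or starved the cells, are
   dropped.

Filter outcomes are recorded in ``filter_status`` (``pass``,
``outlier_negative``, ``outlier_top10``, ``low_viability``); nothing is
physically deleted so survivor counts per stage remain reportable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .plate import WellRole

__all__ = [
    "FilterError",
    "GeneRecord",
    "aggregate_replicates",
    "build_gene_table",
    "filter_outliers",
    "filter_viability",
    "survivor_counts",
]


class FilterError(ValueError):
    pass


@dataclass
class GeneRecord:
    """Per-gene, per-topography scores and filter/category state."""

    gene_id: str
    library: str
    topography: str
    viability_score: float
    osteo_raw: float
    replicate_viability: tuple[float, ...]
    replicate_osteo: tuple[float, ...]
    filter_status: str = "pass"
    category: str = "none"
    osteo_score: float = float("nan")


def aggregate_replicates(values: Sequence[float], rule: str = "mean") -> float:
    """Collapse replicate fold changes to one score (mean or median)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise FilterError("aggregate_replicates of empty sequence")
    if rule == "mean":
        return float(arr.mean())
    if rule == "median":
        return float(np.median(arr))
    raise FilterError(f"unknown aggregation rule {rule!r}")


def build_gene_table(
    normalized: pd.DataFrame, aggregate: str = "mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot normalized readings into replicate- and gene-level tables.

    Parameters
    ----------
    normalized : output of :func:`osteoscreen.normalize.normalize_readings`
        (annotated readings whose ``value`` column holds fold changes).

    Returns
    -------
    genes : DataFrame with one row per (gene_id, library, topography) and
        columns ``viability_score`` (aggregated Alamar Blue fold change),
        ``osteo_raw`` (aggregated RUNX2 fold change), ``n_replicates``,
        ``filter_status`` (initialized to "pass") and ``category`` ("none").
    replicates : DataFrame with one row per (gene_id, library, topography,
        replicate) and columns ``viability_fc, runx2_fc``.
    """
    samples = normalized[
        (normalized["role"] == WellRole.SAMPLE.value)
        & normalized["gene_id"].notna()
    ]
    if samples.empty:
        raise FilterError("no SAMPLE wells with genes in normalized data")
    wide = (
        samples.pivot_table(
            index=["gene_id", "library", "topography", "replicate"],
            columns="channel",
            values="value",
            aggfunc="first",
        )
        .rename(columns={"alamar_blue": "viability_fc", "runx2": "runx2_fc"})
        .reset_index()
    )
    wide.columns.name = None
    if wide[["viability_fc", "runx2_fc"]].isna().any().any():
        bad = wide[wide[["viability_fc", "runx2_fc"]].isna().any(axis=1)].iloc[0]
        raise FilterError(
            f"gene {bad.gene_id} replicate {bad.replicate} is missing a channel"
        )
    genes = (
        wide.groupby(["gene_id", "library", "topography"], sort=True)
        .agg(
            viability_score=("viability_fc", aggregate),
            osteo_raw=("runx2_fc", aggregate),
            n_replicates=("replicate", "size"),
        )
        .reset_index()
    )
    genes["filter_status"] = "pass"
    genes["category"] = "none"
    return genes, wide.sort_values(
        ["gene_id", "library", "topography", "replicate"]
    ).reset_index(drop=True)


def filter_outliers(
    genes: pd.DataFrame, top_fraction: float = 0.10
) -> pd.DataFrame:
    """Flag viability outliers within each (library, topography) stratum.

    Negative viability scores become ``outlier_negative``; of the remaining
    m non-negative genes the ``floor(top_fraction*m)`` highest viability
    scores become ``outlier_top10``.  Ties are broken by descending score
    then ascending gene_id, so the outcome is deterministic.
    """
    if not (0 <= top_fraction < 1):
        raise FilterError(f"top_fraction must be in [0, 1), got {top_fraction}")
    genes = genes.copy()
    for (lib, topo), idx in genes.groupby(
        ["library", "topography"], sort=True
    ).groups.items():
        sub = genes.loc[idx]
        active = sub[sub["filter_status"] == "pass"]
        neg = active[active["viability_score"] < 0]
        genes.loc[neg.index, "filter_status"] = "outlier_negative"
        nonneg = active.drop(neg.index)
        k = int(np.floor(top_fraction * len(nonneg)))
        if k > 0:
            top = nonneg.sort_values(
                ["viability_score", "gene_id"], ascending=[False, True]
            ).head(k)
            genes.loc[top.index, "filter_status"] = "outlier_top10"
    return genes


def filter_viability(
    genes: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Flag genes with viability score strictly below ``threshold``.

    A score exactly at the threshold is retained.  Runs after
    :func:`filter_outliers`; only genes still marked "pass" are examined.
    """
    genes = genes.copy()
    active = genes["filter_status"] == "pass"
    low = active & (genes["viability_score"] < threshold)
    genes.loc[low, "filter_status"] = "low_viability"
    return genes


def survivor_counts(genes: pd.DataFrame) -> pd.DataFrame:
    """Count genes per (library, topography) stratum and filter status."""
    counts = (
        genes.groupby(["library", "topography", "filter_status"], sort=True)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return counts
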