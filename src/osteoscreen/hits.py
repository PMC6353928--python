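"""Osteogenic hit calling.

Filtered genes get an osteogenic score — the RUNX2 fold change divided by
the viability fold change, i.e. RUNX2 per unit of metabolically active cell
mass.  Scores are partitioned, per topography, into upregulated (UR),
downregulated (DR) and no-change (NC) categories around the
scrambled-control reference of 1: the UR set is the top 40% (by count) of
the positive tail (scores above the reference), DR the bottom 40% of the
lower tail, NC everything else.  Categories are intersected across the two
topographies, and genes in each intersection group are tested for a
fiber-versus-smooth difference with a permutation two-sample t-test

    p* = (1/B) * #{ b : |t(b)| >= |t_obs| }

(ties count as extreme), followed by a Bonferroni correction within the
group.  With three replicates per arm the exhaustive permutation space has
C(6,3) = 20 relabelings, so the smallest attainable two-sided p is
2/20 = 0.1 — the test can never reject at alpha = 0.05 in exhaustive mode,
a granularity consequence documented in the methods note.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HitCallingError",
    "DegenerateDataError",
    "CategoryPartition",
    "CategoryIntersection",
    "PermutationTestResult",
    "osteo_score",
    "add_osteo_scores",
    "partition_categories",
    "intersect_categories",
    "permutation_t_test",
    "bonferroni_adjust",
    "select_secondary_candidates",
    "make_enrichment_export",
]


class HitCallingError(ValueError):
    pass


class DegenerateDataError(HitCallingError):
    """All pooled values identical: the t statistic is undefined."""


def osteo_score(osteo_raw: float, viability_score: float) -> float:
    """RUNX2 fold change normalized to viability (cell-number correction)."""
    if viability_score <= 0:
        raise HitCallingError(
            f"viability score {viability_score:.4g} <= 0; osteo score undefined"
        )
    return osteo_raw / viability_score


def add_osteo_scores(
    genes: pd.DataFrame, replicates: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach ``osteo_score`` columns to the gene and replicate tables.

    Only genes with ``filter_status == "pass"`` receive a score; replicate
    ratios are computed for the same genes for use by the permutation test.
    """
    genes = genes.copy()
    genes["osteo_score"] = np.nan
    ok = genes["filter_status"] == "pass"
    bad = ok & (genes["viability_score"] <= 0)
    if bad.any():
        g = genes[bad].iloc[0]
        raise HitCallingError(
            f"gene {g.gene_id} passed filters with viability "
            f"{g.viability_score:.4g} <= 0"
        )
    genes.loc[ok, "osteo_score"] = (
        genes.loc[ok, "osteo_raw"] / genes.loc[ok, "viability_score"]
    )
    replicates = replicates.copy()
    key = ["gene_id", "library", "topography"]
    passing = genes.loc[ok, key]
    replicates = replicates.merge(
        passing.assign(_pass=True), on=key, how="left"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = replicates["runx2_fc"] / replicates["viability_fc"]
    replicates["osteo_score"] = np.where(replicates["_pass"].notna(), ratio, np.nan)
    replicates = replicates.drop(columns="_pass")
    return genes, replicates


@dataclass
class CategoryPartition:
    """UR/DR/NC partition of one topography's passing genes."""

    topography: str
    UR: frozenset
    DR: frozenset
    NC: frozenset
    reference_value: float = 1.0
    upper_cut: Optional[float] = None
    lower_cut: Optional[float] = None

    def category_of(self, gene_id: str) -> str:
        if gene_id in self.UR:
            return "UR"
        if gene_id in self.DR:
            return "DR"
        if gene_id in self.NC:
            return "NC"
        return "none"

    @property
    def genes(self) -> frozenset:
        return self.UR | self.DR | self.NC


def partition_categories(
    scores: Mapping[str, float],
    reference: float = 1.0,
    tail_fraction: float = 0.40,
    topography: str = "",
) -> CategoryPartition:
    """Partition osteo scores into UR / DR / NC around ``reference``.

    The positive tail is every gene scoring strictly above the reference;
    its top ``floor(tail_fraction * n_tail)`` genes by score form UR.  The
    lower tail (strictly below) contributes its bottom
    ``floor(tail_fraction * n_tail)`` genes to DR.  Remaining genes are NC.
    Ties are broken by gene_id so the partition is order-independent.
    """
    if not scores:
        raise HitCallingError("partition_categories on empty score set")
    if not (0 < tail_fraction < 1):
        raise HitCallingError(f"tail_fraction must be in (0,1), got {tail_fraction}")
    items = sorted(scores.items())
    pos = sorted(
        ((s, g) for g, s in items if s > reference),
        key=lambda t: (-t[0], t[1]),
    )
    neg = sorted(
        ((s, g) for g, s in items if s < reference),
        key=lambda t: (t[0], t[1]),
    )
    k_pos = int(math.floor(tail_fraction * len(pos)))
    k_neg = int(math.floor(tail_fraction * len(neg)))
    ur = frozenset(g for _, g in pos[:k_pos])
    dr = frozenset(g for _, g in neg[:k_neg])
    nc = frozenset(g for g, _ in items) - ur - dr
    upper_cut = pos[k_pos - 1][0] if k_pos else None
    lower_cut = neg[k_neg - 1][0] if k_neg else None
    return CategoryPartition(
        topography=topography,
        UR=ur,
        DR=dr,
        NC=nc,
        reference_value=reference,
        upper_cut=upper_cut,
        lower_cut=lower_cut,
    )


@dataclass
class CategoryIntersection:
    """Venn decomposition of fiber vs smooth category memberships."""

    both: dict[str, frozenset]
    fiber_only: dict[str, frozenset]
    smooth_only: dict[str, frozenset]

    def venn_summary(self) -> pd.DataFrame:
        rows = []
        for cat in ("UR", "DR", "NC"):
            rows.append(
                {
                    "category": cat,
                    "fiber_only": len(self.fiber_only[cat]),
                    "both": len(self.both[cat]),
                    "smooth_only": len(self.smooth_only[cat]),
                    "fiber_total": len(self.fiber_only[cat]) + len(self.both[cat]),
                    "smooth_total": len(self.smooth_only[cat]) + len(self.both[cat]),
                }
            )
        return pd.DataFrame(rows)


def intersect_categories(
    fiber: CategoryPartition, smooth: CategoryPartition
) -> CategoryIntersection:
    """Intersect fiber and smooth partitions category by category."""
    both, f_only, s_only = {}, {}, {}
    for cat in ("UR", "DR", "NC"):
        f = getattr(fiber, cat)
        s = getattr(smooth, cat)
        both[cat] = frozenset(f & s)
        f_only[cat] = frozenset(f - s)
        s_only[cat] = frozenset(s - f)
    return CategoryIntersection(both, f_only, s_only)


@dataclass
class PermutationTestResult:
    gene_id: str
    t_obs: float
    B: int
    n_extreme: int
    p_perm: float
    mode: str
    seed: Optional[int] = None
    p_bonferroni: Optional[float] = None


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0
        return math.copysign(math.inf, diff)
    return float(diff / math.sqrt(sp2 * (1 / nx + 1 / ny)))


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 1000,
    seed: Optional[int] = None,
    mode: str = "auto",
    gene_id: str = "",
    exhaustive_limit: int = 10_000,
) -> PermutationTestResult:
    """Two-sample pooled-variance t-test with a permutation null.

    ``mode="exhaustive"`` enumerates all C(nx+ny, nx) relabelings of the
    pooled values (B is set to that count); ``mode="monte_carlo"`` draws B
    uniform random relabelings with replacement.  ``mode="auto"`` picks
    exhaustive when the relabeling space is at most ``exhaustive_limit``.
    The p-value counts relabelings with ``|t(b)| >= |t_obs|``, ties
    included, so the original labeling always counts and p > 0 in
    exhaustive mode.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise HitCallingError(
            f"need >=2 values per group, got {len(x)} and {len(y)}"
        )
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError(
            f"gene {gene_id or '<?>'}: all {len(pooled)} values identical; "
            "t statistic undefined"
        )
    t_obs = _pooled_t(x, y)
    nx, n = len(x), len(pooled)
    n_assign = math.comb(n, nx)
    if mode == "auto":
        mode = "exhaustive" if n_assign <= exhaustive_limit else "monte_carlo"
    if mode not in ("exhaustive", "monte_carlo"):
        raise HitCallingError(f"unknown mode {mode!r}")

    if mode == "exhaustive":
        combos = np.array(
            list(itertools.combinations(range(n), nx)), dtype=int
        )
        B_eff = len(combos)
        xs = pooled[combos]  # (B_eff, nx)
        mask = np.ones((B_eff, n), dtype=bool)
        np.put_along_axis(mask, combos, False, axis=1)
        ys = pooled[np.nonzero(mask)[1]].reshape(B_eff, n - nx)
    else:
        if B < 1:
            raise HitCallingError(f"B must be >= 1, got {B}")
        rng = np.random.default_rng(seed)
        B_eff = int(B)
        order = np.argsort(
            rng.random((B_eff, n)), axis=1
        )  # uniform random relabeling per draw
        shuffled = pooled[order]
        xs = shuffled[:, :nx]
        ys = shuffled[:, nx:]

    t_b = _batch_pooled_t(xs, ys)
    n_extreme = int(np.sum(np.abs(t_b) >= abs(t_obs) - 1e-12))
    p_perm = n_extreme / B_eff
    return PermutationTestResult(
        gene_id=gene_id,
        t_obs=t_obs,
        B=B_eff,
        n_extreme=n_extreme,
        p_perm=p_perm,
        mode=mode,
        seed=seed,
    )


def _batch_pooled_t(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    nx, ny = xs.shape[1], ys.shape[1]
    sp2 = (
        (nx - 1) * xs.var(axis=1, ddof=1) + (ny - 1) * ys.var(axis=1, ddof=1)
    ) / (nx + ny - 2)
    diff = xs.mean(axis=1) - ys.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1 / nx + 1 / ny))
    # zero pooled variance: t is 0 when the means agree, +-inf otherwise
    t = np.where(sp2 == 0, np.where(diff == 0, 0.0, np.copysign(np.inf, diff)), t)
    return t


def bonferroni_adjust(pvals: Sequence[float]) -> list[float]:
    """Family-wise correction: ``min(1, m * p)`` with m = len(pvals)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1)):
        raise HitCallingError("p-values must lie in [0, 1]")
    m = arr.size
    return [float(min(1.0, m * p)) for p in arr]


def select_secondary_candidates(
    partition: CategoryPartition,
    scores: Mapping[str, float],
    fraction: float = 0.10,
) -> dict[str, list[str]]:
    """Pick the most extreme ``fraction`` of each category for re-screening.

    UR candidates are the highest scorers, DR the lowest, NC those closest
    to the reference.  Each non-empty category yields at least one
    candidate (``max(1, floor(fraction * size))``).
    """
    if not (0 < fraction <= 1):
        raise HitCallingError(f"fraction must be in (0,1], got {fraction}")
    ref = partition.reference_value
    out: dict[str, list[str]] = {}
    keyfuns = {
        "UR": lambda g: (-scores[g], g),
        "DR": lambda g: (scores[g], g),
        "NC": lambda g: (abs(scores[g] - ref), g),
    }
    for cat, keyfun in keyfuns.items():
        members = sorted(getattr(partition, cat), key=keyfun)
        if not members:
            out[cat] = []
            continue
        k = max(1, int(math.floor(fraction * len(members))))
        out[cat] = members[:k]
    return out


def make_enrichment_export(
    categories: Mapping[str, str],
    significant: Iterable[str] = (),
    significant_p: float = 0.00001,
) -> pd.DataFrame:
    """Build the pseudo fold-change/p-value table for pathway enrichment.

    UR genes get fold change 2, DR genes -2, NC genes a neutral 1; the
    pseudo p-value is ``significant_p`` for genes flagged significant in
    the two-sample test and 1 otherwise.
    """
    folds = {"UR": 2.0, "DR": -2.0, "NC": 1.0}
    significant = set(significant)
    rows = []
    for gene_id, cat in sorted(categories.items()):
        if cat not in folds:
            raise HitCallingError(
                f"gene {gene_id} has no category (got {cat!r})"
            )
        rows.append(
            {
                "gene_id": gene_id,
                "fold_change": folds[cat],
                "p_value": significant_p if gene_id in significant else 1.0,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "fold_change", "p_value"])
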