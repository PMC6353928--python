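"""End-to-end screen models.

:class:`ScreenAnalysis` is the primary entry point: built from a
:class:`~osteoscreen.plate.ScreenDataset` (plus a :class:`ScreenConfig`),
its :meth:`~ScreenAnalysis.fit` runs the whole chain —

    background -> edge correction -> plate normalization -> fold change
    -> replicate aggregation -> outlier filter -> viability filter
    -> osteo scores -> UR/DR/NC partition per topography -> Venn
    intersection -> permutation t-tests on intersection groups
    -> Bonferroni -> secondary candidates -> enrichment export

— and returns a :class:`ScreenResults` carrying every intermediate table,
a ``summary()`` report and ``save()`` for the CSV outputs.

:class:`MorphologyScreen` is the analogous model for the cell-shape stage:
per-cell measures from labeled masks, then an ANOVA/Fisher-LSD
classification matrix over a comparison plan.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import filters, hits, morphology, normalize
from .plate import Library, ScreenDataset, Topography

__all__ = ["ScreenConfig", "ScreenAnalysis", "ScreenResults", "MorphologyScreen", "MorphologyResults"]


@dataclass
class ScreenConfig:
    """All tunable constants of the screen analysis.

    Defaults are the published analysis constants: 20% trimmed means, a 0.5
    viability cutoff, a 10% top-tail outlier cut, 40% category tails around
    the scrambled-relative reference 1.0, B = 1000 permutations, alpha =
    0.05 after Bonferroni, and a 10% secondary-screen fraction.
    """

    trim_fraction: float = 0.2
    viability_threshold: float = 0.5
    outlier_top_fraction: float = 0.10
    tail_fraction: float = 0.40
    reference: float = 1.0
    b_permutations: int = 1000
    alpha: float = 0.05
    secondary_fraction: float = 0.10
    seed: int = 0
    aggregate: str = "mean"
    permutation_mode: str = "auto"
    #: "intersection" tests only the fiber-and-smooth intersection groups
    #: (the screen's design); "all" tests every gene passing QC in both
    #: topographies, which is the right scope for calibration studies —
    #: intersection membership conditions on cross-topography agreement and
    #: makes the per-gene p-values conservative.
    test_scope: str = "intersection"
    positive_control_roles: tuple = normalize.POSITIVE_CONTROL_ROLES

    def __post_init__(self) -> None:
        for name in (
            "trim_fraction",
            "outlier_top_fraction",
            "tail_fraction",
            "secondary_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.b_permutations < 1:
            raise ValueError("b_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "positive_control_roles" in data:
            data["positive_control_roles"] = tuple(data["positive_control_roles"])
        return cls(**data)


class ScreenAnalysis:
    """Primary-screen hit-calling model over a validated dataset."""

    def __init__(self, dataset: ScreenDataset, config: Optional[ScreenConfig] = None):
        self.dataset = dataset
        self.config = config or ScreenConfig()

    def fit(self) -> "ScreenResults":
        cfg = self.config
        log: list[str] = [f"config: {asdict(cfg)}"]
        self.dataset.validate()
        annotated = self.dataset.annotated()
        log.append(
            f"dataset: {len(self.dataset.layouts)} plates, "
            f"{len(annotated)} readings"
        )

        norm, norm_records = normalize.normalize_readings(
            annotated,
            trim_fraction=cfg.trim_fraction,
            positive_control_roles=cfg.positive_control_roles,
        )
        log.append(
            "normalized: mock medians "
            + ", ".join(
                f"{r.channel}={r.mock_median:.4f}"
                for r in norm_records.drop_duplicates("channel").itertuples()
            )
        )

        genes, replicates = filters.build_gene_table(norm, aggregate=cfg.aggregate)
        log.append(f"aggregated ({cfg.aggregate}): {len(genes)} gene x topography records")
        genes = filters.filter_outliers(genes, top_fraction=cfg.outlier_top_fraction)
        self._log_survivors(genes, log, "after outlier filter")
        genes = filters.filter_viability(genes, threshold=cfg.viability_threshold)
        self._log_survivors(genes, log, "after viability filter")

        genes, replicates = hits.add_osteo_scores(genes, replicates)

        partitions: dict[tuple[str, str], hits.CategoryPartition] = {}
        for (lib, topo), sub in genes[genes["filter_status"] == "pass"].groupby(
            ["library", "topography"], sort=True
        ):
            scores = dict(zip(sub["gene_id"], sub["osteo_score"]))
            part = hits.partition_categories(
                scores,
                reference=cfg.reference,
                tail_fraction=cfg.tail_fraction,
                topography=topo,
            )
            partitions[(lib, topo)] = part
            for cat in ("UR", "DR", "NC"):
                members = getattr(part, cat)
                sel = (
                    (genes["library"] == lib)
                    & (genes["topography"] == topo)
                    & genes["gene_id"].isin(members)
                )
                genes.loc[sel, "category"] = cat
            log.append(
                f"partition {lib}/{topo}: UR={len(part.UR)} DR={len(part.DR)} "
                f"NC={len(part.NC)}"
            )

        intersections: dict[str, hits.CategoryIntersection] = {}
        venn_frames = []
        for lib in sorted({k[0] for k in partitions}):
            fiber = partitions.get((lib, Topography.FIBER.value))
            smooth = partitions.get((lib, Topography.SMOOTH.value))
            if fiber is None or smooth is None:
                continue
            inter = hits.intersect_categories(fiber, smooth)
            intersections[lib] = inter
            vf = inter.venn_summary()
            vf.insert(0, "library", lib)
            venn_frames.append(vf)
        venn = (
            pd.concat(venn_frames, ignore_index=True)
            if venn_frames
            else pd.DataFrame()
        )

        tests = self._run_permutation_tests(replicates, intersections, log)

        significant = set(
            tests.loc[tests["p_bonferroni"] < cfg.alpha, "gene_id"]
        ) if len(tests) else set()
        log.append(
            f"permutation tests: {len(tests)} genes in intersection groups, "
            f"{len(significant)} significant at alpha={cfg.alpha} after Bonferroni"
        )

        candidates: dict[tuple[str, str], dict[str, list[str]]] = {}
        for (lib, topo), part in partitions.items():
            sub = genes[
                (genes["library"] == lib)
                & (genes["topography"] == topo)
                & (genes["filter_status"] == "pass")
            ]
            scores = dict(zip(sub["gene_id"], sub["osteo_score"]))
            candidates[(lib, topo)] = hits.select_secondary_candidates(
                part, scores, fraction=cfg.secondary_fraction
            )

        enrichment: dict[str, pd.DataFrame] = {}
        for topo in (Topography.FIBER.value, Topography.SMOOTH.value):
            cats: dict[str, str] = {}
            for (lib, t), part in partitions.items():
                if t != topo:
                    continue
                for cat in ("UR", "DR", "NC"):
                    for g in getattr(part, cat):
                        cats[g] = cat
            if cats:
                enrichment[topo] = hits.make_enrichment_export(cats, significant)

        genes = self._attach_test_columns(genes, tests, candidates)
        survivors = filters.survivor_counts(genes)

        return ScreenResults(
            config=cfg,
            genes=genes,
            replicates=replicates,
            normalization=norm_records,
            partitions=partitions,
            intersections=intersections,
            venn=venn,
            tests=tests,
            candidates=candidates,
            enrichment=enrichment,
            survivors=survivors,
            log=log,
        )

    @staticmethod
    def _log_survivors(genes: pd.DataFrame, log: list, stage: str) -> None:
        passing = genes[genes["filter_status"] == "pass"]
        counts = passing.groupby(["library", "topography"]).size()
        pretty = ", ".join(f"{lib}/{topo}={n}" for (lib, topo), n in counts.items())
        log.append(f"{stage}: {pretty}")

    def _run_permutation_tests(
        self,
        replicates: pd.DataFrame,
        intersections: Mapping[str, hits.CategoryIntersection],
        log: list,
    ) -> pd.DataFrame:
        """Permutation t-tests per intersection group (fiber vs smooth).

        Genes in each category's fiber-and-smooth intersection are tested on
        their replicate-level osteo scores; Bonferroni m = group size, per
        the family being each intersection group.
        """
        cfg = self.config
        rows = []
        rep = replicates.dropna(subset=["osteo_score"])
        by_gene_topo = rep.groupby(["gene_id", "topography"])["osteo_score"]
        series = {k: v.to_numpy() for k, v in by_gene_topo}
        seed_seq = np.random.SeedSequence(cfg.seed)
        testable = {
            g
            for g in rep["gene_id"].unique()
            if (g, Topography.FIBER.value) in series
            and (g, Topography.SMOOTH.value) in series
        }
        for cat in ("UR", "DR", "NC"):
            if cfg.test_scope == "all":
                # one family: every testable gene
                if cat != "NC":
                    continue
                cat = "all"
                group = sorted(testable)
            else:
                group = sorted(
                    set().union(
                        *(inter.both[cat] for inter in intersections.values())
                    )
                    if intersections
                    else set()
                )
            if not group:
                continue
            seeds = seed_seq.spawn(len(group))
            pvals, results = [], []
            for g, child in zip(group, seeds):
                x = series.get((g, Topography.FIBER.value))
                y = series.get((g, Topography.SMOOTH.value))
                if x is None or y is None or len(x) < 2 or len(y) < 2:
                    continue
                gene_seed = int(child.generate_state(1)[0] % (2**31))
                try:
                    res = hits.permutation_t_test(
                        x,
                        y,
                        B=cfg.b_permutations,
                        seed=gene_seed,
                        mode=cfg.permutation_mode,
                        gene_id=g,
                    )
                except hits.DegenerateDataError:
                    log.append(f"gene {g}: degenerate data, test skipped")
                    continue
                results.append((g, cat, res))
                pvals.append(res.p_perm)
            adjusted = hits.bonferroni_adjust(pvals)
            for (g, cat_, res), p_adj in zip(results, adjusted):
                res.p_bonferroni = p_adj
                rows.append(
                    {
                        "gene_id": g,
                        "intersection_group": cat_,
                        "t_stat": res.t_obs,
                        "p_perm": res.p_perm,
                        "p_bonferroni": p_adj,
                        "B": res.B,
                        "mode": res.mode,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "intersection_group",
                "t_stat",
                "p_perm",
                "p_bonferroni",
                "B",
                "mode",
            ],
        )

    @staticmethod
    def _attach_test_columns(
        genes: pd.DataFrame,
        tests: pd.DataFrame,
        candidates: Mapping[tuple, Mapping[str, list]],
    ) -> pd.DataFrame:
        genes = genes.merge(
            tests[["gene_id", "t_stat", "p_perm", "p_bonferroni"]],
            on="gene_id",
            how="left",
        )
        chosen = set()
        for (lib, topo), cats in candidates.items():
            for cat, members in cats.items():
                for g in members:
                    chosen.add((g, topo))
        genes["secondary_candidate"] = [
            (g, t) in chosen for g, t in zip(genes["gene_id"], genes["topography"])
        ]
        return genes


@dataclass
class ScreenResults:
    """Fitted screen: hit table, partitions, tests and exports."""

    config: ScreenConfig
    genes: pd.DataFrame
    replicates: pd.DataFrame
    normalization: pd.DataFrame
    partitions: dict
    intersections: dict
    venn: pd.DataFrame
    tests: pd.DataFrame
    candidates: dict
    enrichment: dict
    survivors: pd.DataFrame
    log: list

    def summary(self) -> str:
        buf = _io.StringIO()
        print("Osteogenic siRNA screen — primary analysis", file=buf)
        print("=" * 58, file=buf)
        passing = self.genes[self.genes["filter_status"] == "pass"]
        print(
            f"{self.genes['gene_id'].nunique()} genes screened; "
            f"{passing['gene_id'].nunique()} pass QC in at least one topography",
            file=buf,
        )
        print("\nSurvivor counts (gene x topography strata):", file=buf)
        pivot = self.survivors.pivot_table(
            index=["library", "topography"],
            columns="filter_status",
            values="n_genes",
            fill_value=0,
            aggfunc="first",
        )
        print(pivot.to_string(), file=buf)
        if len(self.venn):
            print("\nCategory intersections (fiber vs smooth):", file=buf)
            print(self.venn.to_string(index=False), file=buf)
        if len(self.tests):
            sig = self.tests[self.tests["p_bonferroni"] < self.config.alpha]
            print(
                f"\nPermutation tests: {len(self.tests)} intersection genes, "
                f"{len(sig)} significant (Bonferroni, alpha={self.config.alpha})",
                file=buf,
            )
        n_cand = sum(
            len(v) for cats in self.candidates.values() for v in cats.values()
        )
        print(f"Secondary-screen candidates: {n_cand}", file=buf)
        return buf.getvalue()

    def save(self, outdir) -> dict[str, Path]:
        from . import io as screen_io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["hit_table"] = outdir / "hit_table.csv"
        screen_io.write_hit_table(self.genes, paths["hit_table"])
        paths["venn"] = outdir / "venn_summary.csv"
        self.venn.to_csv(paths["venn"], index=False)
        paths["normalization"] = outdir / "normalization_records.csv"
        self.normalization.to_csv(paths["normalization"], index=False)
        paths["tests"] = outdir / "permutation_tests.csv"
        self.tests.to_csv(paths["tests"], index=False)
        for topo, table in self.enrichment.items():
            p = outdir / f"enrichment_{topo}.csv"
            table.to_csv(p, index=False)
            paths[f"enrichment_{topo}"] = p
        cand_rows = [
            {"library": lib, "topography": topo, "category": cat, "gene_id": g}
            for (lib, topo), cats in self.candidates.items()
            for cat, members in cats.items()
            for g in members
        ]
        paths["candidates"] = outdir / "secondary_candidates.csv"
        pd.DataFrame(
            cand_rows, columns=["library", "topography", "category", "gene_id"]
        ).to_csv(paths["candidates"], index=False)
        paths["log"] = outdir / "run_log.txt"
        paths["log"].write_text("\n".join(self.log) + "\n")
        return paths


class MorphologyScreen:
    """Cell-shape comparison model over labeled masks by condition."""

    def __init__(
        self,
        masks_by_condition: Mapping[str, Sequence[morphology.CellMask]],
        plan: Sequence[tuple[str, str, str]],
        alpha: float = 0.05,
        parameters: Sequence[str] = morphology.SHAPE_PARAMETERS,
        perimeter_tolerance: float = 1.0,
    ):
        if len(masks_by_condition) < 2:
            raise morphology.MorphologyError("need >= 2 conditions")
        for cond, masks in masks_by_condition.items():
            if len(masks) < 2:
                raise morphology.MorphologyError(
                    f"condition {cond!r} has {len(masks)} cells, need >= 2"
                )
        self.masks_by_condition = masks_by_condition
        self.plan = list(plan)
        self.alpha = alpha
        self.parameters = tuple(parameters)
        self.perimeter_tolerance = perimeter_tolerance

    def fit(self) -> "MorphologyResults":
        measures = morphology.measures_table(
            self.masks_by_condition, perimeter_tolerance=self.perimeter_tolerance
        )
        matrix, details = morphology.classify_shape_changes(
            measures, self.plan, parameters=self.parameters, alpha=self.alpha
        )
        return MorphologyResults(
            measures=measures, matrix=matrix, comparisons=details, alpha=self.alpha
        )


@dataclass
class MorphologyResults:
    measures: pd.DataFrame
    matrix: pd.DataFrame
    comparisons: list
    alpha: float

    def summary(self) -> str:
        buf = _io.StringIO()
        print("Cell-shape morphometrics", file=buf)
        print("=" * 40, file=buf)
        counts = self.measures.groupby("condition").size()
        print("cells per condition: " + ", ".join(f"{c}={n}" for c, n in counts.items()), file=buf)
        print(f"\nclassification (alpha={self.alpha}):", file=buf)
        print(self.matrix.to_string(), file=buf)
        return buf.getvalue()

    def save(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "measures": outdir / "cell_measures.csv",
            "matrix": outdir / "shape_classification.csv",
            "comparisons": outdir / "shape_comparisons.csv",
        }
        self.measures.to_csv(paths["measures"], index=False)
        self.matrix.to_csv(paths["matrix"])
        pd.DataFrame([vars(c) for c in self.comparisons]).to_csv(
            paths["comparisons"], index=False
        )
        return paths
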