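"""Pipeline orchestration, cohort summary tables and figure output.

``run_pipeline`` sequences the full analysis: score raw IHC readings into
marker calls, estimate Kaplan-Meier curves per endpoint, compare single-
marker and combined-marker stratifications against the pooled null model,
test plateau-vs-no-plateau for each group, and optionally run the
enrichment stage.  Results are written as a deterministic JSON bundle plus
CSV tables and SVG figures; every output records the seed and a hash of
the configuration.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import enrichment as enr
from . import ihc as ihc_mod
from . import selection as sel
from . import survival as surv
from .errors import EmptyCohortError, UnmergeableGroupingError, ValidationError
from .plateau import FitConfig, PlateauFit, fit_exponential_to_zero, fit_plateau
from .survival import KMCurve, SurvivalRecord

logger = logging.getLogger("hlstrat")

__all__ = [
    "CohortSummary",
    "PipelineConfig",
    "summarize_cohort",
    "run_pipeline",
    "fit_to_dict",
    "format_percent",
]


def format_percent(count: int, denom: int) -> float:
    """Percentage rounded to one decimal place."""
    if denom <= 0:
        raise ValidationError("denominator must be positive")
    return round(100.0 * count / denom, 1)


@dataclass
class CohortSummary:
    """Per-variable counts and percentages plus median age and IQR."""

    n: int
    variables: Dict[str, List[Tuple[str, int, float]]]  # var -> [(category, count, pct)]
    age_median: Optional[float] = None
    age_iqr: Optional[Tuple[float, float]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, entries in self.variables.items():
            for category, count, pct in entries:
                rows.append({"variable": var, "category": category, "count": count, "percent": pct})
        return pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])


def summarize_cohort(
    records: Sequence[SurvivalRecord],
    variables: Optional[Sequence[str]] = None,
) -> CohortSummary:
    """Count/percentage table per categorical covariate; median age + IQR.

    Percentages use the per-variable non-missing denominator and are
    rounded to one decimal place.
    """
    records = list(records)
    if not records:
        raise EmptyCohortError("summarize_cohort needs at least one record")
    if variables is None:
        seen: Dict[str, None] = {}
        for r in records:
            for key, value in r.covariates.items():
                if key != "age" and not isinstance(value, (int, float, np.floating)):
                    seen.setdefault(key, None)
        variables = list(seen)

    out: Dict[str, List[Tuple[str, int, float]]] = {}
    for var in variables:
        values = [r.covariates.get(var) for r in records]
        present = [str(v) for v in values if v is not None and v == v]
        denom = len(present)
        counts: Dict[str, int] = {}
        for v in present:
            counts[v] = counts.get(v, 0) + 1
        out[var] = [
            (category, count, format_percent(count, denom))
            for category, count in sorted(counts.items())
        ]

    ages = [float(r.covariates["age"]) for r in records if "age" in r.covariates]
    age_median = age_iqr = None
    if ages:
        arr = np.asarray(ages)
        age_median = float(np.median(arr))
        age_iqr = (float(np.percentile(arr, 25)), float(np.percentile(arr, 75)))
    return CohortSummary(n=len(records), variables=out, age_median=age_median, age_iqr=age_iqr)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Inputs, fitting options and output layout for one pipeline run."""

    out_dir: str = "hlstrat_report"
    cohort_csv: Optional[str] = None
    measurements_csv: Optional[str] = None
    simulate_spec: Optional[str] = None       # YAML path, or "paper_like"
    expression_tsv: Optional[str] = None
    gene_sets_gmt: Optional[str] = None
    driver_gene: Optional[str] = None
    endpoints: Tuple[str, ...] = ("OS", "PFS")
    markers: Tuple[str, ...] = ("satb1", "p16")
    min_group_size: int = 10
    # default comparison basis is the censored-data likelihood (calibrated
    # AIC); the regression fits still provide RSS, F and plateau-vs-none
    fit: FitConfig = field(default_factory=lambda: FitConfig(loss="mle"))
    ssgsea_alpha: float = 0.75
    seed: int = 0
    make_plots: bool = True

    def content_hash(self) -> str:
        """Hash of the analytic configuration (output location and plotting
        toggles excluded, so identical analyses hash identically)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload.pop("make_plots", None)
        return hashlib.sha256(repr(payload).encode()).hexdigest()[:16]


def fit_to_dict(fit: PlateauFit) -> Dict[str, object]:
    def clean(x):
        if x is None:
            return None
        x = float(x)
        return x if math.isfinite(x) else str(x)

    return {
        "s0": clean(fit.params.s0),
        "plateau": clean(fit.params.plateau),
        "k_per_month": clean(fit.params.k),
        "half_life_months": clean(fit.half_life),
        "se": {key: clean(v) for key, v in fit.se.items()},
        "rss": clean(fit.rss),
        "n_points": fit.n_points,
        "n_free": fit.n_free,
        "aic": clean(fit.aic),
        "converged": fit.converged,
        "at_bounds": list(fit.at_bounds),
        "degenerate": fit.degenerate,
    }


def _comparison_to_dict(cmp: sel.ModelComparison) -> Dict[str, object]:
    mag = cmp.evidence_ratio.magnitude
    return {
        "delta_aic": round(cmp.delta_aic, 4) if math.isfinite(cmp.delta_aic) else str(cmp.delta_aic),
        "evidence_ratio": mag if math.isfinite(mag) else str(mag),
        "evidence_ratio_rendered": cmp.evidence_ratio.render(),
        "direction": cmp.evidence_ratio.direction,
        "f_stat": round(cmp.f_stat, 4) if math.isfinite(cmp.f_stat) else str(cmp.f_stat),
        "f_p": cmp.f_p,
        "n_points": cmp.n_points,
        "df_null": cmp.df_null,
        "df_strat": cmp.df_strat,
        "null_fit": fit_to_dict(cmp.null_fit),
        "group_fits": {g: fit_to_dict(f) for g, f in sorted(cmp.strat_fits.items())},
    }


def _plateau_vs_none(curve: KMCurve, config: FitConfig) -> Dict[str, object]:
    """Rival-model check for one group: free plateau vs plateau pinned at 0.

    delta_aic = AIC(no plateau) - AIC(with plateau): positive values
    support the existence of a survival plateau.
    """
    with_p = fit_plateau(curve, config)
    without = fit_exponential_to_zero(curve, config)
    delta = without.aic - with_p.aic
    er = sel.evidence_ratio(delta) if math.isfinite(delta) else None
    out = {
        "delta_aic": delta if math.isfinite(delta) else str(delta),
        "with_plateau": fit_to_dict(with_p),
        "no_plateau": fit_to_dict(without),
        "plateau_at_bound": "plateau" in with_p.at_bounds,
    }
    if er is not None:
        out["evidence_ratio"] = er.magnitude if math.isfinite(er.magnitude) else str(er.magnitude)
        out["evidence_ratio_rendered"] = er.render()
        out["direction"] = (
            "favors_plateau" if delta > 0 else "favors_no_plateau" if delta < 0 else "equivocal"
        )
    return out


def _markers_with_both_levels(records: Sequence[SurvivalRecord], markers: Sequence[str]) -> List[str]:
    kept = []
    for m in markers:
        attr = "satb1_positive" if m.lower() == "satb1" else "p16_positive"
        levels = {bool(getattr(r, attr)) for r in records}
        if len(levels) == 2:
            kept.append(m)
        else:
            logger.warning("marker %s has a single level in this cohort; dropped from grouping", m)
    return kept


def _plot_groups(
    curves: Dict[str, KMCurve],
    fits: Dict[str, PlateauFit],
    title: str,
    path: Path,
) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.2))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, (label, curve) in enumerate(sorted(curves.items())):
        color = colors[i % len(colors)]
        ts = np.concatenate([[0.0], curve.times])
        ys = np.concatenate([[1.0], curve.survival])
        ax.step(ts, ys, where="post", color=color, label=label)
        fit = fits.get(label)
        if fit is not None:
            grid = np.linspace(0, max(float(curve.times.max()), 1.0), 200)
            model = fit.params.plateau + (fit.params.s0 - fit.params.plateau) * np.exp(
                -fit.params.k * grid
            )
            ax.plot(grid, model, linestyle="--", color=color, alpha=0.8)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def _load_inputs(config: PipelineConfig):
    if config.simulate_spec is not None:
        if config.simulate_spec == "paper_like":
            spec = cohort_mod.paper_like_spec()
        else:
            spec = cohort_mod.load_spec(config.simulate_spec)
        synthetic = cohort_mod.simulate_cohort(spec, seed=config.seed)
        return synthetic.records, synthetic.measurements
    if config.cohort_csv is None:
        raise ValidationError("pipeline needs either cohort_csv or simulate_spec")
    records = surv.read_cohort_csv(config.cohort_csv)
    measurements = (
        ihc_mod.read_measurements_csv(config.measurements_csv)
        if config.measurements_csv
        else None
    )
    return records, measurements


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns the results dictionary that is also serialised to
    ``results.json``.  Re-running with the same inputs and seed reproduces
    the JSON byte-identically.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    results: Dict[str, object] = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
    }
    try:
        records, measurements = _load_inputs(config)
        logger.info("cohort loaded: %d records", len(records))

        # --- IHC scoring stage -------------------------------------------
        if measurements is not None:
            calls = ihc_mod.call_cohort(measurements)
            positive_counts = (
                calls.groupby("marker")["positive"].sum().astype(int).to_dict()
            )
            results["ihc"] = {
                "n_measurements": int(len(calls)),
                "positive_counts": positive_counts,
            }
            calls.to_csv(out_dir / "marker_calls.csv", index=False)
            # marker flags on the records follow the calls
            flag_map = {
                (row.sample_id, row.marker): bool(row.positive)
                for row in calls.itertuples()
            }
            for r in records:
                if (r.sample_id, "SATB1") in flag_map:
                    r.satb1_positive = flag_map[(r.sample_id, "SATB1")]
                if (r.sample_id, "P16") in flag_map:
                    r.p16_positive = flag_map[(r.sample_id, "P16")]

        # --- cohort summary ----------------------------------------------
        summary = summarize_cohort(records)
        summary.to_frame().to_csv(out_dir / "cohort_summary.csv", index=False)
        results["cohort"] = {
            "n": summary.n,
            "follow_up": surv.follow_up_summary(records),
            "age_median": summary.age_median,
            "age_iqr": list(summary.age_iqr) if summary.age_iqr else None,
            "marker_positive": {
                "satb1": sum(r.satb1_positive for r in records),
                "p16": sum(r.p16_positive for r in records),
            },
        }

        # --- survival modelling ------------------------------------------
        markers = _markers_with_both_levels(records, config.markers)
        comparisons: Dict[str, object] = {}
        for endpoint in config.endpoints:
            ep_results: Dict[str, object] = {}
            for marker in markers:
                grouping = sel.assign_groups(records, [marker], min_group_size=1)
                cmp = sel.compare_stratification(records, endpoint, grouping, config.fit)
                ep_results[marker] = _comparison_to_dict(cmp)
                if config.make_plots:
                    curves = sel._group_curves(records, endpoint, grouping)
                    _plot_groups(
                        curves, cmp.strat_fits, f"{endpoint} by {marker}",
                        out_dir / f"km_{endpoint.lower()}_{marker}.svg",
                    )
            if len(markers) >= 2:
                try:
                    grouping = sel.assign_groups(
                        records, markers, min_group_size=config.min_group_size
                    )
                except UnmergeableGroupingError as exc:
                    logger.warning("combined grouping skipped for %s: %s", endpoint, exc)
                    ep_results["combined"] = {"skipped": str(exc)}
                    comparisons[endpoint] = ep_results
                    continue
                cmp = sel.compare_stratification(records, endpoint, grouping, config.fit)
                combined = _comparison_to_dict(cmp)
                combined["groups"] = {g: len(grouping.members(g)) for g in grouping.labels}
                combined["merged_from"] = grouping.merged_from
                # plateau-vs-no-plateau for each combined group
                curves = sel._group_curves(records, endpoint, grouping)
                combined["plateau_tests"] = {
                    g: _plateau_vs_none(curve, config.fit) for g, curve in sorted(curves.items())
                }
                ep_results["combined"] = combined
                if config.make_plots:
                    _plot_groups(
                        curves, cmp.strat_fits, f"{endpoint} by combined markers",
                        out_dir / f"km_{endpoint.lower()}_combined.svg",
                    )
            elif len(markers) == 1:
                logger.warning(
                    "combined analysis degraded to single-marker (%s): "
                    "other marker has one level", markers[0],
                )
            comparisons[endpoint] = ep_results
        results["comparisons"] = comparisons

        # --- enrichment stage (optional) ---------------------------------
        if config.expression_tsv and config.gene_sets_gmt:
            expr = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
            sets = enr.read_gmt(config.gene_sets_gmt)
            scores = enr.score_matrix(expr, sets, alpha=config.ssgsea_alpha)
            scores.to_csv(out_dir / "ssgsea_scores.csv")
            enrichment: Dict[str, object] = {"alpha": config.ssgsea_alpha, "n_sets": len(sets)}
            if config.driver_gene:
                if config.driver_gene not in expr.index:
                    raise ValidationError(
                        f"driver gene {config.driver_gene!r} not in the expression matrix"
                    )
                driver = expr.loc[config.driver_gene].to_numpy(dtype=float)
                rma_results = {}
                for s in sets:
                    fit = enr.rma_regression(scores.loc[s.name].to_numpy(), driver)
                    rma_results[s.name] = {
                        "slope": fit.slope, "intercept": fit.intercept,
                        "r": fit.r, "p": fit.p, "n": fit.n,
                    }
                enrichment["rma_vs_driver"] = {"driver": config.driver_gene, "fits": rma_results}
            results["enrichment"] = enrichment
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()

    with open(out_dir / "results.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, allow_nan=False, default=str)
        fh.write("\n")
    return results
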