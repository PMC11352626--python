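"""Null-vs-stratified survival model comparison.

The inferential question: does splitting a cohort by marker-defined
subgroups describe the time-to-event data better than a single curve?  The
null model gives every subgroup one shared decay-to-plateau parameter set;
the stratified model gives each group its own.  Comparison is reported
three ways:

* delta AIC = AIC_null - AIC_stratified (positive favors stratification),
* the evidence ratio exp(|dAIC|/2) with its direction, and
* the extra-sum-of-squares F test on the nested least-squares curve fits.

Two fitting routes back the AIC.  The default (``loss="mle"``) scores both
models with the censored-data likelihood of the cure model, a proper
i.i.d. likelihood whose AIC differences are calibrated: under the null,
twice the log-likelihood gain of the stratified model is approximately
chi-square with one degree of freedom per extra parameter.  The
regression route (``loss="km_ls"``) instead compares least-squares fits to
the per-group Kaplan-Meier staircases evaluated on one identical pooled
point set; it mirrors how survival curves are fitted in graphical
statistics packages, but KM points are serially correlated, so its AIC
differences and the F p-values are systematically too eager to stratify --
they are reported as descriptive diagnostics.  The RSS-based F test is
always computed from the regression fits, whichever route supplies the
AIC.

Group construction cross-classifies the cohort by binary marker calls and
merges any group smaller than ``min_group_size`` with the groups sharing
its rightmost positive marker (e.g. tiny SATB1+/p16+ and SATB1-/p16+ cells
collapse into a single "p16+" group).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    UnmergeableGroupingError,
    ValidationError,
)
from .plateau import FitConfig, PlateauFit, _curve_points, aic_least_squares, fit_points
from .survival import KMCurve, SurvivalRecord, km_estimate

__all__ = [
    "Grouping",
    "EvidenceRatio",
    "ModelComparison",
    "assign_groups",
    "global_fit",
    "evidence_ratio",
    "extra_ss_f_test",
    "compare_stratification",
    "test_shared_dynamics",
    "covariate_association",
]

_MARKER_ATTRS = {"satb1": "satb1_positive", "p16": "p16_positive"}
_MARKER_DISPLAY = {"satb1": "SATB1", "p16": "p16"}


@dataclass
class Grouping:
    """Assignment of every cohort member to exactly one group."""

    labels: List[str]
    assignment: Dict[str, str]              # sample_id -> group label
    merged_from: Dict[str, List[str]] = field(default_factory=dict)
    min_group_size: int = 1

    def members(self, label: str) -> List[str]:
        return [sid for sid, g in self.assignment.items() if g == label]

    def sizes(self) -> Dict[str, int]:
        out = {label: 0 for label in self.labels}
        for g in self.assignment.values():
            out[g] += 1
        return out


@dataclass(frozen=True)
class EvidenceRatio:
    """Evidence-ratio magnitude exp(|dAIC|/2) plus direction of support."""

    magnitude: float
    direction: str  # favors_stratified | favors_null | equivocal

    def render(self) -> str:
        """Format in reporting style: 'ER > 100', 'ER = 1/126' or 'ER = 1.02'.

        Magnitudes close to 1 are printed directly whatever the direction;
        larger null-favoring ratios are rendered as a fraction '1/x'.
        """
        if self.direction == "favors_null" and round(self.magnitude) >= 2:
            return f"ER = 1/{self.magnitude:.0f}"
        if self.magnitude > 100:
            return "ER > 100"
        return f"ER = {self.magnitude:.2f}"


@dataclass
class ModelComparison:
    """Null (shared curve) vs stratified (per-group curves) comparison."""

    null_fit: PlateauFit
    strat_fits: Dict[str, PlateauFit]
    delta_aic: float            # AIC_null - AIC_stratified
    evidence_ratio: EvidenceRatio
    f_stat: float
    f_p: float
    n_points: int
    df_null: int
    df_strat: int
    rss_null: float
    rss_strat: float

    @property
    def er_direction(self) -> str:
        return self.evidence_ratio.direction


def _marker_flags(record: SurvivalRecord, markers: Sequence[str]) -> Tuple[bool, ...]:
    flags = []
    for m in markers:
        attr = _MARKER_ATTRS.get(m.lower())
        if attr is None:
            raise ValidationError(f"unknown marker {m!r}; expected one of {sorted(_MARKER_ATTRS)}")
        flags.append(bool(getattr(record, attr)))
    return tuple(flags)


def _profile_label(profile: Tuple[bool, ...], markers: Sequence[str]) -> str:
    return "/".join(
        f"{_MARKER_DISPLAY[m.lower()]}{'+' if flag else '-'}"
        for m, flag in zip(markers, profile)
    )


def assign_groups(
    records: Sequence[SurvivalRecord],
    markers: Sequence[str] = ("satb1", "p16"),
    min_group_size: int = 10,
) -> Grouping:
    """Cross-classify the cohort by binary marker calls, merging small groups.

    A group smaller than ``min_group_size`` is merged with every group
    sharing its rightmost positive marker; the merged group is named after
    that marker (e.g. "p16+").  Merging an all-negative small group, or a
    merge that still cannot reach the minimum size, raises
    :class:`UnmergeableGroupingError`.
    """
    if min_group_size < 1:
        raise ValidationError("min_group_size must be >= 1")
    records = list(records)
    markers = list(markers)

    # group state: label -> set of member profiles
    group_profiles: Dict[str, set] = {}
    assignment: Dict[str, str] = {}
    for r in records:
        profile = _marker_flags(r, markers)
        label = _profile_label(profile, markers)
        group_profiles.setdefault(label, set()).add(profile)
        if r.sample_id in assignment:
            raise ValidationError(f"duplicate sample_id {r.sample_id!r} in cohort")
        assignment[r.sample_id] = label

    merged_from: Dict[str, List[str]] = {}

    def sizes() -> Dict[str, int]:
        out = {label: 0 for label in group_profiles}
        for g in assignment.values():
            out[g] += 1
        return out

    for _ in range(len(group_profiles) + len(markers)):
        current = sizes()
        small = sorted(
            (label for label, n in current.items() if n < min_group_size),
            key=lambda lb: (current[lb], lb),
        )
        if not small:
            break
        label = small[0]
        profiles = group_profiles[label]
        # markers positive in every member profile, rightmost first
        shared_positive = [
            i for i in reversed(range(len(markers)))
            if all(p[i] for p in profiles)
        ]
        merge_done = False
        for i in shared_positive:
            partners = [
                other for other, profs in group_profiles.items()
                if other != label and all(p[i] for p in profs)
            ]
            if not partners:
                continue
            new_label = f"{_MARKER_DISPLAY[markers[i].lower()]}+"
            sources = [label] + partners
            new_profiles = set()
            for src in sources:
                new_profiles |= group_profiles.pop(src)
            group_profiles[new_label] = new_profiles
            for sid, g in assignment.items():
                if g in sources:
                    assignment[sid] = new_label
            provenance: List[str] = []
            for src in sources:
                provenance.extend(merged_from.pop(src, [src]))
            merged_from[new_label] = provenance
            merge_done = True
            break
        if not merge_done:
            raise UnmergeableGroupingError(
                f"group {label!r} (n={current[label]}) is below min_group_size="
                f"{min_group_size} and has no merge partner"
            )
    else:
        raise UnmergeableGroupingError(
            f"merging did not reach min_group_size={min_group_size}; "
            f"group sizes: {sizes()}"
        )

    labels = sorted(group_profiles)
    return Grouping(
        labels=labels,
        assignment=assignment,
        merged_from=merged_from,
        min_group_size=min_group_size,
    )


def global_fit(
    curves: Dict[str, KMCurve],
    shared: bool,
    config: FitConfig = FitConfig(),
) -> Dict[str, object]:
    """Fit the rival models over a set of per-group KM curves.

    ``shared=True``: one parameter set for the union of all groups' points
    (the null model).  ``shared=False``: independent per-group fits whose
    RSS and parameter counts are summed.  N (total fitted points) is
    identical for both, which is what makes the AICs comparable.
    """
    if not curves:
        raise ValidationError("global_fit needs at least one group curve")
    points = {}
    for label, curve in curves.items():
        ts, ys = _curve_points(curve, config)
        points[label] = (ts, ys)

    n_total = sum(len(ts) for ts, _ in points.values())
    if shared:
        all_t = np.concatenate([ts for ts, _ in points.values()])
        all_y = np.concatenate([ys for _, ys in points.values()])
        fit = fit_points(all_t, all_y, config)
        rss, k_free = fit.rss, fit.n_free
        fits = {"pooled": fit}
    else:
        fits = {}
        rss = 0.0
        k_free = 0
        for label, (ts, ys) in points.items():
            try:
                fit = fit_points(ts, ys, config)
            except InsufficientDataError as exc:
                raise InsufficientDataError(f"group {label!r}: {exc}") from None
            fits[label] = fit
            rss += fit.rss
            k_free += fit.n_free
    return {
        "rss": rss,
        "n": n_total,
        "k_free": k_free,
        "aic": aic_least_squares(rss, n_total, k_free, config.aic),
        "fits": fits,
    }


def evidence_ratio(delta_aic: float) -> EvidenceRatio:
    """Evidence ratio exp(|dAIC|/2) with the direction given by the sign.

    dAIC is AIC_null - AIC_stratified: positive values favor the stratified
    model, negative the null, zero is equivocal.
    """
    if not math.isfinite(delta_aic):
        raise ValidationError(f"delta_aic must be finite, got {delta_aic!r}")
    try:
        magnitude = math.exp(abs(delta_aic) / 2.0)
    except OverflowError:
        magnitude = math.inf
    if delta_aic > 0:
        direction = "favors_stratified"
    elif delta_aic < 0:
        direction = "favors_null"
    else:
        direction = "equivocal"
    return EvidenceRatio(magnitude=magnitude, direction=direction)


def extra_ss_f_test(
    rss_null: float,
    df_null: int,
    rss_strat: float,
    df_strat: int,
) -> Tuple[float, float]:
    """Extra-sum-of-squares F test for nested least-squares models.

    F = ((RSS_null - RSS_strat)/(df_null - df_strat)) / (RSS_strat/df_strat)
    with p from the F(df_null - df_strat, df_strat) distribution.
    """
    if not (df_null > df_strat > 0):
        raise ValidationError(
            f"need df_null > df_strat > 0, got df_null={df_null}, df_strat={df_strat}"
        )
    if rss_null < rss_strat - 1e-9 * max(rss_strat, 1.0):
        raise ValidationError(
            f"nested models require rss_null >= rss_strat "
            f"(got {rss_null} < {rss_strat})"
        )
    extra = max(rss_null - rss_strat, 0.0)
    df_extra = df_null - df_strat
    if rss_strat == 0.0:
        f = math.inf if extra > 0 else 0.0
        return f, 0.0 if extra > 0 else 1.0
    f = (extra / df_extra) / (rss_strat / df_strat)
    p = float(stats.f.sf(f, df_extra, df_strat))
    return f, p


def _group_curves(
    records: Sequence[SurvivalRecord],
    endpoint: str,
    grouping: Grouping,
) -> Dict[str, KMCurve]:
    by_group: Dict[str, List[SurvivalRecord]] = {label: [] for label in grouping.labels}
    for r in records:
        label = grouping.assignment.get(r.sample_id)
        if label is None:
            raise ValidationError(f"sample {r.sample_id!r} missing from grouping")
        by_group[label].append(r)
    # fit on the full staircase (events + censorings) so censored follow-up
    # informs the tail of each group's curve
    return {
        label: km_estimate(recs, endpoint, at="observed")
        for label, recs in by_group.items()
        if recs
    }


def compare_stratification(
    records: Sequence[SurvivalRecord],
    endpoint: str,
    grouping: Grouping,
    config: Optional[FitConfig] = None,
) -> ModelComparison:
    """Compare one-shared-curve (null) vs one-curve-per-group (stratified).

    With the default configuration the AIC / evidence ratio come from the
    censored-data likelihood (``loss="mle"``); pass a config with
    ``loss="km_ls"`` to take them from the least-squares staircase fits
    instead.  The F test is always the extra-sum-of-squares test on the
    least-squares fits.
    """
    if config is None:
        config = FitConfig(loss="mle")
    records = list(records)
    by_group: Dict[str, List[SurvivalRecord]] = {}
    for r in records:
        label = grouping.assignment.get(r.sample_id)
        if label is None:
            raise ValidationError(f"sample {r.sample_id!r} missing from grouping")
        by_group.setdefault(label, []).append(r)
    if len(by_group) < 2:
        raise ValidationError(
            f"stratified comparison needs at least 2 non-empty groups, got {len(by_group)}"
        )
    curves = _group_curves(records, endpoint, grouping)

    # regression route: always computed (RSS, F test; AIC when loss="km_ls")
    null_ls = global_fit(curves, shared=True, config=config)
    strat_ls = global_fit(curves, shared=False, config=config)
    n = null_ls["n"]
    df_null = n - null_ls["k_free"]
    df_strat = n - strat_ls["k_free"]
    f, p = extra_ss_f_test(null_ls["rss"], df_null, strat_ls["rss"], df_strat)

    if config.loss == "mle":
        from .plateau import fit_plateau_mle

        null_fit = fit_plateau_mle(records, endpoint, config)
        strat_fits = {
            label: fit_plateau_mle(recs, endpoint, config)
            for label, recs in sorted(by_group.items())
        }
        delta_aic = null_fit.aic - sum(fit.aic for fit in strat_fits.values())
    else:
        null_fit = null_ls["fits"]["pooled"]
        strat_fits = strat_ls["fits"]
        delta_aic = null_ls["aic"] - strat_ls["aic"]

    return ModelComparison(
        null_fit=null_fit,
        strat_fits=strat_fits,
        delta_aic=delta_aic,
        evidence_ratio=evidence_ratio(delta_aic),
        f_stat=f,
        f_p=p,
        n_points=n,
        df_null=df_null,
        df_strat=df_strat,
        rss_null=null_ls["rss"],
        rss_strat=strat_ls["rss"],
    )


def test_shared_dynamics(
    records: Sequence[SurvivalRecord],
    endpoint: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    config: Optional[FitConfig] = None,
    labels: Tuple[str, str] = ("A", "B"),
) -> ModelComparison:
    """Do two disjoint subgroups follow the same survival dynamic?

    Compares "one curve for A union B" against "separate curves for A and B"
    with the same shared-vs-separate machinery.  ``group_a``/``group_b`` are
    sample-id collections.
    """
    set_a, set_b = set(group_a), set(group_b)
    overlap = set_a & set_b
    if overlap:
        raise ValidationError(f"groups overlap on samples: {sorted(overlap)[:5]}")
    subset = [r for r in records if r.sample_id in set_a | set_b]
    assignment = {
        r.sample_id: labels[0] if r.sample_id in set_a else labels[1] for r in subset
    }
    grouping = Grouping(labels=list(labels), assignment=assignment, min_group_size=1)
    return compare_stratification(subset, endpoint, grouping, config)


# keep an alias that cannot be mistaken for a pytest test when star-imported
shared_dynamics_comparison = test_shared_dynamics


def covariate_association(
    records: Sequence[SurvivalRecord],
    marker: str,
    covariate: str,
) -> Tuple[pd.DataFrame, float]:
    """Association between a binary marker call and a categorical covariate.

    Returns the contingency table and a p-value: Fisher's exact test for
    2x2 tables, chi-square otherwise.  A constant covariate (or constant
    marker) yields a degenerate table and p = 1 with a warning.
    """
    records = list(records)
    attr = _MARKER_ATTRS.get(marker.lower())
    if attr is None:
        raise ValidationError(f"unknown marker {marker!r}")
    flags = [bool(getattr(r, attr)) for r in records]
    values = [r.covariates.get(covariate) for r in records]
    if any(v is None for v in values):
        raise ValidationError(f"covariate {covariate!r} missing for some records")
    table = pd.crosstab(
        pd.Series(flags, name=marker), pd.Series(values, name=covariate)
    )
    if table.shape[0] < 2 or table.shape[1] < 2:
        warnings.warn(
            f"degenerate contingency table for {marker} vs {covariate}; p set to 1",
            stacklevel=2,
        )
        return table, 1.0
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table.to_numpy())
    else:
        _, p, _, _ = stats.chi2_contingency(table.to_numpy())
    return table, float(p)
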