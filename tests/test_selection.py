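"""Model selection: grouping, evidence ratios, F test, null-vs-stratified."""
import math

import numpy as np
import pytest
from scipy import integrate

from hlstrat import selection
from hlstrat.errors import UnmergeableGroupingError, ValidationError
from hlstrat.plateau import FitConfig
from hlstrat.selection import (
    Grouping,
    assign_groups,
    compare_stratification,
    covariate_association,
    evidence_ratio,
    extra_ss_f_test,
    global_fit,
)
from hlstrat.survival import KMCurve
from hlstrat.cohort import simulate_cohort

from conftest import make_record, two_group_spec


def curve_from(ts, ys):
    ts = np.asarray(ts, dtype=float)
    return KMCurve(times=ts, survival=np.asarray(ys, dtype=float),
                   at_risk=np.zeros_like(ts), n_events=np.zeros_like(ts))


def model(ts, plateau, k):
    return plateau + (1.0 - plateau) * np.exp(-k * np.asarray(ts, dtype=float))


class TestEvidenceRatio:
    def test_printed_shared_dynamics_value(self):
        er = evidence_ratio(-9.672)
        assert er.direction == "favors_null"
        assert round(er.magnitude) == 126
        assert er.render() == "ER = 1/126"

    def test_printed_near_equivocal_value(self):
        er = evidence_ratio(-0.03)
        assert round(er.magnitude, 2) == 1.02
        assert er.render() == "ER = 1.02"

    def test_large_differences_exceed_reporting_threshold(self):
        assert evidence_ratio(148.9).magnitude > 100
        assert evidence_ratio(148.9).render() == "ER > 100"
        assert evidence_ratio(30.65).magnitude > 100

    def test_zero_is_equivocal(self):
        er = evidence_ratio(0.0)
        assert er.magnitude == 1.0 and er.direction == "equivocal"

    def test_magnitude_is_exp_half_linear(self):
        for delta in (1.3, 4.0, 9.672):
            assert evidence_ratio(2 * delta).magnitude == pytest.approx(
                evidence_ratio(delta).magnitude ** 2
            )
            # reciprocal deltas give identical magnitudes, opposite directions
            assert evidence_ratio(-delta).magnitude == pytest.approx(
                evidence_ratio(delta).magnitude
            )

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            evidence_ratio(float("nan"))


class TestExtraSSFTest:
    def test_equal_rss_gives_f_zero_p_one(self):
        f, p = extra_ss_f_test(5.0, 18, 5.0, 16)
        assert f == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        f, p = extra_ss_f_test(20.0, 18, 10.0, 16)
        assert f == pytest.approx(8.0)

    def test_p_matches_numerically_integrated_f_density(self):
        # independent oracle: integrate the F density from first principles
        f, p = extra_ss_f_test(20.0, 18, 10.0, 16)
        d1, d2 = 2, 16

        def f_pdf(x):
            lognum = (
                math.lgamma((d1 + d2) / 2)
                - math.lgamma(d1 / 2)
                - math.lgamma(d2 / 2)
                + (d1 / 2) * math.log(d1 / d2)
                + (d1 / 2 - 1) * math.log(x)
                - ((d1 + d2) / 2) * math.log(1 + d1 * x / d2)
            )
            return math.exp(lognum)

        oracle, _ = integrate.quad(f_pdf, f, np.inf)
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_scale_invariance(self):
        f1, p1 = extra_ss_f_test(20.0, 18, 10.0, 16)
        f2, p2 = extra_ss_f_test(40.0, 18, 20.0, 16)
        assert f1 == pytest.approx(f2) and p1 == pytest.approx(p2)

    def test_df_violation_rejected(self):
        with pytest.raises(ValidationError):
            extra_ss_f_test(20.0, 16, 10.0, 16)


class TestAssignGroups:
    @staticmethod
    def cohort_with_cells(n_pp, n_pq, n_qp, n_qq):
        """Cohort with the four SATB1/p16 cells in the given sizes."""
        records, i = [], 0
        for count, satb1, p16 in [
            (n_pp, True, False), (n_pq, True, True), (n_qp, False, True), (n_qq, False, False),
        ]:
            for _ in range(count):
                records.append(make_record(i, 10 + i, satb1=satb1, p16=p16))
                i += 1
        return records

    def test_paper_like_merge_produces_three_groups(self):
        records = self.cohort_with_cells(12, 8, 4, 62)
        grouping = assign_groups(records, ["satb1", "p16"], min_group_size=10)
        assert grouping.sizes() == {"SATB1+/p16-": 12, "p16+": 12, "SATB1-/p16-": 62}
        assert sorted(grouping.merged_from["p16+"]) == ["SATB1+/p16+", "SATB1-/p16+"]

    def test_single_marker_no_merge(self):
        records = self.cohort_with_cells(16, 0, 0, 70)
        grouping = assign_groups(records, ["satb1"], min_group_size=10)
        assert grouping.sizes() == {"SATB1+": 16, "SATB1-": 70}

    def test_min_size_one_never_merges(self):
        records = self.cohort_with_cells(12, 8, 4, 62)
        grouping = assign_groups(records, ["satb1", "p16"], min_group_size=1)
        assert len(grouping.labels) == 4
        assert grouping.merged_from == {}

    def test_unmergeable_small_groups_raise(self):
        # SATB1+/p16- has no partner sharing its only positive marker
        records = self.cohort_with_cells(2, 0, 0, 62)
        with pytest.raises(UnmergeableGroupingError):
            assign_groups(records, ["satb1", "p16"], min_group_size=10)


class TestGlobalFit:
    def test_parameter_counting(self, rng):
        curves = {}
        for g, (plateau, k) in enumerate([(0.3, 0.1), (0.5, 0.05), (0.8, 0.2)]):
            ts = np.sort(rng.uniform(1, 100, size=12))
            curves[f"g{g}"] = curve_from(ts, model(ts, plateau, k))
        separate = global_fit(curves, shared=False)
        assert separate["k_free"] == 6
        shared = global_fit(curves, shared=True)
        assert shared["k_free"] == 2
        assert shared["n"] == separate["n"]

    def test_identical_groups_penalty_decides(self, rng):
        ts = np.sort(rng.uniform(1, 100, size=20))
        ys = model(ts, 0.5, 0.08) + rng.normal(0, 0.005, size=20)
        curves = {"a": curve_from(ts, ys), "b": curve_from(ts, ys.copy())}
        shared = global_fit(curves, shared=True)
        separate = global_fit(curves, shared=False)
        # duplicated data: RSS identical, so dAIC is exactly the parameter penalty
        assert shared["rss"] == pytest.approx(separate["rss"], rel=1e-4)
        assert shared["aic"] - separate["aic"] == pytest.approx(-4.0, abs=0.1)

    def test_divergent_groups_shared_fit_much_worse(self, rng):
        ts = np.sort(rng.uniform(1, 100, size=25))
        curves = {
            "high": curve_from(ts, model(ts, 0.9, 0.2)),
            "low": curve_from(ts, model(ts, 0.3, 0.05)),
        }
        shared = global_fit(curves, shared=True)
        separate = global_fit(curves, shared=False)
        assert shared["rss"] > 50 * max(separate["rss"], 1e-9)

    def test_null_rss_never_below_stratified(self, rng):
        # nesting invariant over a random sweep
        for _ in range(100):
            curves = {}
            for g in range(int(rng.integers(2, 4))):
                n = int(rng.integers(4, 15))
                ts = np.sort(rng.uniform(1, 150, size=n))
                ys = np.clip(
                    model(ts, rng.uniform(0, 0.9), rng.uniform(0.01, 0.4))
                    + rng.normal(0, 0.04, size=n),
                    0.0, 1.0,
                )
                curves[f"g{g}"] = curve_from(ts, ys)
            assert (
                global_fit(curves, shared=True)["rss"]
                >= global_fit(curves, shared=False)["rss"] - 1e-9
            )


class TestCompareStratification:
    def test_requires_two_groups(self, paper_cohort):
        records = paper_cohort.records
        grouping = Grouping(
            labels=["all"], assignment={r.sample_id: "all" for r in records}
        )
        with pytest.raises(ValidationError):
            compare_stratification(records, "OS", grouping)

    def test_invariant_to_labels_and_row_order(self):
        spec = two_group_spec(0.85, 5.0, 0.5, 40.0, 0.3)
        cohort = simulate_cohort(spec, seed=42)
        records = cohort.records

        def comparison(recs, name_a, name_b):
            assignment = {
                r.sample_id: (name_a if r.satb1_positive else name_b) for r in recs
            }
            grouping = Grouping(labels=[name_a, name_b], assignment=assignment)
            return compare_stratification(recs, "OS", grouping)

        c1 = comparison(records, "A", "B")
        c2 = comparison(records[::-1], "positive", "negative")
        assert c1.delta_aic == pytest.approx(c2.delta_aic, abs=1e-6)
        assert c1.f_stat == pytest.approx(c2.f_stat, abs=1e-6)

    def test_strong_separation_favors_stratification(self):
        spec = two_group_spec(0.9, 3.0, 0.2, 20.0, 0.5, n=120)
        cohort = simulate_cohort(spec, seed=5)
        grouping = Grouping(
            labels=["A", "B"],
            assignment={
                r.sample_id: ("A" if r.satb1_positive else "B") for r in cohort.records
            },
        )
        cmp = compare_stratification(cohort.records, "OS", grouping)
        assert cmp.evidence_ratio.direction == "favors_stratified"
        assert cmp.f_stat > 1.0

    def test_false_stratification_rate_stays_under_pinned_ceiling(self):
        # ceiling calibrated once by simulation: the fraction of identical-group
        # replicates called pro-stratification at dAIC > 2 was ~5%
        spec = two_group_spec(0.6, 30.0, 0.6, 30.0, 0.5)
        strong_calls = 0
        n_reps = 40
        for i in range(n_reps):
            cohort = simulate_cohort(spec, seed=7000 + i)
            grouping = Grouping(
                labels=["A", "B"],
                assignment={
                    r.sample_id: ("A" if r.satb1_positive else "B")
                    for r in cohort.records
                },
            )
            cmp = compare_stratification(cohort.records, "OS", grouping)
            strong_calls += cmp.delta_aic > 2
        assert strong_calls / n_reps <= 0.15


class TestSharedDynamics:
    def test_overlapping_groups_rejected(self, paper_cohort):
        ids = [r.sample_id for r in paper_cohort.records]
        with pytest.raises(ValidationError):
            selection.test_shared_dynamics(
                paper_cohort.records, "OS", ids[:10], ids[5:15]
            )

    def test_extreme_separation_detected(self):
        spec = two_group_spec(0.9, 3.0, 0.2, 10.0, 0.5, n=120)
        cohort = simulate_cohort(spec, seed=9)
        group_a = [r.sample_id for r in cohort.records if r.satb1_positive]
        group_b = [r.sample_id for r in cohort.records if not r.satb1_positive]
        cmp = selection.test_shared_dynamics(cohort.records, "OS", group_a, group_b)
        assert cmp.evidence_ratio.direction == "favors_stratified"

    def test_identical_groups_usually_share_dynamics(self):
        spec = two_group_spec(0.6, 25.0, 0.6, 25.0, 0.5)
        wins = 0
        for i in range(20):
            cohort = simulate_cohort(spec, seed=8000 + i)
            group_a = [r.sample_id for r in cohort.records if r.satb1_positive]
            group_b = [r.sample_id for r in cohort.records if not r.satb1_positive]
            cmp = selection.test_shared_dynamics(cohort.records, "OS", group_a, group_b)
            wins += cmp.evidence_ratio.direction == "favors_null"
        assert wins >= 12  # majority behaviour


class TestCovariateAssociation:
    @staticmethod
    def records_from_table(table):
        # table[marker_positive][category] = count
        records, i = [], 0
        for flag, row in zip([True, False], table):
            for cat, count in enumerate(row):
                for _ in range(count):
                    records.append(
                        make_record(i, 10.0, satb1=flag, stage=f"c{cat}")
                    )
                    i += 1
        return records

    def test_balanced_table_no_association(self):
        _, p = covariate_association(
            self.records_from_table([[10, 10], [10, 10]]), "satb1", "stage"
        )
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        _, p = covariate_association(
            self.records_from_table([[20, 0], [0, 20]]), "satb1", "stage"
        )
        assert p < 1e-6

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        records = self.records_from_table([[1, 9], [11, 3]])
        _, p = covariate_association(records, "satb1", "stage")

        # oracle: enumerate all tables with the observed margins
        def log_table_prob(a, r1, r2, c1, n):
            return (
                math.lgamma(r1 + 1) - math.lgamma(a + 1) - math.lgamma(r1 - a + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - a + 1)
                - math.lgamma(r2 - c1 + a + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
            )

        r1, r2, c1, n, a_obs = 10, 14, 12, 24, 1
        probs = {
            a: math.exp(log_table_prob(a, r1, r2, c1, n))
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
        }
        p_obs = probs[a_obs]
        oracle = sum(q for q in probs.values() if q <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p == pytest.approx(0.0028, abs=2e-4)

    def test_constant_covariate_warns_p_one(self):
        records = [make_record(i, 10.0, satb1=i % 2 == 0, stage="II") for i in range(10)]
        with pytest.warns(UserWarning):
            _, p = covariate_association(records, "satb1", "stage")
        assert p == 1.0
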