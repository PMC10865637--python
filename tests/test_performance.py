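import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

from ctgobs import (
    HYPOXIA,
    NORMAL,
    participant_points,
    sample_size_sens_spec,
    significant_differences,
    success_by_ph_bin,
    summarize_performance,
    wilson_interval,
)

from conftest import make_study
from _oracles import wilson_by_root_finding


class TestWilsonInterval:
    @pytest.mark.parametrize("k,n", [(0, 10), (1, 10), (5, 10), (17, 29), (1711, 2950), (99, 100)])
    def test_matches_statsmodels(self, k, n):
        ci = wilson_interval(k, n)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert ci.lower == pytest.approx(lo, abs=1e-12)
        assert ci.upper == pytest.approx(hi, abs=1e-12)

    @pytest.mark.parametrize("p,n", [(0.58, 2950), (0.5, 100), (0.61, 826), (0.03, 33)])
    def test_matches_score_inversion_root_finder(self, p, n):
        ci = wilson_interval(p, n)
        lo, hi = wilson_by_root_finding(p, n)
        assert ci.lower == pytest.approx(lo, abs=1e-9)
        assert ci.upper == pytest.approx(hi, abs=1e-9)

    def test_published_overall_success_interval(self):
        """p=0.58 over 2950 annotations gives (0.56, 0.60) at 2 decimals."""
        ci = wilson_interval(0.58, 2950)
        assert (round(ci.lower, 2), round(ci.upper, 2)) == (0.56, 0.60)

    def test_halfwidth_example_at_n_100(self):
        ci = wilson_interval(0.5, 100)
        assert ci.lower == pytest.approx(0.404, abs=5e-4)
        assert ci.upper == pytest.approx(0.596, abs=5e-4)

    def test_boundary_clipping_at_zero(self):
        assert wilson_interval(0, 50).lower == 0.0
        assert wilson_interval(50, 50).upper == 1.0

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)

    @settings(max_examples=200, derandomize=True)
    @given(k=st.integers(0, 200), n=st.integers(1, 200))
    def test_contains_estimate_and_reflects(self, k, n):
        k = min(k, n)
        ci = wilson_interval(k, n)
        assert ci.lower <= ci.estimate <= ci.upper
        flipped = wilson_interval(n - k, n)
        assert flipped.lower == pytest.approx(1 - ci.upper, abs=1e-12)
        assert flipped.upper == pytest.approx(1 - ci.lower, abs=1e-12)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_width_decreases_with_n(self, p):
        widths = [
            wilson_interval(p, n).upper - wilson_interval(p, n).lower
            for n in (10, 30, 100, 1000)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_empirical_coverage_near_nominal(self):
        """At p=0.5, n=30, 10^4 simulated draws: coverage within 2pp of 95%."""
        rng = np.random.default_rng(2024)
        n, p = 30, 0.5
        bounds = np.array([(wilson_interval(k, n).lower, wilson_interval(k, n).upper)
                           for k in range(n + 1)])
        ks = rng.binomial(n, p, size=10_000)
        covered = (bounds[ks, 0] <= p) & (p <= bounds[ks, 1])
        assert abs(covered.mean() - 0.95) <= 0.02


def _study_with_known_counts():
    # 2 cases (one of each outcome), 3 participants in different professions
    return make_study(
        [("h1", 7.00), ("n1", 7.30)],
        [("p1", "resident", 1.0), ("p2", "midwife", 3.0), ("p3", "obstetrician_gynecologist", 10.0)],
        [
            ("p1", "h1", HYPOXIA), ("p1", "n1", NORMAL),      # all correct
            ("p2", "h1", NORMAL), ("p2", "n1", HYPOXIA),      # all wrong
            ("p3", "h1", HYPOXIA), ("p3", "n1", HYPOXIA),     # half right
        ],
    )


class TestSummarizePerformance:
    def test_perfect_and_inverted_predictions(self):
        study = _study_with_known_counts()
        by_prof = {s.group_label: s for s in summarize_performance(study, "profession")}
        assert by_prof["resident"].success_rate.estimate == 1.0
        assert by_prof["resident"].sensitivity.estimate == 1.0
        assert by_prof["resident"].specificity.estimate == 1.0
        assert by_prof["midwife"].success_rate.estimate == 0.0
        assert by_prof["midwife"].sensitivity.estimate == 0.0
        assert by_prof["midwife"].specificity.estimate == 0.0

    def test_success_pools_sensitivity_and_specificity(self):
        (total,) = summarize_performance(_study_with_known_counts(), "none")
        assert total.success_rate.numerator == (
            total.sensitivity.numerator + total.specificity.numerator
        )
        assert total.success_rate.n == total.sensitivity.n + total.specificity.n

    def test_pooled_identity_across_groupings(self, default_study):
        study, _ = default_study
        (total,) = summarize_performance(study, "none")
        for grouping in ("profession", "experience_band"):
            groups = summarize_performance(study, grouping)
            assert sum(
                s.success_rate.numerator for s in groups if s.success_rate
            ) == total.success_rate.numerator

    def test_degenerate_stratum_reports_undefined(self):
        study = make_study(
            [("h1", 7.00)],
            [("p1", "resident", 1.0)],
            [("p1", "h1", HYPOXIA)],
        )
        (total,) = summarize_performance(study, "none")
        assert total.specificity is None
        assert total.sensitivity.estimate == 1.0

    def test_overlap_flags_use_non_overlap(self):
        study = _study_with_known_counts()
        flags = significant_differences(summarize_performance(study, "profession"))
        row = flags[
            (flags.metric == "success_rate")
            & (flags.group_a == "resident")
            & (flags.group_b == "midwife")
        ].iloc[0]
        # CIs at n=2 are wide enough to overlap even for 1.0 vs 0.0
        assert row["different"] == (
            not summarize_performance(study, "profession")[0]
            .success_rate.overlaps(summarize_performance(study, "profession")[1].success_rate)
        )


class TestParticipantPoints:
    def _study(self, n_hyp_correct, n_nrm_correct, n_each=10):
        cases = [(f"h{i}", 7.00) for i in range(n_each)] + [(f"n{i}", 7.30) for i in range(n_each)]
        anns = []
        for i in range(n_each):
            anns.append(("p1", f"h{i}", HYPOXIA if i < n_hyp_correct else NORMAL))
            anns.append(("p1", f"n{i}", NORMAL if i < n_nrm_correct else HYPOXIA))
        return make_study(cases, [("p1", "midwife", 2.0)], anns)

    def test_all_correct_is_top_left_corner(self):
        pts = participant_points(self._study(10, 10))
        assert pts[0].tpr == 1.0 and pts[0].fpr == 0.0

    def test_counting_matches_exhaustive_enumeration(self):
        (pt,) = participant_points(self._study(6, 7))
        assert pt.tpr == pytest.approx(0.6)
        assert pt.fpr == pytest.approx(0.3)
        assert pt.n_annotations == 20

    def test_exactly_ten_annotations_excluded(self):
        study = self._study(5, 5, n_each=5)  # 10 annotations total
        assert participant_points(study, min_annotations=10) == []

    def test_participant_without_normal_cases_omitted(self):
        cases = [(f"h{i}", 7.00) for i in range(6)] + [(f"n{i}", 7.30) for i in range(6)]
        anns = [("p1", f"h{i}", HYPOXIA) for i in range(6)] + [
            ("p1", f"n{i}", NORMAL) for i in range(6)
        ]
        anns_only_hyp = [("p2", f"h{i}", HYPOXIA) for i in range(6)]
        study = make_study(
            cases,
            [("p1", "midwife", 2.0), ("p2", "midwife", 2.0)],
            anns + anns_only_hyp,
        )
        pts = participant_points(study, min_annotations=5)
        assert [p.participant_id for p in pts] == ["p1"]


class TestSuccessByPhBin:
    def test_eight_thresholds_make_nine_bins(self, default_study):
        study, _ = default_study
        bins = success_by_ph_bin(study)
        assert len(bins) == 9
        assert bins[0].bin_lower == -math.inf and bins[-1].bin_upper == math.inf
        edges = [b.bin_lower for b in bins[1:]]
        assert edges == sorted(edges)
        # every annotation lands in exactly one bin
        assert sum(b.success_rate.n for b in bins if b.success_rate) == study.n_annotations

    def test_half_open_convention(self):
        study = make_study(
            [("a", 6.98), ("b", 7.0499), ("c", 7.05)],
            [("p1", "midwife", 2.0)],
            [("p1", "a", HYPOXIA), ("p1", "b", HYPOXIA), ("p1", "c", HYPOXIA)],
        )
        bins = success_by_ph_bin(study)
        by_edge = {b.bin_lower: b for b in bins}
        assert by_edge[6.98].success_rate.n == 2   # 6.98 and 7.0499 share [6.98, 7.05)
        assert by_edge[7.05].success_rate.n == 1   # 7.05 opens the next bin

    def test_unsorted_thresholds_rejected(self, default_study):
        study, _ = default_study
        with pytest.raises(ValueError, match="increasing"):
            success_by_ph_bin(study, (7.0, 6.9))


class TestSampleSize:
    def test_study_design_inputs_give_97(self):
        assert sample_size_sens_spec(0.45, 0.67, 0.14, 0.5) == 97

    def test_hand_evaluated_example(self):
        # 1.96^2 * 0.8 * 0.2 / (0.1^2 * 0.5) = 122.93 -> 123
        assert sample_size_sens_spec(0.8, 0.8, 0.1, 0.5) == 123

    def test_algebraic_inversion_recovers_n(self):
        from scipy.stats import norm

        n = 400
        z = norm.ppf(0.975)
        precision = z * 0.5 / math.sqrt(n * 0.5)
        assert sample_size_sens_spec(0.5, 0.5, precision, 0.5) == n

    def test_monotone_in_precision_and_maximised_at_half(self):
        sizes = [sample_size_sens_spec(0.5, 0.5, d, 0.5) for d in (0.05, 0.1, 0.2)]
        assert sizes == sorted(sizes, reverse=True)
        assert sample_size_sens_spec(0.5, 0.5, 0.1, 0.5) >= sample_size_sens_spec(
            0.9, 0.9, 0.1, 0.5
        )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_out_of_range_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            sample_size_sens_spec(0.5, 0.5, bad if bad else 0.0, 0.5)
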