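"""Serial ctDNA kinetics: CI-overlap significance, percent change, RECIST
categories, responder grouping, and partition/monotonicity properties."""

import pytest

from ctmeth import calling, response, simulate
from ctmeth.calling import MarkerPanel
from ctmeth.ddpcr import DropletWell, ValidationError, quantify_sample, quantify_table
from ctmeth.pipeline import serial_pairs_from_measurements
from ctmeth.response import (
    SerialPair,
    TimepointState,
    ci_overlap_change,
    classify_pair,
    classify_pairs,
    percent_change,
    responder_group,
    summarize_calls,
)

GROUP_RANK = {"good": 0, "poor": 1, "progressive": 2}


class TestCiOverlapChange:
    @pytest.mark.parametrize("base,post,expected", [
        ((10, 20), (21, 30), "increase"),
        ((21, 30), (10, 20), "decrease"),
        ((10, 20), (20, 30), "none"),    # touching counts as overlap
        ((10, 20), (10, 20), "none"),
        ((10, 20), (15, 25), "none"),
    ])
    def test_interval_logic(self, base, post, expected):
        assert ci_overlap_change(base, post) == expected

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValidationError):
            ci_overlap_change((20, 10), (0, 1))


class TestPercentChange:
    @pytest.mark.parametrize("b,p,expected", [
        (0.40, 0.08, -80.0),
        (0.40, 0.10, -75.0),   # boundary: does NOT qualify as > 75% decrease
        (0.40, 0.40, 0.0),
    ])
    def test_arithmetic(self, b, p, expected):
        assert percent_change(b, p) == pytest.approx(expected)

    def test_zero_baseline_undefined(self):
        assert percent_change(0.0, 0.2) is None


def _state(fraction, ci, positive, droplets):
    return TimepointState(fraction=fraction, ci_low=ci[0], ci_high=ci[1],
                          ctdna_positive=positive, marker_droplets_total=droplets)


class TestClassifyPair:
    def _pair(self, base, post):
        return SerialPair(patient_id="p1", baseline=base, post=post)

    def test_significant_increase_is_pd_progressive(self):
        call = classify_pair(self._pair(
            _state(0.2, (0.1, 0.3), True, 20),
            _state(1.0, (0.8, 1.2), True, 90)))
        assert call.recist == "PD"
        assert call.group == "progressive"
        assert call.change_significant == "increase"

    def test_no_change_is_sd(self):
        call = classify_pair(self._pair(
            _state(0.2, (0.1, 0.3), True, 20),
            _state(0.25, (0.15, 0.35), True, 24)))
        assert call.recist == "SD"
        assert call.group == "poor"  # consistently positive, stable

    def test_decrease_still_positive_is_pr(self):
        call = classify_pair(self._pair(
            _state(1.0, (0.8, 1.2), True, 90),
            _state(0.4, (0.3, 0.5), True, 40)))
        assert call.recist == "PR"
        assert call.group == "poor"  # -60% decrease, <= 75%

    def test_deep_decrease_is_pr_good(self):
        call = classify_pair(self._pair(
            _state(1.0, (0.8, 1.2), True, 90),
            _state(0.1, (0.05, 0.15), True, 10)))
        assert call.recist == "PR"
        assert call.group == "good"  # -90% > 75% decrease

    def test_decrease_to_negative_with_residual_droplets_is_ncr(self):
        call = classify_pair(self._pair(
            _state(1.0, (0.8, 1.2), True, 90),
            _state(0.02, (0.005, 0.04), False, 3)))
        assert call.recist == "NCR"
        assert call.group == "good"
        assert call.status_pair == "PN"

    def test_decrease_to_zero_droplets_is_cr(self):
        call = classify_pair(self._pair(
            _state(1.0, (0.8, 1.2), True, 90),
            _state(0.0, (0.0, 0.008), False, 0)))
        assert call.recist == "CR"
        assert call.group == "good"

    def test_boundary_75_percent_is_poor(self):
        call = classify_pair(self._pair(
            _state(0.40, (0.35, 0.45), True, 40),
            _state(0.10, (0.08, 0.12), True, 10)))
        assert call.percent_change == pytest.approx(-75.0)
        assert call.group == "poor"  # strict > 75% required for good

    def test_nn_pair_is_good(self):
        call = classify_pair(self._pair(
            _state(0.01, (0.0, 0.03), False, 1),
            _state(0.01, (0.0, 0.03), False, 1)))
        assert call.status_pair == "NN"
        assert call.group == "good"

    def test_np_pair_is_progressive(self):
        call = classify_pair(self._pair(
            _state(0.0, (0.0, 0.01), False, 0),
            _state(0.5, (0.4, 0.6), True, 50)))
        assert call.status_pair == "NP"
        assert call.group == "progressive"


def _measurement(counts, alb=3000, n=40_000, sid="s"):
    wells = [DropletWell(sid, "w", m, c, n) for m, c in counts.items()]
    wells.append(DropletWell(sid, "w", "ALB", alb, n))
    return quantify_sample(wells)


class TestAggregateFraction:
    def test_sum_aggregation_uses_all_markers(self, default_panel):
        m = _measurement({"NPY": 20, "FRMD4B": 10, "GDAP1L1": 5, "CELF2": 3,
                          "CLIP4": 2})
        state = response.aggregate_fraction(m, default_panel)
        assert state.marker_droplets_total == 40
        assert state.ci_low <= state.fraction <= state.ci_high
        assert state.ctdna_positive

    def test_zero_alb_flags_undefined_fraction(self, default_panel):
        m = _measurement({"NPY": 20, "FRMD4B": 10, "GDAP1L1": 5, "CELF2": 3,
                          "CLIP4": 2}, alb=0)
        state = response.aggregate_fraction(m, default_panel)
        assert state.fraction is None

    def test_monotone_post_shrinkage_never_worsens_group(self, default_panel):
        """Holding baseline fixed, scaling every post marker count down never
        moves a patient toward a worse responder group."""
        base = response.aggregate_fraction(
            _measurement({"NPY": 60, "FRMD4B": 30, "GDAP1L1": 20, "CELF2": 10,
                          "CLIP4": 8}), default_panel)
        post_counts = {"NPY": 80, "FRMD4B": 40, "GDAP1L1": 30, "CELF2": 15,
                       "CLIP4": 10}
        prev_rank = None
        for scale in (1.5, 1.0, 0.6, 0.3, 0.1, 0.02, 0.0):
            post = response.aggregate_fraction(
                _measurement({m: int(c * scale) for m, c in post_counts.items()}),
                default_panel)
            call = classify_pair(SerialPair("p", base, post))
            rank = GROUP_RANK[call.group]
            if prev_rank is not None:
                assert rank <= prev_rank
            prev_rank = rank


class TestCohortLevelConsistency:
    def test_categories_partition_and_counts_add_up(self, default_cohort, calibrated):
        mdrop = default_cohort.droplets[
            default_cohort.droplets.sample_id.str.startswith("mcrc")]
        meas, _ = quantify_table(mdrop)
        pairs = serial_pairs_from_measurements(meas, default_cohort.samples,
                                               calibrated.panel)
        calls = classify_pairs(pairs)
        assert len(calls) == 65
        summary = summarize_calls(calls)
        n_dec = summary["change"].get("decrease", 0)
        n_inc = summary["change"].get("increase", 0)
        n_none = summary["change"].get("none", 0)
        recist = summary["recist"]
        assert recist.get("NCR", 0) + recist.get("PR", 0) + recist.get("CR", 0) == n_dec
        assert recist.get("PD", 0) == n_inc
        assert recist.get("SD", 0) == n_none
        assert sum(summary["group"].values()) == 65

    def test_generating_groups_recovered(self, default_cohort, calibrated):
        mdrop = default_cohort.droplets[
            default_cohort.droplets.sample_id.str.startswith("mcrc")]
        meas, _ = quantify_table(mdrop)
        pairs = serial_pairs_from_measurements(meas, default_cohort.samples,
                                               calibrated.panel)
        calls = classify_pairs(pairs)
        truth = default_cohort.truth.set_index("patient_id")
        agree = sum(truth.loc[c.patient_id, "response_group"] == c.group
                    for c in calls)
        assert agree / len(calls) >= 0.9
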