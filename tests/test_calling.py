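"""LoB calibration and combined-rule calling: brute-force Youden oracle,
published-panel behaviour, rule-search scenarios, performance metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctmeth import calling, simulate
from ctmeth.calling import (
    DEFAULT_LOB,
    MarkerPanel,
    calibrate_panel,
    call_marker,
    call_sample,
    combined_rule_search,
    performance_metrics,
    roc_and_youden,
)
from ctmeth.ddpcr import ValidationError


def brute_force_youden(controls, cases):
    """Independent oracle: enumerate every integer threshold, maximize
    J = sensitivity + specificity - 1, break ties toward the higher t."""
    best_t, best_j = None, -2.0
    for t in range(0, max(max(controls), max(cases)) + 1):
        sens = sum(c > t for c in cases) / len(cases)
        spec = sum(c <= t for c in controls) / len(controls)
        j = sens + spec - 1
        if j >= best_j - 1e-12:
            if j > best_j + 1e-12 or t > best_t:
                best_t, best_j = t, max(j, best_j)
    return best_t, best_j


class TestRocAndYouden:
    def test_perfect_separation(self):
        r = roc_and_youden([0, 0, 0, 0], [10, 12, 9, 11])
        assert r.auc == 1.0
        assert r.youden_j == pytest.approx(1.0)
        assert 0 <= r.youden_threshold < 9  # separates the groups

    def test_identical_distributions_auc_half(self):
        r = roc_and_youden([0, 1, 2, 3], [0, 1, 2, 3])
        assert r.auc == pytest.approx(0.5)

    def test_documented_example_matches_brute_force(self):
        controls, cases = [0, 1, 2, 0], [3, 5, 2, 8]
        t, j = brute_force_youden(controls, cases)
        r = roc_and_youden(controls, cases)
        assert (r.youden_threshold, r.youden_j) == (t, pytest.approx(j))
        assert r.youden_threshold == 2  # frozen from the oracle
        assert r.youden_j == pytest.approx(0.75)

    def test_auc_shift_invariance(self):
        rng = np.random.default_rng(11)
        controls = rng.poisson(1.0, 30).tolist()
        cases = rng.poisson(6.0, 30).tolist()
        a = roc_and_youden(controls, cases).auc
        b = roc_and_youden([c + 7 for c in controls], [c + 7 for c in cases]).auc
        assert a == pytest.approx(b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            roc_and_youden([], [1, 2])

    def test_j_maximal_at_reported_threshold(self):
        rng = np.random.default_rng(5)
        controls = rng.poisson(2.0, 40).tolist()
        cases = rng.poisson(9.0, 40).tolist()
        r = roc_and_youden(controls, cases)
        j_at = dict(zip(r.thresholds,
                        np.array(r.sensitivity) + np.array(r.specificity) - 1))
        assert j_at[r.youden_threshold] == pytest.approx(max(j_at.values()))


class TestCallMarker:
    def test_published_lob_semantics(self, default_panel):
        assert call_marker(5, "NPY", default_panel)        # 5 > LoB 4
        assert not call_marker(4, "NPY", default_panel)    # strictly above
        assert call_marker(2, "CLIP4", default_panel)      # 2 > LoB 1

    def test_unknown_marker_rejected(self, default_panel):
        with pytest.raises(ValidationError):
            call_marker(3, "KRAS", default_panel)

    def test_inclusive_mode(self):
        panel = MarkerPanel(strict=False)
        assert call_marker(4, "NPY", panel)


class TestCallSample:
    def _counts(self, **kw):
        counts = {m: 0 for m in calling.DEFAULT_MARKERS}
        counts.update(kw)
        return counts

    def test_exception_pair_is_negative(self, default_panel):
        c = call_sample(self._counts(NPY=5, GDAP1L1=3), default_panel)
        assert c.positive_markers == {"NPY", "GDAP1L1"}
        assert not c.positive

    def test_superset_of_exception_is_positive(self, default_panel):
        c = call_sample(self._counts(NPY=5, GDAP1L1=3, CELF2=3), default_panel)
        assert len(c.positive_markers) == 3
        assert c.positive

    def test_single_marker_is_negative(self, default_panel):
        c = call_sample(self._counts(NPY=10), default_panel)
        assert not c.positive

    def test_missing_marker_rejected(self, default_panel):
        with pytest.raises(ValidationError):
            call_sample({"NPY": 5}, default_panel)

    @given(data=st.data())
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_counts(self, default_panel, data):
        """Raising counts never flips positive -> negative, provided the
        starting positive set is not a subset of an exception set."""
        counts = {m: data.draw(st.integers(0, 8)) for m in calling.DEFAULT_MARKERS}
        call = call_sample(counts, default_panel)
        if not call.positive:
            return
        if any(call.positive_markers <= e for e in default_panel.exception_sets):
            return
        bumped = {m: c + data.draw(st.integers(0, 5)) for m, c in counts.items()}
        assert call_sample(bumped, default_panel).positive


class TestPerformanceMetrics:
    def test_published_control_specificity(self):
        # 2 positive calls among 60 true-negative controls
        calls = [True] * 2 + [False] * 58
        m = performance_metrics(calls, [False] * 60)
        assert m.as_dict()["specificity"] == 96.7
        assert 100 - m.as_dict()["specificity"] == pytest.approx(3.3)

    def test_published_localized_sensitivity(self):
        calls = [True] * 38 + [False] * 21
        m = performance_metrics(calls, [True] * 59)
        assert m.as_dict()["sensitivity"] == 64.4

    def test_perfect_agreement(self):
        m = performance_metrics([True, False, True], [True, False, True])
        d = m.as_dict()
        assert d["sensitivity"] == d["specificity"] == d["accuracy"] == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            performance_metrics([True], [True, False])


class TestCombinedRuleSearch:
    def _profiles(self, rows):
        return {f"s{i}": {m: c for m, c in zip(calling.DEFAULT_MARKERS, row)}
                for i, row in enumerate(rows)}

    def test_perfect_separation_selects_k1(self):
        ctrl = self._profiles([[0] * 5] * 20)
        case = self._profiles([[9, 9, 9, 9, 9]] * 20)
        res = combined_rule_search(ctrl, case, DEFAULT_LOB)
        assert res.panel.min_positive_markers == 1
        assert res.panel.exception_sets == ()
        assert res.reached_specificity

    def test_all_zero_controls_select_k1(self):
        ctrl = self._profiles([[0] * 5] * 10)
        case = self._profiles([[2, 0, 0, 0, 9]] * 10)
        res = combined_rule_search(ctrl, case, DEFAULT_LOB)
        assert res.panel.min_positive_markers == 1

    def test_pair_only_false_positives_promote_exception(self):
        # controls: 6 with exactly the NPY+GDAP1L1 pair above LoB, plus clean
        # singles; cases separate on three markers
        ctrl_rows = [[9, 0, 9, 0, 0]] * 6 + [[9, 0, 0, 0, 0]] * 10 + [[0] * 5] * 44
        case_rows = [[9, 9, 9, 9, 9]] * 40
        res = combined_rule_search(self._profiles(ctrl_rows),
                                   self._profiles(case_rows), DEFAULT_LOB)
        assert res.panel.min_positive_markers == 2
        assert frozenset({"NPY", "GDAP1L1"}) in res.panel.exception_sets
        assert res.reached_specificity

    def test_unreachable_specificity_warns_and_falls_back(self):
        ctrl = self._profiles([[9, 9, 9, 9, 9]] * 10)
        case = self._profiles([[9, 9, 9, 9, 9]] * 10)
        with pytest.warns(UserWarning):
            res = combined_rule_search(ctrl, case, DEFAULT_LOB)
        assert not res.reached_specificity
        assert res.panel.min_positive_markers == len(calling.DEFAULT_MARKERS)

    def test_selected_rule_meets_specificity_on_calibration_controls(
            self, calibrated, cohort_profiles, default_cohort):
        base = default_cohort.samples[default_cohort.samples.timepoint == "baseline"]
        ctrl_ids = base.loc[base.cohort == "control", "sample_id"]
        calls = [call_sample(cohort_profiles[s], calibrated.panel).positive
                 for s in ctrl_ids]
        assert 100 * (1 - np.mean(calls)) >= 95.0


def test_youden_equals_brute_force_on_random_instances():
    rng = np.random.default_rng(17)
    for _ in range(40):
        controls = rng.poisson(rng.uniform(0.3, 3.0), rng.integers(4, 25)).tolist()
        cases = rng.poisson(rng.uniform(1.0, 10.0), rng.integers(4, 25)).tolist()
        t, j = brute_force_youden(controls, cases)
        r = roc_and_youden(controls, cases)
        assert r.youden_threshold == t
        assert r.youden_j == pytest.approx(j)


def test_rule_recovery_on_default_cohorts():
    """Calibration on default synthetic cohorts recovers the published rule
    structure (k = 2 with the NPY+GDAP1L1 exception) in >= 90% of seeds."""
    hits = 0
    seeds = range(12)
    for seed in seeds:
        cohort = simulate.simulate_cohorts(simulate.CohortSpec(seed=seed))
        prof = calling.profiles_from_table(cohort.droplets)
        base = cohort.samples[cohort.samples.timepoint == "baseline"]
        cal = calibrate_panel(
            {s: prof[s] for s in base.loc[base.cohort == "control", "sample_id"]},
            {s: prof[s] for s in base.loc[base.cohort == "localized", "sample_id"]})
        p = cal.panel
        hits += (p.min_positive_markers == 2
                 and frozenset({"NPY", "GDAP1L1"}) in p.exception_sets)
    assert hits / len(seeds) >= 0.9
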