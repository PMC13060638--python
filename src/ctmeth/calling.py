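"""Limit-of-blank calibration and multi-marker ctDNA positivity calling.

The assay measures five methylation markers (NPY, FRMD4B, GDAP1L1, CELF2,
CLIP4) plus an ALB reference in each multiplex well. Calibration proceeds in
two stages on a control cohort (healthy, analyte-free plasma) versus a case
cohort:

1. **Per-marker limit of blank (LoB).** For each marker, the pooled
   positive-droplet counts of controls and cases define an empirical ROC; the
   LoB is the integer threshold maximising Youden's J = sensitivity +
   specificity − 1, ties broken toward the *higher* threshold (LoB semantics
   favour specificity). A sample is marker-positive when its pooled count is
   strictly above the LoB.

2. **Combined rule.** A sample is ctDNA-positive when at least
   ``min_positive_markers`` markers are above their LoB — unless its positive
   set equals an *exception set*, a specific marker combination observed to
   recur in analyte-free controls (correlated background). The rule search
   ascends k = 1..n_markers, trying the plain k-of-n rule and then single
   exact-set exceptions harvested from control false positives, and adopts
   the first rule meeting the requested specificity (≥ 95% by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ddpcr import ValidationError

__all__ = [
    "DEFAULT_MARKERS",
    "DEFAULT_LOB",
    "MarkerPanel",
    "RocResult",
    "PerformanceMetrics",
    "SampleCall",
    "roc_and_youden",
    "call_marker",
    "call_sample",
    "combined_rule_search",
    "performance_metrics",
    "calibrate_panel",
    "profiles_from_table",
]

DEFAULT_MARKERS: tuple[str, ...] = ("NPY", "FRMD4B", "GDAP1L1", "CELF2", "CLIP4")
DEFAULT_LOB: dict[str, int] = {"NPY": 4, "FRMD4B": 3, "GDAP1L1": 2, "CELF2": 2, "CLIP4": 1}
DEFAULT_EXCEPTIONS: tuple[frozenset[str], ...] = (frozenset({"NPY", "GDAP1L1"}),)


@dataclass(frozen=True)
class MarkerPanel:
    """The calibrated panel: markers, per-marker LoB and the combined rule."""

    markers: tuple[str, ...] = DEFAULT_MARKERS
    reference: str = "ALB"
    lob: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LOB))
    min_positive_markers: int = 2
    exception_sets: tuple[frozenset[str], ...] = DEFAULT_EXCEPTIONS
    strict: bool = True  # marker positive iff count > LoB; False → >=

    def __post_init__(self) -> None:
        if self.reference in self.markers:
            raise ValidationError("reference target cannot be a panel marker")
        missing = [m for m in self.markers if m not in self.lob]
        if missing:
            raise ValidationError(f"LoB undefined for markers {missing}")
        for s in self.exception_sets:
            if len(s) < self.min_positive_markers:
                raise ValidationError(
                    f"exception set {sorted(s)} smaller than min_positive_markers")
            if not s <= set(self.markers):
                raise ValidationError(f"exception set {sorted(s)} contains unknown markers")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "markers": list(self.markers),
            "reference": self.reference,
            "lob": dict(self.lob),
            "min_positive_markers": self.min_positive_markers,
            "exception_sets": [sorted(s) for s in self.exception_sets],
            "strict": self.strict,
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerPanel":
        obj = json.loads(Path(path).read_text())
        return cls(
            markers=tuple(obj["markers"]),
            reference=obj.get("reference", "ALB"),
            lob={k: int(v) for k, v in obj["lob"].items()},
            min_positive_markers=int(obj["min_positive_markers"]),
            exception_sets=tuple(frozenset(s) for s in obj.get("exception_sets", [])),
            strict=bool(obj.get("strict", True)),
        )


@dataclass(frozen=True)
class RocResult:
    marker: str
    thresholds: tuple[int, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float
    youden_threshold: int
    youden_j: float


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    positive: bool
    positive_markers: frozenset[str]


@dataclass(frozen=True)
class PerformanceMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / n if n else float("nan")

    def as_dict(self, ndigits: int = 1) -> dict[str, float | int]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "ppv": round(self.ppv, ndigits),
            "npv": round(self.npv, ndigits),
            "accuracy": round(self.accuracy, ndigits),
        }


def roc_and_youden(control_counts: Sequence[int], case_counts: Sequence[int],
                   marker: str = "") -> RocResult:
    """Empirical ROC over integer droplet-count thresholds plus Youden's J.

    A sample is called positive at threshold ``t`` when its count is strictly
    greater than ``t``. Every integer threshold from 0 to the largest
    observed count is a candidate; among J-maximising thresholds the highest
    is returned (maximal specificity, matching limit-of-blank semantics).
    """
    controls = np.asarray(control_counts)
    cases = np.asarray(case_counts)
    if controls.size == 0 or cases.size == 0:
        raise ValidationError("control and case count lists must be non-empty")
    if (controls < 0).any() or (cases < 0).any():
        raise ValidationError("droplet counts must be non-negative")

    thresholds = np.arange(0, int(max(controls.max(), cases.max())) + 1)
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])
    j = sens + spec - 1.0

    best_j = j.max()
    best_t = int(thresholds[j >= best_j - 1e-12].max())  # tie → higher threshold

    labels = np.concatenate([np.zeros(controls.size), np.ones(cases.size)])
    scores = np.concatenate([controls, cases]).astype(float)
    if np.unique(scores).size == 1:
        auc = 0.5
    else:
        auc = float(roc_auc_score(labels, scores))

    return RocResult(
        marker=marker,
        thresholds=tuple(int(t) for t in thresholds),
        sensitivity=tuple(float(s) for s in sens),
        specificity=tuple(float(s) for s in spec),
        auc=auc,
        youden_threshold=best_t,
        youden_j=float(best_j),
    )


def call_marker(count: int, marker: str, panel: MarkerPanel) -> bool:
    """True iff the marker's pooled positive-droplet count exceeds its LoB."""
    if marker not in panel.lob:
        raise ValidationError(f"unknown marker {marker!r}")
    if panel.strict:
        return count > panel.lob[marker]
    return count >= panel.lob[marker]


def positive_marker_set(counts: Mapping[str, int], panel: MarkerPanel) -> frozenset[str]:
    missing = [m for m in panel.markers if m not in counts]
    if missing:
        raise ValidationError(f"counts missing markers {missing}")
    return frozenset(m for m in panel.markers if call_marker(counts[m], m, panel))


def call_sample(counts: Mapping[str, int], panel: MarkerPanel,
                sample_id: str = "") -> SampleCall:
    """Combined positivity rule: at least ``min_positive_markers`` markers
    above LoB and the positive set is not exactly an exception set."""
    pos = positive_marker_set(counts, panel)
    positive = len(pos) >= panel.min_positive_markers and pos not in panel.exception_sets
    return SampleCall(sample_id=sample_id, positive=positive, positive_markers=pos)


def performance_metrics(calls: Sequence[bool], truth: Sequence[bool]) -> PerformanceMetrics:
    if len(calls) != len(truth):
        raise ValidationError("calls and truth must have equal length")
    if not calls:
        raise ValidationError("empty inputs")
    calls_a = np.asarray(calls, dtype=bool)
    truth_a = np.asarray(truth, dtype=bool)
    return PerformanceMetrics(
        tp=int((calls_a & truth_a).sum()),
        fp=int((calls_a & ~truth_a).sum()),
        tn=int((~calls_a & ~truth_a).sum()),
        fn=int((~calls_a & truth_a).sum()),
    )


@dataclass(frozen=True)
class RuleSearchResult:
    panel: MarkerPanel
    k_table: pd.DataFrame  # k, sensitivity, specificity for plain k-of-n rules
    reached_specificity: bool
    log: tuple[str, ...]


def _rule_spec_sens(
    control_sets: Sequence[frozenset[str]],
    case_sets: Sequence[frozenset[str]],
    k: int,
    exceptions: tuple[frozenset[str], ...],
) -> tuple[float, float]:
    def pos(s: frozenset[str]) -> bool:
        return len(s) >= k and s not in exceptions

    spec = 100.0 * sum(not pos(s) for s in control_sets) / len(control_sets)
    sens = 100.0 * sum(pos(s) for s in case_sets) / len(case_sets)
    return spec, sens


def combined_rule_search(
    control_profiles: Mapping[str, Mapping[str, int]],
    case_profiles: Mapping[str, Mapping[str, int]],
    lobs: Mapping[str, int],
    min_specificity: float = 95.0,
    markers: Sequence[str] = DEFAULT_MARKERS,
    reference: str = "ALB",
    strict: bool = True,
) -> RuleSearchResult:
    """Search the k-of-n rule family (with exact-set exceptions) for the
    least stringent rule achieving the target control specificity.

    For each k ascending: the plain rule (positive iff ≥ k markers above LoB)
    is evaluated first; if it misses the specificity target, each exact
    positive-marker set of size exactly k occurring among the control false
    positives is tried as a single exception (most frequent first, ties
    broken lexicographically). Only minimal sets (|set| = k) are eligible:
    a larger exception would call a sample negative while one of its
    subsets is called positive, breaking monotonicity. The first
    configuration reaching ``min_specificity`` wins, so a k=2 rule rescued
    by an exception is preferred over a plain k=3 rule — it keeps more case
    sensitivity.
    """
    if not 0 < min_specificity <= 100:
        raise ValidationError("min_specificity must be in (0, 100]")
    markers = tuple(markers)
    base = MarkerPanel(markers=markers, reference=reference, lob=dict(lobs),
                       min_positive_markers=1, exception_sets=(), strict=strict)

    control_sets = [positive_marker_set(p, base) for p in control_profiles.values()]
    case_sets = [positive_marker_set(p, base) for p in case_profiles.values()]

    k_rows = []
    for k in range(1, len(markers) + 1):
        spec, sens = _rule_spec_sens(control_sets, case_sets, k, ())
        k_rows.append({"k": k, "specificity": spec, "sensitivity": sens})
    k_table = pd.DataFrame(k_rows)

    log: list[str] = []
    for k in range(1, len(markers) + 1):
        spec, sens = _rule_spec_sens(control_sets, case_sets, k, ())
        log.append(f"k={k}: plain rule specificity {spec:.1f}%, sensitivity {sens:.1f}%")
        if spec >= min_specificity:
            panel = MarkerPanel(markers=markers, reference=reference, lob=dict(lobs),
                                min_positive_markers=k, exception_sets=(), strict=strict)
            return RuleSearchResult(panel, k_table, True, tuple(log))

        # exception discovery: minimal (size-k) exact positive sets among
        # control false positives
        fp_sets = [s for s in control_sets if len(s) >= k]
        candidates: dict[frozenset[str], int] = {}
        for s in fp_sets:
            if len(s) == k:
                candidates[s] = candidates.get(s, 0) + 1
        ordered = sorted(candidates.items(),
                         key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
        for cand, n_ctrl in ordered:
            spec_e, sens_e = _rule_spec_sens(control_sets, case_sets, k, (cand,))
            # adopt only when the exception yields the better
            # sensitivity-specificity combination, not specificity alone
            if spec_e >= min_specificity and spec_e + sens_e > spec + sens:
                n_case = sum(s == cand for s in case_sets)
                log.append(
                    f"k={k}: exception {sorted(cand)} (seen in {n_ctrl} control FPs, "
                    f"{n_case} cases) lifts specificity to {spec_e:.1f}% "
                    f"(sensitivity {sens_e:.1f}%); adopted")
                panel = MarkerPanel(markers=markers, reference=reference, lob=dict(lobs),
                                    min_positive_markers=k, exception_sets=(cand,),
                                    strict=strict)
                return RuleSearchResult(panel, k_table, True, tuple(log))

    warnings.warn("no k-of-n rule reached the requested specificity; "
                  "falling back to k = n_markers", stacklevel=2)
    panel = MarkerPanel(markers=markers, reference=reference, lob=dict(lobs),
                        min_positive_markers=len(markers), exception_sets=(), strict=strict)
    log.append("no rule reached the requested specificity; k = n_markers with warning")
    return RuleSearchResult(panel, k_table, False, tuple(log))


def profiles_from_table(droplets: pd.DataFrame,
                        markers: Sequence[str] = DEFAULT_MARKERS) -> dict[str, dict[str, int]]:
    """Pool duplicate wells and return per-sample marker → positive-droplet
    count maps (the calling currency of the panel)."""
    pooled = (droplets[droplets.target.isin(markers)]
              .groupby(["sample_id", "target"])["n_positive"].sum().unstack(fill_value=0))
    missing = [m for m in markers if m not in pooled.columns]
    for m in missing:
        pooled[m] = 0
    return {str(s): {m: int(pooled.loc[s, m]) for m in markers} for s in pooled.index}


@dataclass(frozen=True)
class CalibrationResult:
    panel: MarkerPanel
    roc: Mapping[str, RocResult]
    rule_search: RuleSearchResult
    metrics: PerformanceMetrics

    def to_json(self, path: str | Path) -> None:
        obj = {
            "lob": {m: r.youden_threshold for m, r in self.roc.items()},
            "auc": {m: r.auc for m, r in self.roc.items()},
            "min_positive_markers": self.panel.min_positive_markers,
            "exception_sets": [sorted(s) for s in self.panel.exception_sets],
            "k_table": self.rule_search.k_table.to_dict(orient="records"),
            "calibration_metrics": self.metrics.as_dict(),
            "log": list(self.rule_search.log),
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def calibrate_panel(
    control_profiles: Mapping[str, Mapping[str, int]],
    case_profiles: Mapping[str, Mapping[str, int]],
    min_specificity: float = 95.0,
    markers: Sequence[str] = DEFAULT_MARKERS,
    reference: str = "ALB",
    strict: bool = True,
) -> CalibrationResult:
    """Full calibration: per-marker Youden LoB, then the combined-rule search."""
    roc: dict[str, RocResult] = {}
    lobs: dict[str, int] = {}
    for m in markers:
        ctrl = [p[m] for p in control_profiles.values()]
        case = [p[m] for p in case_profiles.values()]
        r = roc_and_youden(ctrl, case, marker=m)
        roc[m] = r
        lobs[m] = r.youden_threshold

    search = combined_rule_search(control_profiles, case_profiles, lobs,
                                  min_specificity=min_specificity, markers=markers,
                                  reference=reference, strict=strict)
    panel = search.panel
    calls = ([call_sample(p, panel).positive for p in control_profiles.values()]
             + [call_sample(p, panel).positive for p in case_profiles.values()])
    truth = [False] * len(control_profiles) + [True] * len(case_profiles)
    return CalibrationResult(panel=panel, roc=roc, rule_search=search,
                             metrics=performance_metrics(calls, truth))


def classify_profiles(profiles: Mapping[str, Mapping[str, int]],
                      panel: MarkerPanel) -> pd.DataFrame:
    rows = []
    for sid, counts in profiles.items():
        c = call_sample(counts, panel, sample_id=sid)
        rows.append({
            "sample_id": sid,
            "ctdna_status": "positive" if c.positive else "negative",
            "positive_markers": ";".join(sorted(c.positive_markers)),
        })
    return pd.DataFrame(rows)
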