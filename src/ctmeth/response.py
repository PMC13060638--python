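"""Molecular response classification from serial ctDNA measurements.

Metastatic patients are sampled at baseline and after the first treatment
cycle. Each timepoint yields an aggregated **ctDNA fraction** — here the sum
of the five methylation markers' copies over ALB copies × 100, with a 95% CI
obtained by applying the Wilson/Poisson machinery to the summed positive
droplet counts (summation is monotone, uses all signal, and keeps a natural
count-level CI; max-marker and mean-of-positive-markers aggregations are
available as alternatives).

A change between timepoints is significant when the two 95% CIs do not
overlap (touching intervals count as overlap). Categories follow a
RECIST-like scheme driven purely by ctDNA kinetics:

* PD  — significant increase
* SD  — no significant change
* PR  — significant decrease, still ctDNA-positive
* NCR — significant decrease to ctDNA-negative (residual sub-LoB droplets)
* CR  — significant decrease to zero positive droplets on all five markers

and the three-level responder grouping collapses these with the >75%
fraction-decrease rule: *progressive* (increase, or a negative→positive
transition), *good* (post-treatment negative regardless of change, or
consistently positive with a significant decrease of more than 75%), *poor*
(consistently positive with ≤75% decrease or stable fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .calling import MarkerPanel, SampleCall, call_sample
from .ddpcr import SampleMeasurement, ValidationError, concentration_from_droplets

__all__ = [
    "TimepointState",
    "SerialPair",
    "ResponseCall",
    "aggregate_fraction",
    "ci_overlap_change",
    "percent_change",
    "ctdna_recist",
    "responder_group",
    "classify_pair",
    "classify_pairs",
    "summarize_calls",
]

Change = Literal["increase", "decrease", "none"]
Recist = Literal["CR", "NCR", "PR", "SD", "PD"]
Group = Literal["good", "poor", "progressive"]


@dataclass(frozen=True)
class TimepointState:
    """One timepoint of one patient, reduced to what the kinetics need."""

    fraction: float | None  # aggregated % methylated; None when ALB = 0
    ci_low: float
    ci_high: float
    ctdna_positive: bool
    marker_droplets_total: int  # summed positive droplets across the 5 markers

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValidationError("inverted confidence interval")


@dataclass(frozen=True)
class SerialPair:
    patient_id: str
    baseline: TimepointState
    post: TimepointState

    @property
    def status_pair(self) -> str:
        return ("P" if self.baseline.ctdna_positive else "N") + \
               ("P" if self.post.ctdna_positive else "N")


@dataclass(frozen=True)
class ResponseCall:
    patient_id: str
    status_pair: str
    change_significant: Change
    percent_change: float | None
    recist: Recist
    group: Group


def aggregate_fraction(
    measurement: SampleMeasurement,
    panel: MarkerPanel,
    mode: str = "sum",
) -> TimepointState | None:
    """Aggregate a multi-marker measurement into one ctDNA fraction with CI.

    ``sum`` (default) pools the five markers' positive droplet counts and
    quantifies the pooled count as if it were one target; the CI is the
    Wilson-transformed interval on that pooled count, scaled by the ALB point
    estimate. ``max`` takes the single highest-fraction marker's count;
    ``mean-positive`` averages over markers with non-zero copies.

    Returns None-fraction state (flagged) when ALB measured zero copies.
    """
    alb = measurement.quants.get(panel.reference)
    if alb is None:
        raise ValidationError(f"measurement lacks the reference target {panel.reference}")
    marker_quants = {m: measurement.quants[m] for m in panel.markers
                     if m in measurement.quants}
    if len(marker_quants) < len(panel.markers):
        missing = set(panel.markers) - set(marker_quants)
        raise ValidationError(f"measurement lacks markers {sorted(missing)}")

    counts = {m: q.n_positive_merged for m, q in marker_quants.items()}
    droplet_total = sum(counts.values())
    n_total = max(q.n_total_merged for q in marker_quants.values())

    if mode == "sum":
        n_pos = droplet_total
    elif mode == "max":
        n_pos = max(counts.values())
    elif mode == "mean-positive":
        pos = [c for c in counts.values() if c > 0]
        n_pos = int(round(sum(pos) / len(pos))) if pos else 0
    else:
        raise ValidationError(f"unknown aggregation mode {mode!r}")

    agg = concentration_from_droplets(min(n_pos, n_total), n_total,
                                      target="aggregate")
    call = call_sample(counts, panel)

    if alb.copies_per_ul == 0:
        return TimepointState(fraction=None, ci_low=0.0, ci_high=0.0,
                              ctdna_positive=call.positive,
                              marker_droplets_total=droplet_total)
    scale = 100.0 / alb.copies_per_ul
    return TimepointState(
        fraction=agg.copies_per_ul * scale,
        ci_low=agg.ci_low * scale,
        ci_high=agg.ci_high * scale,
        ctdna_positive=call.positive,
        marker_droplets_total=droplet_total,
    )


def ci_overlap_change(baseline_ci: tuple[float, float],
                      post_ci: tuple[float, float]) -> Change:
    """Significant change iff the two 95% CIs do not overlap; touching
    intervals count as overlapping (no change)."""
    b_lo, b_hi = baseline_ci
    p_lo, p_hi = post_ci
    if b_lo > b_hi or p_lo > p_hi:
        raise ValidationError("inverted confidence interval")
    if p_hi < b_lo:
        return "decrease"
    if p_lo > b_hi:
        return "increase"
    return "none"


def percent_change(f_baseline: float, f_post: float) -> float | None:
    """Signed percent change of the ctDNA fraction; ``None`` (undefined) when
    the baseline fraction is zero."""
    if f_baseline < 0 or f_post < 0:
        raise ValidationError("fractions cannot be negative")
    if f_baseline == 0:
        return None
    return 100.0 * (f_post - f_baseline) / f_baseline


def ctdna_recist(change: Change, post: TimepointState) -> Recist:
    """RECIST-like category from the significance call and the post state."""
    if change == "increase":
        return "PD"
    if change == "none":
        return "SD"
    if post.marker_droplets_total == 0:
        return "CR"
    if not post.ctdna_positive:
        return "NCR"
    return "PR"


def responder_group(status_pair: str, change: Change, pct_change: float | None,
                    decrease_threshold: float = 75.0) -> Group:
    """Three-level grouping: progressive / good / poor (see module docstring)."""
    if status_pair == "NP" or change == "increase":
        return "progressive"
    if status_pair in ("PN", "NN"):
        return "good"  # post-treatment ctDNA-negative, regardless of change
    # consistently positive (PP)
    if change == "decrease" and pct_change is not None and pct_change < -decrease_threshold:
        return "good"
    return "poor"


def classify_pair(pair: SerialPair, decrease_threshold: float = 75.0) -> ResponseCall:
    b, p = pair.baseline, pair.post
    change = ci_overlap_change((b.ci_low, b.ci_high), (p.ci_low, p.ci_high))
    if b.fraction is None or p.fraction is None:
        pct = None
    else:
        pct = percent_change(b.fraction, p.fraction)
    return ResponseCall(
        patient_id=pair.patient_id,
        status_pair=pair.status_pair,
        change_significant=change,
        percent_change=pct,
        recist=ctdna_recist(change, p),
        group=responder_group(pair.status_pair, change, pct, decrease_threshold),
    )


def classify_pairs(pairs: Sequence[SerialPair],
                   decrease_threshold: float = 75.0) -> list[ResponseCall]:
    return [classify_pair(p, decrease_threshold) for p in pairs]


def summarize_calls(calls: Sequence[ResponseCall]) -> dict[str, dict[str, int]]:
    """Category counts mirroring the published summaries: status transitions,
    significance of change, RECIST categories, responder groups."""
    out: dict[str, dict[str, int]] = {
        "status_pair": {}, "change": {}, "recist": {}, "group": {},
    }
    for c in calls:
        out["status_pair"][c.status_pair] = out["status_pair"].get(c.status_pair, 0) + 1
        out["change"][c.change_significant] = out["change"].get(c.change_significant, 0) + 1
        out["recist"][c.recist] = out["recist"].get(c.recist, 0) + 1
        out["group"][c.group] = out["group"].get(c.group, 0) + 1
    return out


def calls_table(calls: Sequence[ResponseCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "patient_id": c.patient_id,
            "status_pair": c.status_pair,
            "change_significant": c.change_significant,
            "percent_change": c.percent_change,
            "recist": c.recist,
            "group": c.group,
        }
        for c in calls
    ])
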