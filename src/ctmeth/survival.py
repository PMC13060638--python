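"""Survival stratification of response groups.

Kaplan–Meier product-limit curves with Greenwood-based confidence intervals,
log-rank group comparison, and a single-covariate Cox proportional-hazards
contract (Efron tie handling) delegated to lifelines. Medians that the curve
never reaches are propagated as the token ``"NR"`` in tabular output, never
as infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .ddpcr import ValidationError

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "HazardRatio",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "median_table",
]

NOT_REACHED = "NR"


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months from first treatment
    event: bool  # True = progression/death observed; False = censored
    stratum: str = ""
    endpoint: str = "PFS"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValidationError("survival time must be positive")


@dataclass(frozen=True)
class KMEstimate:
    timeline: np.ndarray
    survival: np.ndarray
    median: float | None           # None = not reached
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    @property
    def median_token(self) -> str:
        return NOT_REACHED if self.median is None else f"{self.median:g}"


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord], alpha: float = 0.05) -> KMEstimate:
    """Product-limit estimator with median survival and its 95% CI.

    The median is the earliest time at which the estimated survival drops to
    0.5 or below; when the curve never does, the median is ``None`` ("not
    reached"). The median CI comes from inverting the Greenwood log-log
    confidence band at 0.5.
    """
    if not records:
        raise ValidationError("need at least one survival record")
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(t, event_observed=e)
        med = kmf.median_survival_time_
        ci = median_survival_times(kmf.confidence_interval_)

    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMEstimate(
        timeline=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        median=None if np.isinf(med) else float(med),
        median_ci=(None if np.isinf(lo) else lo, None if np.isinf(hi) else hi),
        n=len(records),
        n_events=int(e.sum()),
    )


def logrank_test(groups: Mapping[str, Sequence[SurvivalRecord]]) -> tuple[float, float]:
    """Log-rank comparison of two or more groups → (chi², p-value).

    Degenerate input with zero events anywhere returns (0, 1) with a warning.
    """
    if len(groups) < 2:
        raise ValidationError("log-rank needs at least two groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValidationError("all groups must be non-empty")

    times, events, labels = [], [], []
    for label, recs in groups.items():
        t, e = _to_arrays(recs)
        times.append(t)
        events.append(e)
        labels.extend([label] * len(recs))
    t_all = np.concatenate(times)
    e_all = np.concatenate(events)
    if e_all.sum() == 0:
        warnings.warn("no events in any group; log-rank is degenerate (p = 1)",
                      stacklevel=2)
        return 0.0, 1.0
    res = multivariate_logrank_test(t_all, np.array(labels), e_all)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class HazardRatio:
    group: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    unstable: bool = False


def hazard_ratio(groups: Mapping[str, Sequence[SurvivalRecord]],
                 reference: str) -> dict[str, HazardRatio]:
    """Cox proportional-hazards fit with the group as a single categorical
    covariate; returns per-group HR (vs reference) with 95% CI.

    Ties use lifelines' Efron approximation. A reference arm without events
    is flagged unstable rather than rejected.
    """
    if reference not in groups or len(groups[reference]) == 0:
        raise ValidationError(f"reference group {reference!r} is missing or empty")
    for label, recs in groups.items():
        if label != reference and len(recs) == 0:
            raise ValidationError(f"group {label!r} is empty")

    unstable = sum(r.event for r in groups[reference]) == 0
    if unstable:
        warnings.warn("no events in the reference group; hazard ratios are unstable",
                      stacklevel=2)

    frames = []
    others = [g for g in groups if g != reference]
    for label, recs in groups.items():
        t, e = _to_arrays(recs)
        df = pd.DataFrame({"time": t, "event": e.astype(int)})
        for o in others:
            df[f"g_{o}"] = float(label == o)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col="time", event_col="event")

    out: dict[str, HazardRatio] = {}
    with np.errstate(over="ignore"):  # unstable fits can overflow exp(CI)
        for o in others:
            cov = f"g_{o}"
            coef = float(cph.params_[cov])
            lo, hi = cph.confidence_intervals_.loc[cov]
            out[o] = HazardRatio(
                group=o,
                hr=float(np.exp(coef)),
                ci_low=float(np.exp(lo)),
                ci_high=float(np.exp(hi)),
                p_value=float(cph.summary.loc[cov, "p"]),
                unstable=unstable,
            )
    return out


def median_table(groups: Mapping[str, Sequence[SurvivalRecord]],
                 reference: str | None = None) -> pd.DataFrame:
    """Per-stratum median survival (95% CI) table, with HRs against the
    reference stratum when one is given; medians never reached print "NR"."""
    rows = []
    hrs = hazard_ratio(groups, reference) if reference is not None and len(groups) > 1 else {}
    for label, recs in groups.items():
        km = km_estimate(recs)
        lo = NOT_REACHED if km.median_ci[0] is None else f"{km.median_ci[0]:.1f}"
        hi = NOT_REACHED if km.median_ci[1] is None else f"{km.median_ci[1]:.1f}"
        row = {
            "stratum": label,
            "n": km.n,
            "events": km.n_events,
            "median": km.median_token,
            "median_ci": f"{lo}-{hi}",
        }
        if reference is not None:
            if label == reference:
                row.update({"hr": "Reference", "hr_ci": "", "p": ""})
            elif label in hrs:
                h = hrs[label]
                row.update({"hr": f"{h.hr:.2f}",
                            "hr_ci": f"{h.ci_low:.2f}-{h.ci_high:.2f}",
                            "p": f"{h.p_value:.3g}"})
        rows.append(row)
    return pd.DataFrame(rows)
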