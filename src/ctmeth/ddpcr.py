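"""Poisson quantification of droplet digital PCR (ddPCR) wells.

A ddPCR reaction is partitioned into ~20,000 nanolitre-scale droplets and each
droplet is read out as positive (>= 1 template copy) or negative. Under random
partitioning the copy number per droplet is Poisson, so the mean occupancy is
recovered from the fraction of positive droplets ``p`` as

    lambda = -ln(1 - p),        p = n_positive / n_total

and the concentration in the reaction is ``lambda / v`` with ``v`` the droplet
volume. Confidence intervals are obtained by computing a Wilson score interval
on ``p`` and pushing its bounds through the same (monotone) log transform,
which is stable down to zero-count wells and preserves interval ordering.

Duplicate wells for the same sample and target are pooled by *adding* droplet
counts before quantification: droplets from replicate wells of one reaction
mix are exchangeable, so pooling is exact, whereas averaging per-well
estimates is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DropletWell",
    "TargetQuant",
    "SampleMeasurement",
    "VolumeConfig",
    "ValidationError",
    "concentration_from_droplets",
    "merge_wells",
    "percent_methylated",
    "copies_per_ml_plasma",
    "quantify_sample",
    "quantify_table",
]


class ValidationError(ValueError):
    """Raised when droplet counts or volumes violate their preconditions."""


@dataclass(frozen=True)
class DropletWell:
    """Raw gated droplet counts from one well for one target."""

    sample_id: str
    well_id: str
    target: str
    n_positive: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError(
                f"well {self.well_id}/{self.target}: n_total must be positive, got {self.n_total}"
            )
        if not 0 <= self.n_positive <= self.n_total:
            raise ValidationError(
                f"well {self.well_id}/{self.target}: need 0 <= n_positive <= n_total, "
                f"got {self.n_positive}/{self.n_total}"
            )


@dataclass(frozen=True)
class TargetQuant:
    """Concentration estimate for one target in one sample.

    ``lambda_hat`` is mean copies per droplet; ``copies_per_ul`` refers to the
    ddPCR reaction volume. For saturated wells (every droplet positive) the
    point estimate is the Wilson *lower* bound pushed through the transform —
    a flagged lower bound, not a usable point estimate — and ``ci_high`` is
    ``inf``.
    """

    target: str
    lambda_hat: float
    copies_per_ul: float
    ci_low: float
    ci_high: float
    n_positive_merged: int
    n_total_merged: int
    saturated: bool = False

    @property
    def copies_per_reaction(self) -> float:
        raise AttributeError("use VolumeConfig-aware helpers; reaction volume not stored here")


@dataclass(frozen=True)
class VolumeConfig:
    """Volume chain from droplet to plasma.

    The droplet volume is an instrument constant not reported by assay
    vendors' summary tables; 0.85 nL is the QX-series convention and every
    copies/µL figure scales inversely with it. The default chain assumes
    duplicate 5 µL templates drawn from a 15 µL bisulfite-converted eluate
    that derives from 4 mL plasma.
    """

    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    template_volume_ul: float = 5.0
    eluate_volume_ul: float = 15.0
    plasma_volume_ml: float = 4.0
    ci_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("droplet_volume_nl", "reaction_volume_ul", "template_volume_ul",
                     "eluate_volume_ul", "plasma_volume_ml"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.ci_alpha < 1:
            raise ValidationError("ci_alpha must be in (0, 1)")

    def analyzed_fraction(self, n_wells: int) -> float:
        frac = n_wells * self.template_volume_ul / self.eluate_volume_ul
        if not 0 < frac <= 1:
            raise ValidationError(
                f"analyzed fraction {frac:.3f} outside (0, 1]; check template/eluate volumes"
            )
        return frac


def _lambda(p: float) -> float:
    # guard against p == 1 producing -ln(0)
    return math.inf if p >= 1.0 else -math.log1p(-p)


def concentration_from_droplets(
    n_positive: int,
    n_total: int,
    droplet_volume_nl: float = 0.85,
    ci_alpha: float = 0.05,
    target: str = "",
) -> TargetQuant:
    """Poisson occupancy estimate with a Wilson-transformed 95% CI.

    Parameters mirror a (possibly pooled) well: ``n_positive`` positive of
    ``n_total`` accepted droplets. Returns copies per µL of reaction.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValidationError(f"need 0 <= n_positive <= n_total, got {n_positive}/{n_total}")
    if droplet_volume_nl <= 0:
        raise ValidationError("droplet_volume_nl must be positive")

    v_ul = droplet_volume_nl / 1000.0
    p_low, p_high = proportion_confint(n_positive, n_total, alpha=ci_alpha, method="wilson")
    lam_low, lam_high = _lambda(p_low), _lambda(p_high)

    if n_positive == n_total:
        # Saturated: the point estimate is unreliable; report the CI lower
        # bound as a flagged floor.
        lam = lam_low
        return TargetQuant(
            target=target,
            lambda_hat=lam,
            copies_per_ul=lam / v_ul,
            ci_low=lam_low / v_ul,
            ci_high=math.inf,
            n_positive_merged=n_positive,
            n_total_merged=n_total,
            saturated=True,
        )

    p_hat = n_positive / n_total
    lam = _lambda(p_hat)
    if n_positive == 0:
        lam_low = 0.0  # Wilson lower bound at zero counts is 0 exactly
    return TargetQuant(
        target=target,
        lambda_hat=lam,
        copies_per_ul=lam / v_ul,
        ci_low=lam_low / v_ul,
        ci_high=lam_high / v_ul,
        n_positive_merged=n_positive,
        n_total_merged=n_total,
        saturated=False,
    )


def merge_wells(wells: Sequence[DropletWell]) -> DropletWell:
    """Pool duplicate wells for one sample and target by adding counts."""
    if not wells:
        raise ValidationError("cannot merge an empty list of wells")
    sample_ids = {w.sample_id for w in wells}
    targets = {w.target for w in wells}
    if len(sample_ids) > 1:
        raise ValidationError(f"wells span multiple samples: {sorted(sample_ids)}")
    if len(targets) > 1:
        raise ValidationError(f"wells span multiple targets: {sorted(targets)}")
    return DropletWell(
        sample_id=wells[0].sample_id,
        well_id="+".join(w.well_id for w in wells),
        target=wells[0].target,
        n_positive=sum(w.n_positive for w in wells),
        n_total=sum(w.n_total for w in wells),
    )


def percent_methylated(target_quant: TargetQuant, alb_quant: TargetQuant) -> float | None:
    """Percent methylated = 100 × target copies / ALB copies.

    Returns ``None`` (an explicit undefined flag, not zero) when the ALB
    reference measured zero copies.
    """
    if alb_quant.copies_per_ul == 0:
        return None
    return 100.0 * target_quant.copies_per_ul / alb_quant.copies_per_ul


def copies_per_ml_plasma(
    copies_per_reaction: float,
    analyzed_fraction: float,
    plasma_volume_ml: float,
) -> float:
    """Scale total measured copies (summed over analyzed wells) to copies per
    mL of plasma, dividing out the fraction of the eluate that was analyzed."""
    if not 0 < analyzed_fraction <= 1:
        raise ValidationError("analyzed_fraction must be in (0, 1]")
    if plasma_volume_ml <= 0:
        raise ValidationError("plasma_volume_ml must be positive")
    if copies_per_reaction < 0:
        raise ValidationError("copies cannot be negative")
    return copies_per_reaction / analyzed_fraction / plasma_volume_ml


@dataclass(frozen=True)
class SampleMeasurement:
    """Per-sample quantification across the marker panel plus the reference.

    ``percent_methylated`` maps marker → percentage or ``None`` (undefined
    when ALB is zero). ``copies_per_ml_plasma`` maps target → plasma-scale
    copy number.
    """

    sample_id: str
    quants: Mapping[str, TargetQuant]
    percent_methylated: Mapping[str, float | None]
    copies_per_ml_plasma: Mapping[str, float]
    n_wells: Mapping[str, int]
    volumes: VolumeConfig = field(default_factory=VolumeConfig)
    reference: str = "ALB"

    def pooled_counts(self) -> dict[str, int]:
        return {t: q.n_positive_merged for t, q in self.quants.items()}


def quantify_sample(
    wells: Iterable[DropletWell],
    reference: str = "ALB",
    volumes: VolumeConfig | None = None,
) -> SampleMeasurement:
    """Merge duplicate wells per target and quantify one sample end to end."""
    volumes = volumes or VolumeConfig()
    wells = list(wells)
    if not wells:
        raise ValidationError("no wells supplied")
    sample_ids = {w.sample_id for w in wells}
    if len(sample_ids) > 1:
        raise ValidationError(f"wells span multiple samples: {sorted(sample_ids)}")
    sample_id = wells[0].sample_id

    by_target: dict[str, list[DropletWell]] = {}
    for w in wells:
        by_target.setdefault(w.target, []).append(w)

    quants: dict[str, TargetQuant] = {}
    n_wells: dict[str, int] = {}
    plasma: dict[str, float] = {}
    for tgt, tgt_wells in by_target.items():
        merged = merge_wells(tgt_wells)
        q = concentration_from_droplets(
            merged.n_positive, merged.n_total,
            droplet_volume_nl=volumes.droplet_volume_nl,
            ci_alpha=volumes.ci_alpha,
            target=tgt,
        )
        quants[tgt] = q
        n_wells[tgt] = len(tgt_wells)
        copies_total = q.copies_per_ul * volumes.reaction_volume_ul * len(tgt_wells)
        plasma[tgt] = copies_per_ml_plasma(
            copies_total,
            volumes.analyzed_fraction(len(tgt_wells)),
            volumes.plasma_volume_ml,
        )

    pct: dict[str, float | None] = {}
    alb = quants.get(reference)
    for tgt, q in quants.items():
        if tgt == reference:
            continue
        pct[tgt] = percent_methylated(q, alb) if alb is not None else None

    return SampleMeasurement(
        sample_id=sample_id,
        quants=quants,
        percent_methylated=pct,
        copies_per_ml_plasma=plasma,
        n_wells=n_wells,
        volumes=volumes,
        reference=reference,
    )


def quantify_table(
    droplets: pd.DataFrame,
    reference: str = "ALB",
    volumes: VolumeConfig | None = None,
) -> tuple[dict[str, SampleMeasurement], pd.DataFrame]:
    """Quantify every sample in a droplet table.

    Returns the per-sample measurements and a tidy long-format table with one
    row per sample × target.
    """
    from .io import wells_from_table  # local import to avoid a cycle

    measurements: dict[str, SampleMeasurement] = {}
    for sample_id, group in droplets.groupby("sample_id", sort=True):
        measurements[str(sample_id)] = quantify_sample(
            wells_from_table(group), reference=reference, volumes=volumes
        )

    rows = []
    for sid, m in measurements.items():
        for tgt, q in m.quants.items():
            rows.append({
                "sample_id": sid,
                "target": tgt,
                "n_positive": q.n_positive_merged,
                "n_total": q.n_total_merged,
                "lambda_hat": q.lambda_hat,
                "copies_per_ul": q.copies_per_ul,
                "ci_low": q.ci_low,
                "ci_high": q.ci_high,
                "saturated": q.saturated,
                "percent_methylated": m.percent_methylated.get(tgt, np.nan)
                if tgt != m.reference else np.nan,
                "copies_per_ml_plasma": m.copies_per_ml_plasma[tgt],
            })
    return measurements, pd.DataFrame(rows)
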