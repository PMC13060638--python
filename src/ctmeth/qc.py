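"""Preanalytical quality control of plasma cfDNA samples.

Four ddPCR QC assays are evaluated per sample before methylation analysis:

* **CPP1 recovery** — an exogenous spike-in (~36,000 copies added to the
  plasma before extraction); the recovered fraction measures isolation
  efficiency.
* **PBC contamination** — a B-cell-specific rearranged IGH assay; a high
  PBC/cfDNA ratio indicates lymphocyte genomic DNA leaking into plasma.
* **EMC7 long/short ratio** — 250 bp vs 65 bp fragments of EMC7; cfDNA is
  short, so an elevated ratio flags high-molecular-weight contamination.
* **Total cfDNA** — the EMC7 short fragment scaled to copies per mL plasma.

Flags are advisory: they never exclude a sample by themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ddpcr import ValidationError, VolumeConfig, quantify_sample
from .io import wells_from_table

__all__ = [
    "QCConfig",
    "QCReport",
    "cpp1_recovery",
    "pbc_contamination",
    "emc7_fragment_ratio",
    "qc_report",
    "qc_table",
]

QC_TARGETS = ("CPP1", "PBC", "EMC7_short", "EMC7_long")

LOW_RECOVERY = "LOW_RECOVERY"
LYMPHOCYTE_CONTAMINATION = "LYMPHOCYTE_CONTAMINATION"
HMW_CONTAMINATION = "HMW_CONTAMINATION"


@dataclass(frozen=True)
class QCConfig:
    """Thresholds and volumes for the QC multiplex (single well per sample).

    ``low_recovery_threshold`` (0.42) is the lowest recovery observed in
    practice on passing samples; ``emc7_ratio_threshold`` (0.35) separates the
    contaminated outlier regime (~0.5) from the bulk (≤ 0.347). Both are
    advisory conventions, not assay constants. The PBC threshold (2%) is the
    established lymphocyte-contamination cutoff.
    """

    spiked_cpp1_copies: float = 36_000.0
    low_recovery_threshold: float = 0.42
    pbc_threshold_pct: float = 2.0
    emc7_ratio_threshold: float = 0.35
    volumes: VolumeConfig = field(default_factory=lambda: VolumeConfig(
        template_volume_ul=5.0, eluate_volume_ul=200.0))


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    cpp1_recovery_fraction: float
    pbc_cfdna_ratio_pct: float
    emc7_long_short_ratio: float
    total_cfdna_copies_per_ml: float
    flags: frozenset[str]


def cpp1_recovery(recovered_copies: float, spiked_copies: float,
                  threshold: float = 0.42) -> tuple[float, bool]:
    """Recovered fraction of the CPP1 spike-in; flagged when below threshold."""
    if spiked_copies <= 0:
        raise ValidationError("spiked_copies must be positive")
    if recovered_copies < 0:
        raise ValidationError("recovered_copies cannot be negative")
    frac = recovered_copies / spiked_copies
    return frac, frac < threshold


def pbc_contamination(pbc_copies: float, cfdna_copies: float,
                      threshold_pct: float = 2.0) -> tuple[float, bool]:
    """PBC/cfDNA ratio in percent; flagged strictly above the threshold."""
    if cfdna_copies <= 0:
        raise ValidationError("cfdna_copies must be positive")
    if pbc_copies < 0:
        raise ValidationError("pbc_copies cannot be negative")
    ratio = 100.0 * pbc_copies / cfdna_copies
    return ratio, ratio > threshold_pct


def emc7_fragment_ratio(long_copies: float, short_copies: float,
                        threshold: float = 0.35) -> tuple[float, bool]:
    """EMC7 250 bp / 65 bp copy ratio; flagged strictly above the threshold."""
    if short_copies <= 0:
        raise ValidationError("short_copies must be positive")
    if long_copies < 0:
        raise ValidationError("long_copies cannot be negative")
    ratio = long_copies / short_copies
    return ratio, ratio > threshold


def qc_report(sample_id: str, copies: dict[str, float], config: QCConfig | None = None,
              total_cfdna_copies_per_ml: float | None = None) -> QCReport:
    """Assemble a QC report from per-target copy numbers.

    ``copies`` maps the four QC targets to recovered copies on a common scale
    (whole-sample copies for CPP1 vs the spike-in; any consistent scale for
    the ratio metrics).
    """
    config = config or QCConfig()
    missing = [t for t in QC_TARGETS if t not in copies]
    if missing:
        raise ValidationError(f"QC copies missing targets {missing}")

    rec, low = cpp1_recovery(copies["CPP1"], config.spiked_cpp1_copies,
                             config.low_recovery_threshold)
    pbc, lymph = pbc_contamination(copies["PBC"], copies["EMC7_short"],
                                   config.pbc_threshold_pct)
    emc7, hmw = emc7_fragment_ratio(copies["EMC7_long"], copies["EMC7_short"],
                                    config.emc7_ratio_threshold)
    flags = set()
    if low:
        flags.add(LOW_RECOVERY)
    if lymph:
        flags.add(LYMPHOCYTE_CONTAMINATION)
    if hmw:
        flags.add(HMW_CONTAMINATION)
    return QCReport(
        sample_id=sample_id,
        cpp1_recovery_fraction=rec,
        pbc_cfdna_ratio_pct=pbc,
        emc7_long_short_ratio=emc7,
        total_cfdna_copies_per_ml=(
            total_cfdna_copies_per_ml if total_cfdna_copies_per_ml is not None
            else copies["EMC7_short"] / config.volumes.plasma_volume_ml),
        flags=frozenset(flags),
    )


def qc_table(droplets: pd.DataFrame, config: QCConfig | None = None) -> pd.DataFrame:
    """QC reports for every sample in a QC droplet table.

    The table uses the standard droplet schema with targets CPP1, PBC,
    EMC7_short and EMC7_long; copies are scaled to whole-sample copies via
    the configured QC volume chain, so the CPP1 recovered fraction is
    directly comparable to the spiked amount.
    """
    config = config or QCConfig()
    vols = config.volumes
    rows = []
    for sample_id, grp in droplets.groupby("sample_id", sort=True):
        m = quantify_sample(wells_from_table(grp), reference="__none__", volumes=vols)
        copies = {}
        for tgt in QC_TARGETS:
            if tgt not in m.quants:
                raise ValidationError(f"sample {sample_id}: QC table lacks target {tgt}")
            # copies in the whole plasma-equivalent sample
            copies[tgt] = (m.copies_per_ml_plasma[tgt] * vols.plasma_volume_ml)
        rep = qc_report(
            str(sample_id), copies, config,
            total_cfdna_copies_per_ml=m.copies_per_ml_plasma["EMC7_short"],
        )
        rows.append({
            "sample_id": rep.sample_id,
            "cpp1_recovery_fraction": rep.cpp1_recovery_fraction,
            "pbc_cfdna_ratio_pct": rep.pbc_cfdna_ratio_pct,
            "emc7_long_short_ratio": rep.emc7_long_short_ratio,
            "total_cfdna_copies_per_ml": rep.total_cfdna_copies_per_ml,
            "flags": ";".join(sorted(rep.flags)),
        })
    return pd.DataFrame(rows)
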