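"""Reading and writing the delimited-text tables the pipeline exchanges.

All tables are plain CSV/TSV with headers (delimiter sniffed from the file
extension: ``.tsv``/``.txt`` → tab, otherwise comma). Schemas:

* droplet table: sample_id, well_id, target, n_positive, n_total
* sample sheet:  sample_id plus free metadata columns (group, patient_id,
  timepoint, cohort, ...)
* beta matrix:   probe IDs in the first column, one column per sample
* group sheet:   sample_id, group (COLON/REST)
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .ddpcr import DropletWell, ValidationError

DROPLET_COLUMNS = ["sample_id", "well_id", "target", "n_positive", "n_total"]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_droplet_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype={"sample_id": str, "well_id": str})
    missing = [c for c in DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"droplet table {path} is missing columns {missing}")
    df["n_positive"] = df["n_positive"].astype(int)
    df["n_total"] = df["n_total"].astype(int)
    bad = df[(df.n_positive < 0) | (df.n_total <= 0) | (df.n_positive > df.n_total)]
    if len(bad):
        raise ValidationError(
            f"droplet table {path}: invalid counts for samples {sorted(bad.sample_id.unique())}"
        )
    return df


def wells_from_table(df: pd.DataFrame) -> list[DropletWell]:
    return [
        DropletWell(
            sample_id=str(r.sample_id),
            well_id=str(r.well_id),
            target=str(r.target),
            n_positive=int(r.n_positive),
            n_total=int(r.n_total),
        )
        for r in df.itertuples()
    ]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"sample sheet {path} needs a sample_id column")
    return df


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Beta matrix: probes in rows (cg IDs in the first column), samples in
    columns. Tolerates a manifest-style first column named anything."""
    df = pd.read_csv(path, sep=_sep(path))
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    return df.astype(float)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index=False)
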