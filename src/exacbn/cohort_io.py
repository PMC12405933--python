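"""Cohort CSV round-trip.

Missing cells are encoded as empty fields — and *only* empty fields.  The
default pandas NA sentinels must not apply, because the chronic-rhinosinusitis
level is literally labelled ``None`` and would silently vanish on re-read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_cohort_csv", "write_cohort_csv"]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="")
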