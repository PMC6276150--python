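"""Cohort table schema and CSV round-trip.

A cohort table holds one row per subject:

====================  =====================================================
``subject_id``        integer identifier
``entry_age``         age at recruitment, years
``exit_age``          age at first event or censoring, years (> entry_age)
``event``             one of ``er_pos``, ``er_neg``, ``unknown_er``,
                      ``competing``, ``censored``
risk factors          categorical codes / floats per :mod:`erisk.coding`
``country``           stratum label (optional)
``external_risk``     externally supplied 5-year risk score (optional)
====================  =====================================================
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coding import DEFAULT_COVARIATES, EVENT_CODES

CORE_COLUMNS = ("subject_id", "entry_age", "exit_age", "event")

_CATEGORICAL_COLUMNS = tuple(
    c.name for c in DEFAULT_COVARIATES if c.kind == "categorical"
) + ("country",)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    dtypes = {c: "str" for c in _CATEGORICAL_COLUMNS}
    df = pd.read_csv(path, dtype=dtypes)
    for c in _CATEGORICAL_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(object).where(df[c].notna(), np.nan)
    return df


def validate_cohort(df: pd.DataFrame, *, with_events: bool = True) -> None:
    """Raise on schema violations; silently accept a valid table."""
    missing = [c for c in ("subject_id", "entry_age") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    if with_events:
        if "exit_age" not in df.columns or "event" not in df.columns:
            raise ValueError("cohort table lacks exit_age/event columns")
        bad = set(pd.unique(df["event"])) - set(EVENT_CODES)
        if bad:
            raise ValueError(f"unknown event codes {sorted(bad)!r}")
        if not (df["exit_age"].to_numpy() > df["entry_age"].to_numpy()).all():
            raise ValueError("exit_age must exceed entry_age for every subject")
    for cov in DEFAULT_COVARIATES:
        if cov.applicable_if is None or cov.name not in df.columns:
            continue
        parent, values = cov.applicable_if
        if parent not in df.columns:
            continue
        inapplicable = ~df[parent].isin(list(values))
        if df.loc[inapplicable, cov.name].notna().any():
            raise ValueError(
                f"{cov.name!r} has values on rows where {parent!r} makes it not applicable"
            )
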