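"""Covariate codings and event vocabulary shared across the pipeline.

Every stage (cohort generation, hazard fitting, risk projection) must agree
on how each epidemiological risk factor is categorised and which contrasts
enter the linear predictor.  A :class:`Covariate` records that coding once:
the category list (reference level first), structural applicability (e.g.
age at menopause exists only for postmenopausal women), and for continuous
variables the centring and scale used in the linear predictor (body height
enters per 10-cm increment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Closed event vocabulary for cohort tables.
EVENT_ER_POS = "er_pos"
EVENT_ER_NEG = "er_neg"
EVENT_UNKNOWN_ER = "unknown_er"
EVENT_COMPETING = "competing"
EVENT_CENSORED = "censored"
EVENT_CODES = (EVENT_ER_POS, EVENT_ER_NEG, EVENT_UNKNOWN_ER, EVENT_COMPETING, EVENT_CENSORED)

#: tumour causes modelled cause-specifically (mutually competing)
CAUSES = (EVENT_ER_POS, EVENT_ER_NEG)

#: events pooled into the Gompertz competing-event channel: tumours of
#: unknown receptor status, other primaries and non-cancer deaths.
COMPETING_EVENTS = (EVENT_COMPETING, EVENT_UNKNOWN_ER)


@dataclass(frozen=True)
class Covariate:
    """Coding of one risk factor.

    Parameters
    ----------
    name:
        Column name in the cohort table.
    kind:
        ``"categorical"`` or ``"continuous"``.
    categories:
        Category labels, reference level first (categorical only).
    applicable_if:
        ``(parent_name, allowed_values)`` — the variable is structurally
        defined only on rows where the parent takes one of those values;
        elsewhere it is stored as NA and contributes zero to the linear
        predictor (it is *not* treated as missing data).
    center, scale:
        Continuous variables enter the linear predictor as
        ``(value - center) / scale``.
    """

    name: str
    kind: str = "categorical"
    categories: tuple = ()
    applicable_if: tuple | None = None
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and len(self.categories) < 2:
            raise ValueError(f"categorical covariate {self.name!r} needs >= 2 categories")

    @property
    def contrast_levels(self) -> tuple:
        """Non-reference categories, one design column each."""
        return tuple(self.categories[1:]) if self.kind == "categorical" else ()

    def n_columns(self) -> int:
        return len(self.contrast_levels) if self.kind == "categorical" else 1

    def applicability_mask(self, df: pd.DataFrame) -> np.ndarray:
        """Boolean mask of rows where the variable is structurally defined."""
        if self.applicable_if is None:
            return np.ones(len(df), dtype=bool)
        parent, values = self.applicable_if
        return df[parent].isin(list(values)).to_numpy()

    def design_block(self, df: pd.DataFrame, *, strict: bool = True) -> np.ndarray:
        """Design columns for this covariate (n_rows x n_columns).

        Structurally not-applicable rows contribute zeros.  With
        ``strict=True`` a NaN on an applicable row (genuinely missing data)
        raises, since hazard models must be fitted on completed data.
        """
        n = len(df)
        applicable = self.applicability_mask(df)
        col = df[self.name]
        if self.kind == "continuous":
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            missing = applicable & ~np.isfinite(vals)
            if strict and missing.any():
                raise ValueError(
                    f"covariate {self.name!r} has {int(missing.sum())} missing values "
                    "on applicable rows; impute before fitting"
                )
            out = (vals - self.center) / self.scale
            out[~np.isfinite(out)] = 0.0
            out[~applicable] = 0.0
            return out[:, None]
        vals = col.astype(object).to_numpy()
        isna = pd.isna(vals)
        if strict and (applicable & isna).any():
            raise ValueError(
                f"covariate {self.name!r} has missing values on applicable rows; "
                "impute before fitting"
            )
        known = set(self.categories)
        bad = [v for v in pd.unique(vals[~isna]) if v not in known]
        if bad:
            raise ValueError(f"covariate {self.name!r}: unseen categories {bad!r}")
        out = np.zeros((n, len(self.contrast_levels)))
        for j, level in enumerate(self.contrast_levels):
            out[:, j] = (vals == level) & applicable & ~isna
        return out

    def column_names(self) -> list[str]:
        if self.kind == "continuous":
            return [self.name]
        return [f"{self.name}={level}" for level in self.contrast_levels]


# ---------------------------------------------------------------------------
# Default codings: the risk-factor set of the ER-specific models
# ---------------------------------------------------------------------------

MENOPAUSE = Covariate("menopausal_status", categories=("pre", "post"))
# Defined only for postmenopausal women; reference <= 45 years, so the plain
# postmenopausal contrast corresponds to menopause at or before 45.
AGE_MENOPAUSE = Covariate(
    "age_menopause",
    categories=("le45", "m45_50", "m50_55", "gt55"),
    applicable_if=("menopausal_status", ("post",)),
)
AGE_MENARCHE = Covariate("age_menarche", categories=("le11", "y12", "y13", "y14", "ge15"))
HRT_YEARS = Covariate("hrt_years", categories=("none", "y0_1", "y1_2", "y2_3", "gt3"))
BMI = Covariate("bmi", categories=("lt25", "b25_30", "b30_35", "ge35"))
# BMI x menopausal-status interaction, coded 0-3: 0 premenopausal or
# postmenopausal with BMI < 25; 1/2/3 postmenopausal with BMI 25-29.9 /
# 30-34.9 / >= 35.  Derived deterministically from bmi and menopausal_status.
BMI_MENOPAUSE = Covariate("bmi_menopause", categories=("0", "1", "2", "3"))
ALCOHOL = Covariate("alcohol", categories=("none", "lt1", "d1_2", "ge2"))
PAROUS = Covariate("parous", categories=("no", "yes"))
N_FTP = Covariate(
    "n_ftp", categories=("1", "2", "ge3"), applicable_if=("parous", ("yes",))
)
AGE_FIRST_FTP = Covariate(
    "age_first_ftp",
    categories=("le20", "a20_25", "a25_30", "a30_35", "gt35"),
    applicable_if=("parous", ("yes",)),
)
BREASTFEEDING = Covariate(
    "breastfeeding",
    categories=("none", "m0_6", "m6_12", "gt12"),
    applicable_if=("parous", ("yes",)),
)
HEIGHT = Covariate("height_cm", kind="continuous", center=160.0, scale=10.0)

DEFAULT_COVARIATES: tuple[Covariate, ...] = (
    MENOPAUSE,
    AGE_MENOPAUSE,
    AGE_MENARCHE,
    HRT_YEARS,
    BMI,
    BMI_MENOPAUSE,
    ALCOHOL,
    PAROUS,
    N_FTP,
    AGE_FIRST_FTP,
    BREASTFEEDING,
    HEIGHT,
)


def derive_bmi_menopause(df: pd.DataFrame) -> pd.Series:
    """Derive the 0-3 BMI x menopause interaction code from its parents."""
    code = np.zeros(len(df), dtype=object)
    post = (df["menopausal_status"] == "post").to_numpy()
    bmi = df["bmi"].astype(object).to_numpy()
    code[:] = "0"
    code[post & (bmi == "b25_30")] = "1"
    code[post & (bmi == "b30_35")] = "2"
    code[post & (bmi == "ge35")] = "3"
    return pd.Series(code, index=df.index, name="bmi_menopause")
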