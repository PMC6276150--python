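"""Multiple imputation by chained equations and Rubin pooling.

Missing risk-factor values are completed ``m`` times by cycling variable-
by-variable conditional draws: multinomial-logistic models for categorical
variables and normal-linear models for continuous ones, each conditioning
on all other risk factors, the tumour-event indicator and log follow-up
time.  Tables start from a random hot-deck fill and are cycled a fixed
number of sweeps.  Structural non-applicability (age at menopause for a
premenopausal woman, parity detail for a nulliparous one) is a valid
state, not missing data: such cells are never imputed, and applicability
is re-evaluated whenever a parent variable is itself imputed.  Downstream
estimates from the ``m`` completed tables are combined by Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .coding import CAUSES, DEFAULT_COVARIATES, EVENT_UNKNOWN_ER, derive_bmi_menopause

#: imputation order: parents before structurally dependent children
_IMPUTE_ORDER = (
    "menopausal_status",
    "parous",
    "age_menarche",
    "hrt_years",
    "bmi",
    "alcohol",
    "height_cm",
    "age_menopause",
    "n_ftp",
    "age_first_ftp",
    "breastfeeding",
)
_DERIVED = ("bmi_menopause",)

_COV_BY_NAME = {c.name: c for c in DEFAULT_COVARIATES}


@dataclass
class ImputationSet:
    """``m`` completed cohort tables with their provenance."""

    tables: list[pd.DataFrame]
    seeds: list[int]
    sweeps: int

    @property
    def m(self) -> int:
        return len(self.tables)


@dataclass
class PooledEstimate:
    """Rubin-pooled estimate: total variance = within + (1 + 1/m) between."""

    mean: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total: np.ndarray
    df: np.ndarray
    m: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(np.atleast_2d(self.total)))


def _predictor_matrix(df: pd.DataFrame, exclude: str) -> np.ndarray:
    cols = [np.ones((len(df), 1))]
    for cov in DEFAULT_COVARIATES:
        if cov.name == exclude or cov.name in _DERIVED or cov.name not in df.columns:
            continue
        cols.append(cov.design_block(df, strict=False))
    if "event" in df.columns:
        tumour = df["event"].isin(list(CAUSES) + [EVENT_UNKNOWN_ER]).to_numpy(dtype=float)
        cols.append(tumour[:, None])
    if "exit_age" in df.columns:
        fu = df["exit_age"].to_numpy(dtype=float) - df["entry_age"].to_numpy(dtype=float)
        cols.append(np.log(np.clip(fu, 1e-6, None))[:, None])
    return np.hstack(cols)


def _draw_categorical(
    df: pd.DataFrame, name: str, observed: np.ndarray, fill: np.ndarray, rng
) -> np.ndarray:
    cov = _COV_BY_NAME[name]
    x = _predictor_matrix(df, exclude=name)
    y = df[name].astype(object).to_numpy()
    classes = [c for c in cov.categories if (y[observed] == c).any()]
    out = np.empty(int(fill.sum()), dtype=object)
    if len(classes) < 2:
        out[:] = classes[0] if classes else cov.categories[0]
        return out
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf = LogisticRegression(max_iter=200)
            clf.fit(x[observed], y[observed].astype(str))
        proba = clf.predict_proba(x[fill])
        cum = np.cumsum(proba, axis=1)
        u = rng.uniform(size=len(proba))
        pick = (u[:, None] > cum).sum(axis=1)
        out[:] = clf.classes_[np.minimum(pick, len(clf.classes_) - 1)]
    except Exception:  # non-convergent or degenerate fit: marginal fallback
        warnings.warn(
            f"conditional model for {name!r} failed; falling back to marginal draws",
            RuntimeWarning,
            stacklevel=2,
        )
        out[:] = rng.choice(y[observed], size=int(fill.sum()))
    return out


def _draw_continuous(
    df: pd.DataFrame, name: str, observed: np.ndarray, fill: np.ndarray, rng
) -> np.ndarray:
    x = _predictor_matrix(df, exclude=name)
    y = df[name].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x[observed], y[observed], rcond=None)
    resid = y[observed] - x[observed] @ beta
    sigma = float(np.sqrt((resid**2).sum() / max(len(resid) - x.shape[1], 1)))
    draws = x[fill] @ beta + rng.normal(scale=sigma, size=int(fill.sum()))
    # bounded epidemiological variables: truncate to the observed range
    return np.clip(draws, y[observed].min(), y[observed].max())


def impute_chained(
    cohort: pd.DataFrame,
    m: int = 5,
    sweeps: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equations multiple imputation of missing risk factors."""
    if m < 1:
        raise ValueError("m must be >= 1")
    variables = [
        v
        for v in _IMPUTE_ORDER
        if v in cohort.columns
        and bool((cohort[v].isna() & _COV_BY_NAME[v].applicability_mask(cohort)).any())
    ]
    for v in variables:
        if cohort[v].isna().all():
            raise ValueError(f"variable {v!r} is entirely missing and cannot be imputed")
    orig_missing = {v: cohort[v].isna().to_numpy() for v in variables}

    tables: list[pd.DataFrame] = []
    seeds: list[int] = []
    for j in range(m):
        rng = np.random.default_rng(seed + j)
        df = cohort.copy()
        if variables:
            for sweep in range(sweeps + 1):
                for v in variables:
                    cov = _COV_BY_NAME[v]
                    applicable = cov.applicability_mask(df)
                    df.loc[~applicable, v] = np.nan
                    observed = applicable & ~orig_missing[v] & df[v].notna().to_numpy()
                    fill = applicable & (orig_missing[v] | df[v].isna().to_numpy())
                    if not fill.any():
                        continue
                    if sweep == 0:  # random hot-deck initialisation
                        pool = df.loc[observed, v].to_numpy()
                        df.loc[fill, v] = rng.choice(pool, size=int(fill.sum()))
                    elif cov.kind == "continuous":
                        df.loc[fill, v] = _draw_continuous(df, v, observed, fill, rng)
                    else:
                        df.loc[fill, v] = _draw_categorical(df, v, observed, fill, rng)
                if "bmi_menopause" in df.columns:
                    df["bmi_menopause"] = derive_bmi_menopause(df)
        tables.append(df)
        seeds.append(seed + j)
    return ImputationSet(tables=tables, seeds=seeds, sweeps=sweeps)


def pool_rubin(
    estimates,
    variances=None,
    *,
    nu_complete: float = np.inf,
) -> PooledEstimate:
    """Combine per-imputation estimates by Rubin's rules.

    ``estimates`` is a sequence of coefficient vectors (or scalars);
    ``variances`` the matching covariance matrices (or scalar variances).
    Degrees of freedom follow Barnard-Rubin, reducing to the classic
    ``(m−1)(1 + 1/r)²`` when the complete-data df is infinite; with a
    single imputation (or identical estimates) the between component is
    zero by convention and df is infinite.
    """
    q = np.asarray(estimates, dtype=float)
    if q.ndim == 0:
        q = q[None, None]
    elif q.ndim == 1:  # one scalar estimate per imputation
        q = q[:, None]
    m, p = q.shape
    if variances is None:
        u = np.zeros((m, p, p))
    else:
        u = np.stack([np.atleast_2d(np.asarray(v, dtype=float)) for v in variances])
        if u.shape != (m, p, p):
            raise ValueError("variance matrices do not match the estimates")
    qbar = q.mean(axis=0)
    within = u.mean(axis=0)
    if m > 1:
        dev = q - qbar
        between = dev.T @ dev / (m - 1)
    else:
        between = np.zeros((p, p))
    total = within + (1.0 + 1.0 / m) * between

    w_d = np.diag(within)
    b_d = np.diag(between)
    t_d = np.diag(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * b_d / w_d
        nu_old = (m - 1) * (1.0 + 1.0 / r) ** 2
        if np.isinf(nu_complete):
            df = nu_old
        else:
            lam = (1.0 + 1.0 / m) * b_d / t_d
            nu_obs = (nu_complete + 1.0) / (nu_complete + 3.0) * nu_complete * (1.0 - lam)
            df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    df = np.where(b_d == 0, np.inf, df)
    df = np.where(w_d == 0, np.maximum(m - 1.0, 1.0), df)
    return PooledEstimate(
        mean=qbar, within=within, between=between, total=total, df=df, m=m
    )
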