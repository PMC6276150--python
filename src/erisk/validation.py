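"""Discrimination and calibration of projected 5-year risks.

Discrimination is a concordance (C) statistic over comparable pairs within
the projection window: a subject with the target tumour in the first
``horizon`` years should carry a higher predicted risk than any subject
still event-free (for that cause) and under observation at that time —
Harrell's C on follow-up truncated at the horizon, ties in risk scored
half.  Mean calibration is the expected-to-observed ratio E/O, with E the
sum of predicted risks and O the count of target events inside the window;
its confidence interval uses the log-scale Poisson approximation
``(E/O) exp(∓1.96/sqrt(O))``.  Calibration-in-the-small is tabulated by
risk deciles.  Internal validation is fivefold cross-validation with
pooled out-of-fold predictions; external validation combines source-model
coefficients with target-cohort baselines (see
:func:`erisk.absolute_risk.recalibrate_baseline`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index

from .absolute_risk import project_risks, recalibrate_baseline
from .coding import CAUSES
from .hazards import fit_gompertz, fit_piecewise, split_person_time
from .models import ModelSpec, PiecewiseHazardModel

_RISK_COLUMN = {"er_pos": "risk_er_pos", "er_neg": "risk_er_neg"}


def _window_outcome(cohort: pd.DataFrame, cause: str, horizon: float):
    time = cohort["exit_age"].to_numpy(dtype=float) - cohort["entry_age"].to_numpy(dtype=float)
    case = (cohort["event"].to_numpy() == cause) & (time <= horizon)
    return np.minimum(time, horizon), case


def cstatistic_5yr(
    risks: np.ndarray,
    cohort: pd.DataFrame,
    cause: str,
    *,
    horizon: float = 5.0,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Horizon-truncated Harrell C with a subject-level bootstrap CI."""
    risks = np.asarray(risks, dtype=float)
    t, case = _window_outcome(cohort, cause, horizon)
    if case.sum() == 0 or case.all():
        raise ValueError("no comparable case/control pairs within the horizon")
    c = float(concordance_index(t, -risks, case))
    if n_bootstrap <= 0:
        return c, (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(t), size=len(t))
        if case[idx].sum() == 0 or case[idx].all():
            continue
        reps.append(concordance_index(t[idx], -risks[idx], case[idx]))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return c, (float(lo), float(hi))


def expected_observed(
    risks: np.ndarray,
    cohort: pd.DataFrame,
    cause: str,
    *,
    horizon: float = 5.0,
    km_adjust: bool = False,
) -> tuple[float, tuple[float, float]]:
    """E/O ratio with the log-scale Poisson CI.

    By default O is the crude count of target events within the horizon
    (censoring-induced undercount ignored).  ``km_adjust=True`` instead
    scales up to the Aalen-Johansen cumulative incidence at the horizon,
    as a sensitivity analysis when within-window censoring is heavy.
    """
    risks = np.asarray(risks, dtype=float)
    e = float(risks.sum())
    t, case = _window_outcome(cohort, cause, horizon)
    o = float(case.sum())
    if o == 0:
        raise ValueError("no observed events of the target cause within the horizon")
    if km_adjust:
        from lifelines import AalenJohansenFitter

        time = cohort["exit_age"].to_numpy(dtype=float) - cohort["entry_age"].to_numpy(dtype=float)
        state = np.zeros(len(cohort), dtype=int)
        state[cohort["event"].to_numpy() == cause] = 1
        other = (~cohort["event"].isin([cause, "censored"])).to_numpy()
        state[other] = 2
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(time, state, event_of_interest=1)
        cif = float(
            np.interp(horizon, ajf.cumulative_density_.index.to_numpy(),
                      ajf.cumulative_density_.iloc[:, 0].to_numpy())
        )
        o = cif * len(cohort)
    ratio = e / o
    half = 1.96 / np.sqrt(o)
    return ratio, (float(ratio * np.exp(-half)), float(ratio * np.exp(half)))


def calibration_deciles(
    risks: np.ndarray,
    cohort: pd.DataFrame,
    cause: str,
    *,
    horizon: float = 5.0,
    n_groups: int = 10,
) -> pd.DataFrame:
    """Mean predicted vs observed event proportion by predicted-risk decile."""
    risks = np.asarray(risks, dtype=float)
    if len(risks) < n_groups:
        raise ValueError("need at least one subject per decile")
    _, case = _window_outcome(cohort, cause, horizon)
    order = np.argsort(risks, kind="stable")
    rows = []
    for g, idx in enumerate(np.array_split(order, n_groups)):
        rows.append(
            {
                "decile": g + 1,
                "n": len(idx),
                "risk_lo": float(risks[idx].min()),
                "risk_hi": float(risks[idx].max()),
                "mean_predicted": float(risks[idx].mean()),
                "observed": float(case[idx].mean()),
                "n_events": int(case[idx].sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CauseValidation:
    cause: str
    c_statistic: float
    c_ci: tuple[float, float]
    e_over_o: float
    eo_ci: tuple[float, float]
    deciles: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "cause": self.cause,
            "c_statistic": self.c_statistic,
            "c_ci": list(self.c_ci),
            "e_over_o": self.e_over_o,
            "eo_ci": list(self.eo_ci),
            "deciles": self.deciles.to_dict(orient="records"),
        }


@dataclass
class ValidationReport:
    overall: dict[str, CauseValidation]
    by_menopause: dict[str, dict[str, dict]] = field(default_factory=dict)
    oof_risks: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "overall": {k: v.to_dict() for k, v in self.overall.items()},
            "by_menopause": self.by_menopause,
        }


def _evaluate(
    risk_df: pd.DataFrame,
    cohort: pd.DataFrame,
    *,
    horizon: float,
    seed: int,
    n_bootstrap: int,
    rank_risks: pd.DataFrame | None = None,
) -> ValidationReport:
    rank_risks = rank_risks if rank_risks is not None else risk_df
    overall: dict[str, CauseValidation] = {}
    by_meno: dict[str, dict[str, dict]] = {}
    for cause in CAUSES:
        col = _RISK_COLUMN[cause]
        c, c_ci = cstatistic_5yr(
            rank_risks[col].to_numpy(), cohort, cause,
            horizon=horizon, n_bootstrap=n_bootstrap, seed=seed,
        )
        eo, eo_ci = expected_observed(risk_df[col].to_numpy(), cohort, cause, horizon=horizon)
        dec = calibration_deciles(risk_df[col].to_numpy(), cohort, cause, horizon=horizon)
        overall[cause] = CauseValidation(cause, c, c_ci, eo, eo_ci, dec)
        sub: dict[str, dict] = {}
        for status in ("pre", "post"):
            mask = (cohort["menopausal_status"] == status).to_numpy()
            if mask.sum() == 0:
                continue
            try:
                c_s, _ = cstatistic_5yr(
                    rank_risks[col].to_numpy()[mask], cohort[mask], cause,
                    horizon=horizon, n_bootstrap=0, seed=seed,
                )
                eo_s, _ = expected_observed(
                    risk_df[col].to_numpy()[mask], cohort[mask], cause, horizon=horizon
                )
                sub[status] = {"c_statistic": c_s, "e_over_o": eo_s}
            except ValueError:
                continue
        by_meno[cause] = sub
    return ValidationReport(overall=overall, by_menopause=by_meno, oof_risks=risk_df)


def crossvalidate_5fold(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    *,
    horizon: float = 5.0,
    n_folds: int = 5,
    eliminate_stratum: bool = False,
    n_bootstrap: int = 200,
) -> ValidationReport:
    """Internal validation: seeded folds, pooled out-of-fold predictions.

    With ``eliminate_stratum=True`` the risk used for *ranking* (the C
    statistic) is recomputed with stratum coefficients zeroed, assessing
    discrimination net of between-country baseline differences; E/O and
    the decile table keep the full predictions.
    """
    n = len(cohort)
    events = cohort["event"].to_numpy()

    def make_folds(s: int) -> np.ndarray:
        perm = np.random.default_rng(s).permutation(n)
        fold = np.empty(n, dtype=int)
        fold[perm] = np.arange(n) % n_folds
        return fold

    fold = make_folds(seed)
    for attempt in range(2):
        ok = all(
            ((events == c) & (fold == k)).any() for c in CAUSES for k in range(n_folds)
        )
        if ok:
            break
        if attempt == 1:
            raise ValueError("a fold has no events of some tumour cause after re-randomising")
        fold = make_folds(seed + 1)

    oof = pd.DataFrame(index=np.arange(n), columns=["risk_er_pos", "risk_er_neg"], dtype=float)
    oof_rank = oof.copy()
    for k in range(n_folds):
        train = cohort[fold != k]
        test = cohort[fold == k]
        model = fit_piecewise(split_person_time(train, spec.cutoffs), spec)
        gomp = fit_gompertz(train)
        proj = project_risks(model, gomp, test, horizon=horizon)
        oof.loc[fold == k, ["risk_er_pos", "risk_er_neg"]] = proj[
            ["risk_er_pos", "risk_er_neg"]
        ].to_numpy()
        if eliminate_stratum:
            proj_ns = project_risks(model, gomp, test, horizon=horizon, include_stratum=False)
            oof_rank.loc[fold == k, ["risk_er_pos", "risk_er_neg"]] = proj_ns[
                ["risk_er_pos", "risk_er_neg"]
            ].to_numpy()
    assert not oof["risk_er_pos"].isna().any()
    report = _evaluate(
        oof,
        cohort,
        horizon=horizon,
        seed=seed,
        n_bootstrap=n_bootstrap,
        rank_risks=oof_rank if eliminate_stratum else None,
    )
    report.oof_risks = oof.assign(fold=fold, subject_id=cohort["subject_id"].to_numpy())
    return report


def external_validation(
    source: PiecewiseHazardModel,
    target: pd.DataFrame,
    seed: int = 0,
    *,
    horizon: float = 5.0,
    n_bootstrap: int = 200,
) -> ValidationReport:
    """External validation: source coefficients, target baseline hazards.

    Tumour baselines are recalibrated on the target cohort with the source
    coefficients frozen, and the competing-event Gompertz model is refitted
    on the target; risks are then projected from each target subject's
    entry age.
    """
    recal = recalibrate_baseline(source, target)
    gomp = fit_gompertz(target)
    proj = project_risks(recal, gomp, target, horizon=horizon)
    return _evaluate(
        proj[["risk_er_pos", "risk_er_neg"]],
        target,
        horizon=horizon,
        seed=seed,
        n_bootstrap=n_bootstrap,
    )
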