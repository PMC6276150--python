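"""Absolute (cumulative-incidence) risk under competing risks.

The probability of a first ER+ tumour in ``[a, a+h)`` for a woman with
covariates ``x`` is the cause-specific cumulative incidence

    P_k(a, h) = integral over [a, a+h) of h_k(t) S(a, t) dt,

where ``h_k`` is the cause-k hazard and ``S(a, t)`` the probability of
remaining free of *all* modelled first events (ER+ tumour, ER− tumour,
pooled competing event) from ``a`` to ``t``.  The integral is evaluated by
partitioning ``[a, a+h)`` at the age-band cutoffs.  Within a segment the
tumour hazards are constant and the Gompertz competing hazard has an exact
integral, so all-cause survival is updated in closed form.  Tumour-cause
increments use the constant-hazard closed form when no age-varying
competing hazard is present, and fixed-order Gauss-Legendre quadrature of
the (smooth) integrand against the exact survival otherwise; the
competing-cause increment is the remainder of total event mass, which
makes the identity  sum of cause risks + survival = 1  hold to rounding.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .coding import EVENT_ER_NEG, EVENT_ER_POS
from .hazards import LOG_HAZARD_FLOOR, split_person_time
from .models import GompertzModel, ModelSpec, PiecewiseHazardModel

_GL_ORDER = 24
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_GL_ORDER)


def _segment_points(a: np.ndarray, h: float, cutoffs: np.ndarray) -> np.ndarray:
    """Per-row sorted partition of ``[a, a+h]`` at the cutoffs (m, n_cut+2).

    Cutoffs outside the window are clipped onto its ends, yielding
    zero-length segments that contribute nothing.
    """
    b = a + h
    pts = np.concatenate(
        [a[:, None], np.clip(cutoffs[None, :], a[:, None], b[:, None]), b[:, None]], axis=1
    )
    return np.sort(pts, axis=1)


def _project_chunk(
    a: np.ndarray,
    h: float,
    rate_pos: np.ndarray,
    rate_neg: np.ndarray,
    gompertz: GompertzModel | None,
    cutoffs: np.ndarray,
    band_of,
) -> dict[str, np.ndarray]:
    m = len(a)
    pts = _segment_points(a, h, cutoffs)
    surv = np.ones(m)
    inc_pos = np.zeros(m)
    inc_neg = np.zeros(m)
    inc_comp = np.zeros(m)
    use_quadrature = gompertz is not None and abs(gompertz.gamma) >= GompertzModel._GAMMA_EPS
    hg_const = 0.0 if gompertz is None else float(np.exp(gompertz.alpha))

    for j in range(pts.shape[1] - 1):
        u, v = pts[:, j], pts[:, j + 1]
        dt = v - u
        live = dt > 0
        if not live.any():
            continue
        band = band_of(u)
        rp = rate_pos[np.arange(m), band]
        rn = rate_neg[np.arange(m), band]
        lam = rp + rn
        if not use_quadrature:
            q = lam + hg_const
            with np.errstate(divide="ignore", invalid="ignore"):
                mass = surv * -np.expm1(-q * dt)
                frac_p = np.where(q > 0, rp / np.where(q > 0, q, 1.0), 0.0)
                frac_n = np.where(q > 0, rn / np.where(q > 0, q, 1.0), 0.0)
            dp = np.where(live, frac_p * mass, 0.0)
            dn = np.where(live, frac_n * mass, 0.0)
            s_new = surv * np.exp(-q * dt)
        else:
            dh_seg = gompertz.cumhaz(u, v)
            s_new = surv * np.exp(-lam * dt - dh_seg)
            # Gauss-Legendre on the exact integrand h_k(t) S(u, t)
            t_nodes = u[:, None] + dt[:, None] * (_GL_NODES[None, :] + 1.0) / 2.0
            s_inner = np.exp(
                -lam[:, None] * (t_nodes - u[:, None]) - gompertz.cumhaz(u[:, None], t_nodes)
            )
            quad = (dt / 2.0) * (s_inner @ _GL_WEIGHTS)
            dp = np.where(live, surv * rp * quad, 0.0)
            dn = np.where(live, surv * rn * quad, 0.0)
        total_mass = np.where(live, surv - s_new, 0.0)
        inc_pos += dp
        inc_neg += dn
        inc_comp += total_mass - dp - dn
        surv = np.where(live, s_new, surv)

    return {
        "risk_er_pos": inc_pos,
        "risk_er_neg": inc_neg,
        "risk_competing": inc_comp,
        "risk_any": 1.0 - surv,
        "survival": surv,
    }


def project_risks(
    piecewise: PiecewiseHazardModel,
    gompertz: GompertzModel | None,
    cohort: pd.DataFrame,
    *,
    start_age: np.ndarray | None = None,
    horizon: float = 5.0,
    include_stratum: bool = True,
    chunk: int = 20_000,
) -> pd.DataFrame:
    """Project cause-specific absolute risks over ``[start, start+horizon)``.

    ``start_age`` defaults to each subject's entry age.  Returns one row per
    subject with per-cause risks, the all-cause event probability and the
    survival probability; the three cause risks and survival sum to one.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    spec = piecewise.spec
    cutoffs = np.asarray(spec.cutoffs, dtype=float)
    a = (
        cohort["entry_age"].to_numpy(dtype=float)
        if start_age is None
        else np.broadcast_to(np.asarray(start_age, dtype=float), (len(cohort),)).copy()
    )
    lp_pos = piecewise.linear_predictor(cohort, EVENT_ER_POS, include_stratum=include_stratum)
    lp_neg = piecewise.linear_predictor(cohort, EVENT_ER_NEG, include_stratum=include_stratum)
    base_pos = piecewise.baseline_hazard(EVENT_ER_POS)
    base_neg = piecewise.baseline_hazard(EVENT_ER_NEG)

    out: dict[str, list[np.ndarray]] = {}
    for s in range(0, len(cohort), chunk):
        sl = slice(s, min(s + chunk, len(cohort)))
        rp = base_pos[None, :] * np.exp(lp_pos[sl])[:, None]
        rn = base_neg[None, :] * np.exp(lp_neg[sl])[:, None]
        res = _project_chunk(a[sl], horizon, rp, rn, gompertz, cutoffs, spec.band_index)
        for k, v in res.items():
            out.setdefault(k, []).append(v)

    result = pd.DataFrame({k: np.concatenate(v) for k, v in out.items()})
    result.insert(0, "horizon", horizon)
    result.insert(0, "start_age", a)
    if "subject_id" in cohort.columns:
        result.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    return result


def cumulative_incidence(
    piecewise: PiecewiseHazardModel,
    gompertz: GompertzModel | None,
    x: pd.DataFrame | pd.Series | dict,
    a: float,
    h: float = 5.0,
) -> dict[str, float]:
    """Single-profile absolute risk; see :func:`project_risks`."""
    if isinstance(x, dict):
        x = pd.DataFrame([x])
    elif isinstance(x, pd.Series):
        x = x.to_frame().T
    row = project_risks(
        piecewise, gompertz, x, start_age=np.array([a]), horizon=h
    ).iloc[0]
    return {
        k: float(row[k])
        for k in ("risk_er_pos", "risk_er_neg", "risk_competing", "risk_any", "survival")
    }


# ---------------------------------------------------------------------------
# External baseline recalibration
# ---------------------------------------------------------------------------

def recalibrate_baseline(
    source: PiecewiseHazardModel,
    target: pd.DataFrame,
    *,
    drop_stratum: bool = True,
) -> PiecewiseHazardModel:
    """Re-estimate the per-band per-cause baselines on an external cohort.

    All covariate coefficients are frozen at the source fit; the baseline of
    each band-cause cell then has the closed-form MLE

        lambda = events in cell / sum of exposure * exp(beta' x).

    The returned model combines the source's relative risks with the target
    population's baseline hazards.  Stratum (country) coefficients of the
    source do not transfer to an external population and are dropped by
    default — the recalibrated baselines absorb the target's level.
    """
    spec = source.spec
    episodes = split_person_time(target, spec.cutoffs)
    band = episodes["band"].to_numpy()
    exposure = episodes["exposure"].to_numpy(dtype=float)
    event = episodes["event"].to_numpy()

    if drop_stratum and spec.stratum is not None:
        from dataclasses import replace

        new_spec = replace(spec, stratum=None)
    else:
        new_spec = spec

    params: dict[str, float] = {
        nm: v for nm, v in source.params.items() if not nm.startswith("base:")
    }
    if drop_stratum and spec.stratum is not None:
        stratum_cols = {f"{c}:{cn}" for c in spec.causes for cn in spec.stratum.column_names()}
        params = {nm: v for nm, v in params.items() if nm not in stratum_cols}

    n_empty = 0
    for cause in spec.causes:
        lp = source.linear_predictor(episodes, cause, include_stratum=not drop_stratum)
        w = exposure * np.exp(lp)
        for b in range(spec.n_bands):
            in_band = band == b
            d = float(((event == cause) & in_band).sum())
            denom = float(w[in_band].sum())
            if d > 0 and denom > 0:
                params[f"base:{cause}:{b}"] = float(np.log(d / denom))
            else:
                params[f"base:{cause}:{b}"] = LOG_HAZARD_FLOOR
                n_empty += 1
    if n_empty:
        warnings.warn(
            f"{n_empty} empty band-cause cells in the target cohort; baseline pinned "
            f"to log hazard {LOG_HAZARD_FLOOR}",
            RuntimeWarning,
            stacklevel=2,
        )
    return PiecewiseHazardModel(spec=new_spec, params=params)
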