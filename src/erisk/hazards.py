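"""Maximum-likelihood fitting of the cause-specific hazard models.

The piecewise-exponential model is fitted through its Poisson equivalence:
after splitting follow-up into age-band episodes, the log-likelihood

    sum over episodes and causes of  d * eta − T * exp(eta),
    eta = log(baseline hazard of the episode's band and cause) + beta' x

is exactly the piecewise-exponential likelihood.  ER+ and ER− tumours are
fitted *jointly* by stacking one replicate of the episode table per cause,
with cause-specific baseline strata; a covariate whose coefficient is
shared between causes contributes one design column spanning both
replicates, a heterogeneous covariate contributes one column per cause.
Realising the sharing constraint in the design matrix (rather than by
averaging two separate fits) is what makes the likelihood-ratio test for
heterogeneity valid.

Tumours of unknown receptor status never contribute ER-specific events:
they enter these fits as exposure only and are treated as events by the
pooled Gompertz competing-event fit, together with other primary cancers
and non-cancer deaths.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coding import COMPETING_EVENTS, EVENT_CENSORED
from .models import GompertzModel, ModelSpec, PiecewiseHazardModel

#: log-hazard floor for band-cause cells with no events
LOG_HAZARD_FLOOR = -30.0
GRAD_TOL = 1e-8
MAX_ITER = 200


# ---------------------------------------------------------------------------
# Episode splitting
# ---------------------------------------------------------------------------

def split_person_time(cohort: pd.DataFrame, cutoffs) -> pd.DataFrame:
    """Split each subject's follow-up ``[entry, exit)`` at the age cutoffs.

    Returns one row per subject x traversed band with the exposure time in
    that band; the subject's event code is attached to the final episode,
    earlier episodes carry ``censored``.  The first and last bands are
    open-ended, so any attainable age is covered.  Exposure is conserved:
    per subject it sums to ``exit − entry`` exactly up to float rounding.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if len(cutoffs) and not (np.diff(cutoffs) > 0).all():
        raise ValueError("cutoffs must be strictly increasing")
    entry = cohort["entry_age"].to_numpy(dtype=float)
    exit_ = cohort["exit_age"].to_numpy(dtype=float)
    if not (exit_ > entry).all():
        raise ValueError("exit_age must exceed entry_age")

    edges = np.concatenate([[-np.inf], cutoffs, [np.inf]])
    starts = np.maximum(edges[:-1][None, :], entry[:, None])
    ends = np.minimum(edges[1:][None, :], exit_[:, None])
    dur = ends - starts
    ii, bb = np.nonzero(dur > 0)  # row-major: episodes ordered by subject

    episodes = cohort.iloc[ii].reset_index(drop=True)
    episodes["band"] = bb
    episodes["age_start"] = starts[ii, bb]
    episodes["age_end"] = ends[ii, bb]
    episodes["exposure"] = dur[ii, bb]
    last = np.ones(len(ii), dtype=bool)
    last[:-1] = ii[:-1] != ii[1:]
    ev = np.full(len(ii), EVENT_CENSORED, dtype=object)
    ev[last] = cohort["event"].to_numpy()[ii[last]]
    episodes["event"] = ev
    return episodes


# ---------------------------------------------------------------------------
# Stacked design and Newton fit
# ---------------------------------------------------------------------------

def _stacked_design(episodes: pd.DataFrame, spec: ModelSpec):
    """Dense stacked design: one replicate of the episode table per cause."""
    n_ep = len(episodes)
    band = episodes["band"].to_numpy()
    names = spec.param_names()
    pos = {nm: j for j, nm in enumerate(names)}
    X = np.zeros((len(spec.causes) * n_ep, len(names)))
    y = np.zeros(len(spec.causes) * n_ep)
    event = episodes["event"].to_numpy()

    blocks: dict[str, np.ndarray] = {}
    for ci, cause in enumerate(spec.causes):
        rows = slice(ci * n_ep, (ci + 1) * n_ep)
        for b in range(spec.n_bands):
            X[rows, pos[f"base:{cause}:{b}"]] = band == b
        for name, cov, j in spec.lp_terms(cause):
            if cov.name not in blocks:
                blocks[cov.name] = cov.design_block(episodes)
            X[rows, pos[name]] += blocks[cov.name][:, j]
        y[rows] = event == cause
    offset = np.tile(np.log(episodes["exposure"].to_numpy(dtype=float)), len(spec.causes))
    return X, y, offset, names


def _poisson_newton(X, y, offset, beta0):
    """Newton-Raphson for the Poisson log-likelihood with offset."""
    beta = beta0.copy()
    eta = X @ beta + offset
    mu = np.exp(eta)
    ll = float(y @ eta - mu.sum())
    for _ in range(MAX_ITER):
        resid = y - mu
        grad = X.T @ resid
        if np.abs(grad).max() <= GRAD_TOL:
            break
        H = _weighted_gram(X, mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"singular information matrix in Newton step: {err}") from err
        # step halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            eta_c = X @ cand + offset
            with np.errstate(over="ignore"):
                mu_c = np.exp(eta_c)
            ll_c = float(y @ eta_c - mu_c.sum())
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                beta, eta, mu, ll = cand, eta_c, mu_c, ll_c
                break
            scale *= 0.5
        else:
            raise RuntimeError("step halving failed to improve the likelihood")
    else:
        raise RuntimeError(
            f"Newton did not reach gradient norm {GRAD_TOL} in {MAX_ITER} iterations "
            f"(final sup-norm {np.abs(X.T @ (y - np.exp(X @ beta + offset))).max():.3g})"
        )
    H = _weighted_gram(X, mu)
    return beta, ll, H


def _weighted_gram(X: np.ndarray, w: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """``X' diag(w) X`` accumulated in chunks to bound temporary memory."""
    p = X.shape[1]
    H = np.zeros((p, p))
    for s in range(0, X.shape[0], chunk):
        Xi = X[s : s + chunk]
        H += Xi.T @ (Xi * w[s : s + chunk, None])
    return H


def fit_piecewise(episodes: pd.DataFrame, spec: ModelSpec) -> PiecewiseHazardModel:
    """Fit the joint cause-specific piecewise-exponential model by MLE.

    ``episodes`` is the output of :func:`split_person_time`.  Band-cause
    cells without any event have their baseline log hazard pinned to a
    floor of −30 (with a warning) instead of diverging to −infinity;
    design columns that are identically zero are likewise excluded.
    Convergence criterion: gradient sup-norm ≤ 1e-8.
    """
    X, y, offset, names = _stacked_design(episodes, spec)
    n_ep = len(episodes)
    event = episodes["event"].to_numpy()
    total_time = float(episodes["exposure"].sum())

    init = np.zeros(len(names))
    pinned: dict[str, float] = {}
    for ci, cause in enumerate(spec.causes):
        d_cause = float((event == cause).sum())
        if d_cause == 0:
            raise ValueError(f"no events of cause {cause!r}; cannot fit")
        for b in range(spec.n_bands):
            nm = f"base:{cause}:{b}"
            col = ci * n_ep + np.nonzero(episodes["band"].to_numpy() == b)[0]
            d_cell = float(y[col].sum()) if len(col) else 0.0
            if d_cell == 0.0:
                pinned[nm] = LOG_HAZARD_FLOOR
            else:
                init[names.index(nm)] = np.log(d_cause / total_time)
    if pinned:
        warnings.warn(
            f"{len(pinned)} band-cause cells without events; baseline pinned to "
            f"log hazard {LOG_HAZARD_FLOOR}",
            RuntimeWarning,
            stacklevel=2,
        )
    # identically-zero design columns (absent categories) cannot be estimated
    nonzero = np.abs(X).sum(axis=0) > 0
    for j, nm in enumerate(names):
        if not nonzero[j] and nm not in pinned:
            pinned[nm] = LOG_HAZARD_FLOOR if nm.startswith("base:") else 0.0

    free_idx = [j for j, nm in enumerate(names) if nm not in pinned]
    free_names = [names[j] for j in free_idx]
    pin_idx = [j for j, nm in enumerate(names) if nm in pinned]
    offset_adj = offset.copy()
    if pin_idx:
        offset_adj = offset_adj + X[:, pin_idx] @ np.array([pinned[names[j]] for j in pin_idx])
    Xf = X[:, free_idx]

    beta, ll, H = _poisson_newton(Xf, y, offset_adj, init[free_idx])

    cov_free = np.linalg.inv(H)
    cov = pd.DataFrame(0.0, index=names, columns=names)
    cov.loc[free_names, free_names] = cov_free
    params = {nm: float(v) for nm, v in zip(free_names, beta)}
    params.update({nm: float(v) for nm, v in pinned.items()})
    return PiecewiseHazardModel(spec=spec, params=params, loglik=ll, cov=cov)


# ---------------------------------------------------------------------------
# Gompertz competing-event model
# ---------------------------------------------------------------------------

def _gompertz_w(gamma: float, entry: np.ndarray, exit_: np.ndarray) -> float:
    """``sum (exp(g*t2) − exp(g*t1)) / g`` with the exponential limit at g=0."""
    if abs(gamma) < 1e-9:
        return float(np.sum(exit_ - entry))
    return float(np.sum(np.exp(gamma * exit_) - np.exp(gamma * entry)) / gamma)


def fit_gompertz(
    cohort: pd.DataFrame, *, gamma_bounds: tuple[float, float] = (-0.5, 0.5)
) -> GompertzModel:
    """MLE of the pooled competing-event Gompertz hazard, left-truncated at entry.

    Events are competing events and tumours of unknown receptor status;
    ER-specific tumours and administrative censoring are treated as
    censoring for this cause.  The slope is profiled out: for fixed gamma
    the intercept has the closed form ``exp(alpha) = D / W(gamma)``, and the
    one-dimensional profile likelihood is maximised numerically within
    ``gamma_bounds``.
    """
    entry = cohort["entry_age"].to_numpy(dtype=float)
    exit_ = cohort["exit_age"].to_numpy(dtype=float)
    delta = cohort["event"].isin(list(COMPETING_EVENTS)).to_numpy()
    d = int(delta.sum())
    if d == 0:
        raise ValueError("no competing events; cannot fit the Gompertz model")
    sum_t_events = float(exit_[delta].sum())

    def neg_profile(gamma: float) -> float:
        w = _gompertz_w(gamma, entry, exit_)
        return -(d * np.log(d / w) + gamma * sum_t_events - d)

    res = optimize.minimize_scalar(neg_profile, bounds=gamma_bounds, method="bounded")
    gamma = float(res.x)
    alpha = float(np.log(d / _gompertz_w(gamma, entry, exit_)))
    ll = -float(res.fun)

    def full_ll(a: float, g: float) -> float:
        return d * a + g * sum_t_events - np.exp(a) * _gompertz_w(g, entry, exit_)

    # observed information by central finite differences of the full likelihood
    ha, hg = 1e-5, 1e-6
    hess = np.empty((2, 2))
    hess[0, 0] = (full_ll(alpha + ha, gamma) - 2 * full_ll(alpha, gamma) + full_ll(alpha - ha, gamma)) / ha**2
    hess[1, 1] = (full_ll(alpha, gamma + hg) - 2 * full_ll(alpha, gamma) + full_ll(alpha, gamma - hg)) / hg**2
    hess[0, 1] = hess[1, 0] = (
        full_ll(alpha + ha, gamma + hg)
        - full_ll(alpha + ha, gamma - hg)
        - full_ll(alpha - ha, gamma + hg)
        + full_ll(alpha - ha, gamma - hg)
    ) / (4 * ha * hg)
    cov = np.linalg.inv(-hess)
    return GompertzModel(alpha=alpha, gamma=gamma, loglik=ll, cov=cov)


# ---------------------------------------------------------------------------
# Likelihood-ratio test for heterogeneity by ER status
# ---------------------------------------------------------------------------

def lrt_heterogeneity(
    free: PiecewiseHazardModel, constrained: PiecewiseHazardModel
) -> tuple[float, int, float]:
    """LRT of cross-cause coefficient equality: ``2 (ll_free − ll_constrained)``.

    ``constrained`` must be the same specification fitted on the same
    episodes with strictly more sharing; the degrees of freedom are the
    extra cause-specific coefficient copies released in the free model.
    """
    fs, cs = free.spec, constrained.spec
    if tuple(fs.cutoffs) != tuple(cs.cutoffs) or len(fs.covariates) != len(cs.covariates):
        raise ValueError("models are not nested: different cutoffs or covariates")
    df = 0
    for fcov, ccov in zip(fs.covariates, cs.covariates):
        if fcov.name != ccov.name:
            raise ValueError("models are not nested: covariate lists differ")
        f_sh, c_sh = fs.shared[fcov.name], cs.shared[ccov.name]
        if f_sh and not c_sh:
            raise ValueError(
                f"models are not nested: {fcov.name!r} is shared in the free model "
                "but cause-specific in the constrained one"
            )
        if c_sh and not f_sh:
            df += fcov.n_columns() * (len(fs.causes) - 1)
    if df < 1:
        raise ValueError("identical sharing patterns: nothing to test")
    if free.loglik is None or constrained.loglik is None:
        raise ValueError("both models must carry a maximised log-likelihood")
    stat = 2.0 * (free.loglik - constrained.loglik)
    if stat < -1e-6:
        raise RuntimeError(
            f"negative LRT statistic {stat:.3g}: one of the fits did not converge"
        )
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))
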