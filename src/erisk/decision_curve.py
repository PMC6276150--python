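"""Decision curve analysis: net benefit, threshold algebra, applicability area.

Treating a woman whose predicted risk is at least the threshold ``p_t``
yields the population net benefit

    NB(p_t) = TP/n − (FP/n) · p_t / (1 − p_t),

where TP and FP count treated subjects who do and do not develop the
outcome within the window.  The comparators are treat-all,
``NB_all = pi − (1 − pi) p_t/(1 − p_t)`` with ``pi`` the outcome
proportion, and treat-none at zero.  At the indifference threshold the
benefit B of treating a future case balances the harm H of treating a
never-case, ``p_t B = (1 − p_t) H``, so a threshold implies a
benefit-to-harm ratio ``B/H = (1 − p_t)/p_t``.  A model's clinical
applicability is the signed area between its net-benefit curve and the
upper envelope of the two extreme strategies, accumulated over the
threshold grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_GRID_STEP = 5e-4


def threshold_bh(p_t: float, *, rounded: bool = False) -> float:
    """Benefit-to-harm ratio implied by a risk threshold.

    ``rounded=True`` rounds to the nearest multiple of 5, the resolution at
    which such ratios are usually quoted.
    """
    if not 0.0 < p_t < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    ratio = (1.0 - p_t) / p_t
    return round_to_multiple(ratio, 5) if rounded else ratio


def bh_threshold(ratio: float) -> float:
    """Risk threshold implied by a benefit-to-harm ratio (inverse of above)."""
    if ratio <= 0:
        raise ValueError("benefit-to-harm ratio must be positive")
    return 1.0 / (1.0 + ratio)


def round_to_multiple(x: float, base: float = 5.0) -> float:
    return float(base * np.round(x / base))


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    event_proportion: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_all": self.nb_all,
                "nb_none": np.zeros_like(self.thresholds),
            }
        )


def net_benefit_curve(
    risks: np.ndarray,
    outcomes: np.ndarray,
    grid: np.ndarray | None = None,
    *,
    grid_step: float = DEFAULT_GRID_STEP,
) -> DecisionCurve:
    """Net benefit of treat-if-risk>=threshold across a threshold grid.

    The default grid runs in ``grid_step`` increments from ``grid_step`` up
    to the maximal risk estimate (the treat-none end); the treat-all
    strategy corresponds to the zero-threshold limit.
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes).astype(bool)
    if risks.shape != outcomes.shape:
        raise ValueError("risks and outcomes must align")
    if (risks < 0).any() or (risks > 1).any():
        raise ValueError("risks must lie in [0, 1]")
    n = len(risks)
    if grid is None:
        upper = max(float(risks.max()), grid_step)
        grid = np.arange(grid_step, upper + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    if (grid >= 1.0).any() or (grid <= 0.0).any():
        raise ValueError("thresholds must lie strictly between 0 and 1")
    if (np.diff(grid) <= 0).any():
        raise ValueError("threshold grid must be strictly increasing")

    order = np.argsort(risks)
    sorted_risks = risks[order]
    events_from = np.concatenate([np.cumsum(outcomes[order][::-1])[::-1], [0]])
    pi = float(outcomes.mean())
    # subjects treated at threshold t: risk >= t
    first = np.searchsorted(sorted_risks, grid, side="left")
    treated = n - first
    tp = events_from[first]
    fp = treated - tp
    odds = grid / (1.0 - grid)
    nb_model = tp / n - (fp / n) * odds
    nb_all = pi - (1.0 - pi) * odds
    return DecisionCurve(
        thresholds=grid, nb_model=nb_model, nb_all=nb_all, event_proportion=pi, n=n
    )


def applicability_area(curve: DecisionCurve) -> tuple[float, float, float]:
    """Signed area between the model curve and the extreme-strategy envelope.

    The envelope is ``max(NB_all, 0)``.  Trapezoidal integration of
    ``NB_model − envelope`` over the grid is split into its negative part
    (where the model underperforms the envelope), its positive part, and
    their sum — the total applicability.
    """
    t = curve.thresholds
    steps = np.diff(t)
    if len(steps) and (np.abs(steps - steps[0]) > 1e-9 * max(steps[0], 1e-12)).any():
        warnings.warn("non-uniform threshold grid; re-interpolating", RuntimeWarning, stacklevel=2)
        uniform = np.linspace(t[0], t[-1], max(len(t), 2))
        curve = DecisionCurve(
            thresholds=uniform,
            nb_model=np.interp(uniform, t, curve.nb_model),
            nb_all=np.interp(uniform, t, curve.nb_all),
            event_proportion=curve.event_proportion,
            n=curve.n,
        )
        t = uniform
    envelope = np.maximum(curve.nb_all, 0.0)
    excess = curve.nb_model - envelope
    area_below = float(np.trapezoid(np.minimum(excess, 0.0), t))
    area_above = float(np.trapezoid(np.maximum(excess, 0.0), t))
    return area_below, area_above, area_below + area_above
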