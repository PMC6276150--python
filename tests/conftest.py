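"""Shared fixtures: small synthetic cohorts and reduced model specifications."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from erisk.coding import HEIGHT, MENOPAUSE, Covariate
from erisk.models import GompertzModel, ModelSpec, PiecewiseHazardModel
from erisk.synthetic import TrueModel, simulate_outcomes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

COUNTRY = Covariate("country", categories=("FR", "IT", "ES", "UK"))

_BANDS_POS = (0.55e-3, 0.95e-3, 1.35e-3, 1.70e-3, 2.00e-3, 2.25e-3, 2.45e-3, 2.60e-3)
_BANDS_NEG = (0.22e-3, 0.27e-3, 0.31e-3, 0.34e-3, 0.36e-3, 0.38e-3, 0.39e-3, 0.40e-3)


def reduced_spec(*, with_stratum: bool = False, share_height: bool = False) -> ModelSpec:
    """Two-covariate spec (menopausal status shared, height optionally so)."""
    return ModelSpec(
        covariates=(MENOPAUSE, HEIGHT),
        shared={"menopausal_status": True, "height_cm": share_height},
        stratum=COUNTRY if with_stratum else None,
    )


def reduced_truth(
    *,
    height_hr: tuple[float, float] = (1.19, 1.06),
    with_stratum: bool = False,
    stratum_loghr: float = 0.0,
    unknown_er_prob: float = 0.25,
    gompertz: GompertzModel | None = GompertzModel(alpha=-10.3, gamma=0.09),
) -> TrueModel:
    spec = reduced_spec(with_stratum=with_stratum)
    params: dict[str, float] = {}
    for b in range(8):
        params[f"base:er_pos:{b}"] = float(np.log(_BANDS_POS[b]))
        params[f"base:er_neg:{b}"] = float(np.log(_BANDS_NEG[b]))
    params["shared:menopausal_status=post"] = float(np.log(0.66))
    params["er_pos:height_cm"] = float(np.log(height_hr[0]))
    params["er_neg:height_cm"] = float(np.log(height_hr[1]))
    if with_stratum and stratum_loghr:
        for cause in ("er_pos", "er_neg"):
            for i, c in enumerate(COUNTRY.contrast_levels):
                params[f"{cause}:country={c}"] = stratum_loghr * (i + 1)
    return TrueModel(
        tumor=PiecewiseHazardModel(spec=spec, params=params),
        competing=gompertz,
        unknown_er_prob=unknown_er_prob,
    )


def reduced_cohort(
    n: int,
    seed: int,
    truth: TrueModel | None = None,
    *,
    with_stratum: bool = False,
) -> pd.DataFrame:
    """Minimal cohort (entry age, menopausal status, height, country) + events."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": np.arange(n, dtype=np.int64),
            "entry_age": rng.uniform(40.0, 70.0, size=n),
            "menopausal_status": rng.choice(
                np.array(["pre", "post"], dtype=object), size=n, p=[0.49, 0.51]
            ),
            "height_cm": rng.normal(162.0, 6.5, size=n),
            "country": rng.choice(
                np.array(COUNTRY.categories, dtype=object), size=n, p=[0.35, 0.2, 0.15, 0.3]
            ),
        }
    )
    truth = truth if truth is not None else reduced_truth(with_stratum=with_stratum)
    return simulate_outcomes(df, truth, seed=seed + 1)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return reduced_cohort(20_000, seed=42)


@pytest.fixture(scope="session")
def full_cohort():
    """Full-covariate synthetic cohort under the default ground truth."""
    from erisk.synthetic import simulate_cohort

    return simulate_cohort(20_000, seed=7)
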