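"""Cohort generation configuration: marginal covariate distributions.

The generator needs, beyond the shared codings in :mod:`erisk.coding`, the
marginal category probabilities of each risk factor, the distribution of
continuous variables, the entry-age window, the country (stratum) mix and
the administrative-censoring rule.  Defaults describe a European multi-
centre cohort of women aged 40-70 at recruitment, 51% postmenopausal, with
follow-up averaging about 14 years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .coding import DEFAULT_COVARIATES, Covariate

_PROB_TOL = 1e-12


@dataclass
class CovariateConfig:
    """Marginal distributions paired with the default codings.

    ``category_probs`` maps each categorical covariate name to a probability
    vector aligned with its category list (reference level first).  The
    derived BMI x menopause code has no entry — it is computed from its
    parents.  Dependent variables (age at menopause, parity details,
    breastfeeding) are drawn only on rows where their parent makes them
    applicable.
    """

    category_probs: dict[str, list[float]] = field(default_factory=dict)
    height_mean: float = 162.0
    height_sd: float = 6.5
    entry_age_range: tuple[float, float] = (40.0, 70.0)
    countries: list[str] = field(default_factory=lambda: ["FR", "IT", "ES", "UK"])
    country_weights: list[float] = field(default_factory=lambda: [0.35, 0.20, 0.15, 0.30])

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for cov in self.covariates():
            if cov.kind != "categorical" or cov.name == "bmi_menopause":
                continue
            if cov.name not in self.category_probs:
                raise ValueError(f"no category probabilities configured for {cov.name!r}")
            p = np.asarray(self.category_probs[cov.name], dtype=float)
            if len(p) != len(cov.categories):
                raise ValueError(
                    f"{cov.name!r}: {len(p)} probabilities for {len(cov.categories)} categories"
                )
            if (p < 0).any() or abs(p.sum() - 1.0) > _PROB_TOL:
                raise ValueError(f"{cov.name!r}: probabilities must be >= 0 and sum to 1")
        w = np.asarray(self.country_weights, dtype=float)
        if len(w) != len(self.countries) or (w < 0).any() or abs(w.sum() - 1.0) > _PROB_TOL:
            raise ValueError("country weights must align with countries and sum to 1")
        if self.height_sd <= 0:
            raise ValueError("height_sd must be positive")
        lo, hi = self.entry_age_range
        if not lo < hi:
            raise ValueError("entry_age_range must be an increasing pair")

    @staticmethod
    def covariates() -> tuple[Covariate, ...]:
        return DEFAULT_COVARIATES

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["entry_age_range"] = list(self.entry_age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateConfig":
        d = dict(d)
        if "entry_age_range" in d:
            d["entry_age_range"] = tuple(d["entry_age_range"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "CovariateConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def default_covariate_config() -> CovariateConfig:
    """Default marginals for the synthetic derivation cohort."""
    return CovariateConfig(
        category_probs={
            "menopausal_status": [0.49, 0.51],
            "age_menopause": [0.25, 0.35, 0.30, 0.10],
            "age_menarche": [0.15, 0.20, 0.25, 0.20, 0.20],
            "hrt_years": [0.60, 0.10, 0.08, 0.07, 0.15],
            "bmi": [0.55, 0.30, 0.11, 0.04],
            "alcohol": [0.30, 0.45, 0.15, 0.10],
            "parous": [0.15, 0.85],
            "n_ftp": [0.25, 0.45, 0.30],
            "age_first_ftp": [0.20, 0.40, 0.27, 0.10, 0.03],
            "breastfeeding": [0.30, 0.40, 0.20, 0.10],
        }
    )
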