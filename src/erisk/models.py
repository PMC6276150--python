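"""Model containers: cause-specific piecewise-constant hazards and Gompertz.

The tumour model is piecewise-exponential on the age scale: the baseline
hazard for each cause (ER+ and ER− tumours) is constant within age bands
delimited by cutoffs at 45, 50, 55, 60, 65, 70 and 75 years (first band
open below 45, last open above 75), multiplied by ``exp(beta' x)``.  A
covariate can carry one coefficient shared by both causes or a separate
coefficient per cause; heterogeneity between the two is what the
likelihood-ratio test in :mod:`erisk.hazards` examines.  The pooled
competing-event channel (tumours of unknown receptor status, other primary
cancers, non-cancer deaths) is a Gompertz hazard ``h(t) = exp(alpha +
gamma t)`` with age ``t`` as the time scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import CAUSES, DEFAULT_COVARIATES, Covariate

DEFAULT_CUTOFFS: tuple[float, ...] = (45.0, 50.0, 55.0, 60.0, 65.0, 70.0, 75.0)

#: default sharing pattern: reproductive-history variables and body height
#: are heterogeneous between ER+ and ER− tumours, the rest are shared.
DEFAULT_SHARED: dict[str, bool] = {
    "menopausal_status": True,
    "age_menopause": True,
    "age_menarche": True,
    "hrt_years": True,
    "bmi": True,
    "bmi_menopause": True,
    "alcohol": True,
    "breastfeeding": True,
    "parous": False,
    "n_ftp": False,
    "age_first_ftp": False,
    "height_cm": False,
}

COUNTRY_STRATUM = Covariate("country", categories=("FR", "IT", "ES", "UK"))


@dataclass
class ModelSpec:
    """Covariate coding, sharing pattern and age-band cutoffs of a fit."""

    covariates: tuple[Covariate, ...] = DEFAULT_COVARIATES
    shared: dict[str, bool] = field(default_factory=lambda: dict(DEFAULT_SHARED))
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    stratum: Covariate | None = None
    causes: tuple[str, ...] = CAUSES

    def __post_init__(self):
        cuts = np.asarray(self.cutoffs, dtype=float)
        if len(cuts) and not (np.diff(cuts) > 0).all():
            raise ValueError("cutoffs must be strictly increasing")
        for cov in self.covariates:
            if cov.name not in self.shared:
                raise ValueError(f"no sharing flag for covariate {cov.name!r}")

    @property
    def n_bands(self) -> int:
        return len(self.cutoffs) + 1

    def band_index(self, age) -> np.ndarray:
        """Band containing ``age``; half-open bands ``[c_j, c_{j+1})``."""
        return np.searchsorted(np.asarray(self.cutoffs, dtype=float), np.asarray(age), side="right")

    def band_edges(self) -> np.ndarray:
        """Band boundaries padded with -inf / +inf."""
        return np.concatenate([[-np.inf], np.asarray(self.cutoffs, float), [np.inf]])

    # -- parameter layout ---------------------------------------------------
    def baseline_names(self) -> list[str]:
        return [f"base:{c}:{b}" for c in self.causes for b in range(self.n_bands)]

    def lp_terms(self, cause: str) -> list[tuple[str, Covariate, int]]:
        """Linear-predictor terms for one cause: (param name, covariate, column)."""
        terms = []
        for cov in self.covariates:
            key = "shared" if self.shared[cov.name] else cause
            for j, cn in enumerate(cov.column_names()):
                terms.append((f"{key}:{cn}", cov, j))
        if self.stratum is not None:
            # country/stratum effects are always cause-specific
            for j, cn in enumerate(self.stratum.column_names()):
                terms.append((f"{cause}:{cn}", self.stratum, j))
        return terms

    def coef_names(self) -> list[str]:
        names: list[str] = []
        for cause in self.causes:
            for name, _, _ in self.lp_terms(cause):
                if name not in names:
                    names.append(name)
        return names

    def param_names(self) -> list[str]:
        return self.baseline_names() + self.coef_names()

    def with_shared(self, **flags: bool) -> "ModelSpec":
        """Copy of the spec with some sharing flags overridden."""
        shared = dict(self.shared)
        for k, v in flags.items():
            if k not in shared:
                raise KeyError(f"unknown covariate {k!r}")
            shared[k] = v
        return replace(self, shared=shared)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        def cov_dict(c: Covariate) -> dict:
            return {
                "name": c.name,
                "kind": c.kind,
                "categories": list(c.categories),
                "applicable_if": [c.applicable_if[0], list(c.applicable_if[1])]
                if c.applicable_if
                else None,
                "center": c.center,
                "scale": c.scale,
            }

        return {
            "covariates": [cov_dict(c) for c in self.covariates],
            "shared": dict(self.shared),
            "cutoffs": list(self.cutoffs),
            "stratum": cov_dict(self.stratum) if self.stratum else None,
            "causes": list(self.causes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        def mk_cov(cd: dict) -> Covariate:
            app = cd.get("applicable_if")
            return Covariate(
                cd["name"],
                kind=cd.get("kind", "categorical"),
                categories=tuple(cd.get("categories", ())),
                applicable_if=(app[0], tuple(app[1])) if app else None,
                center=cd.get("center", 0.0),
                scale=cd.get("scale", 1.0),
            )

        return cls(
            covariates=tuple(mk_cov(c) for c in d["covariates"]),
            shared=dict(d["shared"]),
            cutoffs=tuple(d["cutoffs"]),
            stratum=mk_cov(d["stratum"]) if d.get("stratum") else None,
            causes=tuple(d.get("causes", CAUSES)),
        )


def default_model_spec(with_stratum: bool = False) -> ModelSpec:
    return ModelSpec(stratum=COUNTRY_STRATUM if with_stratum else None)


@dataclass
class PiecewiseHazardModel:
    """Fitted (or ground-truth) cause-specific piecewise-exponential model.

    ``params`` maps parameter names (see :meth:`ModelSpec.param_names`) to
    values; baseline parameters are log hazards in events per person-year.
    Shared coefficients appear once under a ``shared:`` key and are used by
    both causes, which keeps them identical by construction.
    """

    spec: ModelSpec
    params: dict[str, float]
    loglik: float | None = None
    cov: pd.DataFrame | None = None

    def log_baseline(self, cause: str) -> np.ndarray:
        return np.array([self.params[f"base:{cause}:{b}"] for b in range(self.spec.n_bands)])

    def baseline_hazard(self, cause: str) -> np.ndarray:
        return np.exp(self.log_baseline(cause))

    def coef(self, name: str) -> float:
        return self.params[name]

    def se(self, name: str) -> float:
        if self.cov is None:
            raise ValueError("model has no covariance matrix")
        return float(np.sqrt(self.cov.loc[name, name]))

    def linear_predictor(
        self, df: pd.DataFrame, cause: str, *, include_stratum: bool = True
    ) -> np.ndarray:
        """``beta' x`` for each row of ``df`` for the given cause."""
        lp = np.zeros(len(df))
        blocks: dict[str, np.ndarray] = {}
        for name, cov, j in self.spec.lp_terms(cause):
            if not include_stratum and self.spec.stratum is not None and cov is self.spec.stratum:
                continue
            if cov.name not in blocks:
                blocks[cov.name] = cov.design_block(df)
            beta = self.params.get(name, 0.0)
            if beta != 0.0:
                lp += beta * blocks[cov.name][:, j]
        return lp

    def hazard(self, df: pd.DataFrame, cause: str, band: np.ndarray | int) -> np.ndarray:
        """Cause-specific hazard for each row in the given age band(s)."""
        lb = self.log_baseline(cause)
        return np.exp(lb[band] + self.linear_predictor(df, cause))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "spec": self.spec.to_dict(),
            "params": {k: float(v) for k, v in self.params.items()},
            "loglik": self.loglik,
        }
        if self.cov is not None:
            d["cov"] = {"names": list(self.cov.index), "matrix": self.cov.to_numpy().tolist()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseHazardModel":
        cov = None
        if d.get("cov"):
            cov = pd.DataFrame(
                np.asarray(d["cov"]["matrix"], dtype=float),
                index=d["cov"]["names"],
                columns=d["cov"]["names"],
            )
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            params={k: float(v) for k, v in d["params"].items()},
            loglik=d.get("loglik"),
            cov=cov,
        )


@dataclass
class GompertzModel:
    """Gompertz hazard ``h(t) = exp(alpha + gamma t)`` on the age scale."""

    alpha: float
    gamma: float
    loglik: float | None = None
    cov: np.ndarray | None = None

    _GAMMA_EPS = 1e-9

    def hazard(self, t) -> np.ndarray:
        return np.exp(self.alpha + self.gamma * np.asarray(t, dtype=float))

    def cumhaz(self, t0, t1) -> np.ndarray:
        """Integrated hazard over ``[t0, t1]`` (exact; exponential limit at gamma=0)."""
        t0 = np.asarray(t0, dtype=float)
        t1 = np.asarray(t1, dtype=float)
        if abs(self.gamma) < self._GAMMA_EPS:
            return np.exp(self.alpha) * (t1 - t0)
        return np.exp(self.alpha) / self.gamma * (np.exp(self.gamma * t1) - np.exp(self.gamma * t0))

    def inverse_time(self, a, e) -> np.ndarray:
        """Age at which the integrated hazard from ``a`` reaches ``e`` (closed form)."""
        a = np.asarray(a, dtype=float)
        e = np.asarray(e, dtype=float)
        if abs(self.gamma) < self._GAMMA_EPS:
            return a + e * np.exp(-self.alpha)
        arg = np.exp(self.gamma * a) + self.gamma * e * np.exp(-self.alpha)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log(arg) / self.gamma
        # gamma < 0 saturates: hazard may never accumulate enough mass
        return np.where(arg > 0, out, np.inf)

    def to_dict(self) -> dict:
        d = {"alpha": float(self.alpha), "gamma": float(self.gamma), "loglik": self.loglik}
        if self.cov is not None:
            d["cov"] = np.asarray(self.cov).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GompertzModel":
        cov = np.asarray(d["cov"], dtype=float) if d.get("cov") else None
        return cls(alpha=float(d["alpha"]), gamma=float(d["gamma"]), loglik=d.get("loglik"), cov=cov)


@dataclass
class RiskModel:
    """Bundle of the tumour model and the competing-event model."""

    piecewise: PiecewiseHazardModel
    gompertz: GompertzModel | None = None

    def to_dict(self) -> dict:
        return {
            "piecewise": self.piecewise.to_dict(),
            "gompertz": self.gompertz.to_dict() if self.gompertz else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(
            piecewise=PiecewiseHazardModel.from_dict(d["piecewise"]),
            gompertz=GompertzModel.from_dict(d["gompertz"]) if d.get("gompertz") else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
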