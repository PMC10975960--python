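"""Hierarchical population model: typical values, allometry, IIV, residual error.

The population model realizes individual structural parameters as

    P_i = theta_P * allometric(WT_i) * covariate_factors * exp(eta_P,i)

with ``eta ~ MVN(0, Omega)`` on the log scale and a combined residual-error
model ``y = f * (1 + eps_prop) + eps_add``.  Clearance scales with fixed
exponent 0.75 and volume with exponent 1.0 relative to a 70 kg reference —
the standard allometric rules used for pediatric extrapolation.

Default numeric values are the published bepotastine population estimates
(KA 4.21 1/h, CL 28.0 L/h, V 103.0 L, ALAG 0.27 h; IIV CV% 112.7 / 22.5 /
22.0 / 32.4 with CL-V correlation 0.65 and CL-ALAG correlation 0.47;
proportional error 10.3%, additive error variance fixed at 0.1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional, Sequence

import numpy as np

from .pk_core import StructuralParams

__all__ = [
    "Covariates",
    "CovariateEffect",
    "PopulationParams",
    "IndividualParams",
    "allometric_scale",
    "covariate_effect_apply",
    "sample_individual",
    "sample_etas",
    "residual_error",
    "PARAM_ORDER",
]

#: order of random effects throughout the package
PARAM_ORDER = ("ka", "cl", "v", "alag")

REFERENCE_WEIGHT = 70.0


@dataclass(frozen=True)
class Covariates:
    """Subject-level covariates. Body weight is mandatory for scaling."""

    wt: float
    age: Optional[float] = None
    scr: Optional[float] = None
    egfr: Optional[float] = None
    sex: Optional[str] = None  # "male" | "female"

    def __post_init__(self) -> None:
        if self.wt is None or not self.wt > 0:
            raise ValueError("body weight (wt) is mandatory and must be positive")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be non-negative")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    def value(self, name: str) -> float:
        if name == "sex":
            return 1.0 if self.sex == "female" else 0.0
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"covariate {name!r} is missing")
        return float(v)


CovariateForm = Literal["linear", "exponential", "power-categorical"]


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative covariate-parameter relationship.

    forms
    -----
    linear              : base * (1 + coef * (cov - ref))
    exponential         : base * exp(coef * (cov - ref))
    power-categorical   : base * coef ** indicator     (ref unused, cov is 0/1)
    """

    parameter: str  # one of PARAM_ORDER
    covariate: str  # Covariates field name
    form: CovariateForm
    coefficient: float
    reference: float = 0.0

    def factor(self, cov_value: float) -> float:
        return covariate_effect_apply(1.0, cov_value, self.form, self.coefficient, self.reference)


def covariate_effect_apply(
    base: float, cov_value: float, form: str, coefficient: float, reference: float = 0.0
) -> float:
    """Apply one covariate relationship to a base parameter value."""
    if form == "linear":
        out = base * (1.0 + coefficient * (cov_value - reference))
        if out <= 0:
            raise ValueError(
                f"linear covariate effect gives non-positive parameter "
                f"({out}) at covariate value {cov_value}"
            )
        return out
    if form == "exponential":
        return base * float(np.exp(coefficient * (cov_value - reference)))
    if form == "power-categorical":
        if coefficient <= 0:
            raise ValueError("power-categorical coefficient must be positive")
        return base * coefficient ** (1.0 if cov_value else 0.0)
    raise ValueError(f"unknown covariate form {form!r}")


@dataclass
class PopulationParams:
    """Population-level parameters of the bepotastine model.

    ``iiv_cv`` holds the IIV magnitudes in CV% (NONMEM reporting convention).
    By default ``omega = CV/100`` on the log-SD scale; set
    ``cv_convention="lognormal"`` for the exact log-normal reading
    ``omega^2 = ln(1 + (CV/100)^2)`` — materially different only for KA.

    The additive residual error is specified as a *variance* of 0.1 (its
    printed unit reads ng/mL); ``additive_error_as_sd=True`` reinterprets the
    0.1 as an SD instead.
    """

    theta: dict = field(
        default_factory=lambda: {"ka": 4.21, "cl": 28.0, "v": 103.0, "alag": 0.27}
    )
    wt_exp_cl: float = 0.75  # fixed, never estimated
    wt_exp_v: float = 1.0  # fixed, never estimated
    ref_wt: float = REFERENCE_WEIGHT
    iiv_cv: dict = field(
        default_factory=lambda: {"ka": 112.7, "cl": 22.5, "v": 22.0, "alag": 32.4}
    )
    corr_cl_v: float = 0.65
    corr_cl_alag: float = 0.47
    sigma_prop: float = 0.103
    additive_error: float = 0.1
    additive_error_as_sd: bool = False
    cv_convention: Literal["sd", "lognormal"] = "sd"
    covariate_effects: list = field(default_factory=list)

    # -- derived quantities -------------------------------------------------

    def omega_sd(self) -> np.ndarray:
        """Log-scale SDs in PARAM_ORDER under the selected CV% convention."""
        cv = np.array([self.iiv_cv[k] for k in PARAM_ORDER]) / 100.0
        if self.cv_convention == "sd":
            return cv
        if self.cv_convention == "lognormal":
            return np.sqrt(np.log1p(cv**2))
        raise ValueError(f"unknown cv_convention {self.cv_convention!r}")

    def omega(self) -> np.ndarray:
        """4x4 log-scale covariance (KA, CL, V, ALAG).

        Only the CL-V and CL-ALAG covariances are non-zero; KA is independent
        and the V-ALAG covariance is structurally 0.
        """
        sd = self.omega_sd()
        corr = np.eye(4)
        corr[1, 2] = corr[2, 1] = self.corr_cl_v
        corr[1, 3] = corr[3, 1] = self.corr_cl_alag
        om = corr * np.outer(sd, sd)
        self._check_pd(om)
        return om

    @staticmethod
    def _check_pd(om: np.ndarray) -> None:
        # with only CL-V and CL-ALAG off-diagonals, PD <=> rho1^2 + rho2^2 < 1
        sd = np.sqrt(np.diag(om))
        if np.any(sd == 0):
            return  # degenerate-but-valid diagonal zeros (no IIV on a parameter)
        r1 = om[1, 2] / (sd[1] * sd[2])
        r2 = om[1, 3] / (sd[1] * sd[3])
        if r1**2 + r2**2 >= 1.0:
            raise ValueError(
                f"omega is not positive definite: CL-V correlation {r1:.3f} and "
                f"CL-ALAG correlation {r2:.3f} satisfy rho1^2 + rho2^2 >= 1"
            )

    @property
    def sigma_add(self) -> float:
        """Additive residual SD (ng/mL)."""
        if self.additive_error_as_sd:
            return self.additive_error
        return float(np.sqrt(self.additive_error))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        d = dict(d)
        effects = [
            CovariateEffect(**e) if isinstance(e, dict) else e
            for e in d.pop("covariate_effects", [])
        ]
        return cls(covariate_effects=effects, **d)

    @classmethod
    def from_json(cls, path) -> "PopulationParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_file(cls, path) -> "PopulationParams":
        """Load from JSON or (by extension) YAML."""
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            with open(path) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        return cls.from_json(path)


@dataclass(frozen=True)
class IndividualParams:
    """A subject's random effects and the realized structural parameters."""

    eta: np.ndarray  # length-4, PARAM_ORDER
    params: StructuralParams


def allometric_scale(pop: PopulationParams, cov: Covariates) -> StructuralParams:
    """Typical structural parameters for a subject with these covariates.

    CL scales as (WT/70)^0.75 and V as (WT/70)^1; KA and ALAG are weight-
    independent.  Any configured covariate effects are applied on top,
    multiplicatively.
    """
    w = cov.wt / pop.ref_wt
    vals = {
        "ka": pop.theta["ka"],
        "cl": pop.theta["cl"] * w**pop.wt_exp_cl,
        "v": pop.theta["v"] * w**pop.wt_exp_v,
        "alag": pop.theta["alag"],
    }
    for eff in pop.covariate_effects:
        vals[eff.parameter] = covariate_effect_apply(
            vals[eff.parameter], cov.value(eff.covariate), eff.form, eff.coefficient, eff.reference
        )
    return StructuralParams(**vals)


def sample_etas(pop: PopulationParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` eta vectors from MVN(0, Omega) via Cholesky factorization."""
    om = pop.omega()
    sd = np.sqrt(np.diag(om))
    if np.all(sd == 0):
        return np.zeros((n, 4))
    # Cholesky of the non-degenerate sub-block; zero-variance etas stay 0
    live = sd > 0
    chol = np.linalg.cholesky(om[np.ix_(live, live)])
    z = rng.standard_normal((n, int(live.sum())))
    etas = np.zeros((n, 4))
    etas[:, live] = z @ chol.T
    return etas


def sample_individual(
    pop: PopulationParams, cov: Covariates, rng: np.random.Generator
) -> IndividualParams:
    """Realize one subject: typical scaled values times exp(eta)."""
    typ = allometric_scale(pop, cov)
    eta = sample_etas(pop, 1, rng)[0]
    fac = np.exp(eta)
    params = StructuralParams(
        ka=typ.ka * fac[0], cl=typ.cl * fac[1], v=typ.v * fac[2], alag=typ.alag * fac[3]
    )
    return IndividualParams(eta=eta, params=params)


def residual_error(
    pred,
    pop: PopulationParams,
    rng: Optional[np.random.Generator] = None,
    eps_prop=None,
    eps_add=None,
):
    """Apply combined residual error ``y = pred*(1 + eps_prop) + eps_add``.

    Either pass an ``rng`` to draw the epsilons or supply them explicitly
    (used by deterministic tests).
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("pred must be non-negative")
    if eps_prop is None:
        if rng is None:
            raise ValueError("provide rng or explicit epsilons")
        eps_prop = rng.normal(0.0, pop.sigma_prop, size=pred.shape)
        eps_add = rng.normal(0.0, pop.sigma_add, size=pred.shape)
    return pred * (1.0 + np.asarray(eps_prop)) + np.asarray(eps_add)
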