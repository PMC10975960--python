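"""One-compartment oral PK model with first-order absorption and lag time.

All concentration profiles in this package come from the Bateman solution of
the two-state (gut, central) linear system

    dA_g/dt = -ka * A_g,        A_g(t_lag) = F * dose
    dA_c/dt =  ka * A_g - ke * A_c,   ke = CL / V

shifted by the absorption lag ``alag``.  Units are fixed package-wide: time in
hours, dose in mg, volume in L, clearance in L/h, concentration in ng/mL.  The
single mg/L -> ng/mL conversion factor (1000) lives here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "StructuralParams",
    "DoseRegimen",
    "ExposureMetrics",
    "conc_single_dose",
    "conc_multi_dose",
    "tmax_cmax",
    "auc",
    "auc_trapezoid",
    "MG_PER_L_TO_NG_PER_ML",
    "FLIP_FLOP_RTOL",
]

#: concentration unit conversion: amount (mg) / volume (L) -> ng/mL
MG_PER_L_TO_NG_PER_ML = 1000.0

#: relative |ka - ke| / ke below which the ka == ke limiting form is used
FLIP_FLOP_RTOL = 1e-8


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural PK parameters.

    Parameters
    ----------
    ka : float
        First-order absorption rate constant (1/h).
    cl : float
        Apparent clearance CL/F (L/h).
    v : float
        Apparent central volume V/F (L).
    alag : float
        Absorption lag time (h).
    f : float
        Bioavailable fraction entering the gut compartment (default 1).
    """

    ka: float
    cl: float
    v: float
    alag: float = 0.0
    f: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "v"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.alag < 0:
            raise ValueError(f"alag must be non-negative, got {self.alag}")
        if not 0 < self.f <= 1:
            raise ValueError(f"f must be in (0, 1], got {self.f}")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V (1/h)."""
        return self.cl / self.v

    def with_(self, **kwargs) -> "StructuralParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated identical oral doses.

    ``interval`` may be omitted for a single dose.  Dose times are
    ``0, interval, ..., (n_doses - 1) * interval``.
    """

    amount: float
    interval: Optional[float] = None
    n_doses: int = 1

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1 and (self.interval is None or not self.interval > 0):
            raise ValueError("interval must be positive for multiple doses")

    def dose_times(self) -> np.ndarray:
        if self.n_doses == 1:
            return np.zeros(1)
        return self.interval * np.arange(self.n_doses, dtype=float)


@dataclass(frozen=True)
class ExposureMetrics:
    """Summary exposure of a concentration-time profile."""

    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float


def _bateman(ka, ke, coef, tau):
    """Elementwise Bateman kernel ``coef * (exp(-ke*tau) - exp(-ka*tau))``.

    ``tau`` is time after absorption starts (already lag-shifted); negative
    values give 0.  All arguments broadcast; the ka ~= ke degenerate case is
    handled with the limiting form ``coef2 * tau * exp(-k*tau)``.
    """
    ka = np.asarray(ka, dtype=float)
    ke = np.asarray(ke, dtype=float)
    coef = np.asarray(coef, dtype=float)
    tau = np.maximum(np.asarray(tau, dtype=float), 0.0)
    degen = np.abs(ka - ke) < FLIP_FLOP_RTOL * ke
    with np.errstate(over="ignore", invalid="ignore"):
        safe_diff = np.where(degen, 1.0, ka - ke)
        out = coef / safe_diff * (np.exp(-ke * tau) - np.exp(-ka * tau))
        # ka == ke limit of the Bateman function
        lim = coef * tau * np.exp(-ke * tau)
    return np.where(degen, lim, out)


def conc_single_dose(p: StructuralParams, dose: float, t) -> np.ndarray | float:
    """Concentration (ng/mL) at time(s) ``t`` after a single oral dose at t=0.

    Returns 0 for ``t <= alag``.  Scalar in, scalar out.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    coef = MG_PER_L_TO_NG_PER_ML * dose * p.f * p.ka / p.v
    out = _bateman(p.ka, p.ke, coef, t_arr - p.alag)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def conc_multi_dose(p: StructuralParams, r: DoseRegimen, t) -> np.ndarray | float:
    """Superposition concentration for a repeated-dose regimen."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    taus = t_arr[:, None] - r.dose_times()[None, :] - p.alag
    coef = MG_PER_L_TO_NG_PER_ML * r.amount * p.f * p.ka / p.v
    out = _bateman(p.ka, p.ke, coef, taus).sum(axis=1)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def tmax_cmax(p: StructuralParams, dose: float) -> tuple[float, float]:
    """Analytic single-dose peak: ``tmax = alag + ln(ka/ke)/(ka - ke)``."""
    ke = p.ke
    if abs(p.ka - ke) < FLIP_FLOP_RTOL * ke:
        tmax = p.alag + 1.0 / ke
    else:
        tmax = p.alag + np.log(p.ka / ke) / (p.ka - ke)
    cmax = conc_single_dose(p, dose, tmax)
    return float(tmax), float(cmax)


def auc(p: StructuralParams, dose: float, t_end: float = np.inf) -> float:
    """Analytic single-dose AUC (h*ng/mL) from 0 to ``t_end`` (or infinity).

    ``auc(p, dose)`` with the default infinite horizon equals
    ``1000 * dose * f / cl`` exactly.
    """
    if np.isinf(t_end):
        return MG_PER_L_TO_NG_PER_ML * dose * p.f / p.cl
    tau = t_end - p.alag
    if tau <= 0:
        return 0.0
    ka, ke = p.ka, p.ke
    coef = MG_PER_L_TO_NG_PER_ML * dose * p.f * ka / p.v
    if abs(ka - ke) < FLIP_FLOP_RTOL * ke:
        return float(coef * (1.0 - (1.0 + ke * tau) * np.exp(-ke * tau)) / ke**2)
    return float(
        coef / (ka - ke) * ((1.0 - np.exp(-ke * tau)) / ke - (1.0 - np.exp(-ka * tau)) / ka)
    )


def auc_trapezoid(p: StructuralParams, dose: float, times) -> float:
    """Linear-trapezoidal AUC of the single-dose profile on a supplied grid."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    c = conc_single_dose(p, dose, times)
    return float(np.trapezoid(c, times))


def exposure(p: StructuralParams, dose: float, t_last: float = 24.0) -> ExposureMetrics:
    """Single-dose exposure summary (Cmax, Tmax, AUC to ``t_last``, AUC-inf)."""
    tmax, cmax = tmax_cmax(p, dose)
    return ExposureMetrics(
        cmax=cmax,
        tmax=tmax,
        auc_last=auc(p, dose, t_last),
        auc_inf=auc(p, dose),
    )
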