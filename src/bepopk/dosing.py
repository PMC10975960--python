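"""Pediatric dose optimization by exposure matching.

The target is the exposure of the reference regimen — a single 10 mg dose in
a typical 70 kg adult: Cmax from the analytic peak and AUC_last as the
analytic 0-24 h integral.  For a child of weight w the typical parameters
follow from allometric scaling (CL ~ (w/70)^0.75, V ~ w/70); because the
model is dose-linear, the continuous matching dose is
``reference_exposure / per-mg exposure`` and is then rounded to the 0.1 mg
prescribing grid (half away from zero).  Simulations are deterministic: no
IIV and no residual error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .pk_core import ExposureMetrics, StructuralParams, auc, tmax_cmax
from .population import Covariates, PopulationParams, allometric_scale

__all__ = [
    "adult_reference",
    "optimal_dose",
    "dose_table_by_weight",
    "dose_table_by_age",
    "AGE_GROUP_MEDIAN_WEIGHTS",
    "WEIGHT_GRID",
    "DOSE_GRID_MG",
]

#: pediatric weight grid (kg) used for the weight-banded dose table
WEIGHT_GRID = tuple(range(10, 32))

#: median body weight (kg) per age group, used for the age-banded table
AGE_GROUP_MEDIAN_WEIGHTS = {2: 14.0, 3: 14.4, 4: 15.9, 5: 17.9, 6: 19.6}

DOSE_GRID_MG = 0.1
_METRICS = ("cmax", "auc_last")


def _round_to_grid(dose: float, grid: float = DOSE_GRID_MG) -> float:
    """Nearest grid multiple, half away from zero.

    The quotient is pre-rounded at 1e-9 resolution so binary representation
    error (3.55 / 0.1 -> 35.4999...) cannot flip a half-way case downward.
    """
    return float(np.floor(np.round(dose / grid, 9) + 0.5) * grid)


def _unit_exposure(p: StructuralParams, t_last: float) -> dict:
    """Cmax and AUC_last per mg of dose."""
    _, cmax = tmax_cmax(p, 1.0)
    return {"cmax": cmax, "auc_last": auc(p, 1.0, t_last)}


def adult_reference(
    pop: PopulationParams,
    dose: float = 10.0,
    weight: float = 70.0,
    t_last: float = 24.0,
) -> ExposureMetrics:
    """Exposure of the reference single 10 mg dose in a typical 70 kg adult."""
    p = allometric_scale(pop, Covariates(wt=weight))
    tmax, cmax = tmax_cmax(p, dose)
    return ExposureMetrics(
        cmax=cmax, tmax=tmax, auc_last=auc(p, dose, t_last), auc_inf=auc(p, dose)
    )


def optimal_dose(
    pop: PopulationParams,
    weight: float,
    metric: str,
    reference: Optional[ExposureMetrics] = None,
    t_last: float = 24.0,
    grid: float = DOSE_GRID_MG,
) -> float:
    """Grid dose (mg) whose typical-child exposure best matches the adult
    reference for the given metric (``"cmax"`` or ``"auc_last"``).

    Exposure is exactly dose-proportional, so the continuous matching dose is
    computed in closed form and snapped to the grid — equivalent to scanning
    all 0.1 mg doses for the smallest |child - reference| difference.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    if not weight > 0:
        raise ValueError("weight must be positive")
    ref = reference if reference is not None else adult_reference(pop, t_last=t_last)
    p = allometric_scale(pop, Covariates(wt=weight))
    per_mg = _unit_exposure(p, t_last)[metric]
    target = ref.cmax if metric == "cmax" else ref.auc_last
    return _round_to_grid(target / per_mg, grid)


def dose_table_by_weight(
    pop: PopulationParams,
    weights: Iterable[float] = WEIGHT_GRID,
    t_last: float = 24.0,
) -> pd.DataFrame:
    """Recommended dose per body weight for both exposure metrics.

    Columns: weight_kg, metric, dose_mg.  The default grid spans the
    pediatric 10-31 kg range (22 integer weights).
    """
    ref = adult_reference(pop, t_last=t_last)
    rows = [
        {
            "weight_kg": float(w),
            "metric": m,
            "dose_mg": optimal_dose(pop, w, m, reference=ref, t_last=t_last),
        }
        for m in _METRICS
        for w in weights
    ]
    return pd.DataFrame(rows)


def dose_table_by_age(
    pop: PopulationParams,
    age_medians: Mapping[int, float] = AGE_GROUP_MEDIAN_WEIGHTS,
    t_last: float = 24.0,
) -> pd.DataFrame:
    """Recommended dose per age group, evaluated at the group's median weight."""
    ref = adult_reference(pop, t_last=t_last)
    rows = [
        {
            "age_years": int(age),
            "median_weight_kg": float(w),
            "metric": m,
            "dose_mg": optimal_dose(pop, w, m, reference=ref, t_last=t_last),
        }
        for m in _METRICS
        for age, w in sorted(age_medians.items())
    ]
    return pd.DataFrame(rows)


def format_dose_table(table: pd.DataFrame) -> str:
    """Wide, human-readable layout of a weight-banded dose table."""
    wide = table.pivot(index="metric", columns="weight_kg", values="dose_mg")
    lines = ["Body weight (kg)  " + "  ".join(f"{int(w):>4d}" for w in wide.columns)]
    for m in ("cmax", "auc_last"):
        if m in wide.index:
            lines.append(f"{m:<17} " + "  ".join(f"{d:>4.1f}" for d in wide.loc[m]))
    return "\n".join(lines)
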