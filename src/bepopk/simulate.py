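"""Synthetic trial simulator and event-table I/O.

Emulates the two study designs behind the bepotastine analysis:

* **adult** arm — 32 healthy adults, a single 10 mg tablet, 13 nominal
  samples over 24 h (0, 0.33, 0.67, 1, 1.33, 1.67, 2, 3, 4, 6, 8, 12, 24 h);
* **pediatric** arm — 30 children aged 2-6 y, 3 mg (1.5 mL of 2 mg/mL dry
  syrup) twice daily for at least four days, with two sparse samples per
  child after the morning dose of day 5: one drawn uniformly in the
  0.5-2 h window and one in the 6-12 h window post-dose.

Demographics are drawn from truncated normals matching the reported
mean (SD) and min-max per arm; pediatric age is integer-uniform on 2-6 with
weight log-normal around the age-group median weights, truncated to the
observed 13-26 kg range.

Event tables use the NONMEM-style long CSV dialect
``ID, TIME, EVID, AMT, DV, BLQ, WT, AGE, SCR, EGFR, SEX`` (EVID 1 = dose,
0 = observation; SEX 0 = male, 1 = female).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pk_core import DoseRegimen, conc_multi_dose
from .population import Covariates, PopulationParams, sample_individual

__all__ = [
    "StudyDesign",
    "adult_design",
    "pediatric_design",
    "simulate_demographics",
    "simulate_study",
    "apply_lloq_filter",
    "read_event_table",
    "write_event_table",
    "validate_event_table",
    "ADULT_NOMINAL_TIMES",
    "PEDIATRIC_WINDOWS",
    "LLOQ",
    "EVENT_COLUMNS",
]

ADULT_NOMINAL_TIMES = (0.0, 0.33, 0.67, 1.0, 1.33, 1.67, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
PEDIATRIC_WINDOWS = ((0.5, 2.0), (6.0, 12.0))
LLOQ = 1.0  # ng/mL

EVENT_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DV", "BLQ", "WT", "AGE", "SCR", "EGFR", "SEX"]

# reported demographics: mean, sd, min, max per arm
_ADULT_WT = (70.95, 8.04, 56.8, 89.6)
_ADULT_AGE = (24.97, 4.02, 19.0, 37.0)
_ADULT_SCR = (0.87, 0.10, 0.69, 1.10)
_ADULT_EGFR = (109.3, 13.30, 80.0, 133.0)
_PED_SCR = (0.38, 0.07, 0.28, 0.52)
_PED_EGFR = (119.4, 16.15, 90.0, 152.0)
_PED_MALE_FRACTION = 19 / 30

# pediatric weight-for-age: median and 5th-95th percentile span (kg)
_PED_WT_BY_AGE = {
    2: (14.0, 13.1, 15.4),
    3: (14.4, 13.4, 16.4),
    4: (15.9, 14.2, 18.6),
    5: (17.9, 15.8, 20.8),
    6: (19.6, 17.0, 23.2),
}
_PED_WT_BOUNDS = (13.0, 26.0)


@dataclass(frozen=True)
class StudyDesign:
    """One trial arm: dosing, sampling scheme and cohort size."""

    arm: str  # "adult" | "pediatric"
    dosing: DoseRegimen
    n_subjects: int
    nominal_times: Optional[Sequence[float]] = None  # adult arm
    sampling_windows: Optional[Sequence[tuple]] = None  # pediatric arm
    obs_dose_index: int = 0  # index of the dose the sampling windows follow

    def __post_init__(self) -> None:
        if self.arm not in ("adult", "pediatric"):
            raise ValueError(f"arm must be 'adult' or 'pediatric', got {self.arm!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.nominal_times is None and self.sampling_windows is None:
            raise ValueError("a design needs nominal_times or sampling_windows")


def adult_design(n_subjects: int = 32) -> StudyDesign:
    """Single 10 mg dose, 13 nominal samples over 24 h."""
    return StudyDesign(
        arm="adult",
        dosing=DoseRegimen(amount=10.0),
        n_subjects=n_subjects,
        nominal_times=ADULT_NOMINAL_TIMES,
    )


def pediatric_design(n_subjects: int = 30) -> StudyDesign:
    """3 mg twice daily; sparse sampling after the 9th dose (day-5 morning).

    Nine q12h doses give >= 4 full days of dosing before PK sampling, so the
    sampled dose is effectively at steady state.
    """
    return StudyDesign(
        arm="pediatric",
        dosing=DoseRegimen(amount=3.0, interval=12.0, n_doses=9),
        n_subjects=n_subjects,
        sampling_windows=PEDIATRIC_WINDOWS,
        obs_dose_index=8,
    )


def _truncnorm(spec, n, rng):
    mean, sd, lo, hi = spec
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_demographics(arm: str, n: int, rng: np.random.Generator) -> list[Covariates]:
    """Draw ``n`` covariate vectors matching the reported arm demographics."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    if arm == "adult":
        wt = _truncnorm(_ADULT_WT, n, rng)
        age = _truncnorm(_ADULT_AGE, n, rng)
        scr = _truncnorm(_ADULT_SCR, n, rng)
        egfr = _truncnorm(_ADULT_EGFR, n, rng)
        for i in range(n):  # the adult cohort was all male
            out.append(
                Covariates(wt=wt[i], age=age[i], scr=scr[i], egfr=egfr[i], sex="male")
            )
    elif arm == "pediatric":
        ages = rng.integers(2, 7, size=n)
        scr = _truncnorm(_PED_SCR, n, rng)
        egfr = _truncnorm(_PED_EGFR, n, rng)
        sexes = np.where(rng.random(n) < _PED_MALE_FRACTION, "male", "female")
        lo, hi = _PED_WT_BOUNDS
        for i in range(n):
            med, p5, p95 = _PED_WT_BY_AGE[int(ages[i])]
            # log-normal around the age-group median, CV set by the 5th-95th span
            sigma = np.log(p95 / p5) / (2 * stats.norm.ppf(0.95))
            a = (np.log(lo) - np.log(med)) / sigma
            b = (np.log(hi) - np.log(med)) / sigma
            wt = float(
                np.exp(
                    stats.truncnorm.rvs(a, b, loc=np.log(med), scale=sigma, random_state=rng)
                )
            )
            out.append(
                Covariates(wt=wt, age=float(ages[i]), scr=scr[i], egfr=egfr[i], sex=str(sexes[i]))
            )
    else:
        raise ValueError(f"unknown arm {arm!r}")
    return out


def _sample_times(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """Observation times (h since first dose) for one subject."""
    if design.nominal_times is not None:
        return np.asarray(design.nominal_times, dtype=float)
    t0 = design.dosing.dose_times()[design.obs_dose_index]
    return np.array([t0 + rng.uniform(lo, hi) for lo, hi in design.sampling_windows])


def simulate_study(
    design: StudyDesign,
    pop: PopulationParams,
    rng: np.random.Generator,
    start_id: int = 1,
) -> pd.DataFrame:
    """Simulate one trial arm into a long-format event table."""
    rows = []
    covs = simulate_demographics(design.arm, design.n_subjects, rng)
    dose_times = design.dosing.dose_times()
    for i, cov in enumerate(covs):
        sid = start_id + i
        # record and simulate with identically rounded covariates
        cov = Covariates(
            wt=round(cov.wt, 3),
            age=round(cov.age, 2) if cov.age is not None else None,
            scr=round(cov.scr, 3) if cov.scr is not None else None,
            egfr=round(cov.egfr, 1) if cov.egfr is not None else None,
            sex=cov.sex,
        )
        ind = sample_individual(pop, cov, rng)
        base = {
            "ID": sid,
            "WT": cov.wt,
            "AGE": cov.age if cov.age is not None else np.nan,
            "SCR": cov.scr if cov.scr is not None else np.nan,
            "EGFR": cov.egfr if cov.egfr is not None else np.nan,
            "SEX": 1 if cov.sex == "female" else 0,
        }
        for dt in dose_times:
            rows.append({**base, "TIME": dt, "EVID": 1, "AMT": design.dosing.amount,
                         "DV": np.nan, "BLQ": 0})
        times = _sample_times(design, rng)
        pred = np.atleast_1d(conc_multi_dose(ind.params, design.dosing, times))
        eps_p = rng.normal(0.0, pop.sigma_prop, size=pred.shape)
        eps_a = rng.normal(0.0, pop.sigma_add, size=pred.shape)
        obs = np.maximum(pred * (1.0 + eps_p) + eps_a, 0.0)
        for t, y in zip(times, obs):
            rows.append({**base, "TIME": float(t), "EVID": 0, "AMT": np.nan,
                         "DV": float(y), "BLQ": int(y < LLOQ)})
    tbl = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return tbl.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


def apply_lloq_filter(tbl: pd.DataFrame, lloq: float = LLOQ) -> pd.DataFrame:
    """Drop pre-dose (t=0) and below-LLOQ observation rows (M1 exclusion).

    Dose rows always pass.  The number of removed rows is recorded in
    ``result.attrs["n_blq_removed"]``.
    """
    is_obs = tbl["EVID"] == 0
    drop = is_obs & ((tbl["DV"] < lloq) | (tbl["TIME"] == 0.0) | tbl["DV"].isna())
    out = tbl.loc[~drop].reset_index(drop=True)
    out.attrs["n_blq_removed"] = int(drop.sum())
    return out


def validate_event_table(tbl: pd.DataFrame) -> None:
    """Check the event-table schema and structural invariants."""
    missing = [c for c in EVENT_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValueError(f"event table is missing mandatory column(s): {', '.join(missing)}")
    for sid, grp in tbl.groupby("ID"):
        if not (grp["EVID"] == 1).any():
            raise ValueError(f"subject {sid} has no dose rows")
        if np.any(np.diff(grp["TIME"].to_numpy()) < 0):
            raise ValueError(f"subject {sid} has decreasing times")
    obs = tbl[tbl["EVID"] == 0]
    bad = obs["DV"].isna() & (obs["BLQ"] == 0)
    if bad.any():
        raise ValueError("observation rows must carry a concentration or a BLQ flag")


def write_event_table(tbl: pd.DataFrame, path) -> None:
    """Write the event table as CSV in the package dialect."""
    validate_event_table(tbl)
    tbl.to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    """Read and validate an event-table CSV."""
    tbl = pd.read_csv(path)
    validate_event_table(tbl)
    tbl = tbl[EVENT_COLUMNS].copy()
    tbl["ID"] = tbl["ID"].astype(int)
    tbl["EVID"] = tbl["EVID"].astype(int)
    tbl["BLQ"] = tbl["BLQ"].astype(int)
    return tbl


def simulate_two_study_dataset(
    pop: PopulationParams,
    rng: np.random.Generator,
    n_adults: int = 32,
    n_children: int = 30,
) -> pd.DataFrame:
    """Both arms in one table (adults first, then children)."""
    ad = simulate_study(adult_design(n_adults), pop, rng, start_id=1)
    ped = simulate_study(pediatric_design(n_children), pop, rng, start_id=n_adults + 1)
    return pd.concat([ad, ped], ignore_index=True)
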