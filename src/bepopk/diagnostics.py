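"""Model diagnostics: GOF quantities, visual predictive check, prediction error.

* PRED is the typical-covariate prediction (eta = 0); IPRED is the prediction
  at the empirical Bayes eta; CWRES whitens the residual about the FOCE-I
  linearization, using the model-implied covariance ``G Omega G' + diag(v)``.
* The VPC simulates replicate datasets under the study design, bins adults by
  nominal time and children by sampling window, and compares observed
  5/50/95th percentiles with the 90% envelope of the simulated percentiles.
  Coverage is the fraction of observations inside the central 90% band of the
  pooled simulated observations of their bin.
* ``prediction_error`` is the mean squared error and ``period_split_compare``
  contrasts two prediction sets over the absorption (0.5-2 h) and
  elimination (6-12 h) sampling windows with a t-test on the squared errors
  (Welch by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats, linalg

from .estimate import (
    CompiledData,
    compile_data,
    empirical_bayes,
    _jac_eta,
    _pred_eta,
    _typical_matrix,
)
from .population import PARAM_ORDER, PopulationParams
from .simulate import (
    LLOQ,
    PEDIATRIC_WINDOWS,
    StudyDesign,
    apply_lloq_filter,
    simulate_study,
)

__all__ = [
    "gof_quantities",
    "VpcResult",
    "vpc",
    "prediction_error",
    "PredictionErrorReport",
    "period_split_compare",
]


def _typical_from_pop(pop: PopulationParams, data: CompiledData) -> np.ndarray:
    theta = np.array([pop.theta[k] for k in PARAM_ORDER])
    return _typical_matrix(
        theta, data, pop.covariate_effects, ref_wt=pop.ref_wt,
        wt_exp_cl=pop.wt_exp_cl, wt_exp_v=pop.wt_exp_v,
    )


def gof_quantities(pop: PopulationParams, tbl: pd.DataFrame) -> pd.DataFrame:
    """Per-observation PRED, IPRED, RES, IWRES and CWRES for a fitted model.

    CWRES uses the FOCE-I linearization about the conditional mode:
    ``E[y] ~= f(eta_hat) - G eta_hat`` and
    ``Cov[y] ~= G Omega G' + diag(v(eta_hat))`` per subject, whitened by a
    triangular solve against the Cholesky factor of that covariance.
    """
    data = compile_data(tbl)
    typ = _typical_from_pop(pop, data)
    omega = pop.omega()
    ebe = empirical_bayes(pop, data)
    E = ebe.to_numpy()
    zeros = np.zeros_like(E)

    pred = _pred_eta(data, typ, zeros)
    ipred, G = _jac_eta(data, typ, E)
    y = data.obs_y
    v = pop.sigma_prop**2 * ipred**2 + pop.sigma_add**2

    cwres = np.empty(data.n_obs)
    for s in range(data.n_sub):
        sel = data.obs_sub == s
        Gs = G[sel]
        mean = ipred[sel] - Gs @ E[s]
        cov = Gs @ omega @ Gs.T + np.diag(v[sel])
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            # near-singular covariance: jitter the diagonal
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
        cwres[sel] = linalg.solve_triangular(L, y[sel] - mean, lower=True)

    return pd.DataFrame(
        {
            "ID": data.subject_ids[data.obs_sub],
            "TIME": data.obs_time,
            "DV": y,
            "PRED": pred,
            "IPRED": ipred,
            "RES": y - pred,
            "IWRES": (y - ipred) / np.sqrt(v),
            "CWRES": cwres,
        }
    )


@dataclass
class VpcResult:
    """Binned VPC summary.

    ``bins`` rows: bin label, n observed, observed 5/50/95th percentiles, the
    90% confidence band of each percentile across simulated replicates, and
    the central 90% band of the pooled simulated observations used for
    coverage.
    """

    bins: pd.DataFrame
    coverage: float
    n_covered: int
    n_considered: int
    n_replicates: int
    excluded_bins: list = field(default_factory=list)

    def to_json(self, path) -> None:
        d = {
            "coverage": self.coverage,
            "n_covered": self.n_covered,
            "n_considered": self.n_considered,
            "n_replicates": self.n_replicates,
            "excluded_bins": self.excluded_bins,
            "bins": self.bins.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _bin_labels(tbl: pd.DataFrame, design: StudyDesign) -> pd.Series:
    """Assign each observation row to a VPC bin."""
    obs = tbl[tbl["EVID"] == 0]
    if design.arm == "adult":
        return obs["TIME"].round(2).astype(str)
    # pediatric: windows by time after the sampled dose
    t0 = design.dosing.dose_times()[design.obs_dose_index]
    tad = obs["TIME"] - t0
    labels = pd.Series("other", index=obs.index)
    for lo, hi in design.sampling_windows:
        labels[(tad >= lo) & (tad <= hi)] = f"{lo}-{hi}h"
    return labels


def vpc(
    pop: PopulationParams,
    design: StudyDesign,
    observed: pd.DataFrame,
    n_replicates: int = 1000,
    rng: Optional[np.random.Generator] = None,
    lloq: float = LLOQ,
    min_bin_obs: int = 3,
) -> VpcResult:
    """Visual predictive check of ``observed`` against ``n_replicates``
    simulated datasets under ``design``.

    The observed table and every simulated replicate get the same LLOQ
    exclusion, so observed and simulated percentiles are comparable.
    """
    rng = rng if rng is not None else np.random.default_rng()
    obs_f = apply_lloq_filter(observed, lloq)
    obs_bins = _bin_labels(obs_f, design)
    obs_dv = obs_f.loc[obs_bins.index, "DV"]

    sim_vals: dict[str, list] = {}
    sim_pcts: dict[str, list] = {}
    for _ in range(n_replicates):
        sim = apply_lloq_filter(simulate_study(design, pop, rng), lloq)
        labels = _bin_labels(sim, design)
        dv = sim.loc[labels.index, "DV"]
        for b, grp in dv.groupby(labels):
            arr = grp.to_numpy()
            sim_vals.setdefault(b, []).append(arr)
            if arr.size:
                sim_pcts.setdefault(b, []).append(np.percentile(arr, [5, 50, 95]))

    rows = []
    excluded = []
    n_cov = 0
    n_tot = 0
    for b, grp in obs_dv.groupby(obs_bins):
        o = grp.to_numpy()
        pooled = np.concatenate(sim_vals.get(b, [np.empty(0)]))
        if o.size < min_bin_obs or pooled.size == 0:
            excluded.append(b)
            continue
        o_p = np.percentile(o, [5, 50, 95])
        reps = np.asarray(sim_pcts[b])  # (n_rep, 3)
        env_lo = np.percentile(reps, 5, axis=0)
        env_hi = np.percentile(reps, 95, axis=0)
        band_lo, band_hi = np.percentile(pooled, [5, 95])
        inside = int(np.sum((o >= band_lo) & (o <= band_hi)))
        n_cov += inside
        n_tot += o.size
        rows.append(
            {
                "bin": b,
                "n_obs": int(o.size),
                "obs_p5": o_p[0], "obs_p50": o_p[1], "obs_p95": o_p[2],
                "p5_lo": env_lo[0], "p5_hi": env_hi[0],
                "p50_lo": env_lo[1], "p50_hi": env_hi[1],
                "p95_lo": env_lo[2], "p95_hi": env_hi[2],
                "band_lo": band_lo, "band_hi": band_hi,
                "n_inside": inside,
            }
        )
    bins = pd.DataFrame(rows)
    coverage = n_cov / n_tot if n_tot else float("nan")
    return VpcResult(
        bins=bins,
        coverage=coverage,
        n_covered=n_cov,
        n_considered=n_tot,
        n_replicates=n_replicates,
        excluded_bins=excluded,
    )


def vpc_plot(result: VpcResult, path=None, ax=None):
    """Plot observed percentiles against simulated envelopes (adult-style bins)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    b = result.bins.copy()
    try:
        x = b["bin"].astype(float).to_numpy()
        order = np.argsort(x)
        b = b.iloc[order]
        x = x[order]
    except ValueError:
        x = np.arange(len(b))
        ax.set_xticks(x, b["bin"])
    for p, color in (("p5", "tab:blue"), ("p50", "tab:red"), ("p95", "tab:blue")):
        ax.fill_between(x, b[f"{p}_lo"], b[f"{p}_hi"], alpha=0.25, color=color)
    ax.plot(x, b["obs_p5"], "o--", color="tab:blue", label="observed 5/95%")
    ax.plot(x, b["obs_p95"], "o--", color="tab:blue")
    ax.plot(x, b["obs_p50"], "o-", color="tab:red", label="observed median")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/mL)")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def gof_plot(gof: pd.DataFrame, path=None):
    """Four-panel goodness-of-fit figure (DV vs PRED/IPRED, CWRES panels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, xcol, ycol in (
        (axes[0, 0], "PRED", "DV"),
        (axes[0, 1], "IPRED", "DV"),
    ):
        ax.plot(gof[xcol], gof[ycol], "o", ms=3, alpha=0.6)
        lim = max(gof[xcol].max(), gof[ycol].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k-", lw=0.8)
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
    for ax, xcol in ((axes[1, 0], "PRED"), (axes[1, 1], "TIME")):
        ax.plot(gof[xcol], gof["CWRES"], "o", ms=3, alpha=0.6)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel(xcol)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def prediction_error(obs, pred) -> float:
    """Mean squared prediction error ``sum (OBS - PRED)^2 / n``."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: obs {obs.shape} vs pred {pred.shape}")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return float(np.mean((obs - pred) ** 2))


@dataclass
class PredictionErrorReport:
    """MSE comparison of two prediction sets, overall and per sampling period."""

    n_total: int
    n_absorption: int
    n_elimination: int
    mse_a: dict  # {"total": .., "absorption": .., "elimination": ..}
    mse_b: dict
    sd_a: dict
    sd_b: dict
    p_values: dict
    test: str = "welch"

    def to_dict(self) -> dict:
        return asdict(self)


def _time_after_dose(tbl: pd.DataFrame) -> np.ndarray:
    """Time since the most recent dose for each observation row."""
    out = []
    for sid, grp in tbl.groupby("ID"):
        dose_t = grp.loc[grp["EVID"] == 1, "TIME"].to_numpy()
        for _, row in grp[grp["EVID"] == 0].iterrows():
            prior = dose_t[dose_t <= row["TIME"]]
            out.append(row["TIME"] - prior.max() if prior.size else np.nan)
    return np.asarray(out)


def period_split_compare(
    tbl: pd.DataFrame,
    pred_a,
    pred_b,
    windows: Sequence[tuple] = PEDIATRIC_WINDOWS,
    equal_var: bool = False,
) -> PredictionErrorReport:
    """Compare squared prediction errors of two models over the absorption
    (first window) and elimination (second window) sampling periods.

    ``pred_a`` / ``pred_b`` align with the observation rows of ``tbl`` in
    order.  Welch's unequal-variance t-test by default (``equal_var=True``
    for the pooled-variance variant); identical error sets report p = 1.
    """
    obs = tbl[tbl["EVID"] == 0]
    y = obs["DV"].to_numpy(dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    if pred_a.shape != y.shape or pred_b.shape != y.shape:
        raise ValueError("predictions must align with the observation rows")
    tad = _time_after_dose(tbl)
    (a_lo, a_hi), (e_lo, e_hi) = windows
    masks = {
        "total": np.ones_like(y, dtype=bool),
        "absorption": (tad >= a_lo) & (tad <= a_hi),
        "elimination": (tad >= e_lo) & (tad <= e_hi),
    }
    sq_a = (y - pred_a) ** 2
    sq_b = (y - pred_b) ** 2

    mse_a, mse_b, sd_a, sd_b, pvals = {}, {}, {}, {}, {}
    for name, m in masks.items():
        if not m.any():
            mse_a[name] = mse_b[name] = sd_a[name] = sd_b[name] = pvals[name] = None
            continue
        ea, eb = sq_a[m], sq_b[m]
        mse_a[name] = float(ea.mean())
        mse_b[name] = float(eb.mean())
        sd_a[name] = float(ea.std(ddof=1)) if ea.size > 1 else 0.0
        sd_b[name] = float(eb.std(ddof=1)) if eb.size > 1 else 0.0
        if np.allclose(ea, eb):
            pvals[name] = 1.0  # identical error sets: no difference
        else:
            pvals[name] = float(stats.ttest_ind(ea, eb, equal_var=equal_var).pvalue)
    return PredictionErrorReport(
        n_total=int(masks["total"].sum()),
        n_absorption=int(masks["absorption"].sum()),
        n_elimination=int(masks["elimination"].sum()),
        mse_a=mse_a,
        mse_b=mse_b,
        sd_a=sd_a,
        sd_b=sd_b,
        p_values=pvals,
        test="pooled" if equal_var else "welch",
    )
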