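"""Independent likelihood oracle: adaptive Gauss-Hermite -2 log-likelihood.

Used to validate the FOCE/Laplace objective on small instances (1-2 subjects,
1-2 live random effects).  The oracle integrates the exact conditional
likelihood over the random effects numerically; it shares only the model
prediction function with the implementation, not the Laplace approximation.
"""

import dataclasses

import numpy as np
from scipy import optimize

import bepopk as bp
from bepopk import estimate as est
from bepopk.population import PARAM_ORDER

TINY_CV = 1e-4  # CV% assigned to frozen random effects


def small_instance(rng, n_sub=1, live=("cl",)):
    """A random dense-sampled instance with 1-2 live random effects."""
    base = bp.PopulationParams()
    theta = {k: v * np.exp(rng.uniform(-0.3, 0.3)) for k, v in base.theta.items()}
    cv = {k: (rng.uniform(15.0, 40.0) if k in live else TINY_CV) for k in PARAM_ORDER}
    pop = dataclasses.replace(
        base,
        theta=theta,
        iiv_cv=cv,
        corr_cl_v=0.0,
        corr_cl_alag=0.0,
        sigma_prop=rng.uniform(0.08, 0.15),
    )
    tbl = bp.apply_lloq_filter(bp.simulate_study(bp.adult_design(n_sub), pop, rng))
    return pop, tbl


def gauss_hermite_ofv(pop, tbl, live, n_nodes=64):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature."""
    data = est.compile_data(tbl)
    theta = np.array([pop.theta[k] for k in PARAM_ORDER])
    typ = est._typical_matrix(theta, data, [])
    live_idx = [PARAM_ORDER.index(k) for k in live]
    om_live = pop.omega()[np.ix_(live_idx, live_idx)]
    om_inv_live = np.linalg.inv(om_live)
    sp, sa2 = pop.sigma_prop, pop.sigma_add**2
    d = len(live_idx)
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    if d == 1:
        Z = z[:, None]
        W = w
    else:
        Z1, Z2 = np.meshgrid(z, z, indexing="ij")
        Z = np.stack([Z1.ravel(), Z2.ravel()], axis=1)
        W = np.outer(w, w).ravel()

    total = 0.0
    for s in range(data.n_sub):
        sel = data.obs_sub == s

        def njoint(e):
            E = np.zeros((data.n_sub, 4))
            E[s, live_idx] = np.atleast_1d(e)
            f = est._pred_eta(data, typ, E)[sel]
            y = data.obs_y[sel]
            v = sp**2 * f**2 + sa2
            e = np.atleast_1d(e)
            return 0.5 * (
                np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v)
                + e @ om_inv_live @ e
                + np.log(np.linalg.det(2 * np.pi * om_live))
            )

        res = optimize.minimize(
            njoint, np.zeros(d), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 5000},
        )
        mode = np.atleast_1d(res.x)
        h = 1e-4
        H = np.zeros((d, d))
        for i in range(d):
            for j in range(d):
                ei, ej = np.zeros(d), np.zeros(d)
                ei[i] = h
                ej[j] = h
                H[i, j] = (
                    njoint(mode + ei + ej) - njoint(mode + ei - ej)
                    - njoint(mode - ei + ej) + njoint(mode - ei - ej)
                ) / (4 * h * h)
        L = np.linalg.cholesky(np.linalg.inv(0.5 * (H + H.T)))
        pts = mode[None, :] + np.sqrt(2.0) * Z @ L.T
        logs = np.array([-njoint(p) for p in pts]) + np.sum(Z**2, axis=1)
        logw = np.log(W)
        m = np.max(logs + logw)
        log_int = (
            m
            + np.log(np.sum(np.exp(logs + logw - m)))
            + 0.5 * d * np.log(2.0)
            + np.log(np.abs(np.linalg.det(L)))
        )
        total += -2.0 * log_int
    return total
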