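"""Shared test utilities: dataset factory and independent dense-matrix oracles.

The oracles build the full N x N marginal covariance explicitly and use
generic dense solves / generic optimizers, so they share no code path with
the package's Woodbury-based fitter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from crossclass import (
    SimulationCondition,
    generate_dataset,
    resolve_population_parameters,
)
from crossclass.study import replication_seed


def make_dataset(
    mc=0.5, f=2, rho=0.0, groups=4, size=10.0, iucc=0.15, seed=7, rep=0, **kw
):
    cond = SimulationCondition(mc, f, rho, groups, size, iucc)
    params = resolve_population_parameters(cond)
    rng = replication_seed(seed, cond.condition_id, rep)
    return generate_dataset(cond, params, rng, **kw), cond, params


def _dense_pieces(records: pd.DataFrame):
    y = records["y"].to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack(
        [np.ones(n), records["x"], records["w"], records["z"]]
    ).astype(float)
    cj = pd.factorize(records["j"], sort=True)[0]
    ck = pd.factorize(records["k"], sort=True)[0]
    Zc = np.eye(cj.max() + 1)[cj]
    Zr = np.eye(ck.max() + 1)[ck]
    return y, X, Zc, Zr


def dense_loglik(records, sigma2, tau_col, tau_row, factors="both"):
    """Profiled (over fixed effects) Gaussian log-likelihood, dense algebra."""
    y, X, Zc, Zr = _dense_pieces(records)
    n = len(y)
    V = sigma2 * np.eye(n)
    if factors in ("both", "col"):
        V = V + tau_col * Zc @ Zc.T
    if factors in ("both", "row"):
        V = V + tau_row * Zr @ Zr.T
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vi @ r)


def dense_fit_oracle(records, model="crossed", retained="row"):
    """Grid-plus-polish ML fit on the dense covariance.

    Coarse grid over the variance ratios, Nelder-Mead polish, residual
    variance profiled analytically.  Returns (deviance, beta, variances).
    """
    y, X, Zc, Zr = _dense_pieces(records)
    n = len(y)
    if model == "crossed":
        mats = [Zc @ Zc.T, Zr @ Zr.T]
    else:
        Zg = Zr if retained == "row" else Zc
        mats = [Zg @ Zg.T]

    def profiled_dev(theta):
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < 0):
            return np.inf
        V0 = np.eye(n)
        for t, Mt in zip(theta, mats):
            V0 = V0 + t * Mt
        Vi = np.linalg.inv(V0)
        A = X.T @ Vi @ X
        beta = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ beta
        rss = float(r @ Vi @ r)
        _, logdet = np.linalg.slogdet(V0)
        return n * np.log(2 * np.pi * rss / n) + logdet + n

    k = len(mats)
    grid_pts = np.array([0.0, 0.02, 0.1, 0.3, 1.0, 3.0])
    best, best_dev = None, np.inf
    grids = np.meshgrid(*([grid_pts] * k))
    for theta in zip(*(g.ravel() for g in grids)):
        dev = profiled_dev(theta)
        if dev < best_dev:
            best, best_dev = np.array(theta), dev
    res = optimize.minimize(
        profiled_dev,
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    theta = np.maximum(res.x, 0.0)
    V0 = np.eye(n)
    for t, Mt in zip(theta, mats):
        V0 = V0 + t * Mt
    Vi = np.linalg.inv(V0)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    sigma2 = float(r @ Vi @ r) / n
    return profiled_dev(theta), beta, sigma2, theta * sigma2


def balanced_anova_oracle(table, outcome, factors, max_order=3):
    """Textbook sums of squares on a balanced design via per-term projections.

    Sum-coded contrast columns of distinct terms are mutually orthogonal on
    a complete balanced grid, so each term's SS is the squared norm of the
    projection of the (uncentered) outcome onto that term's column space.
    """
    y = table[outcome].to_numpy(dtype=float)
    n = len(y)
    # sum-coded contrast columns per factor
    contrasts = {}
    for fct in factors:
        levels = np.sort(table[fct].unique())
        L = len(levels)
        C = np.zeros((n, L - 1))
        codes = np.searchsorted(levels, table[fct].to_numpy())
        for m in range(L - 1):
            C[:, m] = (codes == m).astype(float) - (codes == L - 1).astype(float)
        contrasts[fct] = C

    import itertools

    ss = {}
    model_cols = [np.ones((n, 1))]
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(factors, order):
            blocks = [contrasts[f] for f in combo]
            cols = blocks[0]
            for Bk in blocks[1:]:
                cols = np.einsum("ni,nj->nij", cols, Bk).reshape(n, -1)
            proj, *_ = np.linalg.lstsq(cols, y, rcond=None)
            fitted = cols @ proj
            ss[":".join(combo)] = float(fitted @ fitted)
            model_cols.append(cols)
    Xfull = np.hstack(model_cols)
    coef, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    resid = y - Xfull @ coef
    ss_error = float(resid @ resid)
    return ss, ss_error
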