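"""Independent brute-force oracles for the DEA scores.

These deliberately avoid the package's Charnes-Cooper linearization: the
fractional slacks-based programs are attacked directly — a coarse vectorized
grid over the reference weights supplies feasible starts, and an SLSQP solve
of the fractional objective with explicit linear constraints polishes them.
Both objectives are linear-fractional over a polyhedron (quasiconvex), so a
polished local minimum is the global one.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def closed_form_single_ratio(k, reference):
    """CRS score for m=1, r1=1, r2=0: own output/input ratio divided by the
    best ratio among the *other* units. For interior units this equals the
    standard normalized ratio; for the frontier unit it is its
    super-efficiency margin over the runner-up."""
    own = k.good_outputs_yd[0] / k.inputs_x[0]
    best_other = max(d.good_outputs_yd[0] / d.inputs_x[0]
                     for d in reference if d.id != k.id)
    return own / best_other


def _stack(units):
    X = np.column_stack([d.inputs_x for d in units])
    Yd = np.column_stack([d.good_outputs_yd for d in units])
    r2 = units[0].bad_outputs_yu.size
    Yu = np.column_stack([d.bad_outputs_yu for d in units]) if r2 else np.empty((0, len(units)))
    return X, Yd, Yu


def _grid_starts(objective, upper, pts=9, n_starts=4):
    d = len(upper)
    axes = [np.linspace(0.0, upper[j], pts) for j in range(d)]
    lam = np.array(list(itertools.product(*axes)))
    vals = objective(lam)
    order = np.argsort(vals)
    starts = [lam[j] for j in order[:n_starts] if np.isfinite(vals[j])]
    return starts or [np.zeros(d)]


def sbm_standard_bruteforce(k, reference, include_self=True):
    """CRS standard SBM score of ``k``: slacks are determined by the weights,
    so minimize rho(lambda) directly over the feasible weight polyhedron."""
    others = [d for d in reference if d.id != k.id]
    units = others + [k] if include_self else others
    X, Yd, Yu = _stack(units)
    xk, ydk, yuk = k.inputs_x, k.good_outputs_yd, k.bad_outputs_yu
    m, r1, r2 = k.dims
    nref = len(units)

    def rho_vec(lam):
        lam = np.atleast_2d(lam)
        s_in = xk[None, :] - lam @ X.T
        s_d = lam @ Yd.T - ydk[None, :]
        num = 1.0 - np.mean(s_in / xk, axis=1)
        den = 1.0 + np.sum(s_d / ydk, axis=1) / (r1 + r2)
        infeas = (s_in < -1e-9).any(axis=1) | (s_d < -1e-9).any(axis=1)
        if r2:
            s_u = yuk[None, :] - lam @ Yu.T
            den += np.sum(s_u / yuk, axis=1) / (r1 + r2)
            infeas |= (s_u < -1e-9).any(axis=1)
        out = num / den
        out[infeas] = np.inf
        return out

    cons = [{"type": "ineq", "fun": lambda l: xk - X @ l},
            {"type": "ineq", "fun": lambda l: Yd @ l - ydk}]
    if r2:
        cons.append({"type": "ineq", "fun": lambda l: yuk - Yu @ l})

    def rho_scalar(l):
        num = 1.0 - np.mean((xk - X @ l) / xk)
        den = 1.0 + np.sum((Yd @ l - ydk) / ydk) / (r1 + r2)
        if r2:
            den += np.sum((yuk - Yu @ l) / yuk) / (r1 + r2)
        return num / den

    upper = np.array([min(xk[i] / X[i, j] for i in range(m)) for j in range(nref)])
    best = np.inf
    for start in _grid_starts(rho_vec, upper):
        res = minimize(rho_scalar, start, method="SLSQP", constraints=cons,
                       bounds=[(0, None)] * nref,
                       options={"maxiter": 500, "ftol": 1e-14})
        cand = rho_vec(res.x[None, :])[0] if res.x is not None else np.inf
        best = min(best, cand, float(rho_vec(start[None, :])[0]))
    return float(best)


def sbm_super_bruteforce(k, reference):
    """CRS super-efficiency SBM of a frontier unit, solved as the fractional
    program in (lambda, projected inputs, projected good outputs); the bad
    outputs sit at the evaluated unit's level subject to Yu lambda <= yu_k."""
    others = [d for d in reference if d.id != k.id]
    X, Yd, Yu = _stack(others)
    xk, ydk, yuk = k.inputs_x, k.good_outputs_yd, k.bad_outputs_yu
    m, r1, r2 = k.dims
    nref = len(others)

    def delta_vec(lam):
        lam = np.atleast_2d(lam)
        xbar = np.maximum(lam @ X.T, xk[None, :])
        ydbar = np.minimum(lam @ Yd.T, ydk[None, :])
        num = np.mean(xbar / xk, axis=1)
        den = np.sum(ydbar / ydk, axis=1) / (r1 + r2)
        infeas = np.zeros(len(lam), bool)
        if r2:
            den += r2 / (r1 + r2)
            infeas |= (lam @ Yu.T > yuk[None, :] + 1e-9).any(axis=1)
        out = np.where(den > 1e-12, num / den, np.inf)
        out[infeas] = np.inf
        return out

    # decision vector z = [lambda (nref), xbar (m), ydbar (r1)]
    iX, iY = nref, nref + m

    def unpack(z):
        return z[:nref], z[iX:iX + m], z[iY:iY + r1]

    def obj(z):
        lam, xbar, ydbar = unpack(z)
        num = np.mean(xbar / xk)
        den = np.sum(ydbar / ydk) / (r1 + r2)
        if r2:
            den += r2 / (r1 + r2)
        return num / den if den > 1e-12 else np.inf

    cons = [
        {"type": "ineq", "fun": lambda z: unpack(z)[1] - X @ unpack(z)[0]},
        {"type": "ineq", "fun": lambda z: unpack(z)[1] - xk},
        {"type": "ineq", "fun": lambda z: Yd @ unpack(z)[0] - unpack(z)[2]},
        {"type": "ineq", "fun": lambda z: ydk - unpack(z)[2]},
    ]
    if r2:
        cons.append({"type": "ineq", "fun": lambda z: yuk - Yu @ unpack(z)[0]})

    upper = []
    for j in range(nref):
        u = 3.0 * max(xk[i] / X[i, j] for i in range(m))
        if r2:
            u = min(u, min(yuk[q] / Yu[q, j] for q in range(r2)))
        upper.append(u)

    best = np.inf
    for lam0 in _grid_starts(delta_vec, np.array(upper)):
        z0 = np.concatenate([lam0, np.maximum(X @ lam0, xk),
                             np.minimum(Yd @ lam0, ydk)])
        res = minimize(obj, z0, method="SLSQP", constraints=cons,
                       bounds=[(0, None)] * len(z0),
                       options={"maxiter": 500, "ftol": 1e-14})
        if res.x is not None:
            lam = np.clip(res.x[:nref], 0, None)
            best = min(best, float(delta_vec(lam[None, :])[0]))
        best = min(best, float(delta_vec(lam0[None, :])[0]))
    return best


def sbm_crs_bruteforce(k, reference):
    """Two-stage CRS score matching the package's scoring convention."""
    rho = sbm_standard_bruteforce(k, reference, include_self=True)
    if rho < 1.0 - 1e-7:
        return rho
    return sbm_super_bruteforce(k, reference)
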