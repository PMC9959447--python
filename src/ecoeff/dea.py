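"""Super-efficiency slacks-based-measure (SBM) DEA with undesirable outputs.

Each decision-making unit (here: one province-year) turns ``m`` inputs into
``r1`` desired outputs and ``r2`` undesired outputs (carbon, pollution). The
score is produced in two stages, which together give the behaviour the
applied efficiency literature calls "super-SBM with undesirable outputs":

1. **Standard SBM.** Minimize the ratio of average input contraction to
   average output expansion,

       rho = [1 - (1/m) Σ s⁻_i/x_ik] / [1 + 1/(r1+r2) (Σ sd_s/yd_sk + Σ su_q/yu_qk)]

   subject to x_k = Xλ + s⁻, yd_k = Y^d λ − s^d, yu_k = Y^u λ + s^u,
   all slacks and λ nonnegative (plus Σλ = 1 under VRS). rho ≤ 1, with
   rho = 1 exactly for frontier units.

2. **Super-efficiency.** Frontier units are re-scored against the frontier
   built *without* them: minimize

       delta = [(1/m) Σ x̄_i/x_ik] / [1/(r1+r2) (Σ ȳd_s/yd_sk + Σ ȳu_q/yu_qk)]

   over projected points x̄ ≥ Σ_{j≠k} x_j λ_j, ȳd ≤ Σ_{j≠k} y^d_j λ_j,
   ȳu ≥ Σ_{j≠k} y^u_j λ_j with x̄ ≥ x_k, ȳd ≤ y^d_k, ȳu ≤ y^u_k.
   delta ≥ 1; under VRS this program can be infeasible (a known pathology),
   which is reported as a status rather than raised.

Both fractional programs are linearized with the Charnes–Cooper
substitution and solved with HiGHS via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .exceptions import ValidationError

__all__ = ["DMU", "EfficiencyResult", "sbm_super_efficiency", "sbm_standard", "score_panel"]

logger = logging.getLogger(__name__)

#: a stage-1 score above this is treated as "on the frontier"
_EFFICIENT_CUT = 1.0 - 1e-7


@dataclass(frozen=True)
class DMU:
    """One decision-making unit: inputs, desired outputs, undesired outputs."""

    id: object
    inputs_x: np.ndarray
    good_outputs_yd: np.ndarray
    bad_outputs_yu: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        for name in ("inputs_x", "good_outputs_yd", "bad_outputs_yu"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if self.inputs_x.size < 1 or self.good_outputs_yd.size < 1:
            raise ValidationError(f"DMU {self.id}: needs >= 1 input and >= 1 desired output")
        for name in ("inputs_x", "good_outputs_yd", "bad_outputs_yu"):
            v = getattr(self, name)
            if v.size and np.any(v <= 0):
                raise ValidationError(
                    f"DMU {self.id}: {name} must be strictly positive (SBM ratios are "
                    "undefined at zero); pre-clean or drop the unit"
                )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.inputs_x.size, self.good_outputs_yd.size, self.bad_outputs_yu.size


@dataclass
class EfficiencyResult:
    id: object
    score: float | None
    rts: str
    lambdas: dict          # reference-unit id -> weight (nonzero entries)
    status: str            # 'optimal' | 'infeasible_super' | 'degenerate'
    projected_point: dict | None = None


def _check_dims(k: DMU, others: Sequence[DMU]):
    for d in others:
        if d.dims != k.dims:
            raise ValidationError(
                f"dimension mismatch: DMU {d.id} has dims {d.dims}, expected {k.dims}"
            )


def _stack(units: Sequence[DMU]):
    X = np.column_stack([d.inputs_x for d in units])
    Yd = np.column_stack([d.good_outputs_yd for d in units])
    r2 = units[0].bad_outputs_yu.size
    Yu = (
        np.column_stack([d.bad_outputs_yu for d in units])
        if r2
        else np.empty((0, len(units)))
    )
    return X, Yd, Yu


def sbm_standard(k: DMU, reference: Iterable[DMU], rts: str = "crs",
                 include_self: bool = True) -> EfficiencyResult:
    """Standard (inclusive) SBM score of ``k``; always <= 1 when feasible.

    With ``include_self=False`` the evaluated unit is removed from the
    reference technology, which for interior units leaves the score unchanged.
    """
    if rts not in ("crs", "vrs"):
        raise ValidationError(f"rts must be 'crs' or 'vrs', got {rts!r}")
    ref = [d for d in reference if d.id != k.id]
    _check_dims(k, ref)
    units = ref + [k] if include_self else ref
    if not units:
        raise ValidationError("empty reference set")
    m, r1, r2 = k.dims
    n = len(units)
    X, Yd, Yu = _stack(units)
    xk, ydk, yuk = k.inputs_x, k.good_outputs_yd, k.bad_outputs_yu

    # variables: [t, Lambda(n), Sin(m), Sd(r1), Su(r2)]
    nv = 1 + n + m + r1 + r2
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + n : 1 + n + m] = -1.0 / (m * xk)

    rows, rhs = [], []
    # normalization: t + (1/(r1+r2)) (Sd/ydk + Su/yuk) = 1
    row = np.zeros(nv)
    row[0] = 1.0
    row[1 + n + m : 1 + n + m + r1] = 1.0 / ((r1 + r2) * ydk)
    if r2:
        row[1 + n + m + r1 :] = 1.0 / ((r1 + r2) * yuk)
    rows.append(row); rhs.append(1.0)
    # X Lambda + Sin - xk t = 0
    for i in range(m):
        row = np.zeros(nv)
        row[0] = -xk[i]
        row[1 : 1 + n] = X[i]
        row[1 + n + i] = 1.0
        rows.append(row); rhs.append(0.0)
    # Yd Lambda - Sd - ydk t = 0
    for s in range(r1):
        row = np.zeros(nv)
        row[0] = -ydk[s]
        row[1 : 1 + n] = Yd[s]
        row[1 + n + m + s] = -1.0
        rows.append(row); rhs.append(0.0)
    # Yu Lambda + Su - yuk t = 0
    for q in range(r2):
        row = np.zeros(nv)
        row[0] = -yuk[q]
        row[1 : 1 + n] = Yu[q]
        row[1 + n + m + r1 + q] = 1.0
        rows.append(row); rhs.append(0.0)
    if rts == "vrs":
        row = np.zeros(nv)
        row[0] = -1.0
        row[1 : 1 + n] = 1.0
        rows.append(row); rhs.append(0.0)

    res = linprog(c, A_eq=np.array(rows), b_eq=np.array(rhs), bounds=[(0, None)] * nv,
                  method="highs")
    if res.status == 2:
        return EfficiencyResult(k.id, None, rts, {}, "infeasible_super")
    if not res.success:
        return EfficiencyResult(k.id, None, rts, {}, "degenerate")
    t = res.x[0]
    if t <= 1e-12:
        return EfficiencyResult(k.id, None, rts, {}, "degenerate")
    lam = res.x[1 : 1 + n] / t
    lambdas = {units[j].id: lam[j] for j in range(n) if lam[j] > 1e-9}
    s_in = res.x[1 + n : 1 + n + m] / t
    s_d = res.x[1 + n + m : 1 + n + m + r1] / t
    s_u = res.x[1 + n + m + r1 :] / t
    projected = {
        "inputs": xk - s_in,
        "good_outputs": ydk + s_d,
        "bad_outputs": yuk - s_u if r2 else np.empty(0),
    }
    return EfficiencyResult(k.id, float(res.fun), rts, lambdas, "optimal", projected)


def _super_sbm(k: DMU, others: Sequence[DMU], rts: str) -> EfficiencyResult:
    """Exclusion (super-efficiency) program for a frontier unit; score >= 1."""
    m, r1, r2 = k.dims
    n = len(others)
    X, Yd, Yu = _stack(others)
    xk, ydk, yuk = k.inputs_x, k.good_outputs_yd, k.bad_outputs_yu

    # variables: [t, Lambda(n), Xbar(m), Ydbar(r1), Yubar(r2)]  (Charnes-Cooper scaled)
    nv = 1 + n + m + r1 + r2
    iX, iYd, iYu = 1 + n, 1 + n + m, 1 + n + m + r1
    c = np.zeros(nv)
    c[iX : iX + m] = 1.0 / (m * xk)

    # normalization equality
    eq_rows, eq_rhs = [], []
    row = np.zeros(nv)
    row[iYd : iYd + r1] = 1.0 / ((r1 + r2) * ydk)
    if r2:
        row[iYu:] = 1.0 / ((r1 + r2) * yuk)
    eq_rows.append(row); eq_rhs.append(1.0)
    if rts == "vrs":
        row = np.zeros(nv)
        row[0] = -1.0
        row[1 : 1 + n] = 1.0
        eq_rows.append(row); eq_rhs.append(0.0)

    ub_rows, ub_rhs = [], []
    for i in range(m):  # X_-k Lambda - Xbar <= 0
        row = np.zeros(nv)
        row[1 : 1 + n] = X[i]
        row[iX + i] = -1.0
        ub_rows.append(row); ub_rhs.append(0.0)
    for s in range(r1):  # Ydbar - Yd_-k Lambda <= 0
        row = np.zeros(nv)
        row[1 : 1 + n] = -Yd[s]
        row[iYd + s] = 1.0
        ub_rows.append(row); ub_rhs.append(0.0)
    for q in range(r2):  # Yu_-k Lambda - Yubar <= 0
        row = np.zeros(nv)
        row[1 : 1 + n] = Yu[q]
        row[iYu + q] = -1.0
        ub_rows.append(row); ub_rhs.append(0.0)
    for i in range(m):  # xk t - Xbar <= 0
        row = np.zeros(nv)
        row[0] = xk[i]
        row[iX + i] = -1.0
        ub_rows.append(row); ub_rhs.append(0.0)
    for s in range(r1):  # Ydbar - ydk t <= 0
        row = np.zeros(nv)
        row[0] = -ydk[s]
        row[iYd + s] = 1.0
        ub_rows.append(row); ub_rhs.append(0.0)
    for q in range(r2):  # Yubar - yuk t <= 0
        row = np.zeros(nv)
        row[0] = -yuk[q]
        row[iYu + q] = 1.0
        ub_rows.append(row); ub_rhs.append(0.0)

    res = linprog(c, A_ub=np.array(ub_rows), b_ub=np.array(ub_rhs),
                  A_eq=np.array(eq_rows), b_eq=np.array(eq_rhs),
                  bounds=[(0, None)] * nv, method="highs")
    if res.status == 2:
        return EfficiencyResult(k.id, None, rts, {}, "infeasible_super")
    if not res.success:
        return EfficiencyResult(k.id, None, rts, {}, "degenerate")
    t = res.x[0]
    if t <= 1e-12:
        return EfficiencyResult(k.id, None, rts, {}, "degenerate")
    lam = res.x[1 : 1 + n] / t
    lambdas = {others[j].id: lam[j] for j in range(n) if lam[j] > 1e-9}
    projected = {
        "inputs": res.x[iX : iX + m] / t,
        "good_outputs": res.x[iYd : iYd + r1] / t,
        "bad_outputs": res.x[iYu:] / t if r2 else np.empty(0),
    }
    return EfficiencyResult(k.id, float(res.fun), rts, lambdas, "optimal", projected)


def sbm_super_efficiency(k: DMU, reference: Iterable[DMU], rts: str = "crs") -> EfficiencyResult:
    """Super-efficiency SBM score of ``k`` against ``reference``.

    Interior units receive their standard SBM score (< 1); frontier units are
    re-scored against the reference set with themselves excluded (>= 1).
    ``reference`` may or may not contain ``k``; it is matched by id.
    """
    if rts not in ("crs", "vrs"):
        raise ValidationError(f"rts must be 'crs' or 'vrs', got {rts!r}")
    others = [d for d in reference if d.id != k.id]
    if len(others) < 2:
        raise ValidationError(
            f"DMU {k.id}: super-efficiency needs >= 2 reference units besides the "
            f"evaluated one, got {len(others)}"
        )
    _check_dims(k, others)
    base = sbm_standard(k, others, rts=rts, include_self=True)
    if base.status == "optimal" and base.score < _EFFICIENT_CUT:
        return base
    return _super_sbm(k, others, rts)


def score_panel(dmus: Sequence[DMU], rts: str = "crs",
                frontier: str = "pooled") -> list[EfficiencyResult]:
    """Score every DMU; ``frontier='pooled'`` uses one joint frontier,
    ``'by_year'`` scores each year against its own cross-section (unit ids must
    then be ``(unit, year)`` tuples).

    VRS super-efficiency infeasibility is resolved by substituting the
    standard inclusive score (1.0 for a frontier unit) with a logged warning,
    keeping the panel balanced for downstream regression.
    """
    dmus = list(dmus)
    if frontier == "pooled":
        groups = {None: dmus}
    elif frontier == "by_year":
        groups = {}
        for d in dmus:
            try:
                year = d.id[1]
            except (TypeError, IndexError):
                raise ValidationError(
                    f"frontier='by_year' needs (unit, year) ids, got {d.id!r}"
                ) from None
            groups.setdefault(year, []).append(d)
    else:
        raise ValidationError(f"frontier must be 'pooled' or 'by_year', got {frontier!r}")

    small = [g for g, members in groups.items() if len(members) < 3]
    if small:
        raise ValidationError(f"frontier groups with fewer than 3 DMUs: {small}")

    results = []
    for members in groups.values():
        for k in members:
            res = sbm_super_efficiency(k, members, rts=rts)
            if res.status == "infeasible_super":
                fallback = sbm_standard(k, members, rts=rts, include_self=True)
                msg = (f"DMU {k.id}: VRS super-efficiency infeasible; substituting "
                       f"standard SBM score {fallback.score:.4f}")
                logger.warning(msg)
                warnings.warn(msg, RuntimeWarning, stacklevel=2)
                res = EfficiencyResult(k.id, fallback.score, rts, fallback.lambdas,
                                       "infeasible_super", fallback.projected_point)
            results.append(res)
    return results
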