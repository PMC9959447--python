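"""Composite new-digital-infrastructure (NDI) index construction.

The composite index has three sub-dimensions:

* information infrastructure (INFI) and innovation infrastructure (INNI) —
  entropy-weighted composites of their indicator blocks;
* convergence infrastructure (CI) — the coupled-coordination degree of two
  entropy-weighted subsystem scores (traditional infrastructure vs. the
  degree of informatization);

and the aggregate NDI = 0.4·INFI + 0.3·CI + 0.3·INNI with fixed expert
weights (exogenous inputs here; the elicitation behind them is out of scope).

The entropy weight method assigns larger weights to indicators with more
cross-unit dispersion: after min-max normalization (direction aware, with a
small epsilon shift so logarithms are defined),

    p_ij = v_ij / Σ_i v_ij,   e_j = -(1/ln n) Σ_i p_ij ln p_ij,
    w_j = (1 - e_j) / Σ_j (1 - e_j).

Constant (degenerate) columns are flagged and receive zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "IndicatorMatrix",
    "WeightVector",
    "CouplingResult",
    "NDIRecord",
    "minmax_normalize",
    "entropy_weights",
    "entropy_index",
    "coupling_coordination",
    "composite_ndi",
]

DEFAULT_EPSILON = 1e-4
DEFAULT_NDI_WEIGHTS = (0.4, 0.3, 0.3)


@dataclass
class IndicatorMatrix:
    """units x indicators value matrix with a direction flag per indicator."""

    units: list
    indicators: list
    directions: list       # 'positive' | 'negative' per indicator
    values: np.ndarray
    normalized: bool = False
    degenerate: np.ndarray | None = None  # bool mask over columns, set by normalization

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValidationError(f"indicator matrix needs n >= 2 units and p >= 1 columns, got {n}x{p}")
        if len(self.units) != n or len(self.indicators) != p or len(self.directions) != p:
            raise ValidationError("units/indicators/directions lengths do not match values shape")
        bad = [d for d in self.directions if d not in ("positive", "negative")]
        if bad:
            raise ValidationError(f"directions must be 'positive' or 'negative', got {bad}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("indicator matrix contains missing/non-finite values")


@dataclass
class WeightVector:
    indicators: list
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValidationError("weights must be nonnegative")
        if self.weights.size and abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must sum to 1")


@dataclass(frozen=True)
class CouplingResult:
    coupling_C: float | np.ndarray
    composite_T: float | np.ndarray
    coordination_D: float | np.ndarray


@dataclass(frozen=True)
class NDIRecord:
    infi: float
    ci: float
    inni: float
    ndi: float


def minmax_normalize(M: IndicatorMatrix, epsilon: float = DEFAULT_EPSILON) -> IndicatorMatrix:
    """Direction-aware min-max normalization onto (0, 1].

    Positive columns map x -> (x-min)/(max-min), negative columns
    x -> (max-x)/(max-min); the result is then shifted by ``epsilon`` and
    rescaled, v -> (v+eps)/(1+eps), so no exact zero survives to the entropy
    logarithms. Constant columns are flagged degenerate (set to zero, later
    zero-weighted) rather than raising.
    """
    V = M.values
    lo, hi = V.min(axis=0), V.max(axis=0)
    span = hi - lo
    degenerate = span <= 0
    out = np.zeros_like(V)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = (V - lo) / span
        neg = (hi - V) / span
    for j, direction in enumerate(M.directions):
        if degenerate[j]:
            continue
        base = pos[:, j] if direction == "positive" else neg[:, j]
        out[:, j] = (base + epsilon) / (1.0 + epsilon)
    return IndicatorMatrix(
        units=list(M.units), indicators=list(M.indicators),
        directions=list(M.directions), values=out,
        normalized=True, degenerate=degenerate,
    )


def entropy_weights(M: IndicatorMatrix) -> WeightVector:
    """Entropy weights from a normalized indicator matrix; degenerate columns
    get weight zero."""
    if not M.normalized:
        M = minmax_normalize(M)
    V = M.values
    n, p = V.shape
    degenerate = M.degenerate if M.degenerate is not None else np.zeros(p, bool)
    if np.any(V[:, ~degenerate] <= 0):
        raise ValidationError("normalized values must be strictly positive for entropy weighting")
    one_minus_e = np.zeros(p)
    for j in range(p):
        if degenerate[j]:
            continue
        pj = V[:, j] / V[:, j].sum()
        e_j = -(pj * np.log(pj)).sum() / np.log(n)
        one_minus_e[j] = 1.0 - e_j
    total = one_minus_e.sum()
    if total <= 0:
        # every live column is uniform across units: fall back to equal weights
        live = ~degenerate
        w = np.where(live, 1.0 / live.sum(), 0.0)
    else:
        w = one_minus_e / total
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    return WeightVector(indicators=list(M.indicators), weights=w)


def entropy_index(M: IndicatorMatrix, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Per-unit entropy-weighted composite score in (0, 1]: normalize, weight,
    and sum across indicators."""
    norm = minmax_normalize(M, epsilon=epsilon) if not M.normalized else M
    w = entropy_weights(norm)
    return norm.values @ w.weights


def coupling_coordination(u1, u2, alpha: float = 0.5, beta: float = 0.5) -> CouplingResult:
    """Two-subsystem coupled-coordination degree.

    C = 2·sqrt(u1·u2)/(u1+u2) (0 when both are 0), T = alpha·u1 + beta·u2,
    D = sqrt(C·T). C = 1 iff u1 = u2 > 0. Accepts scalars or arrays.
    """
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-12:
        raise ValidationError("alpha and beta must be nonnegative and sum to 1")
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if np.any((u1 < 0) | (u1 > 1) | (u2 < 0) | (u2 > 1)):
        raise ValidationError("subsystem scores must lie in [0, 1]")
    total = u1 + u2
    with np.errstate(invalid="ignore", divide="ignore"):
        # sqrt factors separately: sqrt(u1*u2) underflows for tiny subnormal inputs
        C = np.where(total > 0,
                     2.0 * np.sqrt(u1) * np.sqrt(u2) / np.where(total > 0, total, 1.0),
                     0.0)
    T = alpha * u1 + beta * u2
    D = np.sqrt(C * T)
    if C.ndim == 0:
        return CouplingResult(float(C), float(T), float(D))
    return CouplingResult(C, T, D)


def composite_ndi(infi: float, ci: float, inni: float,
                  weights: Sequence[float] = DEFAULT_NDI_WEIGHTS) -> NDIRecord:
    """Aggregate NDI as the expert-weighted sum of the three sub-indices
    (defaults 0.4, 0.3, 0.3 for information, convergence, innovation)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (3,) or np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-12:
        raise ValidationError("weights must be 3 nonnegative values summing to 1")
    for name, v in (("infi", infi), ("ci", ci), ("inni", inni)):
        if not 0 <= v <= 1:
            raise ValidationError(f"sub-index {name} must lie in [0, 1], got {v}")
    ndi = float(weights[0] * infi + weights[1] * ci + weights[2] * inni)
    return NDIRecord(infi=float(infi), ci=float(ci), inni=float(inni), ndi=ndi)
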