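"""Panel regressions linking the digital-infrastructure index to eco-efficiency.

All estimators operate on a long province-year panel with columns
``unit, year, aee_vrs, aee_crs, ndi, infi, ci, inni, lu, aed, ps, adr, rhc,
fsa``. The estimators are:

* ``pooled_ols`` — the baseline pooled ("mixed") regression
  AEE = a0 + a1*NDI + a2'Controls + e, with optional symmetric winsorization
  of continuous variables and heteroskedasticity-robust standard errors.
* ``threshold_fit`` — a piecewise (two-regime) model in the innovation
  sub-index, AEE = b0 + b1*INNI*1[INNI<=theta] + b2*INNI*1[INNI>theta]
  + controls, with theta estimated by grid search over observed values and a
  residual-bootstrap F test for threshold existence (sequential single vs.
  double decision).
* ``moderation_fit`` — adds the urbanization interaction NDI x LU (optionally
  with year fixed effects).
* ``lagged_regressor_fit`` — replaces NDI with its within-unit one-year lag.
* ``tobit_fit`` — censored-normal maximum likelihood for a bounded outcome.
* ``iv_2sls`` — two-stage least squares with a user-supplied instrument,
  reporting the excluded-instrument first-stage F.
* ``subsample_fit`` — the same baseline on two sides of a row predicate.

Grid-search and bootstrap costs for the threshold model are kept trivial by
residualizing once on the non-threshold regressors and evaluating every
candidate threshold through a single matrix product (an exact
Frisch–Waugh reformulation, not an approximation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .exceptions import EstimationError, SingularityError, ValidationError

__all__ = [
    "CONTROL_COLS",
    "FitResult",
    "ThresholdFit",
    "TobitSpec",
    "winsorize",
    "ols",
    "pooled_ols",
    "threshold_fit",
    "moderation_fit",
    "marginal_effect",
    "lagged_regressor_fit",
    "tobit_fit",
    "iv_2sls",
    "subsample_fit",
]

CONTROL_COLS = ["aed", "ps", "adr", "rhc", "fsa"]

_OUTCOME_COLS = {"vrs": "aee_vrs", "crs": "aee_crs"}
_REGRESSOR_COLS = {"ndi": "ndi", "infi": "infi", "ci": "ci", "inni": "inni"}


@dataclass
class FitResult:
    model: str
    params: pd.Series
    se: pd.Series
    n_obs: int
    robust_se: pd.Series | None = None
    resid: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.se

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.se, "upper": self.params + z * self.se}
        )

    def summary_table(self) -> str:
        """Plain-text table: coefficient, t in parentheses, stars at 10/5/1%."""
        lines = [f"[{self.model}]  N = {self.n_obs}"]
        for name in self.params.index:
            t = self.tvalues[name]
            p = 2 * stats.norm.sf(abs(t))
            star = "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""
            lines.append(f"{name:>12}  {self.params[name]: .4f}{star:<3} ({t: .2f})")
        return "\n".join(lines)


@dataclass
class ThresholdFit:
    theta_hat: float
    regime_coefs: tuple          # (beta_low, beta_high)
    f_stat: float
    boot_p: float
    n_boot: int
    grid: np.ndarray
    n_thresholds: int
    fit: FitResult
    second: dict | None = None   # sequential double-threshold test, if run


@dataclass(frozen=True)
class TobitSpec:
    lower_bound: float = 0.0
    upper_bound: float = np.inf

    def __post_init__(self):
        if not self.lower_bound < self.upper_bound:
            raise ValidationError("Tobit lower bound must be below upper bound")


def winsorize(s: pd.Series | np.ndarray, frac: float) -> np.ndarray:
    """Symmetric two-sided winsorization: clip at the (frac, 1-frac) empirical
    quantiles. Idempotent; frac = 0 is the identity."""
    x = np.asarray(s, dtype=float)
    if frac == 0:
        return x
    return np.asarray(stats.mstats.winsorize(x, limits=(frac, frac)))


def _require_cols(df: pd.DataFrame, cols: Sequence[str]):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"panel is missing columns {missing}")


def _check_rank(X: np.ndarray, names: Sequence[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns from the diagonal of R in a pivoted QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(len(names)) if j < len(diag) and diag[j] <= tol]
        raise SingularityError(
            f"design matrix is rank deficient; collinear columns: {bad or names}", bad
        )


def ols(df: pd.DataFrame, y: str, xcols: Sequence[str], *, winsor: float = 0.0,
        add_const: bool = True, model: str = "ols") -> FitResult:
    """Least squares with conventional and HC1-robust standard errors."""
    _require_cols(df, [y, *xcols])
    yv = winsorize(df[y], winsor)
    cols = {c: winsorize(df[c], winsor) for c in xcols}
    names = list(xcols)
    X = np.column_stack([cols[c] for c in names]) if names else np.empty((len(df), 0))
    if add_const:
        X = np.column_stack([np.ones(len(df)), X])
        names = ["const", *names]
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    # HC1 sandwich
    meat = (X * resid[:, None] ** 2).T @ X
    robust = np.sqrt(np.diag(XtX_inv @ meat @ XtX_inv) * n / (n - k))
    return FitResult(
        model=model,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        robust_se=pd.Series(robust, index=names),
        n_obs=n,
        resid=resid,
        extra={"sigma2": sigma2, "ssr": float(resid @ resid)},
    )


def pooled_ols(panel: pd.DataFrame, outcome: str = "vrs", regressor: str = "ndi",
               winsor: float = 0.01, controls: Sequence[str] = CONTROL_COLS) -> FitResult:
    """Baseline pooled regression of AEE on one index plus controls."""
    if outcome not in _OUTCOME_COLS:
        raise ValidationError(f"outcome must be one of {sorted(_OUTCOME_COLS)}")
    if regressor not in _REGRESSOR_COLS:
        raise ValidationError(f"regressor must be one of {sorted(_REGRESSOR_COLS)}")
    if not 0 <= winsor <= 0.05:
        raise ValidationError("winsor fraction must lie in [0, 0.05]")
    if len(panel) < 30:
        raise ValidationError(f"pooled regression needs >= 30 rows, got {len(panel)}")
    ycol, xcol = _OUTCOME_COLS[outcome], _REGRESSOR_COLS[regressor]
    fit = ols(panel, ycol, [xcol, *controls], winsor=winsor,
              model=f"pooled_ols[{outcome}~{regressor}]")
    return fit


def _qr_basis(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > np.abs(np.diag(R)).max() * 1e-12
    return Q[:, keep]


def _regime_columns(v: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """n x G matrix whose g-th column is v * 1[v <= grid_g]."""
    return v[:, None] * (v[:, None] <= grid[None, :])


def _best_split(Zt: np.ndarray, norms: np.ndarray, y_t: np.ndarray):
    """Given residualized regime columns, return (argmax index, SSR gain array)."""
    gains = (Zt.T @ y_t) ** 2 / norms
    return int(np.argmax(gains)), gains


def threshold_fit(panel: pd.DataFrame, n_boot: int = 300, trim: float = 0.01,
                  max_thresholds: int = 2, seed: int | None = None,
                  outcome: str = "vrs", threshold_var: str = "inni",
                  controls: Sequence[str] = CONTROL_COLS) -> ThresholdFit:
    """Two-regime threshold regression with a residual-bootstrap existence test.

    The candidate grid is every distinct observed value of the threshold
    variable inside the (trim, 1-trim) quantiles. theta-hat minimizes the SSR
    of the two-regime fit; F = n (SSR_linear - SSR_threshold) / SSR_threshold,
    with its null distribution approximated by ``n_boot`` iid resamples of the
    threshold-model residuals. If the single threshold is significant at 5%
    and ``max_thresholds >= 2``, a second threshold is tested with the same
    machinery (first threshold held fixed).
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    ycol = _OUTCOME_COLS.get(outcome, outcome)
    _require_cols(panel, [ycol, threshold_var, *controls])
    rng = np.random.default_rng(seed)

    y = panel[ycol].to_numpy(float)
    v = panel[threshold_var].to_numpy(float)
    n = len(y)
    W = np.column_stack([np.ones(n), panel[controls].to_numpy(float)])

    lo, hi = np.quantile(v, [trim, 1 - trim])
    grid = np.unique(v[(v >= lo) & (v <= hi)])
    # a split at the largest grid point is no split at all
    grid = grid[grid < v.max()]
    if grid.size < 20:
        raise ValidationError(
            f"threshold variable has only {grid.size} distinct values after trimming; need >= 20"
        )

    # linear null: span(W, v); threshold alternative adds z_theta = v*1[v<=theta]
    Q1 = _qr_basis(np.column_stack([W, v]))
    Z = _regime_columns(v, grid)
    Zt = Z - Q1 @ (Q1.T @ Z)
    norms = (Zt**2).sum(axis=0)
    ok = norms > norms.max() * 1e-12
    grid, Zt, norms = grid[ok], Zt[:, ok], norms[ok]

    y_t = y - Q1 @ (Q1.T @ y)
    ssr0 = float(y_t @ y_t)
    j_hat, gains = _best_split(Zt, norms, y_t)
    theta_hat = float(grid[j_hat])
    ssr1 = ssr0 - float(gains[j_hat])
    f_stat = n * (ssr0 - ssr1) / ssr1

    # regime-coefficient fit at theta-hat
    low = v * (v <= theta_hat)
    high = v - low
    df_fit = panel.assign(_low=low, _high=high)
    fit = ols(df_fit, ycol, ["_low", "_high", *controls], model="threshold")
    fit.params.index = [f"{threshold_var}_low" if c == "_low"
                        else f"{threshold_var}_high" if c == "_high" else c
                        for c in fit.params.index]
    fit.se.index = fit.params.index
    if fit.robust_se is not None:
        fit.robust_se.index = fit.params.index

    # bootstrap the F statistic under the linear null (regressors fixed);
    # null-fitted values lie in span(Q1) and cancel from F, so resampled
    # residuals alone reproduce the null distribution of F
    e1 = fit.resid
    draws = rng.choice(e1, size=(n_boot, n), replace=True)
    f_boot = np.empty(n_boot)
    for b in range(n_boot):
        yb = draws[b]
        yb_t = yb - Q1 @ (Q1.T @ yb)
        ssr0_b = float(yb_t @ yb_t)
        gain = float(np.max((Zt.T @ yb_t) ** 2 / norms))
        f_boot[b] = n * gain / (ssr0_b - gain)
    boot_p = float(np.mean(f_boot >= f_stat))

    second = None
    n_thresholds = 1 if boot_p <= 0.05 else 0
    if boot_p <= 0.05 and max_thresholds >= 2:
        Q2 = _qr_basis(np.column_stack([W, v, v * (v <= theta_hat)]))
        Z2 = _regime_columns(v, grid)
        Z2t = Z2 - Q2 @ (Q2.T @ Z2)
        norms2 = (Z2t**2).sum(axis=0)
        ok2 = norms2 > norms2.max() * 1e-10
        grid2, Z2t, norms2 = grid[ok2], Z2t[:, ok2], norms2[ok2]
        y2_t = y - Q2 @ (Q2.T @ y)
        ssr1_full = float(y2_t @ y2_t)
        j2, gains2 = _best_split(Z2t, norms2, y2_t)
        ssr2 = ssr1_full - float(gains2[j2])
        f2 = n * (ssr1_full - ssr2) / ssr2
        # residuals of the two-threshold model for the second-stage bootstrap
        theta2 = float(grid2[j2])
        lo2, hi2 = sorted((theta_hat, theta2))
        seg1 = v * (v <= lo2)
        seg2 = v * ((v > lo2) & (v <= hi2))
        X2 = np.column_stack([W, seg1, seg2, v * (v > hi2)])
        b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
        e2 = y - X2 @ b2
        draws2 = rng.choice(e2, size=(n_boot, n), replace=True)
        f2_boot = np.empty(n_boot)
        for b in range(n_boot):
            yb_t = draws2[b] - Q2 @ (Q2.T @ draws2[b])
            ssr_b = float(yb_t @ yb_t)
            gain = float(np.max((Z2t.T @ yb_t) ** 2 / norms2))
            f2_boot[b] = n * gain / (ssr_b - gain)
        p2 = float(np.mean(f2_boot >= f2))
        second = {"theta": theta2, "f_stat": f2, "boot_p": p2}
        if p2 <= 0.05:
            n_thresholds = 2

    beta_low = float(fit.params[f"{threshold_var}_low"])
    beta_high = float(fit.params[f"{threshold_var}_high"])
    return ThresholdFit(theta_hat=theta_hat, regime_coefs=(beta_low, beta_high),
                        f_stat=float(f_stat), boot_p=boot_p, n_boot=n_boot,
                        grid=grid, n_thresholds=n_thresholds, fit=fit, second=second)


def moderation_fit(panel: pd.DataFrame, time_fe: bool = True, outcome: str = "vrs",
                   controls: Sequence[str] = CONTROL_COLS) -> FitResult:
    """Interaction model AEE ~ NDI + LU + NDI*LU + controls (+ year dummies)."""
    ycol = _OUTCOME_COLS.get(outcome, outcome)
    _require_cols(panel, [ycol, "ndi", "lu", *controls])
    df = panel.copy()
    df["ndi_lu"] = df["ndi"] * df["lu"]
    xcols = ["ndi", "lu", "ndi_lu", *controls]
    if time_fe:
        years = sorted(df["year"].unique())
        for yr in years[1:]:
            df[f"year_{yr}"] = (df["year"] == yr).astype(float)
        xcols += [f"year_{yr}" for yr in years[1:]]
    fit = ols(df, ycol, xcols, model=f"moderation[{outcome}]")
    return fit


def marginal_effect(fit: FitResult, lu: float) -> float:
    """Marginal effect of NDI at urbanization level ``lu``: a1 + a3*lu."""
    return float(fit.params["ndi"] + fit.params["ndi_lu"] * lu)


def lagged_regressor_fit(panel: pd.DataFrame, outcome: str = "vrs",
                         winsor: float = 0.0,
                         controls: Sequence[str] = CONTROL_COLS) -> FitResult:
    """Baseline regression with NDI replaced by its within-unit one-year lag;
    the first year of every unit drops out."""
    _require_cols(panel, ["unit", "year", "ndi"])
    if panel.groupby("unit")["year"].nunique().min() < 2:
        raise ValidationError("lagged regression needs >= 2 years per unit")
    df = panel.sort_values(["unit", "year"]).copy()
    df["ndi_lag"] = df.groupby("unit")["ndi"].shift(1)
    df = df.dropna(subset=["ndi_lag"])
    ycol = _OUTCOME_COLS.get(outcome, outcome)
    fit = ols(df, ycol, ["ndi_lag", *controls], winsor=winsor,
              model=f"lag1[{outcome}]")
    return fit


def tobit_fit(panel: pd.DataFrame, spec: TobitSpec = TobitSpec(),
              outcome: str = "vrs", regressor: str = "ndi",
              controls: Sequence[str] = CONTROL_COLS,
              maxiter: int = 500) -> FitResult:
    """Censored-normal (Tobit) maximum likelihood, started from OLS.

    The outcome is treated as left-censored at ``spec.lower_bound`` (and
    right-censored at ``spec.upper_bound`` when finite). With no censored
    rows the MLE coincides with OLS.
    """
    ycol = _OUTCOME_COLS.get(outcome, outcome)
    xcol = _REGRESSOR_COLS.get(regressor, regressor)
    _require_cols(panel, [ycol, xcol, *controls])
    y = panel[ycol].to_numpy(float)
    X = np.column_stack([np.ones(len(y)), panel[[xcol, *controls]].to_numpy(float)])
    names = ["const", xcol, *controls]
    _check_rank(X, names)

    lower, upper = spec.lower_bound, spec.upper_bound
    cens_lo = y <= lower
    cens_hi = y >= upper if np.isfinite(upper) else np.zeros_like(cens_lo)
    free = ~(cens_lo | cens_hi)
    n_cens = int(cens_lo.sum() + cens_hi.sum())
    if free.sum() < 10:
        raise EstimationError(
            f"Tobit is unidentified: only {int(free.sum())} uncensored rows"
        )

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta0
    theta0 = np.append(beta0, np.log(max(resid0.std(), 1e-6)))

    def negll(theta):
        beta, log_s = theta[:-1], theta[-1]
        s = np.exp(log_s)
        mu = X @ beta
        ll = 0.0
        if free.any():
            z = (y[free] - mu[free]) / s
            ll += np.sum(-0.5 * z**2 - log_s - 0.5 * np.log(2 * np.pi))
        if cens_lo.any():
            ll += np.sum(stats.norm.logcdf((lower - mu[cens_lo]) / s))
        if np.any(cens_hi):
            ll += np.sum(stats.norm.logsf((upper - mu[cens_hi]) / s))
        return -ll

    res = optimize.minimize(negll, theta0, method="BFGS",
                            options={"maxiter": maxiter, "gtol": 1e-7})
    if not np.all(np.isfinite(res.x)):
        raise EstimationError(f"Tobit MLE diverged: {res.message}")
    if not res.success and res.status != 2:  # status 2 = precision loss, usually benign
        raise EstimationError(
            f"Tobit MLE failed to converge after {maxiter} iterations: {res.message}"
        )
    theta = res.x
    H = numdiff.approx_hess(theta, negll)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"Tobit Hessian is singular: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return FitResult(
        model=f"tobit[{outcome}~{regressor}]",
        params=pd.Series(theta[:-1], index=names),
        se=pd.Series(se[:-1], index=names),
        n_obs=len(y),
        extra={"llf": -res.fun, "sigma": float(np.exp(theta[-1])),
               "n_censored": n_cens},
    )


def iv_2sls(panel: pd.DataFrame, instrument: str, outcome: str = "vrs",
            regressor: str = "ndi",
            controls: Sequence[str] = CONTROL_COLS) -> tuple[FitResult, FitResult]:
    """Two-stage least squares with one excluded instrument.

    Stage 1 regresses the endogenous index on the instrument plus controls
    and reports the excluded-instrument F (squared t of the instrument);
    stage 2 replaces the index with its fitted value. Standard errors use the
    conventional 2SLS formula (structural residuals with the *original*
    regressor). Emits a weak-instrument warning when F < 10.
    """
    ycol = _OUTCOME_COLS.get(outcome, outcome)
    xcol = _REGRESSOR_COLS.get(regressor, regressor)
    _require_cols(panel, [ycol, xcol, instrument, *controls])
    if panel[instrument].nunique() < 2:
        raise ValidationError(f"instrument {instrument!r} is constant")

    first = ols(panel, xcol, [instrument, *controls], model="iv_first_stage")
    t_iv = first.tvalues[instrument]
    f_excl = float(t_iv**2)
    first.extra["f_excluded"] = f_excl
    if f_excl < 10:
        warnings.warn(
            f"weak instrument: excluded-instrument F = {f_excl:.2f} < 10",
            UserWarning, stacklevel=2,
        )

    n = len(panel)
    W = panel[list(controls)].to_numpy(float)
    x = panel[xcol].to_numpy(float)
    y = panel[ycol].to_numpy(float)
    Xf = np.column_stack([np.ones(n), panel[instrument].to_numpy(float), W])
    x_hat = Xf @ np.linalg.lstsq(Xf, x, rcond=None)[0]
    names = ["const", xcol, *controls]
    Xh = np.column_stack([np.ones(n), x_hat, W])
    _check_rank(Xh, names)
    beta = np.linalg.lstsq(Xh, y, rcond=None)[0]
    X_orig = np.column_stack([np.ones(n), x, W])
    resid = y - X_orig @ beta
    k = Xh.shape[1]
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(Xh.T @ Xh)
    second = FitResult(
        model=f"iv_2sls[{outcome}~{regressor}]",
        params=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        n_obs=n,
        resid=resid,
        extra={"f_excluded": f_excl},
    )
    return first, second


def subsample_fit(panel: pd.DataFrame,
                  split: Callable[[pd.DataFrame], pd.Series] | pd.Series,
                  **ols_kwargs) -> tuple[FitResult, FitResult]:
    """Baseline regression on the two sides of a row predicate.

    ``split`` is a boolean mask (or a callable producing one); returns the
    fits for the True side and the False side, in that order.
    """
    mask = split(panel) if callable(split) else split
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or not mask.any():
        raise ValidationError("degenerate split: one side of the subsample is empty")
    sides = (panel.loc[mask], panel.loc[~mask])
    for tag, side in zip(("True", "False"), sides):
        if len(side) < 20:
            raise ValidationError(f"{tag} side of the split has {len(side)} rows; need >= 20")
    return tuple(pooled_ols(side, **ols_kwargs) for side in sides)
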