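"""Batch fermentation kinetics: logistic biomass growth and
Luedeking-Piret product formation.

Biomass follows the logistic ODE ``dX/dt = mu_m X (1 - X/Xm)`` whose closed
form is

    X(t) = X0 Xm e^{mu_m t} / (Xm - X0 + X0 e^{mu_m t})

Product (here enzyme activity) follows the Luedeking-Piret rate
``dP/dt = alpha dX/dt + beta X`` with growth-associated coefficient alpha
and non-growth-associated coefficient beta; integrating along the logistic
trajectory gives

    P(t) = alpha X(t) + beta (Xm/mu_m) ln((Xm - X0 + X0 e^{mu_m t}) / Xm)

so that P(0) = alpha X0 (an optional additive P0 offset is exposed).  The
(alpha, beta) pattern classifies the fermentation into Gaden's types:
I growth-associated (beta = 0), II partially growth-associated, III
non-growth-associated (alpha = 0).

Fitting is two-stage: the three logistic parameters are estimated by
nonlinear least squares; given those, the product model is linear in
(alpha, beta) and solved by linear least squares.  Polynomial meta-models
relate the fitted parameters to operating conditions (stirring speed,
temperature, inoculum size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TimeSeries",
    "LogisticParams",
    "LPParams",
    "ConditionPoint",
    "KineticFitResult",
    "ParamSurfaceFit",
    "GadenType",
    "InvalidParamsError",
    "NoProductionError",
    "UnderdeterminedDesignError",
    "logistic_curve",
    "logistic_rate",
    "fit_logistic",
    "lp_product",
    "lp_rate",
    "fit_lp",
    "classify_gaden",
    "fit_param_surface",
    "GADEN_ZERO_TOL",
]

#: default absolute tolerance below which a Luedeking-Piret coefficient is
#: treated as zero for Gaden classification (parameters are reported to
#: three decimals, so half a unit in the third decimal).
GADEN_ZERO_TOL = 0.005


class InvalidParamsError(ValueError):
    """Kinetic parameters violate their constraints."""


class NoProductionError(ValueError):
    """Both Luedeking-Piret coefficients are zero within tolerance."""


class UnderdeterminedDesignError(ValueError):
    """Fewer independent condition points than requested polynomial terms."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeSeries:
    """A sampled fermentation trajectory (time in hours, strictly increasing)."""

    t: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)

    def truncated(self, t_max: float) -> "TimeSeries":
        """Restrict to t <= t_max (e.g. to exclude the decline phase)."""
        keep = self.t <= t_max
        return TimeSeries(self.t[keep], self.y[keep], self.label)


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth parameters: inoculum X0, capacity Xm (both OD600),
    maximum specific growth rate mu_m (1/h)."""

    x0: float
    xm: float
    mu_m: float

    def __post_init__(self) -> None:
        if not (0 < self.x0 < self.xm):
            raise InvalidParamsError(
                f"need 0 < X0 < Xm, got X0={self.x0}, Xm={self.xm}"
            )
        if self.mu_m <= 0:
            raise InvalidParamsError(f"need mu_m > 0, got {self.mu_m}")


class GadenType:
    """Gaden fermentation pattern labels."""

    I = "I"
    II = "II"
    III = "III"


@dataclass(frozen=True)
class LPParams:
    """Luedeking-Piret coefficients: alpha (U/mL per OD600, growth
    associated) and beta (U/mL per OD600 per h, non-growth associated)."""

    alpha: float
    beta: float
    p0: float = 0.0
    gaden_type: str | None = None


@dataclass(frozen=True)
class ConditionPoint:
    """One operating condition: stirring speed (r/min), temperature (degC),
    inoculum size (mL)."""

    rs: float
    temp: float
    inoc: float

    def __post_init__(self) -> None:
        if min(self.rs, self.temp, self.inoc) <= 0:
            raise ValueError("all condition values must be strictly positive")


@dataclass
class KineticFitResult:
    """Outcome of a kinetic model fit."""

    params: LogisticParams | LPParams
    r_squared: float
    residual_sse: float
    converged: bool
    n_iter: int = 0
    message: str = ""


# ---------------------------------------------------------------------------
# logistic growth
# ---------------------------------------------------------------------------

def logistic_curve(p: LogisticParams, t) -> np.ndarray | float:
    """Closed-form logistic biomass at time t (hours).

    Evaluated as ``X0 Xm / (X0 + (Xm - X0) e^{-mu_m t})``, which is
    algebraically identical to the e^{+mu_m t} form but immune to overflow
    at large mu_m*t.
    """
    t_arr = np.asarray(t, dtype=float)
    x = p.x0 * p.xm / (p.x0 + (p.xm - p.x0) * np.exp(-p.mu_m * t_arr))
    return x if x.ndim else float(x)


def logistic_rate(p: LogisticParams, x) -> np.ndarray | float:
    """Instantaneous growth rate dX/dt = mu_m X (1 - X/Xm) at biomass x."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr > p.xm):
        warnings.warn(
            "biomass above Xm: negative rate lies outside the growth model",
            stacklevel=2,
        )
    r = p.mu_m * x_arr * (1.0 - x_arr / p.xm)
    return r if r.ndim else float(r)


def _logistic_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Starting values: Xm from the plateau, X0 from the first positive
    observation, mu_m from the slope of the logit transform."""
    xm0 = float(y.max()) * 1.05
    positive = y[y > 0]
    x00 = float(positive[0]) if len(positive) else 1e-3
    x00 = min(x00, 0.5 * xm0)
    inner = y / np.maximum(xm0 - y, 1e-12)
    ok = (y > 0) & (y < xm0)
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(inner[ok]), 1)[0]
        mu0 = float(abs(slope)) or 0.1
    else:
        mu0 = 0.1
    return x00, xm0, mu0


def fit_logistic(series: TimeSeries, t_max: float | None = None) -> KineticFitResult:
    """Nonlinear least-squares fit of the logistic curve to a biomass series.

    Requires at least 4 points spanning growth through plateau.  ``t_max``
    optionally truncates the series first (the logistic model does not
    represent a decline phase).
    """
    if t_max is not None:
        series = series.truncated(t_max)
    if len(series) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    t, y = series.t, series.y

    x00, xm0, mu0 = _logistic_init(t, y)

    def residual(theta):
        x0, xm, mu = theta
        return p_curve(x0, xm, mu) - y

    def p_curve(x0, xm, mu):
        return x0 * xm / (x0 + (xm - x0) * np.exp(-mu * t))

    eps = 1e-9
    res = optimize.least_squares(
        residual,
        x0=[x00, xm0, mu0],
        bounds=([eps, eps, eps], [np.inf, np.inf, np.inf]),
        method="trf",
    )
    x0_hat, xm_hat, mu_hat = res.x
    sse = float(2.0 * res.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    converged = bool(res.success) and x0_hat < xm_hat
    if not converged:
        warnings.warn(f"logistic fit did not converge: {res.message}", stacklevel=2)
    # plateau check: warn when the series never flattens
    if y[-1] < 0.9 * xm_hat:
        warnings.warn(
            "series does not reach a plateau; Xm is weakly identified",
            stacklevel=2,
        )
    params = LogisticParams(x0=float(x0_hat), xm=float(xm_hat), mu_m=float(mu_hat))
    return KineticFitResult(
        params=params,
        r_squared=r2,
        residual_sse=sse,
        converged=converged,
        n_iter=int(res.nfev),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Luedeking-Piret product formation
# ---------------------------------------------------------------------------

def _cumulative_biomass(p: LogisticParams, t: np.ndarray) -> np.ndarray:
    """Integral of X(s) ds from 0 to t along the logistic trajectory:
    (Xm/mu_m) ln((Xm - X0 + X0 e^{mu_m t}) / Xm), computed in log space."""
    u = p.mu_m * t
    log_num = np.logaddexp(u + np.log(p.x0), np.log(p.xm - p.x0))
    return (p.xm / p.mu_m) * (log_num - np.log(p.xm))


def lp_product(p: LogisticParams, q: LPParams, t) -> np.ndarray | float:
    """Integrated Luedeking-Piret product concentration at time t.

    ``P(t) = alpha X(t) + beta * integral_0^t X ds + P0``; with the default
    P0 = 0 the baseline is P(0) = alpha * X0.
    """
    t_arr = np.asarray(t, dtype=float)
    out = (
        q.alpha * np.asarray(logistic_curve(p, t_arr))
        + q.beta * _cumulative_biomass(p, t_arr)
        + q.p0
    )
    return out if out.ndim else float(out)


def lp_rate(p: LogisticParams, q: LPParams, t) -> np.ndarray | float:
    """Product formation rate dP/dt = alpha dX/dt + beta X along the curve."""
    x = logistic_curve(p, t)
    out = q.alpha * np.asarray(logistic_rate(p, x)) + q.beta * np.asarray(x)
    return out if out.ndim else float(out)


def fit_lp(
    growth: LogisticParams,
    product_series: TimeSeries,
    fit_p0: bool = False,
    gaden_tol: float = GADEN_ZERO_TOL,
    t_max: float | None = None,
) -> KineticFitResult:
    """Estimate (alpha, beta) given fitted growth parameters.

    With the logistic trajectory fixed, the integrated product model is
    linear in alpha and beta, so the fit is an exact linear least squares:
    regressors X(t) and the cumulative biomass integral (plus an optional
    intercept P0).  A flat biomass trajectory makes the two regressors
    collinear and raises an error.
    """
    if t_max is not None:
        product_series = product_series.truncated(t_max)
    t, y = product_series.t, product_series.y
    if len(t) < (3 if fit_p0 else 2):
        raise ValueError("too few points to identify the product model")

    x = np.asarray(logistic_curve(growth, t))
    cum = _cumulative_biomass(growth, t)
    cols = [x, cum] + ([np.ones_like(t)] if fit_p0 else [])
    X = np.column_stack(cols)
    # near-collinear regressors (e.g. a flat biomass trajectory) make the
    # coefficients unidentifiable; use a conservative rank tolerance
    s = np.linalg.svd(X, compute_uv=False)
    if np.sum(s > s[0] * 1e-10) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "flat biomass trajectory: alpha and beta are not identifiable"
        )
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ theta
    sse = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0

    alpha, beta = float(theta[0]), float(theta[1])
    p0 = float(theta[2]) if fit_p0 else 0.0
    try:
        gtype = classify_gaden(LPParams(alpha=alpha, beta=beta), tol=gaden_tol)
    except NoProductionError:
        gtype = None
    params = LPParams(alpha=alpha, beta=beta, p0=p0, gaden_type=gtype)
    return KineticFitResult(
        params=params, r_squared=r2, residual_sse=sse, converged=True
    )


def classify_gaden(q: LPParams, tol: float = GADEN_ZERO_TOL) -> str:
    """Gaden fermentation type from the Luedeking-Piret coefficients.

    Type I: alpha != 0, beta == 0 (growth-associated);
    type II: both nonzero (partially growth-associated);
    type III: alpha == 0, beta != 0 (non-growth-associated).
    Zero means |value| <= tol.  Raises :class:`NoProductionError` when both
    coefficients vanish.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    a_zero = abs(q.alpha) <= tol
    b_zero = abs(q.beta) <= tol
    if a_zero and b_zero:
        raise NoProductionError("alpha and beta both zero within tolerance")
    if b_zero:
        return GadenType.I
    if a_zero:
        return GadenType.III
    return GadenType.II


# ---------------------------------------------------------------------------
# parameter meta-models over operating conditions
# ---------------------------------------------------------------------------

#: recognised polynomial terms over (I = inoculum mL, T = temperature degC,
#: R = stirring speed r/min)
_TERM_VARS = {"I": "inoc", "T": "temp", "R": "rs"}


def _term_column(term: str, frame: pd.DataFrame) -> np.ndarray:
    term = term.strip()
    if term == "1":
        return np.ones(len(frame))
    if "*" in term:
        a, b = (s.strip() for s in term.split("*"))
        return _term_column(a, frame) * _term_column(b, frame)
    if term.endswith("^2") or term.endswith("2") and term[:-1] in _TERM_VARS:
        base = term[:-2] if term.endswith("^2") else term[:-1]
        return _term_column(base, frame) ** 2
    if term in _TERM_VARS:
        return frame[_TERM_VARS[term]].to_numpy(dtype=float)
    raise ValueError(f"unrecognised term {term!r}")


@dataclass
class ParamSurfaceFit:
    """Polynomial meta-model of one kinetic parameter over conditions."""

    terms: list[str]
    coefficients: np.ndarray
    rank: int
    r_squared: float
    residual_sse: float
    underdetermined: bool

    def predict(self, conditions: list[ConditionPoint]) -> np.ndarray:
        frame = _conditions_frame(conditions)
        X = np.column_stack([_term_column(t, frame) for t in self.terms])
        return X @ self.coefficients

    def coefficient_table(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.terms)


def _conditions_frame(conditions: list[ConditionPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rs": [c.rs for c in conditions],
            "temp": [c.temp for c in conditions],
            "inoc": [c.inoc for c in conditions],
        }
    )


def fit_param_surface(
    conditions: list[ConditionPoint],
    values,
    terms: list[str],
    allow_rank_deficient: bool = False,
) -> ParamSurfaceFit:
    """Least-squares polynomial meta-model of a kinetic parameter.

    ``terms`` declares the polynomial explicitly, e.g.
    ``["1", "I", "T", "R", "T^2"]``; there is no silent default model.  When
    the condition design cannot identify the requested terms (rank of the
    model matrix below the number of terms) the fit refuses unless
    ``allow_rank_deficient`` is set, in which case the minimum-norm solution
    is returned with ``underdetermined=True``.  One-factor-at-a-time designs
    in particular cannot identify a full quadratic with interactions.
    """
    y = np.asarray(values, dtype=float)
    if len(conditions) != len(y):
        raise ValueError("conditions and values differ in length")
    if not terms:
        raise ValueError("terms must be a non-empty list")
    frame = _conditions_frame(conditions)
    X = np.column_stack([_term_column(t, frame) for t in terms])
    rank = int(np.linalg.matrix_rank(X))
    under = rank < len(terms)
    if under and not allow_rank_deficient:
        raise UnderdeterminedDesignError(
            f"model matrix rank {rank} < {len(terms)} requested terms; "
            "the condition design cannot identify this polynomial "
            "(pass allow_rank_deficient=True for a minimum-norm fit)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    sse = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    return ParamSurfaceFit(
        terms=list(terms),
        coefficients=beta,
        rank=rank,
        r_squared=r2,
        residual_sse=sse,
        underdetermined=under,
    )
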