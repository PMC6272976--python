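"""Design-of-experiments analysis: Plackett-Burman screening and
second-order response-surface modelling in coded variables.

The workflow mirrors standard DOE practice for fermentation-medium
optimization:

1. A two-level Plackett-Burman (PB) design screens many medium factors in
   few runs.  Main effects are contrasts between the high- and low-level
   run means; unassigned *dummy* columns estimate the error variance, giving
   a t-test per factor.
2. The surviving factors enter a three-level Box-Behnken design (BBD); the
   response is fitted with a full quadratic polynomial in coded units

       Y = b0 + sum_i bi Xi + sum_i bii Xi^2 + sum_{i<j} bij Xi Xj

   followed by an ANOVA that splits the residual into lack-of-fit and pure
   error (from replicated center runs), and by maximization of the fitted
   surface over the coded experimental cube.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FactorSpec",
    "DesignTable",
    "PBResult",
    "QuadraticFit",
    "AnovaTable",
    "OptimumPoint",
    "InvalidSpecError",
    "DesignError",
    "SingularDesignError",
    "encode_levels",
    "decode_levels",
    "pb_effects",
    "fit_quadratic",
    "anova_quadratic",
    "optimize_quadratic",
    "relative_error",
]


class InvalidSpecError(ValueError):
    """A factor specification violates its constraints."""


class DesignError(ValueError):
    """A design matrix violates the assumptions of the requested analysis."""


class SingularDesignError(DesignError):
    """The model matrix is rank deficient for the requested model."""


# ---------------------------------------------------------------------------
# factor coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorSpec:
    """One design factor with its real-unit <-> coded-unit mapping.

    ``coded = (real - center) / halfwidth``; coded 0 is the center point and
    one coded unit equals ``halfwidth`` real units.
    """

    name: str
    center: float
    halfwidth: float
    levels: tuple[float, ...] = (-1.0, 0.0, 1.0)
    unit: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.halfwidth) or self.halfwidth <= 0:
            raise InvalidSpecError(
                f"factor {self.name!r}: halfwidth must be positive, "
                f"got {self.halfwidth}"
            )

    @classmethod
    def from_two_levels(
        cls, name: str, low: float, high: float, unit: str = ""
    ) -> "FactorSpec":
        """Spec for a two-level factor with ``low -> -1`` and ``high -> +1``."""
        if not high > low:
            raise InvalidSpecError(f"factor {name!r}: need high > low")
        return cls(
            name=name,
            center=(low + high) / 2.0,
            halfwidth=(high - low) / 2.0,
            levels=(-1.0, 1.0),
            unit=unit,
        )

    def encode(self, real_values):
        return encode_levels(self, real_values)

    def decode(self, coded_values):
        return decode_levels(self, coded_values)

    def real_levels(self) -> tuple[float, ...]:
        return tuple(self.decode(np.asarray(self.levels)).tolist())


def encode_levels(spec: FactorSpec, real_values):
    """Map real-unit factor values to coded units."""
    real = np.asarray(real_values, dtype=float)
    coded = (real - spec.center) / spec.halfwidth
    return coded if coded.ndim else float(coded)


def decode_levels(spec: FactorSpec, coded_values):
    """Map coded factor values back to real units (inverse of encode)."""
    coded = np.asarray(coded_values, dtype=float)
    real = spec.center + spec.halfwidth * coded
    return real if real.ndim else float(real)


# ---------------------------------------------------------------------------
# design table
# ---------------------------------------------------------------------------

@dataclass
class DesignTable:
    """A runs x factors coded design matrix with attached response columns.

    ``coded`` holds one column per factor (and per dummy column, for PB
    designs) in coded units; ``responses`` holds measured response values
    with one column per response.  ``uncertainties`` optionally stores the
    replicate standard deviations as printed alongside the means; they are
    carried for reporting but never used in fitting.
    """

    coded: pd.DataFrame
    responses: pd.DataFrame
    dummy_columns: tuple[str, ...] = ()
    factor_specs: dict[str, FactorSpec] = field(default_factory=dict)
    response_units: dict[str, str] = field(default_factory=dict)
    uncertainties: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.coded) != len(self.responses):
            raise DesignError("coded matrix and responses differ in length")
        if self.responses.shape[1] == 0:
            raise DesignError("at least one response column is required")
        missing = set(self.dummy_columns) - set(self.coded.columns)
        if missing:
            raise DesignError(f"dummy columns not in design: {sorted(missing)}")

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def factor_columns(self) -> list[str]:
        return [c for c in self.coded.columns if c not in self.dummy_columns]

    @property
    def replicate_groups(self) -> list[list[int]]:
        """Positional run indices grouped by identical coded rows (size > 1)."""
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(self.coded.itertuples(index=False)):
            groups.setdefault(tuple(row), []).append(i)
        return [g for g in groups.values() if len(g) > 1]

    def response(self, name: str) -> np.ndarray:
        if name not in self.responses.columns:
            raise KeyError(
                f"response {name!r} not found; have {list(self.responses.columns)}"
            )
        return self.responses[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Plackett-Burman screening
# ---------------------------------------------------------------------------

@dataclass
class PBResult:
    """Per-factor screening statistics from a two-level PB design.

    ``factors`` columns: coefficient, effect, t_value, p_value, significant.
    The error estimate comes from the dummy-column effects:
    ``SE_effect = sqrt(sum(effect_dummy^2) / n_dummies)`` with
    ``error_df = n_dummies``.  The significance threshold ``t_limit``
    defaults to the two-sided 5% Student-t quantile at ``error_df`` but can
    be overridden.
    """

    response: str
    factors: pd.DataFrame
    dummy_effects: pd.Series
    error_estimate: float
    error_df: int
    t_limit: float

    def to_frame(self) -> pd.DataFrame:
        return self.factors.copy()


_LEVEL_TOL = 1e-9


def _check_two_level_balanced(col: np.ndarray, name: str) -> None:
    high = np.isclose(col, 1.0, atol=_LEVEL_TOL)
    low = np.isclose(col, -1.0, atol=_LEVEL_TOL)
    if not np.all(high | low):
        raise DesignError(
            f"column {name!r} is not two-level coded +/-1 "
            f"(levels {np.unique(col)})"
        )
    if high.sum() != low.sum():
        raise DesignError(f"column {name!r} is unbalanced")


def _contrast_effect(col: np.ndarray, y: np.ndarray) -> float:
    return float(y[col > 0].mean() - y[col < 0].mean())


def pb_effects(
    table: DesignTable,
    response_name: str,
    t_limit: float | None = None,
    alpha: float = 0.05,
) -> PBResult:
    """Estimate PB main effects, dummy-based error, and per-factor t-tests.

    The effect of a factor is the mean response at its high level minus the
    mean at its low level; the regression coefficient is half the effect.
    Dummy columns (no real variable assigned) provide the error estimate.
    When no dummies exist the effects are still returned but t/p are NaN,
    with a warning.
    """
    y = table.response(response_name)
    coded = table.coded.to_numpy(dtype=float)
    for j, name in enumerate(table.coded.columns):
        _check_two_level_balanced(coded[:, j], name)

    effects = {
        name: _contrast_effect(table.coded[name].to_numpy(dtype=float), y)
        for name in table.coded.columns
    }
    dummy_effects = pd.Series(
        {d: effects[d] for d in table.dummy_columns}, dtype=float
    )

    n_dummies = len(table.dummy_columns)
    if n_dummies == 0:
        warnings.warn(
            "no dummy columns: error estimate unavailable, t/p omitted",
            stacklevel=2,
        )
        se_effect = np.nan
        error_df = 0
        limit = np.nan if t_limit is None else float(t_limit)
    else:
        se_effect = float(np.sqrt(np.sum(dummy_effects.to_numpy() ** 2) / n_dummies))
        error_df = n_dummies
        limit = (
            float(stats.t.ppf(1.0 - alpha / 2.0, error_df))
            if t_limit is None
            else float(t_limit)
        )

    records = []
    for name in table.factor_columns:
        eff = effects[name]
        if n_dummies and se_effect > 0:
            t_val = eff / se_effect
            p_val = 2.0 * stats.t.sf(abs(t_val), error_df)
            signif = abs(t_val) > limit
        else:
            t_val = p_val = np.nan
            signif = False
        records.append(
            {
                "factor": name,
                "coefficient": eff / 2.0,
                "effect": eff,
                "t_value": t_val,
                "p_value": p_val,
                "significant": signif,
            }
        )
    factors = pd.DataFrame.from_records(records).set_index("factor")
    return PBResult(
        response=response_name,
        factors=factors,
        dummy_effects=dummy_effects,
        error_estimate=se_effect,
        error_df=error_df,
        t_limit=limit,
    )


# ---------------------------------------------------------------------------
# quadratic response-surface model
# ---------------------------------------------------------------------------

def _quadratic_terms(factor_names: list[str]) -> list[tuple[str, tuple[int, ...]]]:
    """Term list for the full quadratic model, as (label, column index tuple).

    Order: intercept, linear, pairwise interactions (i<j), pure quadratics.
    """
    k = len(factor_names)
    terms: list[tuple[str, tuple[int, ...]]] = [("Intercept", ())]
    terms += [(factor_names[i], (i,)) for i in range(k)]
    terms += [
        (f"{factor_names[i]}:{factor_names[j]}", (i, j))
        for i, j in itertools.combinations(range(k), 2)
    ]
    terms += [(f"{factor_names[i]}^2", (i, i)) for i in range(k)]
    return terms


def _model_matrix(coded: np.ndarray, terms) -> np.ndarray:
    cols = [np.prod(coded[:, list(idx)], axis=1) if idx else np.ones(len(coded))
            for _, idx in terms]
    return np.column_stack(cols)


@dataclass
class QuadraticFit:
    """A fitted full second-order polynomial in coded variables."""

    response: str
    factor_names: list[str]
    coefficients: pd.Series  # indexed by term label
    r_squared: float
    fitted_values: np.ndarray
    residuals: np.ndarray
    n_runs: int

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    @property
    def intercept(self) -> float:
        return float(self.coefficients["Intercept"])

    def linear(self) -> np.ndarray:
        return np.array(
            [self.coefficients[n] for n in self.factor_names], dtype=float
        )

    def hessian(self) -> np.ndarray:
        """Hessian of the fitted surface: H_ii = 2*b_ii, H_ij = b_ij."""
        k = len(self.factor_names)
        H = np.zeros((k, k))
        for i in range(k):
            H[i, i] = 2.0 * self.coefficients[f"{self.factor_names[i]}^2"]
        for i, j in itertools.combinations(range(k), 2):
            b = self.coefficients[f"{self.factor_names[i]}:{self.factor_names[j]}"]
            H[i, j] = H[j, i] = b
        return H

    def predict(self, coded) -> np.ndarray | float:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        terms = _quadratic_terms(self.factor_names)
        X = _model_matrix(coded, terms)
        out = X @ self.coefficients.to_numpy()
        return float(out[0]) if out.shape == (1,) else out


def fit_quadratic(table: DesignTable, response_name: str) -> QuadraticFit:
    """Ordinary least squares fit of the full quadratic model in coded units.

    For k factors the model has 1 + k + k(k-1)/2 + k parameters (intercept,
    linear, interaction, squared).  Raises :class:`SingularDesignError`,
    naming the collinear columns, if the model matrix is rank deficient.
    """
    y = table.response(response_name)
    names = table.factor_columns
    coded = table.coded[names].to_numpy(dtype=float)
    terms = _quadratic_terms(names)
    X = _model_matrix(coded, terms)

    n_runs, n_params = X.shape
    if n_runs < n_params:
        raise DesignError(
            f"{n_runs} runs cannot identify {n_params} parameters"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < n_params:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [terms[i][0] for i in np.argsort(diag)[: n_params - rank]]
        raise SingularDesignError(
            f"model matrix rank {rank} < {n_params}; "
            f"collinear columns include {bad}"
        )

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_resid = float(resid @ resid)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_resid / ss_total if ss_total > 0 else 1.0
    return QuadraticFit(
        response=response_name,
        factor_names=names,
        coefficients=pd.Series(beta, index=[t[0] for t in terms]),
        r_squared=r2,
        fitted_values=fitted,
        residuals=resid,
        n_runs=n_runs,
    )


# ---------------------------------------------------------------------------
# ANOVA with lack-of-fit split
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """ANOVA rows for a quadratic response-surface fit.

    Per-term rows carry the extra (partial) sum of squares of the term given
    all others; on an orthogonal Box-Behnken basis this coincides with the
    sequential SS for linear and interaction terms.  ``model``, ``residual``
    and ``total`` satisfy ``SS(model) + SS(residual) == SS(total)``, and
    when replicates exist ``SS(lack-of-fit) + SS(pure-error) == SS(residual)``;
    degrees of freedom are additive the same way.
    """

    response: str
    table: pd.DataFrame  # index: source; columns: SS, df, MS, F, p

    def row(self, source: str) -> pd.Series:
        return self.table.loc[source]


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova_quadratic(fit: QuadraticFit, table: DesignTable) -> AnovaTable:
    """ANOVA of a quadratic fit, with pure-error/lack-of-fit split.

    Pure error is the within-group sum of squares over replicate groups
    (runs with identical coded rows); lack-of-fit is the remainder of the
    residual.  Without replicates only model/residual/total rows are
    returned, with a warning.
    """
    y = table.response(fit.response)
    names = fit.factor_names
    coded = table.coded[names].to_numpy(dtype=float)
    terms = _quadratic_terms(names)
    X = _model_matrix(coded, terms)

    n = len(y)
    p = X.shape[1]
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_resid = float(fit.residuals @ fit.residuals)
    ss_model = ss_total - ss_resid
    df_model, df_resid = p - 1, n - p
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    rows: list[dict] = []

    def add(source, ss, df, f=np.nan, pval=np.nan):
        ms = ss / df if df > 0 else np.nan
        rows.append({"source": source, "SS": ss, "df": df, "MS": ms,
                     "F": f, "p": pval})

    # per-term partial SS: extra SS of dropping the term from the full model
    full_sse = ss_resid
    for j, (label, idx) in enumerate(terms):
        if not idx:
            continue  # intercept carries no ANOVA row
        reduced = np.delete(X, j, axis=1)
        ss_term = _sse(reduced, y) - full_sse
        testable = df_resid > 0 and ms_resid > 0
        f = (ss_term / 1.0) / ms_resid if testable else np.nan
        pval = stats.f.sf(f, 1, df_resid) if testable else np.nan
        add(label, ss_term, 1, f, pval)

    model_testable = df_resid > 0 and ms_resid > 0
    f_model = (ss_model / df_model) / ms_resid if model_testable else np.nan
    add("model", ss_model, df_model, f_model,
        stats.f.sf(f_model, df_model, df_resid) if model_testable else np.nan)
    add("residual", ss_resid, df_resid)

    groups = table.replicate_groups
    if groups:
        ss_pe = 0.0
        df_pe = 0
        for g in groups:
            yg = y[g]
            ss_pe += float(np.sum((yg - yg.mean()) ** 2))
            df_pe += len(g) - 1
        ss_lof = ss_resid - ss_pe
        df_lof = df_resid - df_pe
        if df_lof > 0 and df_pe > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = stats.f.sf(f_lof, df_lof, df_pe)
        else:
            f_lof = p_lof = np.nan
        add("lack-of-fit", ss_lof, df_lof, f_lof, p_lof)
        add("pure-error", ss_pe, df_pe)
    else:
        warnings.warn(
            "no replicate groups: lack-of-fit split unavailable", stacklevel=2
        )

    add("total", ss_total, n - 1)
    frame = pd.DataFrame.from_records(rows).set_index("source")
    return AnovaTable(response=fit.response, table=frame)


# ---------------------------------------------------------------------------
# surface optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimumPoint:
    """Optimum of a fitted quadratic surface over a coded box."""

    coded_location: dict[str, float]
    real_location: dict[str, float]
    predicted_response: float
    on_boundary: bool
    sense: str

    def coded_vector(self) -> np.ndarray:
        return np.array(list(self.coded_location.values()), dtype=float)


def optimize_quadratic(
    fit: QuadraticFit,
    box: tuple[float, float] | dict[str, tuple[float, float]] = (-1.0, 1.0),
    sense: str = "max",
    factors: dict[str, FactorSpec] | None = None,
    n_grid_starts: int = 3,
) -> OptimumPoint:
    """Optimize a fitted quadratic surface over a coded box.

    The stationary point solves ``H x = -g`` (gradient zero).  If the
    Hessian has the right definiteness for the requested sense and the
    stationary point lies inside the box it is returned directly; otherwise
    a deterministic multistart L-BFGS-B search (grid of ``n_grid_starts``
    per axis plus the clipped stationary point) finds the constrained
    optimum, flagged ``on_boundary`` when it sits on a box face.

    ``factors`` maps factor names to :class:`FactorSpec` for decoding the
    optimum into real units; unmapped factors report the coded value.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    names = fit.factor_names
    k = len(names)
    if isinstance(box, dict):
        bounds = [tuple(map(float, box[n])) for n in names]
    else:
        lo, hi = box
        bounds = [(float(lo), float(hi))] * k
    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])

    H = fit.hessian()
    g = fit.linear()
    sign = -1.0 if sense == "max" else 1.0

    def objective(x):
        return sign * fit.predict(x)

    def gradient(x):
        return sign * (g + H @ x)

    x_best = None
    # interior stationary point, when the curvature matches the sense
    try:
        x_stat = np.linalg.solve(H, -g)
    except np.linalg.LinAlgError:
        x_stat = None
    if x_stat is not None:
        eig = np.linalg.eigvalsh(H)
        definite = np.all(eig < 0) if sense == "max" else np.all(eig > 0)
        inside = np.all(x_stat >= lower - 1e-12) and np.all(x_stat <= upper + 1e-12)
        if definite and inside:
            x_best = np.clip(x_stat, lower, upper)

    if x_best is None:
        starts = [
            np.array(s, dtype=float)
            for s in itertools.product(
                *(np.linspace(lo, hi, n_grid_starts) for lo, hi in bounds)
            )
        ]
        if x_stat is not None:
            starts.append(np.clip(x_stat, lower, upper))
        best_val = np.inf
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, jac=gradient, method="L-BFGS-B", bounds=bounds
            )
            if res.fun < best_val - 1e-12:
                best_val = res.fun
                x_best = res.x
    x_best = np.clip(x_best, lower, upper)

    tol = 1e-6
    on_boundary = bool(
        np.any(x_best <= lower + tol) or np.any(x_best >= upper - tol)
    )
    coded_loc = {n: float(v) for n, v in zip(names, x_best)}
    real_loc = {}
    for n, v in coded_loc.items():
        spec = (factors or {}).get(n)
        real_loc[n] = float(decode_levels(spec, v)) if spec else v
    return OptimumPoint(
        coded_location=coded_loc,
        real_location=real_loc,
        predicted_response=float(fit.predict(x_best)),
        on_boundary=on_boundary,
        sense=sense,
    )


def relative_error(predicted: float, observed: float) -> float:
    """|observed - predicted| / |predicted|; undefined at predicted == 0."""
    if predicted == 0:
        raise ZeroDivisionError("relative error undefined for predicted == 0")
    return abs(observed - predicted) / abs(predicted)
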