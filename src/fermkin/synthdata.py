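"""Synthetic-data generators with the statistical structure the analysis
assumes, so every pipeline stage is testable without measured data.

Two generators are provided:

* :func:`simulate_fermentation` draws a noisy logistic biomass curve and a
  Luedeking-Piret product curve on the study's sampling grid (samples every
  4 h over a 72 h batch).
* :func:`simulate_doe` evaluates a declared quadratic surface on a coded
  design matrix and adds response noise, emulating a response-surface
  experiment with replicated center runs.

Noise is additive homoscedastic Gaussian; the default standard deviations
are calibrated to the replicate spread of the packaged center points
(about 5.9 U/mL for enzyme activity, 0.0034 OD600 for biomass).  A seed is
mandatory for every stochastic call; a fixed seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe import DesignTable, QuadraticFit, _model_matrix, _quadratic_terms
from .kinetics import LogisticParams, LPParams, TimeSeries, logistic_curve, lp_product

__all__ = [
    "FermentationTruth",
    "default_time_grid",
    "simulate_fermentation",
    "simulate_doe",
    "box_behnken",
    "EA_NOISE_SD",
    "BM_NOISE_SD",
    "BIOMASS_NOISE_SD",
    "PRODUCT_NOISE_SD",
]

#: response noise calibrated to the center-point replicate spread of the
#: packaged Box-Behnken table
EA_NOISE_SD = 5.9
BM_NOISE_SD = 0.0034
#: trajectory noise for fermentation time series (OD600 and U/mL)
BIOMASS_NOISE_SD = 0.01
PRODUCT_NOISE_SD = 3.0


def default_time_grid() -> np.ndarray:
    """Sampling grid of the batch fermentations: every 4 h over 0-72 h."""
    return np.arange(0.0, 73.0, 4.0)


@dataclass(frozen=True)
class FermentationTruth:
    """Ground-truth parameter set for one simulated fermentation."""

    growth: LogisticParams
    product: LPParams
    t: np.ndarray = field(default_factory=default_time_grid)
    biomass_noise_sd: float = BIOMASS_NOISE_SD
    product_noise_sd: float = PRODUCT_NOISE_SD

    def __post_init__(self) -> None:
        if self.biomass_noise_sd < 0 or self.product_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def simulate_fermentation(
    truth: FermentationTruth, seed: int
) -> tuple[TimeSeries, TimeSeries]:
    """Noisy biomass and product trajectories from one truth parameter set.

    Returns ``(biomass, product)`` time series: the closed-form model values
    plus independent Gaussian noise.  With zero noise the output equals the
    models exactly.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(truth.t, dtype=float)
    x = np.asarray(logistic_curve(truth.growth, t))
    p = np.asarray(lp_product(truth.growth, truth.product, t))
    x_noisy = x + rng.normal(0.0, truth.biomass_noise_sd, size=t.shape)
    p_noisy = p + rng.normal(0.0, truth.product_noise_sd, size=t.shape)
    return (
        TimeSeries(t, x_noisy, label="biomass OD600"),
        TimeSeries(t, p_noisy, label="enzyme activity U/mL"),
    )


def box_behnken(n_factors: int = 4, n_center: int = 5) -> pd.DataFrame:
    """Coded Box-Behnken design matrix: all (+/-1, +/-1) combinations on
    each factor pair with the rest at 0, plus replicated center runs."""
    if n_factors < 3:
        raise ValueError("a Box-Behnken design needs at least 3 factors")
    names = [f"X{i + 1}" for i in range(n_factors)]
    rows = []
    # pair order matches the packaged 4-factor table where applicable
    if n_factors == 4:
        pairs = [(0, 1), (2, 3), (0, 3), (1, 2), (0, 2), (1, 3)]
    else:
        pairs = [(i, j) for i in range(n_factors) for j in range(i + 1, n_factors)]
    for i, j in pairs:
        # first factor of the pair varies fastest
        for b in (-1.0, 1.0):
            for a in (-1.0, 1.0):
                row = [0.0] * n_factors
                row[i], row[j] = a, b
                rows.append(row)
    rows += [[0.0] * n_factors] * n_center
    return pd.DataFrame(rows, columns=names)


def simulate_doe(
    surface: QuadraticFit | dict[str, float],
    design: pd.DataFrame,
    noise_sd: float,
    seed: int,
    response_name: str = "Y",
    factor_names: list[str] | None = None,
) -> DesignTable:
    """Quadratic-surface responses on a coded design, with Gaussian noise.

    ``surface`` is either a fitted :class:`QuadraticFit` (its coefficients
    are reused as truth) or a mapping from term labels (``Intercept``,
    ``X1``, ``X1:X2``, ``X1^2`` ...) to coefficients.  Replicated rows share
    the same truth mean and differ only by noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(surface, QuadraticFit):
        names = surface.factor_names
        coeffs = surface.coefficients
    else:
        names = factor_names or [c for c in design.columns]
        terms = _quadratic_terms(names)
        labels = [lab for lab, _ in terms]
        unknown = set(surface) - set(labels)
        if unknown:
            raise ValueError(
                f"coefficient labels {sorted(unknown)} do not match the "
                f"quadratic terms of factors {names}"
            )
        coeffs = pd.Series({lab: surface.get(lab, 0.0) for lab in labels})

    coded = design[names].to_numpy(dtype=float)
    X = _model_matrix(coded, _quadratic_terms(names))
    mean = X @ coeffs.to_numpy()
    rng = np.random.default_rng(seed)
    y = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    return DesignTable(
        coded=design[names].reset_index(drop=True),
        responses=pd.DataFrame({response_name: y}),
    )
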