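"""Response-surface (selection-gradient) regressions on nutrient intake.

Linear model:      R = alpha + beta_P * P + beta_C * C + eps
Quadratic model:   R = alpha + beta_P * P + beta_C * C
                       + gamma_PP * P^2 + gamma_CC * C^2 + gamma_PC * P*C + eps

Responses are Z-transformed before fitting (mean 0, SD 1) so that surfaces
measured in different units are comparable; predictors stay on their raw
ug/day scale by default. In the quadratic model the linear terms are kept
so the nonlinear gradients are estimated net of linear effects, but they
are not themselves interpreted (flagged in the fit metadata). Negative
quadratic gradients indicate a peak of the response surface, positive ones
a trough; the correlational gradient gamma_PC measures how the nutrient
covariance shifts the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SurfaceData",
    "GradientFit",
    "StationaryPoint",
    "z_transform",
    "fit_linear",
    "fit_quadratic",
    "stationary_point",
]

LINEAR_TERMS = ("intercept", "P", "C")
QUADRATIC_TERMS = ("intercept", "P", "C", "P2", "C2", "PC")


def z_transform(values) -> np.ndarray:
    """Standardise to mean 0 and sample SD 1 (ddof = 1), order preserved."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("Z-transformation needs at least two values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("Z-transformation undefined for zero-variance input")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class SurfaceData:
    """Per-diet response values over the (P, C) intake plane.

    ``P`` and ``C`` are mean intakes in ug/day; ``response`` is typically a
    Z-transformed pace or shape value.
    """

    P: np.ndarray
    C: np.ndarray
    response: np.ndarray
    response_name: str = "response"

    def __post_init__(self) -> None:
        p = np.asarray(self.P, dtype=float).ravel()
        c = np.asarray(self.C, dtype=float).ravel()
        r = np.asarray(self.response, dtype=float).ravel()
        if not (p.size == c.size == r.size):
            raise ValueError("P, C and response must have equal lengths")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(c)) and np.all(np.isfinite(r))):
            raise ValueError("P, C and response must be finite")
        if np.any(p < 0) or np.any(c < 0):
            raise ValueError("intakes must be non-negative")
        object.__setattr__(self, "P", p)
        object.__setattr__(self, "C", c)
        object.__setattr__(self, "response", r)

    @property
    def n(self) -> int:
        return self.P.size

    @classmethod
    def from_summary(
        cls,
        summary: pd.DataFrame,
        response: str,
        standardize: bool = True,
        standardize_predictors: bool = False,
    ) -> "SurfaceData":
        """Build from a per-diet summary table (see :mod:`paceshape.metrics`).

        ``standardize`` Z-transforms the response (the default analysis
        scale); ``standardize_predictors`` optionally does the same to the
        intakes.
        """
        r = summary[response].to_numpy(dtype=float)
        p = summary["mean_protein"].to_numpy(dtype=float)
        c = summary["mean_carb"].to_numpy(dtype=float)
        if standardize:
            r = z_transform(r)
        if standardize_predictors:
            p, c = z_transform(p), z_transform(c)
        return cls(P=p, C=c, response=r, response_name=response)


@dataclass(frozen=True)
class GradientFit:
    """OLS fit of a linear or quadratic nutritional response surface."""

    model_level: str
    response_name: str
    n: int
    coefficients: pd.Series
    standard_errors: pd.Series
    t_statistics: pd.Series
    p_values: pd.Series
    residual_df: int
    ss_residual: float
    ss_model: float
    cov: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def linear_gradient(self) -> np.ndarray:
        """The linear gradient vector (beta_P, beta_C)."""
        return self.coefficients.loc[["P", "C"]].to_numpy()

    def linear_gradient_cov(self) -> np.ndarray:
        """Sampling covariance of (beta_P, beta_C)."""
        return self.cov.loc[["P", "C"], ["P", "C"]].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: term, coefficient, SE, t, df, p."""
        return pd.DataFrame(
            {
                "response": self.response_name,
                "model": self.model_level,
                "term": self.coefficients.index,
                "coefficient": self.coefficients.to_numpy(),
                "se": self.standard_errors.to_numpy(),
                "t": self.t_statistics.to_numpy(),
                "df": self.residual_df,
                "p": self.p_values.to_numpy(),
            }
        )


def _design(data: SurfaceData, terms: tuple[str, ...]) -> pd.DataFrame:
    cols = {
        "intercept": np.ones(data.n),
        "P": data.P,
        "C": data.C,
        "P2": data.P**2,
        "C2": data.C**2,
        "PC": data.P * data.C,
    }
    return pd.DataFrame({t: cols[t] for t in terms})


def _fit(data: SurfaceData, terms: tuple[str, ...], level: str, min_n: int) -> GradientFit:
    if data.n < min_n:
        raise ValueError(f"{level} fit needs at least {min_n} rows, got {data.n}")
    X = _design(data, terms)
    if np.linalg.matrix_rank(X.to_numpy()) < len(terms):
        raise ValueError(
            f"design matrix for the {level} model is rank-deficient "
            "(degenerate diet design, e.g. proportional P and C)"
        )
    res = sm.OLS(data.response, X).fit()
    metadata = {}
    if level == "quadratic_full":
        metadata["linear_terms_note"] = (
            "linear terms included so nonlinear gradients are net of linear "
            "effects; not for interpretation in this model"
        )
    return GradientFit(
        model_level=level,
        response_name=data.response_name,
        n=data.n,
        coefficients=res.params,
        standard_errors=res.bse,
        t_statistics=res.tvalues,
        p_values=res.pvalues,
        residual_df=int(res.df_resid),
        ss_residual=float(res.ssr),
        ss_model=float(res.ess),
        cov=res.cov_params(),
        metadata=metadata,
    )


def fit_linear(data: SurfaceData) -> GradientFit:
    """OLS fit of the linear gradients beta_P, beta_C (residual df n - 3)."""
    return _fit(data, LINEAR_TERMS, "linear", min_n=4)


def fit_quadratic(data: SurfaceData) -> GradientFit:
    """OLS fit of the full quadratic surface (residual df n - 6)."""
    return _fit(data, QUADRATIC_TERMS, "quadratic_full", min_n=7)


@dataclass(frozen=True)
class StationaryPoint:
    """Stationary point of a fitted quadratic surface."""

    P: float
    C: float
    kind: str  # "max", "min" or "saddle"


def stationary_point(fit: GradientFit) -> StationaryPoint | None:
    """Solve grad R = 0 for a quadratic fit and classify the point.

    The Hessian is ``[[2 gamma_PP, gamma_PC], [gamma_PC, 2 gamma_CC]]``;
    eigenvalue signs classify the point. Returns ``None`` (with a warning)
    when the Hessian is singular.
    """
    if fit.model_level != "quadratic_full":
        raise ValueError("stationary_point requires a quadratic fit")
    coef = fit.coefficients
    H = np.array(
        [
            [2.0 * coef["P2"], coef["PC"]],
            [coef["PC"], 2.0 * coef["C2"]],
        ]
    )
    eig = np.linalg.eigvalsh(H)
    scale = max(np.max(np.abs(eig)), 1e-300)
    if np.min(np.abs(eig)) < 1e-10 * scale:
        warnings.warn("singular Hessian: quadratic surface is degenerate, no stationary point")
        return None
    point = np.linalg.solve(H, -coef.loc[["P", "C"]].to_numpy())
    if np.all(eig > 0):
        kind = "min"
    elif np.all(eig < 0):
        kind = "max"
    else:
        kind = "saddle"
    return StationaryPoint(P=float(point[0]), C=float(point[1]), kind=kind)
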