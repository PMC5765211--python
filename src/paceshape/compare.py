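"""Statistical comparison of two nutritional landscapes.

Two tools:

1. Sequential model building. Both (Z-transformed) responses are stacked
   over the shared diet design with a two-level trait indicator, and nested
   OLS models are compared with partial F-tests at three levels, each
   reduced model carrying all terms from the previous levels:

   - linear:        do the traits share linear gradients? Adds trait:P and
     trait:C to a model with common slopes (and a trait intercept).
   - quadratic:     adds shared P^2 and C^2 plus trait:P^2 and trait:C^2.
   - correlational: adds the shared P*C term plus trait:P*C.

   F = ((SS_R - SS_C)/df1) / (SS_C/df2) with SS_R, SS_C the residual sums
   of squares of the reduced and complete models. Where a level is
   significant, univariate follow-ups drop one trait interaction at a time
   from the complete model to attribute the difference to P or C.

2. The angle theta = arccos(a.b / (|a||b|)) between the two traits' linear
   gradient vectors, with a 95% interval obtained by resampling coefficient
   vectors from each fit's multivariate-normal sampling distribution
   (a nonparametric bootstrap over diets is available as an alternative).
   theta = 0 means the nutritional optima lie in the same direction of the
   (P, C) plane; theta = 180 is maximal divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .surface import GradientFit, SurfaceData, fit_linear, z_transform

__all__ = [
    "LevelTest",
    "FollowUp",
    "ComparisonResult",
    "AngleResult",
    "sequential_compare",
    "vector_angle",
    "angle_credible_interval",
]

LEVELS = ("linear", "quadratic", "correlational")


@dataclass(frozen=True)
class LevelTest:
    level: str
    ss_reduced: float
    ss_complete: float
    df1: int
    df2: int
    f_statistic: float
    p_value: float


@dataclass(frozen=True)
class FollowUp:
    level: str
    nutrient: str
    df1: int
    df2: int
    f_statistic: float
    p_value: float


@dataclass(frozen=True)
class ComparisonResult:
    levels: dict
    follow_ups: list
    n_rows: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        """Level table with SS_R, SS_C, DF1, DF2, F and P columns."""
        rows = []
        for name in LEVELS:
            lt = self.levels.get(name)
            if lt is None:
                continue
            rows.append(
                {
                    "level": lt.level,
                    "ss_reduced": lt.ss_reduced,
                    "ss_complete": lt.ss_complete,
                    "df1": lt.df1,
                    "df2": lt.df2,
                    "F": lt.f_statistic,
                    "p": lt.p_value,
                }
            )
        return pd.DataFrame(rows)

    def follow_ups_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "level": fu.level,
                    "nutrient": fu.nutrient,
                    "df1": fu.df1,
                    "df2": fu.df2,
                    "F": fu.f_statistic,
                    "p": fu.p_value,
                }
                for fu in self.follow_ups
            ],
            columns=["level", "nutrient", "df1", "df2", "F", "p"],
        )


@dataclass(frozen=True)
class AngleResult:
    theta: float
    ci_lower: float
    ci_upper: float
    n_draws: int
    seed: int
    method: str = "parametric"


def _check_same_grid(a: SurfaceData, b: SurfaceData) -> None:
    if a.n != b.n:
        raise ValueError("the two datasets cover different numbers of diets")
    pa = np.lexsort((a.C, a.P))
    pb = np.lexsort((b.C, b.P))
    if not (
        np.allclose(a.P[pa], b.P[pb]) and np.allclose(a.C[pa], b.C[pb])
    ):
        raise ValueError("the two datasets must share the same diet grid (P, C points)")


# term -> builder over (P, C, trait indicator)
_TERM_BUILDERS = {
    "1": lambda P, C, T: np.ones_like(P),
    "trait": lambda P, C, T: T,
    "P": lambda P, C, T: P,
    "C": lambda P, C, T: C,
    "trait:P": lambda P, C, T: T * P,
    "trait:C": lambda P, C, T: T * C,
    "P2": lambda P, C, T: P**2,
    "C2": lambda P, C, T: C**2,
    "trait:P2": lambda P, C, T: T * P**2,
    "trait:C2": lambda P, C, T: T * C**2,
    "PC": lambda P, C, T: P * C,
    "trait:PC": lambda P, C, T: T * P * C,
}

_REDUCED_TERMS = {
    "linear": ["1", "trait", "P", "C"],
    "quadratic": ["1", "trait", "P", "C", "trait:P", "trait:C", "P2", "C2"],
    "correlational": [
        "1", "trait", "P", "C", "trait:P", "trait:C",
        "P2", "C2", "trait:P2", "trait:C2", "PC",
    ],
}

_LEVEL_INTERACTIONS = {
    "linear": ["trait:P", "trait:C"],
    "quadratic": ["trait:P2", "trait:C2"],
    "correlational": ["trait:PC"],
}

_FOLLOW_UP_NUTRIENT = {
    "trait:P": "P", "trait:C": "C",
    "trait:P2": "P", "trait:C2": "C",
}


def _build_X(terms, P, C, T) -> np.ndarray:
    return np.column_stack([_TERM_BUILDERS[t](P, C, T) for t in terms])


def _rss(X: np.ndarray, y: np.ndarray) -> float | None:
    """Residual sum of squares of an OLS fit; None if rank-deficient."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    resid = y - X @ coef
    return float(resid @ resid)


def sequential_compare(
    data_A: SurfaceData,
    data_B: SurfaceData,
    alpha: float = 0.05,
    standardize: bool = True,
) -> ComparisonResult:
    """Partial F-tests for shared linear, quadratic and correlational gradients.

    Both responses are Z-transformed (idempotent if already standardised)
    and stacked over the common diet grid. Levels whose complete model is
    rank-deficient or leaves no residual df are skipped with a warning.
    Univariate per-nutrient follow-ups are run at levels significant at
    ``alpha``.
    """
    _check_same_grid(data_A, data_B)
    yA = z_transform(data_A.response) if standardize else data_A.response
    yB = z_transform(data_B.response) if standardize else data_B.response
    P = np.concatenate([data_A.P, data_B.P])
    C = np.concatenate([data_A.C, data_B.C])
    T = np.concatenate([np.zeros(data_A.n), np.ones(data_B.n)])
    y = np.concatenate([yA, yB])
    n = y.size

    levels: dict = {}
    follow_ups: list = []
    for level in LEVELS:
        reduced_terms = _REDUCED_TERMS[level]
        interactions = _LEVEL_INTERACTIONS[level]
        complete_terms = reduced_terms + interactions
        df1 = len(interactions)
        df2 = n - len(complete_terms)
        if df2 < 1:
            warnings.warn(f"{level} level skipped: no residual degrees of freedom")
            levels[level] = None
            continue
        X_complete = _build_X(complete_terms, P, C, T)
        ss_complete = _rss(X_complete, y)
        if ss_complete is None:
            warnings.warn(f"{level} level skipped: complete model is rank-deficient")
            levels[level] = None
            continue
        ss_reduced = _rss(_build_X(reduced_terms, P, C, T), y)
        if ss_reduced is None:
            warnings.warn(f"{level} level skipped: reduced model is rank-deficient")
            levels[level] = None
            continue
        num = max(ss_reduced - ss_complete, 0.0) / df1
        f = num / (ss_complete / df2) if ss_complete > 0 else (0.0 if num == 0 else np.inf)
        p = float(stats.f.sf(f, df1, df2))
        levels[level] = LevelTest(
            level=level,
            ss_reduced=ss_reduced,
            ss_complete=ss_complete,
            df1=df1,
            df2=df2,
            f_statistic=float(f),
            p_value=p,
        )
        if p < alpha and len(interactions) > 1:
            for term in interactions:
                sub_terms = [t for t in complete_terms if t != term]
                ss_drop = _rss(_build_X(sub_terms, P, C, T), y)
                if ss_drop is None:
                    continue
                f_u = max(ss_drop - ss_complete, 0.0) / (ss_complete / df2)
                follow_ups.append(
                    FollowUp(
                        level=level,
                        nutrient=_FOLLOW_UP_NUTRIENT[term],
                        df1=1,
                        df2=df2,
                        f_statistic=float(f_u),
                        p_value=float(stats.f.sf(f_u, 1, df2)),
                    )
                )
    return ComparisonResult(levels=levels, follow_ups=follow_ups, n_rows=n, alpha=alpha)


def vector_angle(a, b) -> float:
    """Angle in degrees, in [0, 180], between two linear gradient vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0:
        raise ValueError("first gradient vector has zero norm; angle undefined")
    if nb == 0:
        raise ValueError("second gradient vector has zero norm; angle undefined")
    cosine = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def _psd_factor(cov: np.ndarray, label: str) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{label}: coefficient covariance must be symmetric 2x2")
    w, V = np.linalg.eigh(cov)
    scale = max(np.max(np.abs(w)), 1.0)
    if np.min(w) < -1e-10 * scale:
        raise ValueError(f"{label}: coefficient covariance is not positive semi-definite")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def angle_credible_interval(
    fit_A: GradientFit,
    fit_B: GradientFit,
    n_draws: int = 10_000,
    seed: int = 0,
    method: str = "parametric",
    data_A: SurfaceData | None = None,
    data_B: SurfaceData | None = None,
) -> AngleResult:
    """95% interval for the angle between two linear gradient vectors.

    The point estimate is the plug-in angle between the fitted vectors.
    ``method="parametric"`` resamples (beta_P, beta_C) from each fit's
    multivariate-normal sampling distribution; ``method="bootstrap"``
    refits both surfaces on diets resampled with replacement (requires
    ``data_A``/``data_B``). The interval is the 2.5%/97.5% quantile range
    of the resampled angles, widened if necessary to include the point
    estimate. Deterministic given ``seed``.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for a stable 95% interval")
    a, b = fit_A.linear_gradient(), fit_B.linear_gradient()
    theta = vector_angle(a, b)
    rng = np.random.default_rng(seed)

    if method == "parametric":
        La = _psd_factor(fit_A.linear_gradient_cov(), "first fit")
        Lb = _psd_factor(fit_B.linear_gradient_cov(), "second fit")
        draws_a = a + rng.standard_normal((n_draws, 2)) @ La.T
        draws_b = b + rng.standard_normal((n_draws, 2)) @ Lb.T
    elif method == "bootstrap":
        if data_A is None or data_B is None:
            raise ValueError("bootstrap method requires data_A and data_B")
        draws_a = np.empty((n_draws, 2))
        draws_b = np.empty((n_draws, 2))
        for i in range(n_draws):
            idx = rng.integers(0, data_A.n, size=data_A.n)
            draws_a[i] = fit_linear(
                SurfaceData(data_A.P[idx], data_A.C[idx], data_A.response[idx])
            ).linear_gradient()
            idx = rng.integers(0, data_B.n, size=data_B.n)
            draws_b[i] = fit_linear(
                SurfaceData(data_B.P[idx], data_B.C[idx], data_B.response[idx])
            ).linear_gradient()
    else:
        raise ValueError(f"unknown method {method!r}")

    na = np.linalg.norm(draws_a, axis=1)
    nb = np.linalg.norm(draws_b, axis=1)
    ok = (na > 0) & (nb > 0)
    if not np.all(ok):
        warnings.warn("zero-norm resampled gradient vectors dropped from the interval")
    cosine = np.clip(
        np.einsum("ij,ij->i", draws_a[ok], draws_b[ok]) / (na[ok] * nb[ok]), -1.0, 1.0
    )
    angles = np.degrees(np.arccos(cosine))
    lo, hi = np.quantile(angles, [0.025, 0.975])
    return AngleResult(
        theta=theta,
        ci_lower=float(min(lo, theta)),
        ci_upper=float(max(hi, theta)),
        n_draws=int(n_draws),
        seed=int(seed),
        method=method,
    )
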