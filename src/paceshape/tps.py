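"""Thin-plate-spline nutritional landscapes with GCV smoothing selection.

A penalised thin-plate spline in two dimensions:

    f(x) = d0 + d1*P + d2*C + sum_i w_i * phi(|x - x_i|),   phi(r) = r^2 log r

with side condition T' w = 0 (T the affine design) and penalty
lambda * w' K w. The coefficients solve the bordered linear system

    [[K + lambda*I, T], [T', 0]] [w; d] = [y; 0].

lambda = 0 interpolates distinct data points; lambda -> infinity collapses
to the ordinary least-squares affine plane (the penalty null space). The
smoothing parameter is chosen by minimising the generalised
cross-validation score GCV(lambda) = n * RSS / (n - tr H)^2 over a
log-spaced grid, where H is the hat matrix mapping y to fitted values.
Coordinates are centred and scaled to unit variance internally so the
lambda grid is comparable across datasets; predictions are returned on the
original intake scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist

from .surface import SurfaceData

__all__ = [
    "ThinPlateSpline",
    "LandscapeGrid",
    "fit_tps",
    "predict_grid",
    "write_grid",
    "plot_landscape",
    "DEFAULT_LAMBDA_GRID",
]

#: Log-spaced smoothing-parameter search grid for GCV.
DEFAULT_LAMBDA_GRID = np.logspace(-6, 4, 60)


def _basis(r: np.ndarray) -> np.ndarray:
    # r^2 log r, continuous 0 at r = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
    return out


@dataclass
class ThinPlateSpline:
    """Fitted penalised thin-plate spline over the (P, C) plane."""

    centers: np.ndarray        # scaled data coordinates, (n, 2)
    w: np.ndarray              # radial coefficients, (n,)
    d: np.ndarray              # affine coefficients, (3,)
    lambda_: float
    gcv_score: float
    coord_mean: np.ndarray
    coord_scale: np.ndarray
    P: np.ndarray              # raw coordinates kept for grids / hull masks
    C: np.ndarray
    y: np.ndarray
    response_name: str

    def predict(self, P, C) -> np.ndarray:
        """Evaluate the fitted surface at raw (P, C) intakes."""
        pts = np.column_stack(
            [np.asarray(P, dtype=float).ravel(), np.asarray(C, dtype=float).ravel()]
        )
        pts = (pts - self.coord_mean) / self.coord_scale
        E = _basis(cdist(pts, self.centers))
        Tn = np.column_stack([np.ones(len(pts)), pts])
        return E @ self.w + Tn @ self.d


def _solve(K: np.ndarray, T: np.ndarray, y: np.ndarray, lam: float):
    n = K.shape[0]
    M = np.zeros((n + 3, n + 3))
    M[:n, :n] = K + lam * np.eye(n)
    M[:n, n:] = T
    M[n:, :n] = T.T
    rhs = np.concatenate([y, np.zeros(3)])
    sol = np.linalg.solve(M, rhs)
    return sol[:n], sol[n:], M


def _hat_matrix(K: np.ndarray, T: np.ndarray, M: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    Minv = np.linalg.inv(M)
    return np.hstack([K, T]) @ Minv[:, :n]


def fit_tps(
    data: SurfaceData,
    lam: float | str = "gcv",
    lambda_grid: np.ndarray | None = None,
) -> ThinPlateSpline:
    """Fit a thin-plate spline; ``lam="gcv"`` selects lambda by GCV.

    Requires at least four non-collinear design points. A GCV minimum at
    either end of the search grid triggers a warning (possible under- or
    over-smoothing).
    """
    n = data.n
    if n < 4:
        raise ValueError("thin-plate spline needs at least 4 design points")
    pts_raw = np.column_stack([data.P, data.C])
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), pts_raw])) < 3:
        raise ValueError("degenerate design: intake points are collinear")

    mean = pts_raw.mean(axis=0)
    scale = pts_raw.std(axis=0)
    scale[scale == 0] = 1.0
    pts = (pts_raw - mean) / scale

    K = _basis(cdist(pts, pts))
    T = np.column_stack([np.ones(n), pts])
    y = data.response

    def gcv_at(l: float) -> float:
        w, d, M = _solve(K, T, y, l)
        H = _hat_matrix(K, T, M)
        resid = y - H @ y
        denom = n - np.trace(H)
        if denom <= 1e-10:
            return np.inf
        return float(n * (resid @ resid) / denom**2)

    if isinstance(lam, str):
        if lam != "gcv":
            raise ValueError(f"unknown smoothing rule {lam!r}")
        grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
        scores = np.array([gcv_at(l) for l in grid])
        i = int(np.argmin(scores))
        if i in (0, len(grid) - 1):
            warnings.warn(
                "GCV minimum at the boundary of the lambda grid; the fit may be "
                "under- or over-smoothed"
            )
        lam_val, gcv_score = float(grid[i]), float(scores[i])
    else:
        lam_val = float(lam)
        if lam_val < 0:
            raise ValueError("lambda must be non-negative")
        gcv_score = gcv_at(lam_val)

    w, d, _ = _solve(K, T, y, lam_val)
    return ThinPlateSpline(
        centers=pts,
        w=w,
        d=d,
        lambda_=lam_val,
        gcv_score=gcv_score,
        coord_mean=mean,
        coord_scale=scale,
        P=data.P.copy(),
        C=data.C.copy(),
        y=y.copy(),
        response_name=data.response_name,
    )


@dataclass
class LandscapeGrid:
    """Rectangular prediction grid over the observed intake range."""

    p_axis: np.ndarray
    c_axis: np.ndarray
    surface: np.ndarray  # shape (len(c_axis), len(p_axis)); NaN outside hull
    lambda_: float
    gcv_score: float
    response_name: str = "response"

    def to_frame(self) -> pd.DataFrame:
        """Long format: protein, carb, value (masked cells dropped)."""
        PP, CC = np.meshgrid(self.p_axis, self.c_axis)
        df = pd.DataFrame(
            {"protein": PP.ravel(), "carb": CC.ravel(), "value": self.surface.ravel()}
        )
        return df.dropna(subset=["value"]).reset_index(drop=True)


def predict_grid(
    spline: ThinPlateSpline, resolution: int = 50, mask_hull: bool = True
) -> LandscapeGrid:
    """Evaluate a fitted spline on a regular grid spanning the data.

    ``mask_hull`` (default on) sets grid cells outside the convex hull of
    the observed intakes to NaN, so the landscape shows no pure
    extrapolation.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    p_axis = np.linspace(spline.P.min(), spline.P.max(), resolution)
    c_axis = np.linspace(spline.C.min(), spline.C.max(), resolution)
    PP, CC = np.meshgrid(p_axis, c_axis)
    values = spline.predict(PP.ravel(), CC.ravel())
    surface = values.reshape(resolution, resolution)
    if mask_hull:
        tri = Delaunay(np.column_stack([spline.P, spline.C]))
        inside = tri.find_simplex(np.column_stack([PP.ravel(), CC.ravel()])) >= 0
        surface = np.where(inside.reshape(surface.shape), surface, np.nan)
    return LandscapeGrid(
        p_axis=p_axis,
        c_axis=c_axis,
        surface=surface,
        lambda_=spline.lambda_,
        gcv_score=spline.gcv_score,
        response_name=spline.response_name,
    )


def write_grid(grid: LandscapeGrid, path) -> None:
    """Write a landscape grid as long-format CSV (protein, carb, value)."""
    grid.to_frame().to_csv(path, index=False)


def plot_landscape(grid: LandscapeGrid, path, title: str | None = None) -> None:
    """Filled-contour rendering, high values red, low values blue."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(grid.p_axis, grid.c_axis, grid.surface, levels=20, cmap="RdBu_r")
    fig.colorbar(cs, ax=ax, label=grid.response_name)
    ax.set_xlabel("protein intake (ug/day)")
    ax.set_ylabel("carbohydrate intake (ug/day)")
    ax.set_title(title or f"{grid.response_name} landscape (lambda={grid.lambda_:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
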