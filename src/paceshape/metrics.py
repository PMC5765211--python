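"""Pace and shape of mortality from individual lifespans.

Pace is life expectancy at age zero, e(0), computed as the mean of observed
lifespans (the discrete counterpart of the integral of the survivor
function). Shape is derived from the Gini coefficient G of the lifespan
distribution:

    S   = 1 - 2G            (non-rescaled shape)
    S_r = (1 + S) / (1 - S) = (1 - G) / G   (rescaled shape)

G = 0.5 (S_r = 1) corresponds to constant mortality over age, i.e.
negligible senescence; G < 0.5 (S_r > 1) to mortality rising with age
(positive senescence); G > 0.5 (S_r < 1) to negative senescence. G = 0 is
the extreme of sharp positive senescence: everyone dies at the same age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DietGrid

__all__ = [
    "life_expectancy",
    "gini",
    "lorenz_curve",
    "ShapeMeasures",
    "shape_measures",
    "summarise_cohort",
    "write_summary",
    "read_summary",
]

SUMMARY_COLUMNS = [
    "diet_id",
    "n",
    "mean_protein",
    "mean_carb",
    "pace",
    "gini",
    "s",
    "s_rescaled",
    "class",
]

#: Half-width of the Gini band classified as negligible senescence.
NEGLIGIBLE_TOL = 0.01


def _as_lifespans(values, min_n: int = 1) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} lifespans, got {x.size}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("lifespans must be finite and strictly positive")
    return x


def life_expectancy(values) -> float:
    """Life expectancy at age zero, e(0): the mean observed lifespan."""
    return float(np.mean(_as_lifespans(values, min_n=1)))


def gini(values, corrected: bool = False) -> float:
    """Gini coefficient of the lifespan distribution.

    Mean-normalised pairwise-difference form,
    ``G = sum_ij |x_i - x_j| / (2 n^2 xbar)``, evaluated with the
    equivalent sort-based O(n log n) formula. ``corrected=True`` applies
    the small-sample n/(n-1) correction.
    """
    x = np.sort(_as_lifespans(values, min_n=2))
    if x[0] == x[-1]:
        return 0.0
    n = x.size
    ranks = np.arange(1, n + 1, dtype=float)
    g = 2.0 * np.sum(ranks * x) / (n * np.sum(x)) - (n + 1.0) / n
    if corrected:
        g *= n / (n - 1.0)
    return float(max(g, 0.0))


def lorenz_curve(values) -> np.ndarray:
    """Lorenz curve of the lifespan distribution.

    Returns an ``(n + 1, 2)`` array of points (cumulative population share,
    cumulative lifespan share), from (0, 0) to (1, 1). Twice the area
    between this curve and the diagonal equals the Gini coefficient.
    """
    x = np.sort(_as_lifespans(values, min_n=1))
    n = x.size
    pop = np.arange(0, n + 1, dtype=float) / n
    share = np.concatenate([[0.0], np.cumsum(x)]) / np.sum(x)
    return np.column_stack([pop, share])


@dataclass(frozen=True)
class ShapeMeasures:
    """Shape values derived from a Gini coefficient."""

    s: float
    s_rescaled: float
    senescence_class: str


def shape_measures(gini_value: float, negligible_tol: float = NEGLIGIBLE_TOL) -> ShapeMeasures:
    """S, S_r and the senescence class implied by a Gini coefficient.

    ``S = 1 - 2G``; ``S_r = (1 - G)/G`` (infinite at G = 0, the
    sharp-senescence extreme). Classification: negligible when
    ``|G - 0.5| <= negligible_tol``, positive senescence when G is below
    the band, negative senescence above it.
    """
    g = float(gini_value)
    if not (0.0 <= g < 1.0) or not math.isfinite(g):
        raise ValueError(f"Gini coefficient must lie in [0, 1), got {g!r}")
    s = 1.0 - 2.0 * g
    s_rescaled = math.inf if g == 0.0 else (1.0 - g) / g
    if abs(g - 0.5) <= negligible_tol:
        senescence_class = "negligible"
    elif g < 0.5:
        senescence_class = "positive"
    else:
        senescence_class = "negative"
    return ShapeMeasures(s=s, s_rescaled=s_rescaled, senescence_class=senescence_class)


def summarise_cohort(
    cohort: pd.DataFrame,
    grid: DietGrid | None = None,
    corrected: bool = False,
    negligible_tol: float = NEGLIGIBLE_TOL,
) -> pd.DataFrame:
    """Per-diet pace and shape summary of a fly-level cohort table.

    One row per diet with mean intakes, e(0), G, S, S_r and the senescence
    class. Rows follow the grid's diet order when ``grid`` is given
    (otherwise first appearance in the cohort). Diets with fewer than two
    flies are excluded with a warning.
    """
    if grid is not None:
        known = grid.diet_ids()
        order = [d for d in known if d in set(cohort["diet_id"])]
        extra = [d for d in pd.unique(cohort["diet_id"]) if d not in set(known)]
        order += extra
    else:
        order = list(pd.unique(cohort["diet_id"]))

    groups = dict(tuple(cohort.groupby("diet_id", sort=False)))
    rows = []
    for diet_id in order:
        sub = groups[diet_id]
        if len(sub) < 2:
            warnings.warn(
                f"diet '{diet_id}' has n={len(sub)} < 2; excluded from summary",
                stacklevel=2,
            )
            continue
        x = sub["lifespan"].to_numpy()
        g = gini(x, corrected=corrected)
        shape = shape_measures(g, negligible_tol=negligible_tol)
        rows.append(
            {
                "diet_id": diet_id,
                "n": len(sub),
                "mean_protein": float(sub["protein_intake"].mean()),
                "mean_carb": float(sub["carb_intake"].mean()),
                "pace": life_expectancy(x),
                "gini": g,
                "s": shape.s,
                "s_rescaled": shape.s_rescaled,
                "class": shape.senescence_class,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write a per-diet summary as headered CSV."""
    summary.loc[:, SUMMARY_COLUMNS].to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"diet_id": str, "class": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary file {path} is missing columns: {missing}")
    return df.loc[:, SUMMARY_COLUMNS]
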