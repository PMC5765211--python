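"""Cohort simulation on a protein x carbohydrate diet grid.

Emulates a geometric-framework nutrition experiment: diets cross a set of
protein:carbohydrate (P:C) ratios with total nutrient concentrations, each
fly's nutrient intake scatters around its diet's target, and lifespans are
drawn from diet-dependent Gompertz hazards mu(x) = a * exp(b * x).

The default design is 7 P:C ratios x 4 concentrations = 28 diets with 36
flies each (1008 flies). The default hazard map makes life expectancy peak
on high-carbohydrate / low-protein diets and gives the shape of mortality a
shallow minimum at intermediate carbohydrate intake, so downstream
landscape analyses have recoverable signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GompertzParams",
    "DietCell",
    "DietGrid",
    "SimConfig",
    "build_default_grid",
    "default_hazard_map",
    "sample_gompertz_lifespan",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

COHORT_COLUMNS = ["diet_id", "protein_intake", "carb_intake", "lifespan"]

#: Default P:C ratios (protein part, carbohydrate part).
DEFAULT_RATIOS: tuple[tuple[float, float], ...] = (
    (0.0, 1.0),
    (1.0, 16.0),
    (1.0, 8.0),
    (1.0, 4.0),
    (1.0, 2.0),
    (1.0, 1.0),
    (1.9, 1.0),
)

#: Default total nutrient concentrations (g / l).
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (45.0, 90.0, 180.0, 360.0)

#: Expected total nutrient intake (ug / day) per unit concentration (g / l).
DEFAULT_INTAKE_SCALE = 0.5

# Default hazard-map constants (see docs/methods.md for rationale).
_BASELINE_HAZARD = 0.005        # per day, at zero intake of both nutrients
_PROTEIN_HAZARD_SLOPE = 0.010   # log-hazard increase per ug/day protein
_CARB_HAZARD_SLOPE = 0.008      # log-hazard decrease per ug/day carbohydrate
_SENESCENCE_FLOOR = 0.08        # per day, minimum Gompertz b
_SENESCENCE_CURVATURE = 4e-6    # curvature of b in carbohydrate intake
_SHAPE_TROUGH_CARB = 90.0       # ug/day carbohydrate where b is minimal


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard mu(x) = a * exp(b * x).

    Parameters
    ----------
    a : float
        Baseline hazard (per day), strictly positive.
    b : float
        Exponential rate of hazard increase with age (per day),
        non-negative. ``b = 0`` degenerates to a constant hazard
        (exponential lifespans).
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and self.a > 0):
            raise ValueError(f"baseline hazard a must be finite and > 0, got {self.a!r}")
        if not (math.isfinite(self.b) and self.b >= 0):
            raise ValueError(f"senescence rate b must be finite and >= 0, got {self.b!r}")


@dataclass(frozen=True)
class DietCell:
    """One diet: a P:C ratio at a total concentration, with mean intakes."""

    diet_id: str
    p_part: float
    c_part: float
    concentration: float
    mean_protein: float
    mean_carb: float
    index: int


@dataclass(frozen=True)
class DietGrid:
    """Factorial design of P:C ratios crossed with total concentrations.

    ``intake_scale`` converts a diet's concentration (g/l) into the expected
    total nutrient intake (ug/day); the expected per-nutrient intakes split
    that total by the ratio parts.
    """

    ratios: tuple[tuple[float, float], ...] = DEFAULT_RATIOS
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    intake_scale: float = DEFAULT_INTAKE_SCALE

    def __post_init__(self) -> None:
        if not self.ratios or not self.concentrations:
            raise ValueError("grid needs at least one ratio and one concentration")
        for p, c in self.ratios:
            if p < 0 or c < 0 or (p == 0 and c == 0):
                raise ValueError(f"ratio parts must be non-negative with one positive, got {(p, c)}")
        for conc in self.concentrations:
            if not (math.isfinite(conc) and conc > 0):
                raise ValueError(f"concentrations must be strictly positive, got {conc!r}")
        if not (math.isfinite(self.intake_scale) and self.intake_scale > 0):
            raise ValueError("intake_scale must be finite and > 0")

    @property
    def n_diets(self) -> int:
        return len(self.ratios) * len(self.concentrations)

    def cells(self) -> list[DietCell]:
        """All diets, ratio-major then concentration, with stable indices."""
        out: list[DietCell] = []
        idx = 0
        for p_part, c_part in self.ratios:
            frac_p = p_part / (p_part + c_part)
            for conc in self.concentrations:
                total = self.intake_scale * conc
                out.append(
                    DietCell(
                        diet_id=f"{p_part:g}:{c_part:g}@{conc:g}",
                        p_part=p_part,
                        c_part=c_part,
                        concentration=conc,
                        mean_protein=total * frac_p,
                        mean_carb=total * (1.0 - frac_p),
                        index=idx,
                    )
                )
                idx += 1
        return out

    def diet_ids(self) -> list[str]:
        return [cell.diet_id for cell in self.cells()]


def build_default_grid() -> DietGrid:
    """The 7 x 4 = 28-diet design: ratios 0:1 ... 1.9:1 by 45-360 g/l."""
    return DietGrid()


def default_hazard_map(mean_protein: float, mean_carb: float) -> GompertzParams:
    """Map a diet's mean intakes (ug/day) to Gompertz parameters.

    Baseline hazard ``a`` rises log-linearly with protein and falls with
    carbohydrate, so life expectancy peaks on high-C / low-P diets.
    Senescence rate ``b`` is U-shaped in carbohydrate with its minimum at
    90 ug/day, which places a shallow trough of lifespan-inequality-based
    shape at intermediate carbohydrate intake.
    """
    a = _BASELINE_HAZARD * math.exp(
        _PROTEIN_HAZARD_SLOPE * mean_protein - _CARB_HAZARD_SLOPE * mean_carb
    )
    b = _SENESCENCE_FLOOR + _SENESCENCE_CURVATURE * (mean_carb - _SHAPE_TROUGH_CARB) ** 2
    return GompertzParams(a=a, b=b)


@dataclass(frozen=True)
class SimConfig:
    """Settings for one simulated cohort.

    ``hazard_map`` is called once per diet with the diet's mean (P, C)
    intake and must return :class:`GompertzParams`. ``seed`` fully
    determines the output; per-diet RNG substreams are keyed by the diet's
    grid index so results do not depend on iteration order.
    """

    grid: DietGrid = field(default_factory=build_default_grid)
    flies_per_diet: int = 36
    hazard_map: Callable[[float, float], GompertzParams] = default_hazard_map
    intake_noise_cv: float = 0.15
    seed: int = 0
    time_resolution: float = 1.0
    discretise: bool = False

    def __post_init__(self) -> None:
        if self.flies_per_diet < 1:
            raise ValueError("flies_per_diet must be a positive integer")
        if self.intake_noise_cv < 0:
            raise ValueError("intake_noise_cv must be non-negative")
        if self.time_resolution <= 0:
            raise ValueError("time_resolution must be positive")


def sample_gompertz_lifespan(params: GompertzParams, u):
    """Invert the Gompertz survivor function at probability ``1 - u``.

    Solves ``S(t) = 1 - u`` where ``S(t) = exp(-(a/b) (e^{bt} - 1))`` for
    ``b > 0`` and ``S(t) = exp(-a t)`` for ``b = 0``; both branches are
    closed form. Accepts a scalar or array of uniform(0, 1) draws.
    """
    u_arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u_arr)) or np.any(u_arr <= 0) or np.any(u_arr >= 1):
        raise ValueError("u must be finite and strictly inside (0, 1)")
    # -log(1 - u) is the cumulative hazard at the sampled lifespan
    cum_haz = -np.log1p(-u_arr)
    if params.b == 0:
        t = cum_haz / params.a
    else:
        t = np.log1p((params.b / params.a) * cum_haz) / params.b
    return float(t) if np.isscalar(u) or u_arr.ndim == 0 else t


def _lognormal_intakes(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if mean == 0 or cv == 0:
        return np.full(n, mean, dtype=float)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def simulate_cohort(config: SimConfig | None = None) -> pd.DataFrame:
    """Simulate one fly-level cohort table.

    Returns a DataFrame with one record per fly and columns
    ``diet_id, protein_intake, carb_intake, lifespan``. Intakes are
    lognormal around the diet means with coefficient of variation
    ``intake_noise_cv``; lifespans are drawn from the Gompertz hazard the
    ``hazard_map`` assigns to the diet's *mean* intake. Identical seeds give
    identical tables.
    """
    if config is None:
        config = SimConfig()
    frames = []
    n = config.flies_per_diet
    for cell in config.grid.cells():
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(cell.index,))
        )
        protein = _lognormal_intakes(rng, cell.mean_protein, config.intake_noise_cv, n)
        carb = _lognormal_intakes(rng, cell.mean_carb, config.intake_noise_cv, n)
        try:
            params = config.hazard_map(cell.mean_protein, cell.mean_carb)
            if not isinstance(params, GompertzParams):
                params = GompertzParams(*params)
        except Exception as exc:
            raise ValueError(
                f"hazard_map returned invalid Gompertz parameters for diet "
                f"'{cell.diet_id}': {exc}"
            ) from exc
        u = rng.random(n)
        while np.any(u <= 0.0):  # rng.random() can (rarely) return exactly 0
            bad = u <= 0.0
            u[bad] = rng.random(int(bad.sum()))
        lifespan = sample_gompertz_lifespan(params, u)
        if config.discretise:
            res = config.time_resolution
            lifespan = np.maximum(np.ceil(np.asarray(lifespan) / res), 1.0) * res
        frames.append(
            pd.DataFrame(
                {
                    "diet_id": cell.diet_id,
                    "protein_intake": protein,
                    "carb_intake": carb,
                    "lifespan": lifespan,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as headered CSV."""
    cohort.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort` (or user data)."""
    df = pd.read_csv(path, dtype={"diet_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    df = df.loc[:, COHORT_COLUMNS]
    numeric = df[["protein_intake", "carb_intake", "lifespan"]].to_numpy(dtype=float)
    if df.isna().any().any() or not np.all(np.isfinite(numeric)):
        raise ValueError(f"cohort file {path} contains missing or non-finite values")
    if np.any(numeric[:, :2] < 0):
        raise ValueError(f"cohort file {path} contains negative intakes")
    if np.any(numeric[:, 2] <= 0):
        raise ValueError(f"cohort file {path} contains non-positive lifespans")
    return df
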