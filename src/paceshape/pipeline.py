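"""End-to-end orchestration: simulate/load -> metrics -> surfaces ->
landscape comparison -> thin-plate-spline grids.

Every stage writes headered CSV; a JSON manifest records the seed,
package version, estimator flags and the files produced. The run is
deterministic under a fixed seed, and any stage failure removes the
partial outputs and re-raises with the stage named.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import angle_credible_interval, sequential_compare
from .metrics import summarise_cohort, write_summary
from .simulate import SimConfig, build_default_grid, read_cohort, simulate_cohort, write_cohort
from .surface import SurfaceData, fit_linear, fit_quadratic
from .tps import fit_tps, predict_grid, write_grid

__all__ = ["RunConfig", "PipelineError", "run_full_analysis", "load_run_config"]

logger = logging.getLogger("paceshape")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Settings for one full analysis run.

    Exactly one of ``input_path`` (fly-level cohort CSV) or simulation is
    active; when ``input_path`` is None a cohort is simulated with
    ``sim`` (or the default design seeded by ``seed``).
    """

    outdir: str | Path = "paceshape_run"
    input_path: str | Path | None = None
    sim: SimConfig | None = None
    responses: tuple[str, str] = ("pace", "s_rescaled")
    seed: int = 0
    n_draws: int = 10_000
    gini_corrected: bool = False
    landscape_resolution: int = 50
    flies_per_diet: int = 36

    def __post_init__(self) -> None:
        if self.input_path is not None and self.sim is not None:
            raise ValueError("give either input_path or simulation settings, not both")
        if len(self.responses) != 2:
            raise ValueError("exactly two responses are compared")


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", None)
    cfg = RunConfig(**{k: tuple(v) if k == "responses" else v for k, v in raw.items()})
    if sim_raw is not None:
        cfg.sim = SimConfig(grid=build_default_grid(), **sim_raw)
    return cfg


def _surface_stage(summary: pd.DataFrame, response: str) -> tuple:
    data = SurfaceData.from_summary(summary, response, standardize=True)
    lin = fit_linear(data)
    tables = [lin.to_frame()]
    quad = None
    if data.n >= 7:
        quad = fit_quadratic(data)
        tables.append(quad.to_frame())
    else:
        warnings.warn(
            f"quadratic fit for '{response}' skipped: only {data.n} diets "
            "(need >= 7 for residual df)"
        )
    return data, lin, quad, pd.concat(tables, ignore_index=True)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole analysis; returns a manifest dict (also written to disk).

    Outputs in ``config.outdir``: ``cohort.csv`` (if simulated),
    ``diet_summary.csv``, ``gradients_<response>.csv`` per response,
    ``comparison.csv`` + ``follow_ups.csv`` + ``angle.csv``,
    ``landscape_<response>.csv`` per response, and ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, writer) -> str:
        path = outdir / name
        writer(path)
        written.append(path)
        return name

    manifest: dict = {
        "package": "paceshape",
        "version": __version__,
        "seed": config.seed,
        "responses": list(config.responses),
        "gini_corrected": config.gini_corrected,
        "n_draws": config.n_draws,
        "files": [],
        "warnings": [],
    }
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "input"
            grid = build_default_grid()
            if config.input_path is not None:
                cohort = read_cohort(config.input_path)
                manifest["input"] = str(config.input_path)
                grid_for_summary = None
            else:
                sim = config.sim or SimConfig(
                    grid=grid, flies_per_diet=config.flies_per_diet, seed=config.seed
                )
                cohort = simulate_cohort(sim)
                grid_for_summary = sim.grid
                manifest["input"] = "simulated"
                manifest["files"].append(emit("cohort.csv", lambda p: write_cohort(cohort, p)))
            logger.info("stage=input records=%d", len(cohort))

            stage = "metrics"
            summary = summarise_cohort(
                cohort, grid=grid_for_summary, corrected=config.gini_corrected
            )
            manifest["files"].append(emit("diet_summary.csv", lambda p: write_summary(summary, p)))
            logger.info("stage=metrics diets=%d", len(summary))
            if len(summary) < 4:
                raise ValueError(
                    f"only {len(summary)} diets with n >= 2; need at least 4 for any surface fit"
                )

            stage = "surfaces"
            surfaces = {}
            for resp in config.responses:
                data, lin, quad, table = _surface_stage(summary, resp)
                surfaces[resp] = (data, lin, quad)
                manifest["files"].append(
                    emit(f"gradients_{resp}.csv", lambda p, t=table: t.to_csv(p, index=False))
                )
            logger.info("stage=surfaces responses=%s", ",".join(config.responses))

            stage = "comparison"
            ra, rb = config.responses
            data_a, lin_a, quad_a = surfaces[ra]
            data_b, lin_b, quad_b = surfaces[rb]
            if data_a.n >= 7:
                comparison = sequential_compare(data_a, data_b)
                manifest["files"].append(
                    emit(
                        "comparison.csv",
                        lambda p: comparison.to_frame().to_csv(p, index=False),
                    )
                )
                manifest["files"].append(
                    emit(
                        "follow_ups.csv",
                        lambda p: comparison.follow_ups_frame().to_csv(p, index=False),
                    )
                )
            else:
                warnings.warn("landscape comparison skipped: fewer than 7 diets")
            angle = angle_credible_interval(
                lin_a, lin_b, n_draws=config.n_draws, seed=config.seed
            )
            angle_df = pd.DataFrame(
                [
                    {
                        "responses": f"{ra} vs {rb}",
                        "theta_deg": angle.theta,
                        "ci_lower": angle.ci_lower,
                        "ci_upper": angle.ci_upper,
                        "n_draws": angle.n_draws,
                        "seed": angle.seed,
                        "method": angle.method,
                    }
                ]
            )
            manifest["files"].append(
                emit("angle.csv", lambda p: angle_df.to_csv(p, index=False))
            )
            logger.info("stage=comparison theta=%.2f", angle.theta)

            stage = "landscapes"
            for resp in config.responses:
                # raw values plotted/gridded, standardized values analysed
                raw = SurfaceData.from_summary(summary, resp, standardize=False)
                spline = fit_tps(raw, lam="gcv")
                lgrid = predict_grid(spline, resolution=config.landscape_resolution)
                manifest["files"].append(
                    emit(f"landscape_{resp}.csv", lambda p, g=lgrid: write_grid(g, p))
                )
            logger.info("stage=landscapes done")

        manifest["warnings"] = sorted({str(w.message) for w in caught})
        stage = "manifest"
        manifest["files"].append("manifest.json")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(outdir / "manifest.json")
        return manifest
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
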