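"""End-to-end orchestration of the two model designs.

``run_model2`` fits the space-time model on all survey years at once (the
gold-standard full-data design) and predicts every year; ``run_model1`` is
the forecasting design — for each forecast year ``t`` it fits on the years
before ``t`` only and carries the model forward to ``t``.  Both return an
in-memory result dict plus, when an output directory is given, a manifest of
written artifacts (stage, path, seed, sha256).

Both entry points consume a *bundle*: the dict produced by
:func:`stuntcast.synthetic.default_bundle`, by :func:`simulate_bundle`
(which also writes it to disk), or by :func:`load_bundle`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .data_model import (
    ClusterRecord,
    CovariateStack,
    PopulationRaster,
    RegionMap,
    extract_covariates,
    read_clusters,
    read_raster,
    read_region_lookup,
    write_clusters,
    write_raster,
    write_region_lookup,
)
from .exceedance import excursion_set, marginal_exceedance
from .mapping import (
    aggregate_regions,
    classify_who,
    forecast_surface,
    predict_surface,
)
from .screening import select_covariates
from .spacetime import ModelConfig, build_mesh, fit
from .validation import compare_models, compute_metrics, split_holdout

__all__ = [
    "RunConfig",
    "simulate_bundle",
    "load_bundle",
    "run_model1",
    "run_model2",
]

log = logging.getLogger("stuntcast")


@dataclasses.dataclass
class RunConfig:
    """Settings shared by the pipeline stages."""

    mesh_max_edge: float = 8.0
    mesh_buffer: float = 10.0
    threshold: float = 0.40
    alpha: float = 0.05
    holdout_fraction: float = 0.10
    forecast_mode: str = "ar"
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    covariates: tuple[str, ...] | None = None  # None -> BIC screening decides
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        model = ModelConfig(**raw.pop("model", {}))
        cov = raw.pop("covariates", None)
        return cls(model=model, covariates=tuple(cov) if cov else None, **raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, outdir: Path | None):
        self.outdir = outdir
        self.rows: list[dict] = []
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)

    def add(self, stage: str, path: Path, seed: int | None = None) -> None:
        self.rows.append(
            {"stage": stage, "path": str(path), "seed": seed, "sha256": _checksum(path)}
        )

    def write(self, name: str = "manifest.json") -> None:
        if self.outdir is not None:
            (self.outdir / name).write_text(json.dumps(self.rows, indent=2))


# ---------------------------------------------------------------------------
# Input bundle IO
# ---------------------------------------------------------------------------

def simulate_bundle(
    outdir: str | Path,
    seed: int = 0,
    design: synthetic.SurveyDesign | None = None,
    params: synthetic.TruthParams | None = None,
) -> dict:
    """Generate the default synthetic bundle and write it to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = synthetic.default_bundle(seed=seed, design=design, params=params)
    geometry = bundle["geometry"]

    write_clusters(bundle["clusters"], outdir / "clusters.csv")
    for name, per_year in bundle["stack"].layers.items():
        for year, grid in per_year.items():
            write_raster(grid, geometry, outdir / f"cov_{name}_{year}.asc")
    write_raster(bundle["regions"].region_id.astype(float), geometry, outdir / "regions.asc")
    write_region_lookup(bundle["regions"], outdir / "region_lookup.csv")
    for year, grid in bundle["population"].counts.items():
        write_raster(grid, geometry, outdir / f"population_{year}.asc")
    for year, grid in bundle["prevalence"].items():
        write_raster(grid, geometry, outdir / f"truth_prevalence_{year}.asc")
    p = bundle["params"]
    (outdir / "truth_params.json").write_text(
        json.dumps(
            {
                "beta0": p.beta0,
                "beta": p.beta,
                "sigma_s": p.sigma_s,
                "range_rho": p.range_rho,
                "phi": p.phi,
                "sigma_eps": p.sigma_eps,
                "seed": p.seed,
            },
            indent=2,
        )
    )
    return bundle


def load_bundle(indir: str | Path) -> dict:
    """Read a bundle directory written by :func:`simulate_bundle`."""
    indir = Path(indir)
    clusters = read_clusters(indir / "clusters.csv")
    years = sorted({c.year for c in clusters})

    layers: dict[str, dict[int, np.ndarray]] = {}
    geometry = None
    for path in sorted(indir.glob("cov_*.asc")):
        stem = path.stem[len("cov_"):]
        name, year = stem.rsplit("_", 1)
        grid, geom = read_raster(path)
        geometry = geometry or geom
        if geom != geometry:
            raise ValueError(f"raster {path.name} has a mismatched geometry")
        layers.setdefault(name, {})[int(year)] = grid
    stack = CovariateStack(geometry=geometry, years=years, layers=layers)

    region_grid, geom = read_raster(indir / "regions.asc")
    zone_of, name_of = read_region_lookup(indir / "region_lookup.csv")
    regions = RegionMap(
        geometry=geometry,
        region_id=np.nan_to_num(region_grid, nan=RegionMap.NODATA).astype(int),
        zone_of=zone_of,
        name_of=name_of,
    )
    counts = {}
    for path in sorted(indir.glob("population_*.asc")):
        year = int(path.stem.rsplit("_", 1)[1])
        counts[year], _ = read_raster(path)
    population = PopulationRaster(geometry=geometry, years=sorted(counts), counts=counts)

    prevalence = {}
    for path in sorted(indir.glob("truth_prevalence_*.asc")):
        year = int(path.stem.rsplit("_", 1)[1])
        prevalence[year], _ = read_raster(path)

    return {
        "geometry": geometry,
        "regions": regions,
        "population": population,
        "stack": stack,
        "prevalence": prevalence,
        "clusters": clusters,
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _select(bundle: dict, config: RunConfig) -> tuple[str, ...]:
    if config.covariates is not None:
        return tuple(config.covariates)
    t0 = time.time()
    best, table = select_covariates(bundle["clusters"])
    log.info("screen: winner=%s (%.1fs, %d subsets)", best, time.time() - t0, len(table))
    return best if best else ("precipitation",)  # never fit with no covariate columns


def _surface_at_clusters(surface, clusters: Sequence[ClusterRecord]) -> np.ndarray:
    geom = surface.geometry
    rows, cols = geom.pixel_of(
        np.array([c.x for c in clusters]), np.array([c.y for c in clusters])
    )
    return surface.mean[rows, cols]


def run_model2(bundle: dict, config: RunConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Full-data design: one fit on all years, per-year surfaces + validation."""
    config = config or RunConfig()
    manifest = _Manifest(Path(outdir) if outdir else None)
    clusters = bundle["clusters"]
    geometry = bundle["geometry"]
    years = sorted({c.year for c in clusters})
    selected = _select(bundle, config)

    mesh = build_mesh(clusters, geometry, max_edge=config.mesh_max_edge, buffer=config.mesh_buffer)
    model_cfg = dataclasses.replace(config.model, seed=config.seed)

    train, hold = split_holdout(
        clusters, fraction=config.holdout_fraction, seed=config.seed, geometry=geometry
    )
    t0 = time.time()
    fit_full = fit(clusters, selected, mesh, model_cfg, years_used=years)
    fit_train = fit(train, selected, mesh, model_cfg, years_used=years)
    log.info(
        "model2 fit: %.1fs, range=%.1f km sigma_s=%.2f phi=%.2f",
        time.time() - t0, fit_full.hyper.range_rho, fit_full.hyper.sigma_s, fit_full.hyper.phi,
    )

    surfaces, class_maps, regional = {}, {}, []
    obs_all, pred_all = [], []
    for year in years:
        surf = predict_surface(fit_full, bundle["stack"], year, geometry)
        surfaces[year] = surf
        class_maps[year] = classify_who(surf)
        regional.append(
            aggregate_regions(surf, bundle["population"], bundle["regions"], year, "model2")
        )
        hold_y = [c for c in hold if c.year == year]
        if hold_y:
            surf_tr = predict_surface(fit_train, bundle["stack"], year, geometry)
            obs_all.extend(c.prevalence for c in hold_y)
            pred_all.extend(_surface_at_clusters(surf_tr, hold_y))
    regional_df = pd.concat(regional, ignore_index=True)
    metrics = compute_metrics(obs_all, pred_all, label="model2 pooled") if obs_all else None

    if manifest.outdir:
        for year in years:
            p = manifest.outdir / f"model2_mean_{year}.asc"
            write_raster(surfaces[year].mean, geometry, p)
            manifest.add("predict", p, config.seed)
            p = manifest.outdir / f"model2_sd_{year}.asc"
            write_raster(surfaces[year].sd, geometry, p)
            manifest.add("predict", p, config.seed)
        p = manifest.outdir / "model2_regional.csv"
        regional_df.to_csv(p, index=False)
        manifest.add("aggregate", p, config.seed)
        if metrics:
            p = manifest.outdir / "model2_validation.csv"
            pd.DataFrame([metrics.as_dict()]).to_csv(p, index=False)
            manifest.add("validate", p, config.seed)
        manifest.write("model2_manifest.json")

    return {
        "fit": fit_full,
        "surfaces": surfaces,
        "classes": class_maps,
        "regional": regional_df,
        "metrics": metrics,
        "selected": selected,
        "manifest": manifest.rows,
    }


def run_model1(bundle: dict, config: RunConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Forecast design: for each year t > first, fit on years < t, forecast t."""
    config = config or RunConfig()
    manifest = _Manifest(Path(outdir) if outdir else None)
    clusters = bundle["clusters"]
    geometry = bundle["geometry"]
    years = sorted({c.year for c in clusters})
    if len(years) < 2:
        raise ValueError("model 1 needs at least two survey years")
    selected = _select(bundle, config)
    mesh = build_mesh(clusters, geometry, max_edge=config.mesh_max_edge, buffer=config.mesh_buffer)
    model_cfg = dataclasses.replace(config.model, seed=config.seed)

    surfaces, class_maps, excursions, regional, metrics = {}, {}, {}, [], {}
    for t in years[1:]:
        past = [c for c in clusters if c.year < t]
        t0 = time.time()
        fit_past = fit(past, selected, mesh, model_cfg, years_used=[y for y in years if y < t])
        surf = forecast_surface(
            fit_past, bundle["stack"], t, geometry, mode=config.forecast_mode,
            seed=config.seed + t,
        )
        log.info("model1 year %d: fit+forecast %.1fs", t, time.time() - t0)
        surfaces[t] = surf
        class_maps[t] = classify_who(surf)
        regional.append(
            aggregate_regions(surf, bundle["population"], bundle["regions"], t, "model1")
        )
        exceed = marginal_exceedance(surf, config.threshold)
        exc = excursion_set(surf, config.threshold, config.alpha)
        excursions[t] = {"marginal": exceed, "set": exc}

        year_t = [c for c in clusters if c.year == t]
        _, hold_t = split_holdout(
            year_t, fraction=config.holdout_fraction, seed=config.seed, geometry=geometry
        )
        if hold_t:
            metrics[t] = compute_metrics(
                [c.prevalence for c in hold_t],
                _surface_at_clusters(surf, hold_t),
                label=f"model1 {t}",
            )

        if manifest.outdir:
            p = manifest.outdir / f"model1_mean_{t}.asc"
            write_raster(surf.mean, geometry, p)
            manifest.add("forecast", p, config.seed)
            p = manifest.outdir / f"model1_exceed_{t}.asc"
            write_raster(exceed.probability, geometry, p)
            manifest.add("exceed", p, config.seed)
            p = manifest.outdir / f"model1_excursion_{t}.asc"
            write_raster(exc.member.astype(float), geometry, p)
            manifest.add("exceed", p, config.seed)

    regional_df = pd.concat(regional, ignore_index=True)
    if manifest.outdir:
        p = manifest.outdir / "model1_regional.csv"
        regional_df.to_csv(p, index=False)
        manifest.add("aggregate", p, config.seed)
        if metrics:
            p = manifest.outdir / "model1_validation.csv"
            pd.DataFrame([m.as_dict() for m in metrics.values()]).to_csv(p, index=False)
            manifest.add("validate", p, config.seed)
        manifest.write("model1_manifest.json")

    return {
        "surfaces": surfaces,
        "classes": class_maps,
        "excursions": excursions,
        "regional": regional_df,
        "metrics": metrics,
        "selected": selected,
        "manifest": manifest.rows,
    }


def compare_model_runs(res1: dict, res2: dict) -> tuple[pd.DataFrame, float]:
    """model-1 vs model-2 regional comparison restricted to the forecast years."""
    forecast_years = sorted(res1["surfaces"])
    m2 = res2["regional"][res2["regional"]["year"].isin(forecast_years)]
    return compare_models(res1["regional"], m2)
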