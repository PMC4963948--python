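"""Pixel prevalence surfaces, WHO classification and regional aggregation.

Two prediction designs are supported, mirroring the forecasting study:

* *full-data prediction* (:func:`predict_surface`) — the year lies inside the
  fitted period and its posterior field is used directly;
* *forecasting* (:func:`forecast_surface`) — the year lies after the fitted
  period; the latent field is carried forward by the AR(1) dynamics with a
  fresh spatially correlated innovation per posterior draw (default), or
  dropped entirely (``mode="fixed_only"``, the covariates-only reading).

Surfaces are summarised per pixel over the joint posterior draws; the
cluster-level nugget is excluded from pixel prediction because it represents
survey noise, not the latent prevalence surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .data_model import (
    ClusterRecord,
    CovariateStack,
    PopulationRaster,
    RasterGeometry,
    RegionMap,
    ValidationError,
)
from .spacetime import PosteriorFit, spde_precision

__all__ = [
    "PrevalenceSurface",
    "WHO_CLASSES",
    "predict_surface",
    "forecast_surface",
    "classify_who",
    "aggregate_regions",
    "observed_region_prevalence",
    "round_half_up",
]

WHO_CLASSES = ("low", "medium", "high", "very_high")
_WHO_BOUNDS = (0.20, 0.30, 0.40)  # left-closed: [0.2, 0.3) is medium, etc.


@dataclass
class PrevalenceSurface:
    """Per-pixel posterior prevalence for one year."""

    geometry: RasterGeometry
    year: int
    mean: np.ndarray  # (rows, cols) in [0, 1]
    sd: np.ndarray  # (rows, cols) >= 0
    samples: np.ndarray | None = None  # (J, rows*cols) in [0, 1]

    def __post_init__(self) -> None:
        ok = ~self.geometry.mask()
        if np.any(self.mean[ok] < 0) or np.any(self.mean[ok] > 1):
            raise ValidationError("surface mean outside [0, 1]")
        if np.any(self.sd[ok] < 0):
            raise ValidationError("surface sd negative")

    @property
    def n_samples(self) -> int:
        return 0 if self.samples is None else self.samples.shape[0]


def _pixel_design(
    fit: PosteriorFit, stack: CovariateStack, year: int, geometry: RasterGeometry
) -> tuple[np.ndarray, sp.csr_matrix]:
    """Fixed-effect design and mesh projector for every pixel center."""
    if stack.geometry != geometry:
        raise ValidationError("covariate stack geometry differs from prediction geometry")
    cx, cy = geometry.cell_centers()
    pts = np.column_stack([cx.ravel(), cy.ravel()])
    A_pix = fit.mesh.projector(pts)
    X = np.ones((geometry.n_pixels, len(fit.beta_names)))
    for j, name in enumerate(fit.beta_names):
        if name == "intercept":
            continue
        if name not in stack.layers:
            raise ValidationError(f"covariate layer {name!r} missing from stack")
        if year not in stack.layers[name]:
            raise ValidationError(f"covariate {name!r} has no layer for year {year}")
        X[:, j] = stack.layers[name][year].ravel()
    return X, A_pix


def _summarise(p_samples: np.ndarray, geometry: RasterGeometry, year: int) -> PrevalenceSurface:
    shape = geometry.shape
    return PrevalenceSurface(
        geometry=geometry,
        year=year,
        mean=p_samples.mean(axis=0).reshape(shape),
        sd=p_samples.std(axis=0, ddof=0).reshape(shape),
        samples=p_samples,
    )


def predict_surface(
    fit: PosteriorFit, stack: CovariateStack, year: int, geometry: RasterGeometry
) -> PrevalenceSurface:
    """Posterior prevalence surface for a year inside the fitted period."""
    if year not in fit.years:
        raise ValidationError(
            f"year {year} not in fitted years {fit.years}; use forecast_surface"
        )
    X, A_pix = _pixel_design(fit, stack, year, geometry)
    t = fit.years.index(year)
    field = fit.samples_field[:, t, :]  # (J, m)
    eta = fit.samples_beta @ X.T + field @ A_pix.T.toarray()
    return _summarise(expit(eta), geometry, year)


def forecast_surface(
    fit: PosteriorFit,
    stack: CovariateStack,
    year: int,
    geometry: RasterGeometry,
    mode: str = "ar",
    seed: int = 0,
) -> PrevalenceSurface:
    """Forecast the prevalence surface for a year after the fitted period.

    ``mode="ar"`` propagates each posterior draw's last-year field forward by
    the AR(1) dynamics, adding a fresh innovation with spatial covariance
    ``(1 - phi^2) Q_s^{-1}`` per step.  ``mode="fixed_only"`` sets the field
    to zero, using only the regression coefficients and the target-year
    covariates.
    """
    last = max(fit.years)
    if year <= last:
        raise ValidationError(f"forecast year {year} must be after last fitted year {last}")
    if mode not in ("ar", "fixed_only"):
        raise ValidationError("mode must be 'ar' or 'fixed_only'")
    X, A_pix = _pixel_design(fit, stack, year, geometry)
    J = fit.n_samples
    if mode == "fixed_only":
        field = np.zeros((J, fit.mesh.n_nodes))
    else:
        h = fit.hyper
        Q_s = spde_precision(fit.mesh, h.kappa, h.tau).toarray()
        L = np.linalg.cholesky(Q_s)  # innovations: solve(L.T, z) ~ N(0, Q_s^-1)
        rng = np.random.default_rng(seed)
        field = fit.samples_field[:, -1, :].copy()
        innov_sd = np.sqrt(max(1.0 - h.phi**2, 0.0))
        from scipy.linalg import solve_triangular

        for _ in range(year - last):
            z = rng.standard_normal((fit.mesh.n_nodes, J))
            omega = solve_triangular(L.T, z, lower=False).T
            field = h.phi * field + innov_sd * omega
    eta = fit.samples_beta @ X.T + field @ A_pix.T.toarray()
    return _summarise(expit(eta), geometry, year)


def classify_who(surface: PrevalenceSurface) -> np.ndarray:
    """WHO prevalence class raster: ``low < 0.20 <= medium < 0.30 <= high <
    0.40 <= very_high`` (left-closed bins); nodata pixels get ``""``.
    """
    mean = surface.mean
    out = np.full(mean.shape, "", dtype=object)
    ok = ~surface.geometry.mask()
    idx = np.digitize(mean[ok], _WHO_BOUNDS, right=False)
    out[ok] = np.array(WHO_CLASSES, dtype=object)[idx]
    return out


def aggregate_regions(
    surface: PrevalenceSurface,
    population: PopulationRaster,
    regions: RegionMap,
    year: int | None = None,
    model_label: str = "model2",
    per_sample: bool = False,
) -> pd.DataFrame:
    """Population-weighted regional prevalence from a pixel surface.

    Per region: estimated stunted count = sum over pixels of
    mean-prevalence x under-five population; prevalence = count / population.
    With ``per_sample=True`` the aggregation is applied to each posterior
    draw and then averaged (available as a sensitivity option; the default
    aggregates the posterior mean surface).
    """
    year = surface.year if year is None else year
    if population.geometry != surface.geometry or regions.geometry != surface.geometry:
        raise ValidationError("geometry mismatch between surface, population and regions")
    if year not in population.counts:
        raise ValidationError(f"population raster has no year {year}")
    pop = population.counts[year].ravel()
    rid = regions.region_id.ravel()
    ok = (rid != RegionMap.NODATA) & ~surface.geometry.mask().ravel()
    labels = regions.labels()
    lab_index = {r: i for i, r in enumerate(labels)}
    idx = np.array([lab_index[r] for r in rid[ok]])

    if per_sample and surface.samples is not None:
        stunted_px = surface.samples[:, ok] * pop[ok]
        stunted = np.vstack(
            [np.bincount(idx, weights=row, minlength=len(labels)) for row in stunted_px]
        ).mean(axis=0)
    else:
        stunted = np.bincount(idx, weights=surface.mean.ravel()[ok] * pop[ok], minlength=len(labels))
    pop_tot = np.bincount(idx, weights=pop[ok], minlength=len(labels))

    rows = []
    for i, r in enumerate(labels):
        if pop_tot[i] > 0:
            prev = stunted[i] / pop_tot[i]
            flagged = False
        else:
            prev = np.nan
            flagged = True
        rows.append(
            {
                "region": r,
                "zone": regions.zone_of[r],
                "year": year,
                "model": model_label,
                "prevalence": prev,
                "stunted_count": stunted[i],
                "population": pop_tot[i],
                "zero_population": flagged,
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (display convention for reported percents)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def observed_region_prevalence(
    clusters: Sequence[ClusterRecord],
    regions: RegionMap | None = None,
) -> pd.DataFrame:
    """Observed per-region summary: clusters, children examined/stunted, percent.

    Regions come from each record's ``region`` attribute or, failing that, a
    :class:`RegionMap` lookup at the cluster location.  Percent stunted is
    ``100 * stunted / examined`` rounded half-up to 2 decimals; a ``Total``
    row pools everything.
    """
    assigned: dict[object, list[ClusterRecord]] = {}
    for c in clusters:
        region = c.region
        if region is None:
            if regions is None:
                raise ValidationError(f"cluster {c.cluster_id}: no region and no RegionMap given")
            region = int(regions.region_at(c.x, c.y))
            if region == RegionMap.NODATA:
                raise ValidationError(f"cluster {c.cluster_id}: outside every region")
        assigned.setdefault(region, []).append(c)

    rows = []
    for region in sorted(assigned, key=str):
        group = assigned[region]
        examined = sum(c.n_examined for c in group)
        stunted = sum(c.n_stunted for c in group)
        rows.append(
            {
                "region": region,
                "n_clusters": len(group),
                "n_examined": examined,
                "n_stunted": stunted,
                "percent_stunted": round_half_up(100.0 * stunted / examined),
            }
        )
    examined = sum(c.n_examined for c in clusters)
    stunted = sum(c.n_stunted for c in clusters)
    rows.append(
        {
            "region": "Total",
            "n_clusters": len(list(clusters)),
            "n_examined": examined,
            "n_stunted": stunted,
            "percent_stunted": round_half_up(100.0 * stunted / examined) if examined else 0.0,
        }
    )
    return pd.DataFrame(rows)
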