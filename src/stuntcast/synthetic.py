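"""Synthetic country generator with known ground truth.

Everything downstream of this module (screening, the space-time model,
mapping, validation) is exercised on data produced here, so the generator
reproduces the statistical structure the analysis assumes:

* a planar 1x1 km raster domain partitioned into contiguous regions,
* spatially autocorrelated environmental covariates with year anomalies,
* a latent Matern (nu=1) Gaussian field with AR(1) year-to-year persistence,
* cluster surveys with binomial stunting counts and a cluster-level nugget.

The latent field is simulated *exactly* by dense Cholesky of the Matern
covariance on the pixel grid, which caps the grid at ~4,000 pixels; the
default domain is 48x48 km (2,304 pixels).  Effect sizes default to
OR = 0.994 per mm of annual precipitation and OR = 0.719 per unit EVI, with
the intercept set so pooled prevalence is close to 30 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.special import expit, k1, logit

from .data_model import (
    ClusterRecord,
    CovariateStack,
    PopulationRaster,
    RasterGeometry,
    RegionMap,
    SEASONS,
    ValidationError,
)

__all__ = [
    "TruthParams",
    "SurveyDesign",
    "make_domain",
    "simulate_covariates",
    "simulate_truth",
    "sample_surveys",
    "matern_covariance",
    "default_bundle",
]

_MAX_EXACT_PIXELS = 4096

DEFAULT_YEARS = [2007, 2008, 2009, 2010]


@dataclass
class TruthParams:
    """Generative parameters of the latent prevalence process (logit scale).

    ``range_rho`` is the Matern nu=1 range: the distance at which spatial
    correlation drops to about 0.13 (kappa = sqrt(8)/rho).  The AR(1)
    coefficient ``phi`` uses the marginal-variance convention: innovations
    have variance ``sigma_s**2 * (1 - phi**2)`` so every year's field has
    marginal variance ``sigma_s**2``.
    """

    beta0: float = 1.05
    beta: dict[str, float] = dc_field(
        default_factory=lambda: {
            "precipitation": math.log(0.994),
            "EVI": math.log(0.719),
        }
    )
    sigma_s: float = 0.30
    range_rho: float = 15.0
    phi: float = 0.99
    sigma_eps: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_s < 0 or self.range_rho <= 0:
            raise ValidationError("sigma_s must be >= 0 and range_rho > 0")
        if not -1 < self.phi < 1:
            raise ValidationError("phi must lie in (-1, 1)")
        if self.sigma_eps < 0:
            raise ValidationError("sigma_eps must be >= 0")


@dataclass
class SurveyDesign:
    """Size and placement of the synthetic cluster surveys."""

    n_years: int = 4
    clusters_per_year: int = 250
    children_range: tuple[int, int] = (30, 150)
    placement: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.children_range[0] < 1 or self.clusters_per_year < 1 or self.n_years < 1:
            raise ValidationError("survey design counts must be >= 1")
        if self.placement not in ("uniform", "clustered"):
            raise ValidationError("placement must be 'uniform' or 'clustered'")


# ---------------------------------------------------------------------------
# Domain: geometry, regions, population
# ---------------------------------------------------------------------------

def make_domain(
    n_rows: int = 48,
    n_cols: int = 48,
    n_regions: int = 18,
    seed: int = 0,
    years: list[int] | None = None,
    pop_median: float = 20.0,
    pop_sigma: float = 1.0,
) -> tuple[RasterGeometry, RegionMap, PopulationRaster]:
    """Generate the raster geometry, a Voronoi region partition and population.

    Regions are the Voronoi cells of ``n_regions`` seeded points (guaranteed
    contiguous); regions are grouped into three zones by the latitude tercile
    of their seed point.  Population per pixel is log-normal with the given
    median and dispersion, replicated across years with small multiplicative
    drift.
    """
    if n_regions > n_rows * n_cols:
        raise ValidationError("n_regions exceeds the number of pixels")
    years = list(years) if years is not None else list(DEFAULT_YEARS)
    rng = np.random.default_rng(seed)
    geometry = RasterGeometry(n_rows=n_rows, n_cols=n_cols)

    seeds_xy = np.column_stack(
        [
            rng.uniform(0, n_cols * geometry.cell_size, n_regions),
            rng.uniform(0, n_rows * geometry.cell_size, n_regions),
        ]
    )
    cx, cy = geometry.cell_centers()
    d2 = (cx[..., None] - seeds_xy[:, 0]) ** 2 + (cy[..., None] - seeds_xy[:, 1]) ** 2
    region_id = np.argmin(d2, axis=-1)

    order = np.argsort(seeds_xy[:, 1])
    zone_names = ("south", "central", "north")
    zone_of: dict[int, str] = {}
    for rank, rid in enumerate(order):
        zone_of[int(rid)] = zone_names[min(rank * 3 // n_regions, 2)]
    name_of = {int(r): f"region_{r:02d}" for r in range(n_regions)}
    regions = RegionMap(geometry=geometry, region_id=region_id, zone_of=zone_of, name_of=name_of)

    base = np.exp(np.log(pop_median) + pop_sigma * rng.standard_normal(geometry.shape))
    counts = {}
    grid = base
    for year in years:
        counts[year] = grid
        grid = grid * np.exp(0.05 * rng.standard_normal(geometry.shape))
    population = PopulationRaster(geometry=geometry, years=years, counts=counts)
    return geometry, regions, population


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], length_scale: float) -> np.ndarray:
    """Unit-variance smooth surface: Gaussian-filtered white noise.

    Filtering white noise with a Gaussian kernel of scale ``l`` yields a
    squared-exponential covariance with length scale ``l*sqrt(2)`` (in cells).
    """
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=length_scale, mode="reflect")
    return (smooth - smooth.mean()) / smooth.std()


def simulate_covariates(
    geometry: RasterGeometry,
    years: list[int],
    seed: int = 0,
    length_scale: float = 8.0,
    anomaly_amplitude: float = 0.25,
) -> CovariateStack:
    """Simulate the five environmental covariate layers per year.

    Precipitation (mm) and temperature (degC) are smooth surfaces with
    year-specific smooth anomalies; EVI is a logistic transform of a smooth
    surface into [0, 1]; distance-to-water (km) is the distance transform of a
    random polyline ("river"); urban is a thresholded smooth population-density
    proxy (top decile), constant across years.
    """
    if not years:
        raise ValidationError("years must be nonempty")
    rng = np.random.default_rng(seed)
    shape = geometry.shape

    precip_base = _smooth_field(rng, shape, length_scale)
    temp_base = _smooth_field(rng, shape, length_scale)
    evi_base = _smooth_field(rng, shape, length_scale)

    # random polyline across the domain, rasterised then distance-transformed
    n_way = 5
    wx = np.sort(rng.uniform(0, geometry.n_cols, n_way))
    wy = rng.uniform(0, geometry.n_rows, n_way)
    river = np.zeros(shape, dtype=bool)
    for i in range(n_way - 1):
        steps = int(4 * max(abs(wx[i + 1] - wx[i]), abs(wy[i + 1] - wy[i]))) + 2
        xs = np.linspace(wx[i], wx[i + 1], steps)
        ys = np.linspace(wy[i], wy[i + 1], steps)
        rr = np.clip(ys.astype(int), 0, geometry.n_rows - 1)
        cc = np.clip(xs.astype(int), 0, geometry.n_cols - 1)
        river[rr, cc] = True
    dist = ndimage.distance_transform_edt(~river) * geometry.cell_size

    density = _smooth_field(rng, shape, length_scale / 2.0)
    urban = (density >= np.quantile(density, 0.9)).astype(float)

    layers: dict[str, dict[int, np.ndarray]] = {
        "precipitation": {},
        "EVI": {},
        "temperature": {},
        "distance_to_water": {},
        "urban": {},
    }
    for year in years:
        if anomaly_amplitude > 0:
            ap = _smooth_field(rng, shape, length_scale) * anomaly_amplitude
            ae = _smooth_field(rng, shape, length_scale) * anomaly_amplitude
            at = _smooth_field(rng, shape, length_scale) * anomaly_amplitude
        else:
            ap = ae = at = np.zeros(shape)
        layers["precipitation"][year] = np.clip(300.0 + 120.0 * (precip_base + ap), 0.0, None)
        layers["EVI"][year] = expit(1.2 * (evi_base + ae) - 0.8)
        layers["temperature"][year] = 27.0 + 3.0 * (temp_base + at)
        layers["distance_to_water"][year] = dist
        layers["urban"][year] = urban
    return CovariateStack(geometry=geometry, years=list(years), layers=layers)


# ---------------------------------------------------------------------------
# Latent truth
# ---------------------------------------------------------------------------

def matern_covariance(dist: np.ndarray, sigma: float, range_rho: float) -> np.ndarray:
    """Matern nu=1 covariance: C(h) = sigma^2 * (kappa h) K_1(kappa h)."""
    kappa = math.sqrt(8.0) / range_rho
    h = np.asarray(dist, dtype=float)
    out = np.empty_like(h)
    zero = h == 0
    kh = kappa * h[~zero]
    out[~zero] = sigma**2 * kh * k1(kh)
    out[zero] = sigma**2
    return out


_chol_cache: dict[tuple, np.ndarray] = {}


def _grid_field_factor(geometry: RasterGeometry, sigma_s: float, range_rho: float) -> np.ndarray:
    """Cholesky factor of the Matern covariance over all pixel centers (cached)."""
    key = (
        geometry.n_rows,
        geometry.n_cols,
        geometry.origin_x,
        geometry.origin_y,
        geometry.cell_size,
        round(sigma_s, 12),
        round(range_rho, 12),
    )
    if key in _chol_cache:
        return _chol_cache[key]
    if geometry.n_pixels > _MAX_EXACT_PIXELS:
        raise ValidationError(
            f"grid has {geometry.n_pixels} pixels; exact simulation capped at {_MAX_EXACT_PIXELS}"
        )
    cx, cy = geometry.cell_centers()
    pts = np.column_stack([cx.ravel(), cy.ravel()])
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    cov = matern_covariance(dist, sigma_s, range_rho)
    jitter = 1e-8 * sigma_s**2
    for _ in range(6):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(len(pts)))
            break
        except np.linalg.LinAlgError:
            jitter *= 10
    else:
        raise ValidationError("Matern covariance not positive definite after jitter")
    _chol_cache[key] = L
    return L


def simulate_truth(
    params: TruthParams,
    stack: CovariateStack,
    geometry: RasterGeometry,
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Simulate the latent field and true prevalence grid for every year.

    Returns ``(prevalence, latent)``, each ``{year: 2-D grid}``.  Year 1 is
    drawn from the stationary distribution; later years follow
    ``S_t = phi * S_{t-1} + omega_t`` with innovation variance
    ``sigma_s**2 * (1 - phi**2)``.
    """
    for name in params.beta:
        if name not in stack.layers:
            raise ValidationError(f"truth references covariate {name!r} absent from stack")
    rng = np.random.default_rng(params.seed)
    shape = geometry.shape
    n_pix = geometry.n_pixels

    if params.sigma_s > 0:
        L = _grid_field_factor(geometry, params.sigma_s, params.range_rho)
        s = L @ rng.standard_normal(n_pix)
    else:
        s = np.zeros(n_pix)
    innov_scale = math.sqrt(max(1.0 - params.phi**2, 0.0))

    latent: dict[int, np.ndarray] = {}
    prevalence: dict[int, np.ndarray] = {}
    for i, year in enumerate(stack.years):
        if i > 0:
            if params.sigma_s > 0:
                omega = innov_scale * (L @ rng.standard_normal(n_pix))
            else:
                omega = np.zeros(n_pix)
            s = params.phi * s + omega
        field = s.reshape(shape)
        eta = np.full(shape, params.beta0) + field
        for name, b in params.beta.items():
            eta = eta + b * stack.layers[name][year]
        latent[year] = field
        prevalence[year] = expit(eta)
    return prevalence, latent


# ---------------------------------------------------------------------------
# Surveys
# ---------------------------------------------------------------------------

def sample_surveys(
    prevalence: dict[int, np.ndarray],
    design: SurveyDesign,
    geometry: RasterGeometry,
    sigma_eps: float = 0.15,
) -> list[ClusterRecord]:
    """Draw cluster surveys from the true prevalence grids.

    Cluster locations are pixel centers sampled per the design placement;
    counts are ``Binomial(n, expit(logit(p) + eps))`` with a cluster-level
    Gaussian nugget ``eps``.  Seasons alternate Gu/Deyr within each year.
    """
    years = sorted(prevalence)
    if len(years) < design.n_years:
        raise ValidationError("truth grids do not cover design.n_years")
    years = years[: design.n_years]
    rng = np.random.default_rng(design.seed)
    ok = ~geometry.mask()
    rows_ok, cols_ok = np.nonzero(ok)

    if design.placement == "clustered":
        n_hot = max(3, design.clusters_per_year // 50)
        hot = rng.choice(len(rows_ok), size=n_hot, replace=False)

    records: list[ClusterRecord] = []
    for year in years:
        p_grid = prevalence[year]
        if design.placement == "uniform":
            idx = rng.choice(len(rows_ok), size=design.clusters_per_year, replace=True)
        else:
            centers = rng.choice(hot, size=design.clusters_per_year, replace=True)
            jr = rng.integers(-5, 6, design.clusters_per_year)
            jc = rng.integers(-5, 6, design.clusters_per_year)
            rr = np.clip(rows_ok[centers] + jr, 0, geometry.n_rows - 1)
            cc = np.clip(cols_ok[centers] + jc, 0, geometry.n_cols - 1)
            idx = None
        for j in range(design.clusters_per_year):
            if idx is not None:
                r, c = rows_ok[idx[j]], cols_ok[idx[j]]
            else:
                r, c = rr[j], cc[j]
            x = geometry.origin_x + (c + 0.5) * geometry.cell_size
            y = geometry.origin_y + (r + 0.5) * geometry.cell_size
            n = int(rng.integers(design.children_range[0], design.children_range[1] + 1))
            p = float(p_grid[r, c])
            if 0.0 < p < 1.0 and sigma_eps > 0:
                p = float(expit(logit(p) + sigma_eps * rng.standard_normal()))
            k = int(rng.binomial(n, p))
            records.append(
                ClusterRecord(
                    cluster_id=f"{year}-{j:04d}",
                    x=x,
                    y=y,
                    year=year,
                    season=SEASONS[j % 2],
                    n_examined=n,
                    n_stunted=k,
                )
            )
    return records


def default_bundle(
    seed: int = 0,
    design: SurveyDesign | None = None,
    params: TruthParams | None = None,
    n_rows: int = 48,
    n_cols: int = 48,
    n_regions: int = 18,
):
    """Convenience: generate the full default synthetic input bundle.

    Returns a dict with geometry, regions, population, stack, truth prevalence,
    latent fields, truth params, and the cluster list (covariates attached).
    """
    from .data_model import extract_covariates

    params = params if params is not None else TruthParams(seed=seed)
    design = design if design is not None else SurveyDesign(seed=seed + 1)
    geometry, regions, population = make_domain(
        n_rows=n_rows, n_cols=n_cols, n_regions=n_regions, seed=seed + 2
    )
    stack = simulate_covariates(geometry, DEFAULT_YEARS[: design.n_years], seed=seed + 3)
    prevalence, latent = simulate_truth(params, stack, geometry)
    clusters = sample_surveys(prevalence, design, geometry, sigma_eps=params.sigma_eps)
    clusters = extract_covariates(clusters, stack)
    return {
        "geometry": geometry,
        "regions": regions,
        "population": population,
        "stack": stack,
        "prevalence": prevalence,
        "latent": latent,
        "params": params,
        "design": design,
        "clusters": clusters,
    }
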