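"""Surfaces, WHO classes, regional aggregation and the observed table."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from stuntcast.data_model import (
    ClusterRecord,
    PopulationRaster,
    RasterGeometry,
    RegionMap,
    ValidationError,
)
from stuntcast.mapping import (
    PrevalenceSurface,
    aggregate_regions,
    classify_who,
    forecast_surface,
    observed_region_prevalence,
    predict_surface,
    round_half_up,
)
from stuntcast.spacetime import Hyperparams, Mesh, ModelConfig, PosteriorFit


def _degenerate_fit(mesh, beta, years, J=600, field=None):
    """PosteriorFit with all posterior mass at one point (no uncertainty)."""
    p = len(beta)
    T = len(years)
    field_arr = np.zeros((J, T, mesh.n_nodes)) if field is None else np.tile(field, (J, 1, 1))
    return PosteriorFit(
        beta_names=("intercept",) + tuple(f"c{i}" for i in range(p - 1)),
        beta_mean=np.asarray(beta, float),
        beta_cov=np.zeros((p, p)),
        hyper=Hyperparams(kappa=0.3, tau=1.0, phi=0.5, sigma_eps=0.0),
        hyper_intervals={},
        years=list(years),
        node_mean=field_arr[0],
        samples_beta=np.tile(np.asarray(beta, float), (J, 1)),
        samples_field=field_arr,
        mesh=mesh,
        engine="laplace",
        seed=0,
        config=ModelConfig(),
    )


@pytest.fixture()
def flat_world():
    geom = RasterGeometry(8, 8)
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-6, 14, 40), rng.uniform(-6, 14, 40)])
    mesh = Mesh.from_points(pts)
    from stuntcast.data_model import CovariateStack

    stack = CovariateStack(
        geometry=geom,
        years=[2007, 2008],
        layers={"c0": {2007: np.full(geom.shape, 0.5), 2008: np.full(geom.shape, 0.25)}},
    )
    return geom, mesh, stack


class TestPredictSurface:
    def test_zero_model_gives_half_everywhere(self, flat_world):
        geom, mesh, stack = flat_world
        f = _degenerate_fit(mesh, [0.0, 0.0], [2007, 2008])
        surf = predict_surface(f, stack, 2007, geom)
        assert np.allclose(surf.mean, 0.5)
        assert np.allclose(surf.sd, 0.0)

    def test_mean_bounded_by_sample_envelope(self, small_bundle):
        from stuntcast.spacetime import build_mesh, fit

        b = small_bundle
        mesh = build_mesh(b["clusters"], b["geometry"], max_edge=6.0, buffer=8.0)
        f = fit(b["clusters"], ("EVI",), mesh, ModelConfig(n_samples=600, seed=0))
        surf = predict_surface(f, b["stack"], 2008, b["geometry"])
        flat = surf.mean.ravel()
        assert np.all(flat >= surf.samples.min(axis=0) - 1e-12)
        assert np.all(flat <= surf.samples.max(axis=0) + 1e-12)
        assert surf.mean.min() >= 0.0 and surf.mean.max() <= 1.0

    def test_unfitted_year_rejected(self, flat_world):
        geom, mesh, stack = flat_world
        f = _degenerate_fit(mesh, [0.0, 0.0], [2007])
        with pytest.raises(ValidationError, match="forecast"):
            predict_surface(f, stack, 2008, geom)

    def test_pixel_error_shrinks_with_more_clusters(self):
        from stuntcast import synthetic
        from stuntcast.spacetime import build_mesh, fit

        errs = {30: [], 300: []}
        for n_cl in errs:
            for seed in (9, 21):
                design = synthetic.SurveyDesign(
                    n_years=2, clusters_per_year=n_cl, seed=seed + n_cl
                )
                b = synthetic.default_bundle(
                    seed=seed, design=design, n_rows=24, n_cols=24, n_regions=6
                )
                mesh = build_mesh(b["clusters"], b["geometry"], max_edge=6.0, buffer=8.0)
                f = fit(
                    b["clusters"], ("precipitation", "EVI"), mesh,
                    ModelConfig(n_samples=200, seed=0),
                )
                surf = predict_surface(f, b["stack"], 2008, b["geometry"])
                errs[n_cl].append(np.abs(surf.mean - b["prevalence"][2008]).mean())
        assert np.mean(errs[300]) < np.mean(errs[30])


class TestForecastSurface:
    def test_fixed_only_equals_covariate_map(self, flat_world):
        geom, mesh, stack = flat_world
        f = _degenerate_fit(mesh, [0.3, -0.8], [2007])
        surf = forecast_surface(f, stack, 2008, geom, mode="fixed_only")
        assert np.allclose(surf.mean, expit(0.3 - 0.8 * 0.25))

    def test_phi_zero_ar_mode_centres_on_covariates(self, flat_world):
        geom, mesh, stack = flat_world
        f = _degenerate_fit(mesh, [0.3, -0.8], [2007], J=4000)
        f.hyper = Hyperparams.from_range_sigma(range_rho=8.0, sigma_s=0.4, phi=0.0)
        surf = forecast_surface(f, stack, 2008, geom, mode="ar", seed=1)
        # mean field is zero, so the surface centres on the covariate-only map
        # (slightly attenuated toward 0.5 by averaging expit over field draws)
        target = expit(0.3 - 0.8 * 0.25)
        assert np.abs(surf.mean - target).max() < 0.05
        assert surf.sd.mean() > 0.01  # innovation variance is present

    def test_backward_forecast_rejected(self, flat_world):
        geom, mesh, stack = flat_world
        f = _degenerate_fit(mesh, [0.0, 0.0], [2007, 2008])
        with pytest.raises(ValidationError, match="after last fitted"):
            forecast_surface(f, stack, 2008, geom)


class TestClassifyWho:
    def _surface(self, means):
        geom = RasterGeometry(1, len(means))
        arr = np.asarray(means, float)[None, :]
        return PrevalenceSurface(geometry=geom, year=2007, mean=arr, sd=np.zeros_like(arr))

    def test_boundaries_left_closed(self):
        surf = self._surface([0.19, 0.20, 0.299, 0.30, 0.399, 0.40, 0.7])
        classes = classify_who(surf)[0]
        assert list(classes) == [
            "low", "medium", "medium", "high", "high", "very_high", "very_high",
        ]

    def test_partition_and_monotonicity(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, 64)
        surf = self._surface(vals)
        classes = classify_who(surf)[0]
        assert all(c in ("low", "medium", "high", "very_high") for c in classes)
        order = {"low": 0, "medium": 1, "high": 2, "very_high": 3}
        bumped = classify_who(self._surface(np.minimum(vals + 0.05, 1.0)))[0]
        assert all(order[b] >= order[a] for a, b in zip(classes, bumped))


class TestAggregateRegions:
    def _world(self):
        geom = RasterGeometry(2, 2)
        regions = RegionMap(
            geometry=geom,
            region_id=np.array([[0, 0], [1, 1]]),
            zone_of={0: "north", 1: "south"},
        )
        pop = PopulationRaster(
            geometry=geom, years=[2007],
            counts={2007: np.array([[100.0, 300.0], [50.0, 50.0]])},
        )
        return geom, regions, pop

    def _surface(self, geom, mean):
        return PrevalenceSurface(
            geometry=geom, year=2007, mean=np.asarray(mean, float), sd=np.zeros(geom.shape)
        )

    def test_uniform_surface_gives_that_prevalence(self):
        geom, regions, pop = self._world()
        out = aggregate_regions(self._surface(geom, np.full((2, 2), 0.27)), pop, regions)
        assert np.allclose(out["prevalence"], 0.27)

    def test_hand_computed_weighting(self):
        geom, regions, pop = self._world()
        surf = self._surface(geom, [[0.2, 0.4], [0.1, 0.1]])
        out = aggregate_regions(surf, pop, regions).set_index("region")
        assert out.loc[0, "prevalence"] == pytest.approx((0.2 * 100 + 0.4 * 300) / 400)
        assert out.loc[1, "prevalence"] == pytest.approx(0.1)

    def test_national_equals_population_weighted_regions(self):
        geom, regions, pop = self._world()
        surf = self._surface(geom, [[0.2, 0.4], [0.1, 0.6]])
        out = aggregate_regions(surf, pop, regions)
        national = out["stunted_count"].sum() / out["population"].sum()
        byhand = (surf.mean * pop.counts[2007]).sum() / pop.counts[2007].sum()
        assert national == pytest.approx(byhand)
        # counts are conserved exactly
        assert out["stunted_count"].sum() == pytest.approx(
            (surf.mean * pop.counts[2007]).sum()
        )

    def test_geometry_mismatch_rejected(self):
        geom, regions, pop = self._world()
        other = RasterGeometry(3, 3)
        surf = PrevalenceSurface(
            geometry=other, year=2007, mean=np.full((3, 3), 0.1), sd=np.zeros((3, 3))
        )
        with pytest.raises(ValidationError, match="geometry"):
            aggregate_regions(surf, pop, regions)

    def test_zero_population_region_flagged(self):
        geom, regions, _ = self._world()
        pop = PopulationRaster(
            geometry=geom, years=[2007],
            counts={2007: np.array([[100.0, 300.0], [0.0, 0.0]])},
        )
        out = aggregate_regions(self._surface(geom, np.full((2, 2), 0.3)), pop, regions)
        row = out.set_index("region").loc[1]
        assert bool(row["zero_population"]) and np.isnan(row["prevalence"])


class TestObservedPrevalence:
    def test_reference_rows_reproduce_published_percents(self):
        from stuntcast.datasets import somalia_summary_clusters

        table = observed_region_prevalence(somalia_summary_clusters())
        t = table.set_index("region")
        assert t.loc["Hiraan", "percent_stunted"] == 21.04
        assert t.loc["Bari", "percent_stunted"] == 26.59
        assert t.loc["Total", "percent_stunted"] == 30.82
        assert t.loc["Total", "n_examined"] == 73778
        assert t.loc["Total", "n_stunted"] == 22739

    def test_zero_stunted_gives_zero_percent(self):
        recs = [
            ClusterRecord(f"c{i}", 0.5, 0.5, 2007, "Gu", 30, 0, region=f"r{i % 2}")
            for i in range(4)
        ]
        table = observed_region_prevalence(recs)
        assert (table["percent_stunted"] == 0.0).all()

    def test_region_lookup_from_map_and_outside_error(self):
        geom = RasterGeometry(2, 2)
        regions = RegionMap(
            geometry=geom, region_id=np.array([[0, 0], [1, 1]]),
            zone_of={0: "n", 1: "s"},
        )
        recs = [ClusterRecord("in1", 0.5, 0.5, 2007, "Gu", 10, 5)]
        out = observed_region_prevalence(recs, regions)
        assert out.iloc[0]["region"] == 0

    def test_half_up_rounding(self):
        assert round_half_up(26.585) == 26.59
        assert round_half_up(21.0350) == 21.04
        assert round_half_up(0.004) == 0.0
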