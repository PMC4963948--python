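"""Generator checks: determinism, ranges, and latent-field moment oracles."""

import numpy as np
import pytest

from stuntcast import synthetic
from stuntcast.data_model import RasterGeometry
from stuntcast.synthetic import (
    SurveyDesign,
    TruthParams,
    make_domain,
    matern_covariance,
    sample_surveys,
    simulate_covariates,
    simulate_truth,
)


class TestMakeDomain:
    def test_single_region_covers_everything(self):
        _, regions, _ = make_domain(n_rows=12, n_cols=12, n_regions=1, seed=0)
        assert regions.labels() == [0]
        assert np.all(regions.region_id == 0)

    def test_deterministic_given_seed(self):
        a = make_domain(n_rows=16, n_cols=16, n_regions=5, seed=9)
        b = make_domain(n_rows=16, n_cols=16, n_regions=5, seed=9)
        assert np.array_equal(a[1].region_id, b[1].region_id)
        assert all(
            np.array_equal(a[2].counts[y], b[2].counts[y]) for y in a[2].years
        )

    def test_regions_partition_all_pixels(self):
        _, regions, _ = make_domain(n_rows=40, n_cols=40, n_regions=18, seed=2)
        labels, counts = np.unique(regions.region_id, return_counts=True)
        assert sorted(labels) == list(range(18))  # every region nonempty
        assert counts.sum() == 1600  # union of regions = all pixels
        assert all(r in regions.zone_of for r in labels)


class TestCovariates:
    def test_evi_within_unit_interval(self):
        geom = RasterGeometry(20, 20)
        stack = simulate_covariates(geom, [2007, 2008], seed=0)
        for year, grid in stack.layers["EVI"].items():
            assert grid.min() >= 0.0 and grid.max() <= 1.0

    def test_zero_anomaly_gives_identical_years(self):
        geom = RasterGeometry(15, 15)
        stack = simulate_covariates(geom, [2007, 2008], seed=1, anomaly_amplitude=0.0)
        for name in ("precipitation", "EVI", "temperature"):
            assert np.array_equal(stack.layers[name][2007], stack.layers[name][2008])

    def test_precipitation_correlogram_decays(self):
        geom = RasterGeometry(40, 40)
        stack = simulate_covariates(geom, [2007], seed=2)
        g = stack.layers["precipitation"][2007]
        g = g - g.mean()
        var = (g * g).mean()

        def corr_at_lag(k):
            return (g[:, :-k] * g[:, k:]).mean() / var

        lags = [1, 4, 10, 20]
        cors = [corr_at_lag(k) for k in lags]
        assert var > 0  # lag-0 correlation is exactly 1 by construction
        assert all(a > b for a, b in zip(cors, cors[1:]))
        assert cors[0] > 0.8 and cors[-1] < 0.5


class TestTruth:
    def _flat_stack(self, geom, years=(2007, 2008)):
        zeros = {y: np.zeros(geom.shape) for y in years}
        return synthetic.CovariateStack(
            geometry=geom, years=list(years), layers={"temperature": dict(zeros)}
        )

    def test_degenerate_field_gives_constant_prevalence(self):
        geom = RasterGeometry(8, 8)
        stack = self._flat_stack(geom)
        params = TruthParams(beta0=0.4, beta={}, sigma_s=0.0, phi=0.5, seed=0)
        prev, latent = simulate_truth(params, stack, geom)
        from scipy.special import expit

        for y in stack.years:
            assert np.allclose(prev[y], expit(0.4))
            assert np.allclose(latent[y], 0.0)

    def test_phi_zero_fields_uncorrelated_across_years(self):
        geom = RasterGeometry(8, 8)
        stack = self._flat_stack(geom)
        cors = []
        for rep in range(200):
            params = TruthParams(
                beta={}, sigma_s=0.5, range_rho=6.0, phi=0.0, seed=1000 + rep
            )
            _, latent = simulate_truth(params, stack, geom)
            a, b = latent[2007].ravel(), latent[2008].ravel()
            cors.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_stationary_variance_matches_closed_form(self):
        geom = RasterGeometry(8, 8)
        stack = self._flat_stack(geom, years=(2007,))
        sigma = 0.5
        draws = []
        for rep in range(300):
            params = TruthParams(
                beta={}, sigma_s=sigma, range_rho=6.0, phi=0.8, seed=2000 + rep
            )
            _, latent = simulate_truth(params, stack, geom)
            draws.append(latent[2007])
        var = np.var(np.stack(draws), axis=0).mean()
        assert var == pytest.approx(sigma**2, rel=0.15)

    def test_matern_covariance_shape(self):
        # C(0) = sigma^2 and correlation at the range is ~0.14 (nu=1 convention)
        assert matern_covariance(np.array(0.0), 0.5, 10.0) == pytest.approx(0.25)
        c = matern_covariance(np.array(10.0), 1.0, 10.0)
        assert c == pytest.approx(0.14, abs=0.02)


class TestSurveys:
    def test_extreme_prevalence_limits(self):
        geom = RasterGeometry(6, 6)
        design = SurveyDesign(n_years=1, clusters_per_year=30, seed=0)
        zeros = {2007: np.zeros(geom.shape)}
        ones = {2007: np.ones(geom.shape)}
        all_zero = sample_surveys(zeros, design, geom)
        assert all(c.n_stunted == 0 for c in all_zero)
        all_one = sample_surveys(ones, design, geom)
        assert all(c.n_stunted == c.n_examined for c in all_one)

    def test_pooled_prevalence_near_design_value(self):
        # study conditions: ~30 % pooled prevalence, averaged over seeds
        ratios = []
        for seed in range(4):
            b = synthetic.default_bundle(seed=seed)
            cl = b["clusters"]
            ratios.append(sum(c.n_stunted for c in cl) / sum(c.n_examined for c in cl))
        assert np.mean(ratios) == pytest.approx(0.30, abs=0.03)

    def test_bundle_determinism(self):
        d = SurveyDesign(n_years=2, clusters_per_year=40, seed=3)
        b1 = synthetic.default_bundle(seed=7, design=d, n_rows=16, n_cols=16, n_regions=4)
        b2 = synthetic.default_bundle(seed=7, design=d, n_rows=16, n_cols=16, n_regions=4)
        from stuntcast.data_model import clusters_to_frame

        assert clusters_to_frame(b1["clusters"]).equals(clusters_to_frame(b2["clusters"]))
        for y in b1["prevalence"]:
            assert np.array_equal(b1["prevalence"][y], b2["prevalence"][y])

    def test_seasons_alternate(self):
        geom = RasterGeometry(6, 6)
        design = SurveyDesign(n_years=1, clusters_per_year=10, seed=0)
        recs = sample_surveys({2007: np.full(geom.shape, 0.3)}, design, geom)
        assert {c.season for c in recs} == {"Gu", "Deyr"}
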