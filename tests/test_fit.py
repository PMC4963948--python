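"""Laplace engine behaviour: invariances, prior limits, posterior summaries."""

import numpy as np
import pytest
from scipy.special import expit

from stuntcast.data_model import ClusterRecord
from stuntcast.spacetime import (
    Hyperparams,
    Mesh,
    ModelConfig,
    PosteriorFit,
    build_st_precision,
    fit,
    odds_ratios,
    spde_precision,
)


@pytest.fixture(scope="module")
def small_fit(small_bundle):
    mesh_clusters = small_bundle["clusters"]
    from stuntcast.spacetime import build_mesh

    mesh = build_mesh(mesh_clusters, small_bundle["geometry"], max_edge=6.0, buffer=8.0)
    cfg = ModelConfig(n_samples=800, seed=2)
    return fit(mesh_clusters, ("precipitation", "EVI"), mesh, cfg), mesh


@pytest.fixture(scope="module")
def tiny_mesh():
    rng = np.random.default_rng(0)
    pts = np.array([[0, 0], [12, 0], [24, 0], [0, 12], [12, 12], [24, 12]], float)
    return Mesh.from_points(pts + rng.normal(0, 0.2, pts.shape))


def _tiny_clusters(seed=0, n=14, years=(2007, 2008)):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cov = float(rng.uniform(0, 1))
        p = expit(0.2 - 0.7 * cov + 0.15 * rng.standard_normal())
        out.append(
            ClusterRecord(
                f"t{i}", float(rng.uniform(2, 22)), float(rng.uniform(2, 10)),
                years[i % len(years)], "Gu", 60, int(rng.binomial(60, p)),
                {"EVI": cov},
            )
        )
    return out


class TestLaplaceEngine:
    def test_cluster_order_invariance(self, tiny_mesh):
        clusters = _tiny_clusters(seed=1)
        cfg = ModelConfig(n_samples=10, seed=0, max_outer_evals=80)
        f1 = fit(clusters, ("EVI",), tiny_mesh, cfg)
        f2 = fit(list(reversed(clusters)), ("EVI",), tiny_mesh, cfg)
        assert np.allclose(f1.beta_mean, f2.beta_mean, atol=1e-4)
        assert f1.hyper.kappa == pytest.approx(f2.hyper.kappa, rel=1e-3)

    def test_empty_clusters_return_exact_prior(self, tiny_mesh):
        h = Hyperparams.from_range_sigma(range_rho=10.0, sigma_s=0.5, phi=0.6, sigma_eps=0.1)
        cfg = ModelConfig(n_samples=5, seed=0, fix_hyperparams=h, beta_prior_sd=10.0)
        f = fit([], ("EVI",), tiny_mesh, cfg, years_used=[2007, 2008])
        assert np.allclose(f.beta_mean, 0.0)
        assert np.allclose(f.node_mean, 0.0)
        assert np.allclose(np.diag(f.beta_cov), 100.0)
        # field block of the posterior covariance equals the prior covariance
        Q_s = spde_precision(tiny_mesh, h.kappa, h.tau)
        Q_st = build_st_precision(Q_s, h.phi, 2).toarray()
        m2 = 2 * tiny_mesh.n_nodes
        # marginal variance of the first node from samples is prior-consistent
        prior_cov = np.linalg.inv(Q_st)
        f_big = fit(
            [], ("EVI",), tiny_mesh,
            ModelConfig(n_samples=4000, seed=1, fix_hyperparams=h),
            years_used=[2007, 2008],
        )
        sample_var = f_big.samples_field.reshape(4000, m2).var(axis=0)
        assert np.allclose(sample_var, np.diag(prior_cov), rtol=0.2)

    def test_year_without_data_follows_ar_propagation(self, tiny_mesh):
        # with no year-2 likelihood, the conditional mode obeys s2 = phi * s1
        clusters = [c for c in _tiny_clusters(seed=2) if c.year == 2007]
        h = Hyperparams.from_range_sigma(range_rho=10.0, sigma_s=0.5, phi=0.7, sigma_eps=0.1)
        cfg = ModelConfig(n_samples=5, seed=0, fix_hyperparams=h)
        f = fit(clusters, ("EVI",), tiny_mesh, cfg, years_used=[2007, 2008])
        assert np.allclose(f.node_mean[1], 0.7 * f.node_mean[0], atol=1e-5)
        assert np.abs(f.node_mean[0]).max() > 1e-4  # year 1 actually moved

    def test_samples_match_stored_moments(self, small_fit):
        f, _ = small_fit
        mc = f.samples_beta.mean(axis=0)
        sd_stored = np.sqrt(np.diag(f.beta_cov))
        sd_mc = f.samples_beta.std(axis=0)
        assert np.allclose(mc, f.beta_mean, atol=4 * sd_stored / np.sqrt(f.n_samples) + 1e-12)
        assert np.allclose(sd_mc, sd_stored, rtol=0.15)

    def test_recovers_generative_hyperparameters(self, default_bundle_seed1):
        from stuntcast.spacetime import build_mesh

        b = default_bundle_seed1
        mesh = build_mesh(b["clusters"], b["geometry"])
        f = fit(b["clusters"], ("precipitation", "EVI"), mesh, ModelConfig(n_samples=10, seed=0))
        p = b["params"]
        assert f.hyper.range_rho == pytest.approx(p.range_rho, rel=0.6)
        assert f.hyper.sigma_s == pytest.approx(p.sigma_s, rel=0.5)
        assert f.hyper.phi > 0.9
        assert f.beta_mean[1] == pytest.approx(p.beta["precipitation"], abs=3e-3)


class TestOddsRatios:
    def _fit_with_samples(self, samples):
        return PosteriorFit(
            beta_names=("intercept", "EVI"),
            beta_mean=samples.mean(axis=0),
            beta_cov=np.cov(samples.T),
            hyper=Hyperparams(kappa=0.3, tau=1.0, phi=0.5),
            hyper_intervals={},
            years=[2007],
            node_mean=np.zeros((1, 3)),
            samples_beta=samples,
            samples_field=np.zeros((len(samples), 1, 3)),
            mesh=Mesh(nodes=np.eye(3, 2), triangles=np.array([[0, 1, 2]])),
            engine="laplace",
            seed=0,
            config=ModelConfig(),
        )

    def test_degenerate_zero_gives_unit_or(self):
        samples = np.zeros((1000, 2))
        table = odds_ratios(self._fit_with_samples(samples))
        row = table.iloc[0]
        assert row["OR"] == 1.0 and row["CrI_2.5%"] == 1.0 and row["CrI_97.5%"] == 1.0
        assert not row["significant"]

    def test_constant_log_or(self):
        samples = np.zeros((1000, 2))
        samples[:, 1] = np.log(0.994)
        row = odds_ratios(self._fit_with_samples(samples)).iloc[0]
        assert row["OR"] == pytest.approx(0.994, rel=1e-12)

    def test_percentiles_match_sorting_oracle(self):
        rng = np.random.default_rng(5)
        samples = np.column_stack([np.zeros(801), rng.normal(-0.3, 0.1, 801)])
        row = odds_ratios(self._fit_with_samples(samples)).iloc[0]
        srt = np.sort(np.exp(samples[:, 1]))
        lo, med, hi = np.percentile(srt, [2.5, 50, 97.5])
        assert row["CrI_2.5%"] == pytest.approx(lo)
        assert row["OR"] == pytest.approx(med)
        assert row["CrI_97.5%"] == pytest.approx(hi)


class TestSerialisation:
    def test_save_load_roundtrip(self, small_fit, tmp_path):
        f, _ = small_fit
        path = tmp_path / "fit.npz"
        f.save(path)
        g = PosteriorFit.load(path)
        assert g.beta_names == f.beta_names
        assert np.allclose(g.beta_mean, f.beta_mean)
        assert np.allclose(g.samples_field, f.samples_field)
        assert g.hyper.kappa == pytest.approx(f.hyper.kappa)
        assert g.years == f.years
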