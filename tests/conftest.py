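"""Shared fixtures: small synthetic worlds sized for fast unit tests."""

import numpy as np
import pytest

from stuntcast import synthetic
from stuntcast.data_model import ClusterRecord, RasterGeometry


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced synthetic world: 24x24 km, 6 regions, 3 years, 80 clusters/year.

    Session-scoped; tests must not mutate it.
    """
    design = synthetic.SurveyDesign(n_years=3, clusters_per_year=80, seed=5)
    return synthetic.default_bundle(
        seed=4, design=design, n_rows=24, n_cols=24, n_regions=6
    )


@pytest.fixture(scope="session")
def default_bundle_seed1():
    """One default-scale bundle (48x48, 18 regions, 4x250 clusters)."""
    return synthetic.default_bundle(seed=1)


@pytest.fixture()
def tiny_geometry():
    return RasterGeometry(n_rows=10, n_cols=12)


def make_glm_clusters(
    beta0: float,
    beta: dict[str, float],
    n_clusters: int,
    seed: int,
    n_children: int = 80,
    extra_null: tuple[str, ...] = (),
) -> list[ClusterRecord]:
    """Clusters from a pure GLM (no spatial field): the screening null world."""
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_clusters):
        covs = {name: float(rng.uniform(0, 1)) for name in set(beta) | set(extra_null)}
        if "precipitation" in covs:
            covs["precipitation"] = float(rng.uniform(0, 600))
        eta = beta0 + sum(b * covs[k] for k, b in beta.items())
        k = int(rng.binomial(n_children, expit(eta)))
        out.append(
            ClusterRecord(
                cluster_id=f"g{i}",
                x=float(rng.uniform(0, 10)),
                y=float(rng.uniform(0, 10)),
                year=2007,
                season="Gu",
                n_examined=n_children,
                n_stunted=k,
                covariates=covs,
            )
        )
    return out
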