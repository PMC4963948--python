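"""Covariate pre-selection by exhaustive BIC search over binomial GLMs.

Candidate environmental covariates are screened with non-spatial binomial
logit GLMs on cluster-level counts; all ``2**m`` subsets (including the empty
model) are fitted and ranked by BIC.  Spatial correlation is deliberately
ignored at this stage — it is a pre-selection step, and the selected subset is
passed to the geostatistical model which does account for it.

``n`` in the BIC penalty is the number of clusters (the binomial observations
of the likelihood), not the number of children.  Covariates enter on their
native scales (mm, EVI units, ...) so coefficients are per native unit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .data_model import ClusterRecord

__all__ = ["GlmFit", "fit_glm", "bic", "select_covariates", "binomial_loglik"]

DEFAULT_CANDIDATES = ("precipitation", "EVI", "temperature", "distance_to_water", "urban")


class FitError(RuntimeError):
    """GLM fitting failed (rank deficiency or non-convergence)."""


@dataclass
class GlmFit:
    """A fitted binomial logit GLM on cluster counts."""

    covariate_names: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    std_errors: dict[str, float]
    log_likelihood: float
    n_obs: int

    @property
    def k(self) -> int:
        """Number of free parameters: intercept + covariates."""
        return 1 + len(self.covariate_names)

    def wald_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        b, se = self.coefficients[name], self.std_errors[name]
        return (b - z * se, b + z * se)


def _design(clusters: Sequence[ClusterRecord], names: Sequence[str]) -> np.ndarray:
    X = np.ones((len(clusters), 1 + len(names)))
    for j, name in enumerate(names):
        try:
            X[:, 1 + j] = [c.covariates[name] for c in clusters]
        except KeyError as exc:
            raise FitError(f"covariate {name!r} missing on some cluster") from exc
    return X


def binomial_loglik(
    beta: np.ndarray, X: np.ndarray, successes: np.ndarray, totals: np.ndarray
) -> float:
    """Direct binomial log-likelihood (with normalising constant) at beta."""
    eta = X @ beta
    const = gammaln(totals + 1) - gammaln(successes + 1) - gammaln(totals - successes + 1)
    return float(np.sum(const + successes * eta - totals * np.log1p(np.exp(eta))))


def fit_glm(clusters: Sequence[ClusterRecord], covariate_names: Sequence[str] = ()) -> GlmFit:
    """Maximum-likelihood binomial logit fit of stunting counts on covariates.

    Fitting is by IRLS (statsmodels GLM); the returned log-likelihood includes
    the binomial normalising constant, so it is comparable across subsets.
    """
    if len(clusters) < 2:
        raise FitError("need at least 2 clusters")
    names = tuple(covariate_names)
    X = _design(clusters, names)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"rank-deficient design for columns ('intercept', {', '.join(names)})")
    y = np.column_stack(
        [
            [c.n_stunted for c in clusters],
            [c.n_examined - c.n_stunted for c in clusters],
        ]
    ).astype(float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # perfect separation etc.
        raise FitError(f"GLM fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError("GLM produced non-finite coefficients")
    labels = ("intercept",) + names
    return GlmFit(
        covariate_names=names,
        coefficients=dict(zip(labels, map(float, res.params))),
        std_errors=dict(zip(labels, map(float, res.bse))),
        log_likelihood=float(res.llf),
        n_obs=len(clusters),
    )


def bic(fit: GlmFit) -> float:
    """Bayesian Information Criterion: k*ln(n_obs) - 2*log_likelihood."""
    return fit.k * math.log(fit.n_obs) - 2.0 * fit.log_likelihood


def select_covariates(
    clusters: Sequence[ClusterRecord],
    candidate_names: Sequence[str] = DEFAULT_CANDIDATES,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Exhaustive BIC model selection over all subsets of the candidates.

    Returns ``(best_subset, audit_table)``.  The audit table has one row per
    subset (including the empty model) with its BIC, log-likelihood and any
    fit error.  Ties in BIC are broken by smaller ``k``, then lexicographic
    subset order.
    """
    candidates = tuple(candidate_names)
    if len(candidates) > 15:
        raise ValueError("exhaustive search limited to 15 candidates")
    rows = []
    fits: dict[tuple[str, ...], GlmFit] = {}
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            try:
                f = fit_glm(clusters, subset)
                fits[subset] = f
                rows.append(
                    {
                        "subset": ",".join(subset) if subset else "(intercept only)",
                        "k": f.k,
                        "log_likelihood": f.log_likelihood,
                        "bic": bic(f),
                        "error": "",
                    }
                )
            except FitError as exc:
                rows.append(
                    {
                        "subset": ",".join(subset) if subset else "(intercept only)",
                        "k": 1 + len(subset),
                        "log_likelihood": np.nan,
                        "bic": np.nan,
                        "error": str(exc),
                    }
                )
    table = pd.DataFrame(rows)
    valid = [(s, bic(f)) for s, f in fits.items()]
    if not valid:
        raise FitError("every candidate subset failed to fit")
    best = min(valid, key=lambda sb: (round(sb[1], 10), len(sb[0]), sb[0]))[0]
    return best, table.sort_values("bic", na_position="last").reset_index(drop=True)
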