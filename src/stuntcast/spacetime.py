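"""Bayesian hierarchical space-time binomial prevalence model.

The model for cluster ``i`` surveyed in year ``t(i)`` at location ``s_i``::

    n_stunted_i ~ Binomial(n_examined_i, p_i)
    logit(p_i)  = x_i' beta + S_{t(i)}(s_i) + eps_i,   eps_i ~ N(0, sigma_eps^2)

with ``S_t`` a Matern (nu=1) Gaussian field evolving as a stationary AR(1)
across years: ``S_t = phi S_{t-1} + omega_t``, innovations scaled so each
year's marginal field variance is ``sigma_s^2``.  The Matern field is
approximated by a Gaussian Markov random field on a triangulated mesh via the
SPDE (alpha=2) finite-element construction, giving a sparse spatial precision

    Q_s = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G)

with C the lumped mass matrix and G the stiffness matrix, and a separable
space-time precision ``Q_time(phi) (x) Q_s``.

Inference engines
-----------------
``laplace`` (default): empirical Bayes — an inner Newton optimisation gives
the Gaussian approximation of the latent posterior at each hyperparameter
value; the Laplace-approximated marginal posterior of the hyperparameters is
maximised numerically; joint samples are drawn from the Gaussian at the mode.
The cluster nugget is eliminated analytically (Schur complement), so the
dense factorisations only involve mesh-node weights and fixed effects.

``mcmc``: an affine-invariant ensemble sampler (emcee) on the identical
posterior, jointly over latent variables and hyperparameters.  It is
practical only for small instances and serves as the reference for the
Laplace engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.spatial import Delaunay
from scipy.special import expit
from scipy.stats import norm

from .data_model import ClusterRecord, RasterGeometry, ValidationError

__all__ = [
    "Mesh",
    "Hyperparams",
    "ModelConfig",
    "PosteriorFit",
    "build_mesh",
    "spde_precision",
    "fem_matrices",
    "ar1_precision",
    "build_st_precision",
    "fit",
    "odds_ratios",
]


class FitError(RuntimeError):
    """Model fitting failed; message carries diagnostics."""


# ---------------------------------------------------------------------------
# Mesh and projector
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Triangulated mesh with a barycentric point projector."""

    nodes: np.ndarray  # (m, 2) km
    triangles: np.ndarray  # (n_tri, 3) int

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self._tri = None

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Mesh":
        points = np.asarray(points, dtype=float)
        if len(points) < 3:
            raise ValidationError("mesh needs at least 3 points")
        tri = Delaunay(points)
        mesh = cls(nodes=tri.points, triangles=tri.simplices)
        mesh._tri = tri
        return mesh

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def _delaunay(self) -> Delaunay:
        if self._tri is None:
            self._tri = Delaunay(self.nodes)
        return self._tri

    def projector(self, points: np.ndarray) -> sp.csr_matrix:
        """Sparse matrix A with A[i] the barycentric weights of point i.

        Each row is non-negative and sums to 1.  Points outside the mesh hull
        raise a ValidationError.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tri = self._delaunay()
        simplex = tri.find_simplex(points, tol=1e-10)
        if np.any(simplex < 0):
            bad = int(np.sum(simplex < 0))
            raise ValidationError(f"{bad} query point(s) outside the mesh hull")
        trans = tri.transform[simplex]
        b = np.einsum("ijk,ik->ij", trans[:, :2, :], points - trans[:, 2, :])
        bary = np.column_stack([b, 1.0 - b.sum(axis=1)])
        bary = np.clip(bary, 0.0, None)
        bary /= bary.sum(axis=1, keepdims=True)
        bary[bary < 1e-12] = 0.0
        bary /= bary.sum(axis=1, keepdims=True)
        rows = np.repeat(np.arange(len(points)), 3)
        cols = tri.simplices[simplex].ravel()
        A = sp.csr_matrix((bary.ravel(), (rows, cols)), shape=(len(points), self.n_nodes))
        A.eliminate_zeros()
        return A


def build_mesh(
    clusters: Sequence[ClusterRecord] | np.ndarray,
    geometry: RasterGeometry,
    max_edge: float = 8.0,
    buffer: float = 10.0,
    cutoff: float | None = None,
) -> Mesh:
    """Triangulation over thinned cluster locations plus a boundary lattice.

    Cluster locations closer than ``cutoff`` (default ``max_edge``) to an
    already-kept location are merged; a regular lattice at ``max_edge``
    spacing extends ``buffer`` km beyond the raster so the hull covers every
    prediction pixel and boundary effects of the SPDE are pushed outside the
    domain.
    """
    if cutoff is None:
        cutoff = max_edge
    if hasattr(clusters, "__len__") and len(clusters) and isinstance(clusters[0], ClusterRecord):
        pts = np.array([[c.x, c.y] for c in clusters], dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(clusters, dtype=float))
    if len(pts) < 3:
        raise ValidationError("need at least 3 cluster locations")
    pts = np.unique(pts, axis=0)

    kept: list[np.ndarray] = []
    for p in pts:
        if all(np.hypot(*(p - q)) >= cutoff for q in kept):
            kept.append(p)
    kept_arr = np.array(kept)

    xmin, xmax, ymin, ymax = geometry.extent
    xmin = min(xmin, pts[:, 0].min()) - buffer
    xmax = max(xmax, pts[:, 0].max()) + buffer
    ymin = min(ymin, pts[:, 1].min()) - buffer
    ymax = max(ymax, pts[:, 1].max()) + buffer
    nx = max(int(math.ceil((xmax - xmin) / max_edge)) + 1, 2)
    ny = max(int(math.ceil((ymax - ymin) / max_edge)) + 1, 2)
    gx, gy = np.meshgrid(np.linspace(xmin, xmax, nx), np.linspace(ymin, ymax, ny))
    lattice = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((lattice[:, None, :] - kept_arr[None, :, :]) ** 2).sum(-1)
    lattice = lattice[d2.min(axis=1) > (0.5 * cutoff) ** 2]

    nodes = np.vstack([kept_arr, lattice])
    return Mesh.from_points(nodes)


# ---------------------------------------------------------------------------
# SPDE precision
# ---------------------------------------------------------------------------

def fem_matrices(mesh: Mesh) -> tuple[np.ndarray, sp.csr_matrix]:
    """Lumped mass diagonal C and stiffness matrix G of the P1 FEM basis."""
    nodes, tris = mesh.nodes, mesh.triangles
    m = mesh.n_nodes
    C = np.zeros(m)
    rows, cols, vals = [], [], []
    for tri in tris:
        p = nodes[tri]
        b = np.array([p[1, 1] - p[2, 1], p[2, 1] - p[0, 1], p[0, 1] - p[1, 1]])
        c = np.array([p[2, 0] - p[1, 0], p[0, 0] - p[2, 0], p[1, 0] - p[0, 0]])
        area = 0.5 * abs(
            (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
            - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1])
        )
        if area <= 1e-12:
            raise ValidationError(f"degenerate (zero-area) triangle {tri.tolist()}")
        C[tri] += area / 3.0
        Gl = (np.outer(b, b) + np.outer(c, c)) / (4.0 * area)
        for a in range(3):
            for bb in range(3):
                rows.append(tri[a])
                cols.append(tri[bb])
                vals.append(Gl[a, bb])
    G = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    return C, G


def spde_precision(mesh: Mesh, kappa: float, tau: float) -> sp.csc_matrix:
    """Sparse GMRF precision of the SPDE (alpha=2) Matern approximation.

    ``Q_s = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G)``; symmetric positive
    definite for kappa, tau > 0.
    """
    if kappa <= 0 or tau <= 0:
        raise ValidationError("kappa and tau must be > 0")
    C, G = fem_matrices(mesh)
    Cinv = sp.diags(1.0 / C)
    Q = kappa**4 * sp.diags(C) + 2.0 * kappa**2 * G + G @ Cinv @ G
    Q = tau**2 * Q
    return ((Q + Q.T) * 0.5).tocsc()


def ar1_precision(phi: float, n: int) -> sp.csc_matrix:
    """Precision of a stationary AR(1) with unit marginal variance."""
    if not -1 < phi < 1:
        raise ValidationError("phi must lie in (-1, 1)")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n == 1:
        return sp.eye(1, format="csc")
    diag = np.ones(n)
    diag[1:-1] = 1.0 + phi**2
    off = -phi * np.ones(n - 1)
    Q = sp.diags([off, diag, off], [-1, 0, 1]) / (1.0 - phi**2)
    return Q.tocsc()


def build_st_precision(Q_s: sp.spmatrix, phi: float, n_years: int) -> sp.csc_matrix:
    """Separable space-time precision ``Q_time(phi) (x) Q_s`` (year-major)."""
    if n_years == 1:
        return sp.csc_matrix(Q_s)
    return sp.kron(ar1_precision(phi, n_years), Q_s, format="csc")


# ---------------------------------------------------------------------------
# Hyperparameters and configuration
# ---------------------------------------------------------------------------

@dataclass
class Hyperparams:
    """SPDE + temporal hyperparameters with the derived range/sd relations."""

    kappa: float
    tau: float
    phi: float
    sigma_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.tau <= 0:
            raise ValidationError("kappa and tau must be > 0")
        if not -1 < self.phi < 1:
            raise ValidationError("phi must lie in (-1, 1)")
        if self.sigma_eps < 0:
            raise ValidationError("sigma_eps must be >= 0")

    @property
    def range_rho(self) -> float:
        """Matern nu=1 range in km: sqrt(8)/kappa."""
        return math.sqrt(8.0) / self.kappa

    @property
    def sigma_s(self) -> float:
        """Marginal field standard deviation: 1/sqrt(4 pi kappa^2 tau^2)."""
        return 1.0 / math.sqrt(4.0 * math.pi * self.kappa**2 * self.tau**2)

    @classmethod
    def from_range_sigma(
        cls, range_rho: float, sigma_s: float, phi: float, sigma_eps: float = 0.0
    ) -> "Hyperparams":
        kappa = math.sqrt(8.0) / range_rho
        tau = 1.0 / (math.sqrt(4.0 * math.pi) * kappa * sigma_s)
        return cls(kappa=kappa, tau=tau, phi=phi, sigma_eps=sigma_eps)


@dataclass
class ModelConfig:
    """Priors, engine and sampling settings for :func:`fit`.

    Priors are weakly informative by default: fixed effects N(0, 10^2);
    log-normal priors on the spatial range (median = ``range_median``, by
    default 1/5 of the mesh bounding-box diagonal) and on the marginal field
    sd (median ``sigma_median``); a normal prior on atanh(phi) favouring
    temporal persistence (chronic-malnutrition surfaces change slowly; set
    ``phi_prior="uniform"`` for a flat prior on (-1, 1)); and a log-normal
    prior on the nugget sd.
    """

    beta_prior_sd: float = 10.0
    range_median: float | None = None
    range_log_sd: float = 1.0
    sigma_median: float = 1.0
    sigma_log_sd: float = 1.0
    eps_median: float = 0.25
    eps_log_sd: float = 1.0
    phi_prior: str = "persistence"  # or "uniform"
    phi_prior_mean: float = 2.0  # on atanh(phi)
    phi_prior_sd: float = 1.3
    hyper_mix_draws: int = 16  # 0 -> pure empirical Bayes at the mode
    include_nugget: bool = True
    engine: str = "laplace"
    n_samples: int = 1000
    seed: int = 0
    fix_hyperparams: Hyperparams | None = None
    max_outer_evals: int = 150
    mcmc_steps: int = 3000
    mcmc_walkers: int | None = None

    def __post_init__(self) -> None:
        for name in ("beta_prior_sd", "range_log_sd", "sigma_median", "sigma_log_sd",
                     "eps_median", "eps_log_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.engine not in ("laplace", "mcmc"):
            raise ValidationError("engine must be 'laplace' or 'mcmc'")
        if self.phi_prior not in ("persistence", "uniform"):
            raise ValidationError("phi_prior must be 'persistence' or 'uniform'")


@dataclass
class PosteriorFit:
    """Posterior summaries and joint samples of the space-time model."""

    beta_names: tuple[str, ...]
    beta_mean: np.ndarray
    beta_cov: np.ndarray
    hyper: Hyperparams
    hyper_intervals: dict[str, tuple[float, float]]
    years: list[int]
    node_mean: np.ndarray  # (T, m)
    samples_beta: np.ndarray  # (J, p)
    samples_field: np.ndarray  # (J, T, m)
    mesh: Mesh
    engine: str
    seed: int
    config: ModelConfig

    @property
    def n_samples(self) -> int:
        return self.samples_beta.shape[0]

    def beta_interval(self, j: int, level: float = 0.95) -> tuple[float, float]:
        """Gaussian-approximation credible interval for coefficient j."""
        z = norm.ppf(0.5 + level / 2.0)
        sd = math.sqrt(self.beta_cov[j, j])
        return (self.beta_mean[j] - z * sd, self.beta_mean[j] + z * sd)

    def save(self, path: str | Path) -> None:
        """Serialise to an .npz archive with a JSON metadata header."""
        header = {
            "beta_names": list(self.beta_names),
            "years": self.years,
            "hyper": {
                "kappa": self.hyper.kappa,
                "tau": self.hyper.tau,
                "phi": self.hyper.phi,
                "sigma_eps": self.hyper.sigma_eps,
            },
            "hyper_intervals": {k: list(v) for k, v in self.hyper_intervals.items()},
            "engine": self.engine,
            "seed": self.seed,
        }
        np.savez_compressed(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            beta_mean=self.beta_mean,
            beta_cov=self.beta_cov,
            node_mean=self.node_mean,
            samples_beta=self.samples_beta,
            samples_field=self.samples_field,
            mesh_nodes=self.mesh.nodes,
            mesh_triangles=self.mesh.triangles,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorFit":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            mesh = Mesh(nodes=z["mesh_nodes"], triangles=z["mesh_triangles"])
            return cls(
                beta_names=tuple(header["beta_names"]),
                beta_mean=z["beta_mean"],
                beta_cov=z["beta_cov"],
                hyper=Hyperparams(**header["hyper"]),
                hyper_intervals={k: tuple(v) for k, v in header["hyper_intervals"].items()},
                years=list(header["years"]),
                node_mean=z["node_mean"],
                samples_beta=z["samples_beta"],
                samples_field=z["samples_field"],
                mesh=mesh,
                engine=header["engine"],
                seed=header["seed"],
                config=ModelConfig(),
            )


# ---------------------------------------------------------------------------
# Internal: likelihood machinery shared by both engines
# ---------------------------------------------------------------------------

class _Problem:
    """Preassembled design for one fit: projector, design matrix, counts."""

    def __init__(
        self,
        clusters: Sequence[ClusterRecord],
        covariate_names: Sequence[str],
        mesh: Mesh,
        years_used: Sequence[int],
        config: ModelConfig,
    ):
        self.mesh = mesh
        self.config = config
        self.years = sorted(years_used)
        self.year_index = {y: i for i, y in enumerate(self.years)}
        self.T = len(self.years)
        self.m = mesh.n_nodes
        self.cov_names = tuple(covariate_names)
        self.beta_names = ("intercept",) + self.cov_names
        self.p = len(self.beta_names)
        self.n = len(clusters)
        self.n_latent = self.T * self.m + self.p

        if self.n:
            for c in clusters:
                if c.year not in self.year_index:
                    raise FitError(f"cluster {c.cluster_id}: year {c.year} not in years_used")
            pts = np.array([[c.x, c.y] for c in clusters])
            A = mesh.projector(pts).tocoo()
            offs = np.array([self.year_index[c.year] * self.m for c in clusters])
            A_exp = sp.csr_matrix(
                (A.data, (A.row, A.col + offs[A.row])), shape=(self.n, self.T * self.m)
            )
            X = np.ones((self.n, self.p))
            for j, name in enumerate(self.cov_names):
                try:
                    X[:, j + 1] = [c.covariates[name] for c in clusters]
                except KeyError as exc:
                    raise FitError(f"covariate {name!r} missing on a cluster") from exc
            self.B = sp.hstack([A_exp, sp.csr_matrix(X)], format="csr")
            self.X = X
            self.y = np.array([c.n_stunted for c in clusters], dtype=float)
            self.N = np.array([c.n_examined for c in clusters], dtype=float)
        else:
            self.B = sp.csr_matrix((0, self.n_latent))
            self.X = np.ones((0, self.p))
            self.y = np.zeros(0)
            self.N = np.zeros(0)

        # mesh bounding-box diagonal drives the default range-prior median
        span = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
        diag = float(np.hypot(*span))
        self.range_median = config.range_median if config.range_median else diag / 5.0
        self._warm: np.ndarray | None = None
        # FEM matrices are theta-free; cache them for the outer optimisation
        C, G = fem_matrices(mesh)
        self._fem = (C, G.tocsc(), (G @ sp.diags(1.0 / C) @ G).tocsc())

    def spde_Q(self, kappa: float, tau: float) -> sp.csc_matrix:
        C, G, GCG = self._fem
        Q = tau**2 * (kappa**4 * sp.diags(C) + 2.0 * kappa**2 * G + GCG)
        return ((Q + Q.T) * 0.5).tocsc()

    # --- priors over transformed hyperparameters psi ---------------------
    def unpack_psi(self, psi: np.ndarray) -> Hyperparams:
        kappa, tau = math.exp(psi[0]), math.exp(psi[1])
        phi = math.tanh(psi[2])
        sig_eps = math.exp(psi[3]) if self.config.include_nugget else 0.0
        return Hyperparams(kappa=kappa, tau=tau, phi=phi, sigma_eps=sig_eps)

    def pack_hyper(self, h: Hyperparams) -> np.ndarray:
        psi = [math.log(h.kappa), math.log(h.tau), math.atanh(h.phi)]
        if self.config.include_nugget:
            psi.append(math.log(max(h.sigma_eps, 1e-8)))
        return np.array(psi)

    def log_prior_psi(self, psi: np.ndarray) -> float:
        def _lognorm(x: float, med: float, sd: float) -> float:
            return -0.5 * ((x - med) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)

        cfg = self.config
        h = self.unpack_psi(psi)
        lp = _lognorm(math.log(h.range_rho), math.log(self.range_median), cfg.range_log_sd)
        lp += _lognorm(math.log(h.sigma_s), math.log(cfg.sigma_median), cfg.sigma_log_sd)
        if cfg.phi_prior == "persistence":
            # annual chronic-malnutrition fields persist; favour phi near 1
            # (base-model-at-1 spirit of PC priors for temporal correlation)
            lp += _lognorm(float(psi[2]), cfg.phi_prior_mean, cfg.phi_prior_sd)
        else:
            lp += math.log(0.5 * (1.0 - h.phi**2))  # uniform phi via atanh transform
        if cfg.include_nugget:
            lp += _lognorm(psi[3], math.log(cfg.eps_median), cfg.eps_log_sd)
        return float(lp)

    def prior_precision(self, h: Hyperparams) -> tuple[np.ndarray, float]:
        """Dense latent prior precision over (field, beta) and its logdet."""
        Q_s = self.spde_Q(h.kappa, h.tau)
        Q_st = build_st_precision(Q_s, h.phi, self.T)
        Q = np.zeros((self.n_latent, self.n_latent))
        Q[: self.T * self.m, : self.T * self.m] = Q_st.toarray()
        Q[self.T * self.m :, self.T * self.m :] = np.eye(self.p) / self.config.beta_prior_sd**2
        try:
            Ls = np.linalg.cholesky(Q_s.toarray())
        except np.linalg.LinAlgError as exc:
            raise FitError("spatial precision not positive definite") from exc
        logdet_s = 2.0 * float(np.sum(np.log(np.diag(Ls))))
        logdet_time = -(self.T - 1) * math.log(1.0 - h.phi**2)
        logdet = self.m * logdet_time + self.T * logdet_s - 2 * self.p * math.log(
            self.config.beta_prior_sd
        )
        return Q, float(logdet)

    def loglik_eta(self, eta: np.ndarray) -> float:
        if not hasattr(self, "_ll_const"):
            from scipy.special import gammaln

            self._ll_const = float(
                np.sum(gammaln(self.N + 1) - gammaln(self.y + 1) - gammaln(self.N - self.y + 1))
            )
        return float(self._ll_const + np.sum(self.y * eta - self.N * np.logaddexp(0.0, eta)))


def _newton_mode(
    prob: _Problem, Q: np.ndarray, sigma_eps: float, u0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Inner Newton optimisation of the latent posterior at fixed theta.

    Returns ``(u_mode, eps_mode, S_u, cf, logdet_D)`` where ``S_u`` is the
    dense Schur-complement precision of (field, beta), ``cf`` its Cholesky
    factorisation, and ``logdet_D`` the log-determinant of the diagonal
    nugget block of the Hessian (0 if the nugget is off or n = 0).
    """
    B, y, N = prob.B, prob.y, prob.N
    n = prob.n
    use_eps = prob.config.include_nugget and sigma_eps > 0 and n > 0
    u = np.zeros(prob.n_latent) if u0 is None else u0.copy()
    eps = np.zeros(n)

    def objective(u, eps):
        eta = B @ u + eps
        val = 0.5 * u @ (Q @ u) - prob.loglik_eta(eta)
        if use_eps:
            val += 0.5 * np.sum(eps**2) / sigma_eps**2
        return val, eta

    f_cur, eta = objective(u, eps)
    S_u = Q.copy()
    logdet_D = 0.0
    for it in range(60):
        p_hat = expit(eta)
        g_eta = N * p_hat - y
        W = np.maximum(N * p_hat * (1.0 - p_hat), 1e-12)
        grad_u = Q @ u + B.T @ g_eta
        if use_eps:
            D = 1.0 / sigma_eps**2 + W
            grad_eps = eps / sigma_eps**2 + g_eta
            W_eff = W - W**2 / D
            rhs = -grad_u + B.T @ (W / D * grad_eps)
        else:
            W_eff = W
            rhs = -grad_u
        BW = B.T.multiply(W_eff)
        S_u = Q + np.asarray((BW @ B).todense()) if n else Q.copy()
        try:
            cf = cho_factor(S_u, lower=True)
        except np.linalg.LinAlgError as exc:
            raise FitError("latent Hessian not positive definite") from exc
        du = cho_solve(cf, rhs)
        if use_eps:
            deps = (-grad_eps - W * (B @ du)) / D
        else:
            deps = np.zeros(n)

        gnorm = max(
            np.abs(grad_u).max() if prob.n_latent else 0.0,
            np.abs(grad_eps).max() if use_eps else 0.0,
        )
        if gnorm < 1e-6 * max(1.0, N.sum() / max(n, 1)):
            logdet_D = float(np.sum(np.log(D))) if use_eps else 0.0
            return u, eps, S_u, cf, logdet_D
        step = 1.0
        for _ in range(30):
            u_new, eps_new = u + step * du, eps + step * deps
            f_new, eta_new = objective(u_new, eps_new)
            if f_new <= f_cur + 1e-12 * abs(f_cur):
                break
            step *= 0.5
        else:
            raise FitError("inner Newton line search failed")
        u, eps, f_cur, eta = u_new, eps_new, f_new, eta_new
    raise FitError(f"inner Newton did not converge (last gradient norm {gnorm:.3g})")


def _laplace_log_marginal(prob: _Problem, psi: np.ndarray) -> tuple[float, dict]:
    """Laplace-approximated log joint p(y, theta) up to theta-free constants."""
    h = prob.unpack_psi(psi)
    Q, logdet_Q = prob.prior_precision(h)
    u, eps, S_u, cf, logdet_D = _newton_mode(prob, Q, h.sigma_eps, u0=prob._warm)
    prob._warm = u
    eta = prob.B @ u + eps
    val = prob.loglik_eta(eta) - 0.5 * u @ (Q @ u) + 0.5 * logdet_Q
    use_eps = prob.config.include_nugget and h.sigma_eps > 0 and prob.n > 0
    if use_eps:
        val += -0.5 * np.sum(eps**2) / h.sigma_eps**2 - prob.n * math.log(h.sigma_eps)
    logdet_S = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    val -= 0.5 * (logdet_S + logdet_D)
    val += prob.log_prior_psi(psi)
    return float(val), {"u": u, "eps": eps, "S_u": S_u, "cf": cf, "hyper": h}


def _fit_laplace(prob: _Problem) -> PosteriorFit:
    cfg = prob.config
    if cfg.fix_hyperparams is not None:
        psi_hat = prob.pack_hyper(cfg.fix_hyperparams)
        hyper_int: dict[str, tuple[float, float]] = {}
    else:
        if prob.n == 0:
            raise FitError("empty cluster list requires fix_hyperparams")
        phi0 = math.tanh(cfg.phi_prior_mean) if cfg.phi_prior == "persistence" else 0.5
        psi0 = prob.pack_hyper(
            Hyperparams.from_range_sigma(
                range_rho=prob.range_median,
                sigma_s=0.5,
                phi=phi0,
                sigma_eps=cfg.eps_median if cfg.include_nugget else 0.0,
            )
        )

        def neg(psi):
            try:
                val, _ = _laplace_log_marginal(prob, psi)
            except FitError:
                return 1e10
            return -val

        res = minimize(
            neg,
            psi0,
            method="Nelder-Mead",
            options={
                "maxfev": cfg.max_outer_evals,
                "xatol": 1e-2,
                "fatol": 5e-2,
            },
        )
        psi_hat = res.x
        # curvature-based hyperparameter intervals from a diagonal finite
        # difference; the same scales drive the mixture over hyperparameters
        hyper_int = {}
        f0 = neg(psi_hat)
        names = ["log_kappa", "log_tau", "atanh_phi"] + (
            ["log_sigma_eps"] if cfg.include_nugget else []
        )
        hstep = 0.1
        psi_sd = np.full(len(psi_hat), 0.3)
        for j, name in enumerate(names):
            e = np.zeros_like(psi_hat)
            e[j] = hstep
            curv = (neg(psi_hat + e) - 2 * f0 + neg(psi_hat - e)) / hstep**2
            sd = 1.0 / math.sqrt(curv) if curv > 0 else float("inf")
            if np.isfinite(sd):
                psi_sd[j] = min(sd, 1.5)
            hyper_int[name] = (float(psi_hat[j] - 1.96 * sd), float(psi_hat[j] + 1.96 * sd))

    # Gaussian mixture over hyperparameter draws around the mode: propagates
    # hyperparameter uncertainty into the latent posterior (importance weights
    # against the Laplace marginal; pure empirical Bayes when draws = 0)
    val_hat, state_hat = _laplace_log_marginal(prob, psi_hat)
    comps: list[tuple[float, dict]] = [(0.0, state_hat)]
    if cfg.fix_hyperparams is None and cfg.hyper_mix_draws > 0:
        rng_mix = np.random.default_rng(cfg.seed + 101)
        for _ in range(cfg.hyper_mix_draws - 1):
            z = np.clip(rng_mix.standard_normal(len(psi_hat)), -2.5, 2.5)
            psi_k = psi_hat + psi_sd * z
            try:
                val_k, state_k = _laplace_log_marginal(prob, psi_k)
            except FitError:
                continue
            comps.append((val_k - val_hat + 0.5 * float(z @ z), state_k))

    lw = np.array([c[0] for c in comps])
    weights = np.exp(lw - lw.max())
    weights /= weights.sum()
    states = [c[1] for c in comps]
    h = state_hat["hyper"]  # point estimate stays at the mode

    Tm = prob.T * prob.m
    means = np.stack([s["u"] for s in states])
    u_mix = weights @ means
    beta_mean = u_mix[Tm:]
    E_beta = np.zeros((prob.n_latent, prob.p))
    E_beta[Tm:] = np.eye(prob.p)
    beta_cov = np.zeros((prob.p, prob.p))
    for w_k, s in zip(weights, states):
        cov_k = cho_solve(s["cf"], E_beta)[Tm:]
        d = s["u"][Tm:] - beta_mean
        beta_cov += w_k * (cov_k + np.outer(d, d))

    rng = np.random.default_rng(cfg.seed)
    counts = rng.multinomial(cfg.n_samples, weights)
    blocks = []
    for c_k, s in zip(counts, states):
        if c_k == 0:
            continue
        L = np.tril(s["cf"][0])
        z = rng.standard_normal((prob.n_latent, c_k))
        blocks.append(s["u"][:, None] + solve_triangular(L.T, z, lower=False))
    draws = np.concatenate(blocks, axis=1)
    samples_field = draws[:Tm].T.reshape(cfg.n_samples, prob.T, prob.m)
    samples_beta = draws[Tm:].T.copy()
    u = u_mix

    return PosteriorFit(
        beta_names=prob.beta_names,
        beta_mean=beta_mean,
        beta_cov=beta_cov,
        hyper=h,
        hyper_intervals=hyper_int,
        years=prob.years,
        node_mean=u[:Tm].reshape(prob.T, prob.m),
        samples_beta=samples_beta,
        samples_field=samples_field,
        mesh=prob.mesh,
        engine="laplace",
        seed=cfg.seed,
        config=cfg,
    )


def _fit_mcmc(prob: _Problem) -> PosteriorFit:
    """Ensemble-sampler reference engine; practical for small instances only."""
    import emcee

    cfg = prob.config
    fixed = cfg.fix_hyperparams
    n_psi = 0 if fixed is not None else (4 if cfg.include_nugget else 3)
    Tm = prob.T * prob.m
    use_eps = cfg.include_nugget
    ndim = n_psi + prob.n_latent + (prob.n if use_eps else 0)

    # dense fast path: MCMC is only run on small instances, and per-call
    # sparse-matrix overhead would dominate the sampler otherwise
    C_diag, G_sp, GCG_sp = prob._fem
    Gd, GCGd = G_sp.toarray(), GCG_sp.toarray()
    Cd = np.diag(C_diag)
    Bd = prob.B.toarray()
    T, m, p = prob.T, prob.m, prob.p
    beta_prec = 1.0 / cfg.beta_prior_sd**2
    log_beta_sd = math.log(cfg.beta_prior_sd)
    y_arr, N_arr = prob.y, prob.N

    def log_post(vec: np.ndarray) -> float:
        i = 0
        if fixed is not None:
            h = fixed
            lp = 0.0
        else:
            psi = vec[:n_psi]
            if np.any(np.abs(psi) > 12):
                return -np.inf
            h = prob.unpack_psi(psi)
            lp = prob.log_prior_psi(psi)
            i = n_psi
        u = vec[i : i + prob.n_latent]
        eps = vec[i + prob.n_latent :] if use_eps else 0.0
        s, beta = u[:Tm], u[Tm:]

        Qs = h.tau**2 * (h.kappa**4 * Cd + 2.0 * h.kappa**2 * Gd + GCGd)
        try:
            Ls = np.linalg.cholesky(Qs)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_s = 2.0 * np.sum(np.log(np.diag(Ls)))
        if T == 1:
            quad = s @ (Qs @ s)
            logdet_st = logdet_s
        else:
            diag_t = np.ones(T)
            diag_t[1:-1] = 1.0 + h.phi**2
            Qt = np.diag(diag_t)
            Qt[np.arange(T - 1), np.arange(1, T)] = -h.phi
            Qt[np.arange(1, T), np.arange(T - 1)] = -h.phi
            Qt /= 1.0 - h.phi**2
            S = s.reshape(T, m)
            quad = np.sum((Qt @ S) * (S @ Qs.T))  # s' (Qt (x) Qs) s
            logdet_st = m * (-(T - 1) * math.log(1.0 - h.phi**2)) + T * logdet_s
        lp += 0.5 * logdet_st - 0.5 * quad
        lp += -0.5 * beta_prec * beta @ beta - p * log_beta_sd
        if use_eps:
            if h.sigma_eps <= 0:
                return -np.inf
            lp += -0.5 * np.sum(eps**2) / h.sigma_eps**2 - prob.n * math.log(h.sigma_eps)
        eta = Bd @ u + eps
        lp += np.sum(y_arr * eta - N_arr * np.logaddexp(0.0, eta))
        return float(lp) if np.isfinite(lp) else -np.inf

    # initialise walkers around the Laplace solution
    lap_cfg = ModelConfig(**{**cfg.__dict__, "engine": "laplace"})
    lap = _fit_laplace(_problem_copy(prob, lap_cfg))
    psi_hat = prob.pack_hyper(lap.hyper)[:n_psi] if fixed is None else np.zeros(0)
    u_hat = np.concatenate([lap.node_mean.ravel(), lap.beta_mean])
    center = np.concatenate([psi_hat, u_hat, np.zeros(prob.n if use_eps else 0)])

    nwalkers = cfg.mcmc_walkers or max(2 * ndim + 2, 48)
    rng = np.random.default_rng(cfg.seed)
    p0 = center[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post)
    state = emcee.State(p0, random_state=np.random.RandomState(cfg.seed).get_state())
    sampler.run_mcmc(state, cfg.mcmc_steps, progress=False)
    burn = cfg.mcmc_steps // 2
    chain = sampler.get_chain(discard=burn, thin=5, flat=True)

    take = min(cfg.n_samples, len(chain))
    sel = rng.choice(len(chain), size=take, replace=False)
    sub = chain[sel]
    i0 = n_psi
    u_samples = sub[:, i0 : i0 + prob.n_latent]
    samples_field = u_samples[:, :Tm].reshape(take, prob.T, prob.m)
    samples_beta = u_samples[:, Tm:]

    if fixed is not None:
        h = fixed
    else:
        psi_med = np.median(chain[:, :n_psi], axis=0)
        h = prob.unpack_psi(psi_med)
    return PosteriorFit(
        beta_names=prob.beta_names,
        beta_mean=samples_beta.mean(axis=0),
        beta_cov=np.atleast_2d(np.cov(samples_beta.T)),
        hyper=h,
        hyper_intervals={},
        years=prob.years,
        node_mean=u_samples[:, :Tm].mean(axis=0).reshape(prob.T, prob.m),
        samples_beta=samples_beta,
        samples_field=samples_field,
        mesh=prob.mesh,
        engine="mcmc",
        seed=cfg.seed,
        config=cfg,
    )


def _problem_copy(prob: _Problem, cfg: ModelConfig) -> _Problem:
    import copy

    new = copy.copy(prob)
    new.config = cfg
    new._warm = None
    return new


def fit(
    clusters: Sequence[ClusterRecord],
    covariate_names: Sequence[str],
    mesh: Mesh,
    config: ModelConfig | None = None,
    years_used: Sequence[int] | None = None,
) -> PosteriorFit:
    """Fit the hierarchical space-time binomial model.

    Parameters
    ----------
    clusters
        Survey records with covariates attached.  May be empty only when
        ``config.fix_hyperparams`` is set, in which case the exact prior
        Gaussian is returned (useful for prior checks).
    covariate_names
        The selected covariates (the fixed-effect design also has an
        intercept).
    mesh
        The SPDE mesh; its hull must contain every cluster.
    years_used
        The years entering the likelihood; defaults to the years present in
        ``clusters``.
    """
    config = config or ModelConfig()
    if years_used is None:
        years_used = sorted({c.year for c in clusters})
        if not years_used:
            raise FitError("years_used must be given when clusters is empty")
    prob = _Problem(clusters, covariate_names, mesh, years_used, config)
    if config.engine == "laplace":
        return _fit_laplace(prob)
    return _fit_mcmc(prob)


def odds_ratios(fit_result: PosteriorFit) -> pd.DataFrame:
    """Posterior odds-ratio table for the covariates (per native unit).

    OR = exp(beta_j) summarised by the sample median and 2.5/97.5 percentiles;
    ``significant`` is True when the credible interval excludes 1.
    """
    if len(fit_result.beta_names) < 2:
        raise ValidationError("fit has no covariates")
    rows = []
    for j, name in enumerate(fit_result.beta_names):
        if name == "intercept":
            continue
        samples = np.exp(fit_result.samples_beta[:, j])
        lo, med, hi = np.percentile(samples, [2.5, 50.0, 97.5])
        rows.append(
            {
                "covariate": name,
                "OR": med,
                "CrI_2.5%": lo,
                "CrI_97.5%": hi,
                "significant": bool(hi < 1.0 or lo > 1.0),
            }
        )
    return pd.DataFrame(rows)
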