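"""Exceedance probabilities and positive excursion sets.

Marginal exceedance: per pixel, the posterior probability that prevalence
exceeds a threshold ``u`` (here typically the WHO "very high" boundary,
40 %).  Positive excursion set ``E+(u, alpha)``: the largest set of pixels
that *jointly* exceed ``u`` with posterior probability at least ``1 - alpha``.

Joint probabilities are evaluated directly on the posterior joint samples
(the fraction of draws in which every member pixel exceeds ``u``), which is
exact within Monte-Carlo error for any posterior representation; this is the
sampling counterpart of the numerical-integration excursion method for
Gaussian posteriors.  The excursion set is built by the one-parameter
parametric-family sweep: pixels are ordered by decreasing marginal exceedance
probability (ties broken by row-major index) and the candidate set grows as a
prefix of that order; the returned set is the largest prefix whose joint
probability still meets the constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import RasterGeometry, ValidationError
from .mapping import PrevalenceSurface

__all__ = ["ExceedanceRaster", "ExcursionSet", "marginal_exceedance", "excursion_set"]

_MIN_SAMPLES = 500


@dataclass
class ExceedanceRaster:
    geometry: RasterGeometry
    threshold: float
    probability: np.ndarray  # (rows, cols) in [0, 1]


@dataclass
class ExcursionSet:
    geometry: RasterGeometry
    threshold: float
    confidence: float  # 1 - alpha
    member: np.ndarray  # boolean (rows, cols)
    joint_probability: float


def _require_samples(surface: PrevalenceSurface) -> np.ndarray:
    if surface.samples is None or surface.n_samples < _MIN_SAMPLES:
        raise ValidationError(
            f"surface carries {surface.n_samples} joint samples; need >= {_MIN_SAMPLES} — "
            "refit/predict with sampling enabled (n_samples >= 500)"
        )
    return surface.samples


def marginal_exceedance(surface: PrevalenceSurface, u: float) -> ExceedanceRaster:
    """Per-pixel P(prevalence > u) as the fraction of joint samples above u."""
    samples = _require_samples(surface)
    prob = (samples > u).mean(axis=0).reshape(surface.geometry.shape)
    mask = surface.geometry.mask()
    prob = prob.astype(float)
    prob[mask] = np.nan
    return ExceedanceRaster(geometry=surface.geometry, threshold=u, probability=prob)


def excursion_set(surface: PrevalenceSurface, u: float, alpha: float = 0.05) -> ExcursionSet:
    """Largest pixel set jointly exceeding ``u`` with probability >= 1 - alpha."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    samples = _require_samples(surface)
    geometry = surface.geometry
    ok = ~geometry.mask().ravel()
    exceed = samples > u  # (J, n_pix)
    marg = exceed.mean(axis=0)
    marg_masked = np.where(ok, marg, -1.0)

    # decreasing marginal probability, ties by row-major pixel index
    order = np.lexsort((np.arange(len(marg_masked)), -marg_masked))
    order = order[marg_masked[order] >= 0]

    level = 1.0 - alpha
    alive = np.ones(samples.shape[0], dtype=bool)  # draws where all members exceed u
    best_len = 0
    n_alive = alive.sum()
    for k, pix in enumerate(order):
        alive &= exceed[:, pix]
        n_alive = alive.sum()
        joint = n_alive / samples.shape[0]
        if joint >= level:
            best_len = k + 1
        else:
            break

    member = np.zeros(len(marg_masked), dtype=bool)
    member[order[:best_len]] = True
    if best_len:
        achieved = float(np.all(exceed[:, member], axis=1).mean())
    else:
        achieved = 1.0  # vacuous
    return ExcursionSet(
        geometry=geometry,
        threshold=u,
        confidence=level,
        member=member.reshape(geometry.shape),
        joint_probability=achieved,
    )
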