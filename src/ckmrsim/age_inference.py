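"""The assumed observation model: age inferred from measured length.

Sampled animals are not aged directly; the estimator sees an integer length
measurement ``l*`` (true length-at-age plus Gaussian error, rounded to the
nearest cm) and marginalises over age using Bayes' rule,

    f(a | l*)  proportional to  f(l* | a) f(a),

where ``f(l* | a)`` is a discretised Normal centred on the assumed growth
curve and ``f(a)`` is the truncated-geometric stationary age distribution
implied by constant survival ``phi`` with a hard maximum age.  The model that
is *assumed* here may deliberately differ from the truth used to generate
the data (misspecified measurement-error SD or a shifted growth curve); the
survival term always uses the true ``phi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .life_history import VBGFParams, stable_age_distribution, vbgf_length

__all__ = [
    "AgeModel",
    "IncompatibleLengthError",
    "length_pmf",
    "age_prior",
    "age_posterior",
    "posterior_matrix",
]

#: Discretised-Normal cell probabilities below this are treated as exact zero.
PMF_FLOOR = 1e-300


class IncompatibleLengthError(ValueError):
    """A measured length has zero probability under the assumed model at
    machine precision; downstream fits treat this as a failure, not a crash."""


@dataclass(frozen=True)
class AgeModel:
    """Assumed growth curve, measurement-error SD, survival and maximum age."""

    vbgf: VBGFParams
    sigma: float
    phi: float
    a_max: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.a_max + 1)


def length_pmf(l_star, age, model: AgeModel):
    """Probability of measuring integer length ``l_star`` at ``age``.

    The Normal density with mean ``mu = l(age)`` and SD ``sigma`` integrated
    over the rounding cell [l* - 0.5, l* + 0.5]:

        f(l* | a) = Phi((l* - mu + 0.5)/sigma) - Phi((l* - mu - 0.5)/sigma).
    """
    mu = vbgf_length(age, model.vbgf)
    z_hi = (np.asarray(l_star, dtype=float) - mu + 0.5) / model.sigma
    z_lo = (np.asarray(l_star, dtype=float) - mu - 0.5) / model.sigma
    p = ndtr(z_hi) - ndtr(z_lo)
    p = np.where(p < PMF_FLOOR, 0.0, p)
    return p if p.ndim else float(p)


def age_prior(age, model: AgeModel):
    """Stationary (truncated geometric) age prior

        f(a) = phi^a (1 - phi) / (1 - phi^(a_max + 1)),   0 <= a <= a_max,

    and zero outside that range."""
    age = np.asarray(age)
    full = stable_age_distribution(model.phi, model.a_max)
    valid = (age >= 0) & (age <= model.a_max)
    p = np.where(valid, full[np.clip(age, 0, model.a_max)], 0.0)
    return p if p.ndim else float(p)


def age_posterior(l_star: int, model: AgeModel) -> np.ndarray:
    """Posterior pmf of age given one measured length, over ages 0..a_max.

    Raises :class:`IncompatibleLengthError` when the marginal f(l*) is zero
    at machine precision (possible when the assumed sigma is much smaller
    than the truth)."""
    key = (model, int(l_star))
    hit = _posterior_cache.get(key)
    if hit is not None:
        return hit
    joint = length_pmf(l_star, model.ages, model) * age_prior(model.ages, model)
    marginal = joint.sum()
    if marginal <= 0.0:
        raise IncompatibleLengthError(
            f"measured length {l_star} has zero probability under the assumed model"
        )
    post = joint / marginal
    post.flags.writeable = False
    _posterior_cache[key] = post
    return post


_posterior_cache: dict = {}


def posterior_matrix(lengths: np.ndarray, model: AgeModel) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise age posteriors for many lengths at once.

    Returns ``(P, ok)`` where ``P[i]`` is the posterior over ages 0..a_max for
    ``lengths[i]`` and ``ok[i]`` is False when that length is impossible under
    the model (its row is left at zero).  Vectorised equivalent of
    :func:`age_posterior` without the per-length exception.
    """
    lengths = np.asarray(lengths, dtype=float)
    mu = vbgf_length(model.ages, model.vbgf)[None, :]
    ls = lengths[:, None]
    pmf = ndtr((ls - mu + 0.5) / model.sigma) - ndtr((ls - mu - 0.5) / model.sigma)
    pmf[pmf < PMF_FLOOR] = 0.0
    joint = pmf * age_prior(model.ages, model)[None, :]
    marg = joint.sum(axis=1)
    ok = marg > 0.0
    out = np.zeros_like(joint)
    out[ok] = joint[ok] / marg[ok, None]
    return out, ok
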