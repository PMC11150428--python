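"""Life-history definitions: growth curves, species configurations, and
survival calibration.

Two fictional shark species are studied.  The *simple* species breeds
annually (litter of two, no gestation, both sexes mature at 10, maximum age
19).  The *complex* species is loosely patterned on a grey reef shark
population: litters of 3-6 pups, a one-year gestation so females breed every
other year, males mature at 17, females at 19, maximum age 63.

Length-at-age follows a von Bertalanffy growth function (VBGF)

    l(a) = l_inf * (1 - exp(-k * (a - a0)))

shared by both sexes and species.  Annual survival ``phi`` is constant over
age and sex; it is not chosen freely but *calibrated* so that the long-run
population growth rate equals one (a stationary population), via the dominant
eigenvalue of a female-based projection matrix that honors the yearly event
order birth -> survival -> ageing, with newborns exposed to survival in their
birth year and certain death once the maximum age is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "VBGFParams",
    "SpeciesConfig",
    "vbgf_length",
    "shifted_growth_curve",
    "female_projection_matrix",
    "population_growth_rate",
    "calibrate_survival",
    "stable_age_distribution",
    "simple_species",
    "complex_species",
]

#: Growth-curve estimates for the grey reef shark population that motivates
#: both fictional species (asymptotic length cm, growth coefficient 1/yr,
#: theoretical age at length zero).
DEFAULT_VBGF = (163.0, 0.0554, -8.27)

#: True standard deviation of the length measurement error (cm).
DEFAULT_SIGMA_L = 2.89


@dataclass(frozen=True)
class VBGFParams:
    """Parameters of a von Bertalanffy growth curve."""

    l_inf: float = DEFAULT_VBGF[0]
    k: float = DEFAULT_VBGF[1]
    a0: float = DEFAULT_VBGF[2]

    def __post_init__(self) -> None:
        if self.l_inf <= 0:
            raise ValueError(f"l_inf must be positive, got {self.l_inf}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")


def vbgf_length(age, params: VBGFParams):
    """Expected length (cm) at ``age`` (years) under the growth curve.

    Accepts scalars or arrays; negative ages are rejected.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    out = params.l_inf * (1.0 - np.exp(-params.k * (age - params.a0)))
    return out if out.ndim else float(out)


def shifted_growth_curve(params: VBGFParams, shift: float) -> VBGFParams:
    """Growth curve whose expected length-at-age is ``(1 + shift)`` times the
    original at every age (a percentage shift of the whole curve, implemented
    by scaling the asymptotic length; ``k`` and ``a0`` are unchanged)."""
    return replace(params, l_inf=(1.0 + shift) * params.l_inf)


@dataclass(frozen=True)
class SpeciesConfig:
    """Full life history and observation model of one simulated species.

    ``litter_sizes`` holds the equally likely litter sizes.  ``phi`` is the
    annual survival probability; leave it ``None`` to have the factory
    functions calibrate it to a stationary population.
    """

    name: str
    a_max: int
    alpha_f: int
    alpha_m: int
    litter_sizes: tuple[int, ...]
    gestation_years: int
    vbgf: VBGFParams = VBGFParams()
    sigma_l: float = DEFAULT_SIGMA_L
    phi: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha_f <= self.a_max and 0 < self.alpha_m <= self.a_max):
            raise ValueError("ages at maturity must lie in (0, a_max]")
        if self.gestation_years not in (0, 1):
            raise ValueError("only gestation of 0 or 1 year is supported")
        if self.phi is not None and not (0.0 < self.phi < 1.0):
            raise ValueError("phi must lie in (0, 1)")
        if not self.litter_sizes:
            raise ValueError("litter_sizes must be non-empty")

    @property
    def mean_litter(self) -> float:
        return float(np.mean(self.litter_sizes))

    @property
    def female_fecundity(self) -> float:
        """Expected female offspring per litter (50:50 sex ratio at birth)."""
        return self.mean_litter / 2.0

    def alpha(self, sex: str) -> int:
        return self.alpha_f if sex == "F" else self.alpha_m

    def with_phi(self, phi: float) -> "SpeciesConfig":
        return replace(self, phi=phi)


def female_projection_matrix(species: SpeciesConfig, phi: float) -> np.ndarray:
    """Female projection matrix for the yearly cycle, censused at the start
    of the year (before breeding).

    For the annual breeder the state is age 1..a_max (age 0 exists only
    between the birth and ageing events).  With a one-year gestation the
    state is (age, gestating?): a mature non-gestating female mates and
    enters the gestating state; a gestating female that survives gives birth
    the next year and cannot remate that year, so births occur every other
    year, the first at age alpha_f + 1.
    """
    amax = species.a_max
    fec = species.female_fecundity
    if species.gestation_years == 0:
        n = amax + 1  # index = age; row/col 0 unused at census but kept for clarity
        m = np.zeros((n, n))
        for a in range(1, amax):
            m[a + 1, a] = phi
        for a in range(species.alpha_f, amax + 1):
            # offspring born this year survive their first year and enter the
            # next census at age 1
            m[1, a] += fec * phi
        return m
    # one-year gestation: stacked states, index a -> available, n + a -> gestating
    n = amax + 1
    m = np.zeros((2 * n, 2 * n))
    for a in range(1, amax):
        if a >= species.alpha_f:
            m[n + a + 1, a] = phi  # available mature female mates this year
        else:
            m[a + 1, a] = phi
        m[a + 1, n + a] = phi  # gestating female gives birth, postpartum
    for a in range(1, amax + 1):
        m[1, n + a] += fec * phi  # her newborns, surviving their first year
    return m


def population_growth_rate(species: SpeciesConfig, phi: float) -> float:
    """Asymptotic yearly growth rate: dominant eigenvalue of the projection
    matrix at survival ``phi``."""
    eigs = np.linalg.eigvals(female_projection_matrix(species, phi))
    return float(np.max(np.abs(eigs)))


def calibrate_survival(species: SpeciesConfig, tol: float = 1e-9) -> float:
    """Annual survival probability at which the population is stationary.

    Solves ``lambda(phi) = 1`` by bisection/Brent on (0, 1); ``lambda`` is
    strictly increasing in ``phi`` so the root is unique.  Raises if no root
    exists, which signals an inconsistent life history.
    """

    def f(phi: float) -> float:
        return population_growth_rate(species, phi) - 1.0

    lo, hi = 0.05, 0.999
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"no stationary survival probability in (0, 1) for species "
            f"{species.name!r}; life history is inconsistent"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def stable_age_distribution(phi: float, a_max: int, age_min: int = 0) -> np.ndarray:
    """Truncated-geometric stable age pmf over ages ``age_min..a_max``
    (returned as a vector over 0..a_max, zero below ``age_min``):

        f(a) = phi^a (1 - phi) / normalizer.

    With ``age_min=0`` this is the stationary age distribution of the
    population as sampled (the estimator's age prior); ``age_min=1`` gives
    the distribution of ages entering a year, before breeding.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    w = phi ** np.arange(a_max + 1, dtype=float)
    if age_min > 0:
        w[:age_min] = 0.0
    return w / w.sum()


def simple_species(phi: Optional[float] = None, **overrides) -> SpeciesConfig:
    """The annually breeding species: litter of 2, no gestation, maturity at
    10 for both sexes, maximum age 19.  ``phi`` is calibrated to a stationary
    population unless given."""
    sp = SpeciesConfig(
        name="simple",
        a_max=19,
        alpha_f=10,
        alpha_m=10,
        litter_sizes=(2,),
        gestation_years=0,
        **overrides,
    )
    return sp.with_phi(phi if phi is not None else calibrate_survival(sp))


def complex_species(phi: Optional[float] = None, **overrides) -> SpeciesConfig:
    """The biennially breeding species: litter uniform on 3..6, one-year
    gestation, male maturity 17, female maturity 19, maximum age 63."""
    sp = SpeciesConfig(
        name="complex",
        a_max=63,
        alpha_f=19,
        alpha_m=17,
        litter_sizes=(3, 4, 5, 6),
        gestation_years=1,
        **overrides,
    )
    return sp.with_phi(phi if phi is not None else calibrate_survival(sp))
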