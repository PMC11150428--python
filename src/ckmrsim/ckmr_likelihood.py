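"""Parent-offspring-pair (POP) pseudo-likelihood for close-kin mark-recapture.

Every unordered pair of capture records is a Bernoulli comparison: either the
pair is a POP or it is not.  Given ages, the probability that record *i* is
the parent of record *j* is a kinship kernel ``m / N_s`` where ``N_s`` is the
adult abundance of the parent's sex and the multiplier ``m`` collects the
maturity indicator, the gestation adjustment, and survival from the parent's
capture to the offspring's conception/birth:

* annual breeder, either parent sex (maturity ``alpha`` by sex)::

      m = 1[y_i + alpha <= y_j] * (1            if c_i >= y_j
                                   phi^(y_j-c_i) otherwise)

* one-year gestation, mother (she must survive gestation, hence the
  ``phi^-1`` on the mating-year abundance, and be mature at mating)::

      m = 1[y_i + alpha_f <= y_j - 1] * phi^-1 * (1 if c_i >= y_j
                                                  phi^(y_j-c_i) otherwise)

* one-year gestation, father (he only needs to be alive and mature in the
  mating year ``y_j - 1``)::

      m = 1[y_i + alpha_m <= y_j - 1] * (1 if c_i >= y_j - 1
                                         phi^(y_j-1-c_i) otherwise)

with ``y`` birth years and ``c`` capture years.  Because age -- and therefore
birth year -- is only known through the measured length, the pair probability
marginalises the kernel over both age posteriors, and because either record
could be the parent both directions are summed:

    Pr(K_ij = PO/OP) = A / N_{sex_i} + B / N_{sex_j},

where A and B are age-marginalised coefficients that do not depend on the
abundances.  Many record pairs share the identical probabilistic statement
(same sexes, capture years and measured lengths), so comparisons are
aggregated into unique keys with POP / non-POP multiplicities before the
pseudo-log-likelihood is evaluated; the aggregated sum is exactly the naive
sum over all n(n-1)/2 pairs.

Adult abundance is assumed constant over time (N_{s,t} = N_s), so the single
pair of parameters (N_f, N_m) carries all abundance information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .age_inference import AgeModel, age_posterior, posterior_matrix
from .life_history import SpeciesConfig

__all__ = [
    "kinship_coefficient",
    "kinship_matrix",
    "pair_coefficients",
    "ComparisonTable",
    "AggregatedComparisons",
    "build_comparison_table",
    "attach_coefficients",
    "aggregate_comparisons",
    "pseudo_log_likelihood",
]

_SEX_CODE = {"F": 0, "M": 1}
#: pair probabilities at or above this are clipped in log(1 - P)
_P_CLIP = 1.0 - 1e-12


def kinship_coefficient(parent_birth_year: int, parent_capture_year: int,
                        offspring_birth_year: int, parent_sex: str,
                        species: SpeciesConfig) -> float:
    """Kinship multiplier ``m`` such that Pr(parent-of | ages, sexes) is
    ``m / N_{parent_sex}``; zero when the maturity indicator fails."""
    phi = species.phi
    g = species.gestation_years
    alpha = species.alpha(parent_sex)
    y_i, c_i, y_j = parent_birth_year, parent_capture_year, offspring_birth_year
    if y_i + alpha > y_j - g:
        return 0.0
    if parent_sex == "F":
        surv_to = y_j          # mother must survive gestation to the birth
        gest = phi ** (-g)
    else:
        surv_to = y_j - g      # father only needs to reach the mating year
        gest = 1.0
    surv = 1.0 if c_i >= surv_to else phi ** (surv_to - c_i)
    return gest * surv


def kinship_matrix(parent_sex: str, parent_capture_year: int,
                   offspring_capture_year: int, species: SpeciesConfig) -> np.ndarray:
    """Kinship multipliers over all (parent age, offspring age) combinations.

    Entry ``[a_i, a_j]`` is ``kinship_coefficient`` with birth years implied
    by the capture years: ``y = c - a``.  Ages run 0..a_max on both axes.
    """
    phi = species.phi
    g = species.gestation_years
    alpha = species.alpha(parent_sex)
    ages = np.arange(species.a_max + 1)
    y_i = parent_capture_year - ages[:, None]
    y_j = offspring_capture_year - ages[None, :]
    mature = y_i + alpha <= y_j - g
    surv_to = y_j if parent_sex == "F" else y_j - g
    exponent = np.maximum(surv_to - parent_capture_year, 0)
    m = np.where(mature, phi ** exponent, 0.0)
    if parent_sex == "F" and g:
        m *= phi ** (-g)
    return m


def pair_coefficients(record_i: pd.Series, record_j: pd.Series,
                      model: AgeModel, species: SpeciesConfig) -> tuple[float, float]:
    """Age-marginalised coefficients (A, B) for one record pair.

    A sums the i-is-parent kernel over both age posteriors, B the
    j-is-parent direction;  Pr(PO/OP) = A / N_{sex_i} + B / N_{sex_j}.
    """
    p_i = age_posterior(int(record_i["measured_length"]), model)
    p_j = age_posterior(int(record_j["measured_length"]), model)
    m_ij = kinship_matrix(record_i["sex"], int(record_i["capture_year"]),
                          int(record_j["capture_year"]), species)
    m_ji = kinship_matrix(record_j["sex"], int(record_j["capture_year"]),
                          int(record_i["capture_year"]), species)
    a = float(p_i @ m_ij @ p_j)
    b = float(p_j @ m_ji @ p_i)
    return a, b


@dataclass(frozen=True)
class ComparisonTable:
    """Scenario-independent deduplication of all pairwise comparisons.

    Records collapse to unique profiles (sex, capture year, measured length);
    each unordered pair of profiles is one key with POP and total
    multiplicities.  Coefficients are attached later for a given assumed age
    model, so one table serves all misspecification scenarios of a replicate.
    """

    profile_sex: np.ndarray      # int8 per unique profile
    profile_year: np.ndarray     # int64
    profile_length: np.ndarray   # int64
    key_lo: np.ndarray           # profile index of the first slot per key
    key_hi: np.ndarray
    n_pop: np.ndarray            # POP multiplicity per key
    n_tot: np.ndarray            # total pair multiplicity per key
    n_records: int

    @property
    def n_keys(self) -> int:
        return self.key_lo.size


@dataclass(frozen=True)
class AggregatedComparisons:
    """Comparison table with age-marginalised coefficients attached.

    Per key:  Pr(PO/OP) = A / N[s1] + B / N[s2] with sex codes 0=female,
    1=male.  ``feasible`` is False when some observed length is impossible
    under the assumed model; the likelihood is then undefined.
    """

    s1: np.ndarray
    s2: np.ndarray
    A: np.ndarray
    B: np.ndarray
    n_pop: np.ndarray
    n_tot: np.ndarray
    n_records: int
    feasible: bool

    def identifiable(self, sex_code: int) -> bool:
        """True when at least one observed POP key puts parental probability
        mass on the given sex, so its abundance enters the likelihood."""
        pop = self.n_pop > 0
        return bool(np.any(pop & (((self.s1 == sex_code) & (self.A > 0))
                                  | ((self.s2 == sex_code) & (self.B > 0)))))


def build_comparison_table(samples: pd.DataFrame, pop_pairs: np.ndarray) -> ComparisonTable:
    """Collapse all n(n-1)/2 record pairs (including the pair formed by two
    captures of one individual, which is a non-POP comparison) to unique
    keys."""
    n = len(samples)
    if n < 2:
        raise ValueError("need at least two capture records")
    sex = samples["sex"].map(_SEX_CODE).to_numpy(dtype=np.int64)
    year = samples["capture_year"].to_numpy(dtype=np.int64)
    length = samples["measured_length"].to_numpy(dtype=np.int64)
    profiles, uid = np.unique(
        np.column_stack([sex, year, length]), axis=0, return_inverse=True
    )
    uid = uid.astype(np.int64)
    n_u = profiles.shape[0]

    # pair multiplicities come straight from the profile counts: c_u * c_v
    # pairs between distinct profiles, C(c_u, 2) within one profile
    counts = np.bincount(uid, minlength=n_u)
    lo, hi = np.triu_indices(n_u)
    tot = np.where(lo == hi, counts[lo] * (counts[lo] - 1) // 2,
                   counts[lo] * counts[hi])

    pop_flat = np.zeros(n_u * n_u, dtype=np.int64)
    if pop_pairs.size:
        p1, p2 = uid[pop_pairs[:, 0]], uid[pop_pairs[:, 1]]
        pflat = np.minimum(p1, p2) * n_u + np.maximum(p1, p2)
        pop_flat = np.bincount(pflat, minlength=n_u * n_u)
    pop = pop_flat[lo * n_u + hi]

    keep = tot > 0
    return ComparisonTable(
        profile_sex=profiles[:, 0].astype(np.int8),
        profile_year=profiles[:, 1],
        profile_length=profiles[:, 2],
        key_lo=lo[keep],
        key_hi=hi[keep],
        n_pop=pop[keep].astype(np.int64),
        n_tot=tot[keep].astype(np.int64),
        n_records=n,
    )


def attach_coefficients(table: ComparisonTable, model: AgeModel,
                        species: SpeciesConfig) -> AggregatedComparisons:
    """Compute the (A, B) coefficients of every key under an assumed age
    model.  Vectorised: posteriors for the unique lengths once, then one
    matrix product per (parent sex, capture-year pair) block."""
    lengths, lidx = np.unique(table.profile_length, return_inverse=True)
    post_u, ok = posterior_matrix(lengths, model)
    feasible = bool(ok.all())
    post = post_u[lidx]  # per profile

    n_u = table.profile_sex.size
    years = np.unique(table.profile_year)
    # directed[u, v] = coefficient for "profile u is the parent of profile v"
    directed = np.zeros((n_u, n_u))
    for sex_code, sex in ((0, "F"), (1, "M")):
        for c_i in years:
            rows = np.nonzero((table.profile_sex == sex_code)
                              & (table.profile_year == c_i))[0]
            if rows.size == 0:
                continue
            for c_j in years:
                cols = np.nonzero(table.profile_year == c_j)[0]
                if cols.size == 0:
                    continue
                m = kinship_matrix(sex, int(c_i), int(c_j), species)
                directed[np.ix_(rows, cols)] = (post[rows] @ m) @ post[cols].T

    a = directed[table.key_lo, table.key_hi]
    b = directed[table.key_hi, table.key_lo]
    # keys with zero coefficients and no observed POP contribute exactly
    # log(1 - 0) = 0 at any abundance; drop them from the likelihood sum
    keep = (a > 0) | (b > 0) | (table.n_pop > 0)
    return AggregatedComparisons(
        s1=table.profile_sex[table.key_lo][keep],
        s2=table.profile_sex[table.key_hi][keep],
        A=a[keep],
        B=b[keep],
        n_pop=table.n_pop[keep],
        n_tot=table.n_tot[keep],
        n_records=table.n_records,
        feasible=feasible,
    )


def aggregate_comparisons(samples: pd.DataFrame, pop_pairs: np.ndarray,
                          model: AgeModel, species: SpeciesConfig) -> AggregatedComparisons:
    """Deduplicated comparison table with coefficients, in one call."""
    return attach_coefficients(build_comparison_table(samples, pop_pairs), model, species)


def pseudo_log_likelihood(n_f: float, n_m: float, agg: AggregatedComparisons) -> float:
    """Pseudo-log-likelihood of the sex-specific adult abundances.

    Sum over keys of  n_pop * log P + (n_tot - n_pop) * log(1 - P)  with
    P = A/N_{s1} + B/N_{s2}.  Returns ``-inf`` when the data are infeasible
    under the assumed model: some observed length impossible, or an observed
    POP whose probability is exactly zero.  P >= 1 (an optimiser excursion to
    tiny abundance) is clipped inside log(1 - P).
    """
    if not agg.feasible:
        return -np.inf
    if n_f <= 0 or n_m <= 0:
        raise ValueError("abundances must be positive")
    n_by_sex = np.array([n_f, n_m], dtype=float)
    p = agg.A / n_by_sex[agg.s1] + agg.B / n_by_sex[agg.s2]
    pops = agg.n_pop > 0
    if np.any(pops & (p <= 0.0)):
        return -np.inf
    ll = 0.0
    if np.any(pops):
        ll += float(np.sum(agg.n_pop[pops] * np.log(p[pops])))
    non = agg.n_tot - agg.n_pop
    mask = non > 0
    if np.any(mask):
        ll += float(np.sum(non[mask] * np.log1p(-np.minimum(p[mask], _P_CLIP))))
    return ll
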