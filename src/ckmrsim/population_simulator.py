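"""Agent-based, pedigree-tracking forward simulation of one population.

Each replicate runs a population for 100 years through the yearly cycle
birth/mating -> sampling (final two years only) -> survival -> ageing, and
returns the sampled records, the set of true parent-offspring pairs (POPs)
among them, and the per-year true adult abundances.

Implementation notes
--------------------
The living population is held in flat numpy arrays (id, birth year, sex,
gestation state) that are compacted at every survival event, so a year costs
O(living individuals).  The pedigree (mother and father of every individual
ever born) is accumulated in append-only buffers and only materialised when
kinship is resolved.  Founders carry no parents.

Conventions the verbal rules above leave open, fixed as follows:

* Founder ages are drawn from the truncated-geometric stationary age
  distribution over 1..a_max: the population *entering* a year has no age-0
  animals, because age 0 exists only between the birth and ageing stages.
* Measured lengths are rounded half away from zero to the nearest cm.
* A male is drawn uniformly (with replacement across litters) from the
  mature males; there is no male gestation state.
* Newborns are sampleable in their birth year (the sampling stage follows
  the birthing stage, and sampling is unrelated to age).
* Within one year the 375 individuals are sampled without replacement;
  recaptures can only occur between the two sampling years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .life_history import SpeciesConfig, stable_age_distribution, vbgf_length

__all__ = [
    "Population",
    "SimOutput",
    "initialize_population",
    "step_year",
    "run_simulation",
    "identify_kinship",
]

NO_PARENT = -1
NOT_GESTATING = -1
FEMALE, MALE = 0, 1


class ExtinctionError(RuntimeError):
    """Raised when a population dies out before sampling can take place."""


@dataclass
class Population:
    """Living individuals (compacted arrays) plus the append-only pedigree."""

    ids: np.ndarray            # int64, unique individual ids
    birth_year: np.ndarray     # int32; founders have year <= 0
    sex: np.ndarray            # int8, 0 = female, 1 = male
    gestating_by: np.ndarray   # int64, id of mate if gestating else -1
    next_id: int
    # pedigree buffers: one (mother_ids, father_ids) block per birth batch,
    # in id order starting at id 0 (founders first, with NO_PARENT)
    _mother_blocks: list = field(default_factory=list, repr=False)
    _father_blocks: list = field(default_factory=list, repr=False)

    @property
    def n_alive(self) -> int:
        return self.ids.size

    def ages(self, year: int) -> np.ndarray:
        return year - self.birth_year

    def adult_count(self, year: int, species: SpeciesConfig) -> tuple[int, int]:
        """(female, male) adults alive, by each sex's age at maturity."""
        age = self.ages(year)
        n_f = int(np.sum((self.sex == FEMALE) & (age >= species.alpha_f)))
        n_m = int(np.sum((self.sex == MALE) & (age >= species.alpha_m)))
        return n_f, n_m

    def pedigree(self) -> tuple[np.ndarray, np.ndarray]:
        """(mother, father) arrays indexed by individual id."""
        mother = np.concatenate(self._mother_blocks) if self._mother_blocks else np.empty(0, np.int64)
        father = np.concatenate(self._father_blocks) if self._father_blocks else np.empty(0, np.int64)
        return mother, father


def initialize_population(n0: int, species: SpeciesConfig, rng: np.random.Generator) -> Population:
    """Found a population of ``n0`` individuals entering year 1.

    Sexes are Bernoulli(1/2); ages are drawn from the stationary
    truncated-geometric distribution over 1..a_max, so birth years are
    ``1 - age``.  For the gestating species, each mature female enters
    gestating with probability 1/2 (her mate a random mature founder male),
    which avoids an artificial synchronised breeding cohort.
    """
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    ids = np.arange(n0, dtype=np.int64)
    sex = rng.integers(0, 2, size=n0).astype(np.int8)
    w = stable_age_distribution(species.phi, species.a_max, age_min=1)
    age = rng.choice(species.a_max + 1, size=n0, p=w)
    birth_year = (1 - age).astype(np.int32)
    gestating_by = np.full(n0, NOT_GESTATING, dtype=np.int64)
    if species.gestation_years == 1 and n0 > 0:
        mature_f = (sex == FEMALE) & (age >= species.alpha_f)
        mature_m_ids = ids[(sex == MALE) & (age >= species.alpha_m)]
        if mature_m_ids.size:
            start = mature_f & (rng.random(n0) < 0.5)
            gestating_by[start] = rng.choice(mature_m_ids, size=int(start.sum()))
    pop = Population(ids, birth_year, sex, gestating_by, next_id=n0)
    pop._mother_blocks.append(np.full(n0, NO_PARENT, dtype=np.int64))
    pop._father_blocks.append(np.full(n0, NO_PARENT, dtype=np.int64))
    return pop


def _spawn(pop: Population, mothers: np.ndarray, fathers: np.ndarray,
           litter_sizes: np.ndarray, year: int, rng: np.random.Generator) -> None:
    """Append newborns (age 0 in ``year``) for per-litter mother/father ids."""
    n_new = int(litter_sizes.sum())
    if n_new == 0:
        return
    mother_ids = np.repeat(mothers, litter_sizes)
    father_ids = np.repeat(fathers, litter_sizes)
    new_ids = np.arange(pop.next_id, pop.next_id + n_new, dtype=np.int64)
    pop.next_id += n_new
    pop._mother_blocks.append(mother_ids)
    pop._father_blocks.append(father_ids)
    pop.ids = np.concatenate([pop.ids, new_ids])
    pop.birth_year = np.concatenate([pop.birth_year, np.full(n_new, year, dtype=np.int32)])
    pop.sex = np.concatenate([pop.sex, rng.integers(0, 2, size=n_new).astype(np.int8)])
    pop.gestating_by = np.concatenate([pop.gestating_by, np.full(n_new, NOT_GESTATING, dtype=np.int64)])


def _birth_stage(pop: Population, year: int, species: SpeciesConfig,
                 rng: np.random.Generator) -> None:
    age = pop.ages(year)
    mature_m_ids = pop.ids[(pop.sex == MALE) & (age >= species.alpha_m)]
    if species.gestation_years == 0:
        mothers = pop.ids[(pop.sex == FEMALE) & (age >= species.alpha_f)]
        if mothers.size == 0 or mature_m_ids.size == 0:
            return
        fathers = rng.choice(mature_m_ids, size=mothers.size)
        litters = np.full(mothers.size, species.litter_sizes[0], dtype=np.int64)
        if len(species.litter_sizes) > 1:
            litters = rng.choice(species.litter_sizes, size=mothers.size).astype(np.int64)
        _spawn(pop, mothers, fathers, litters, year, rng)
        return
    # gestating species: births from last year's matings, then new matings
    birthing = pop.gestating_by != NOT_GESTATING
    mothers = pop.ids[birthing]
    fathers = pop.gestating_by[birthing].copy()
    pop.gestating_by[birthing] = NOT_GESTATING
    if mothers.size:
        litters = rng.choice(species.litter_sizes, size=mothers.size).astype(np.int64)
        _spawn(pop, mothers, fathers, litters, year, rng)
        birthing = np.concatenate([birthing, np.zeros(int(litters.sum()), dtype=bool)])
    # females that just gave birth skip this year's mating
    age = pop.ages(year)
    available = (pop.sex == FEMALE) & (age >= species.alpha_f) & ~birthing \
        & (pop.gestating_by == NOT_GESTATING)
    n_avail = int(available.sum())
    if n_avail and mature_m_ids.size:
        pop.gestating_by[available] = rng.choice(mature_m_ids, size=n_avail)


def _sample_stage(pop: Population, year: int, count: int, species: SpeciesConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    if count > pop.n_alive:
        raise ExtinctionError(
            f"cannot sample {count} from {pop.n_alive} living individuals in year {year}"
        )
    pick = rng.choice(pop.n_alive, size=count, replace=False)
    age = pop.ages(year)[pick]
    true_len = vbgf_length(age, species.vbgf)
    measured = np.floor(true_len + rng.normal(0.0, species.sigma_l, size=count) + 0.5)
    measured = np.maximum(measured, 1.0).astype(np.int64)
    return pd.DataFrame(
        {
            "individual_id": pop.ids[pick],
            "capture_year": np.full(count, year, dtype=np.int64),
            "sex": np.where(pop.sex[pick] == FEMALE, "F", "M"),
            "true_age": age.astype(np.int64),
            "measured_length": measured,
        }
    )


def _survival_stage(pop: Population, year: int, species: SpeciesConfig,
                    rng: np.random.Generator) -> None:
    age = pop.ages(year)
    survive = (age < species.a_max) & (rng.random(pop.n_alive) < species.phi)
    pop.ids = pop.ids[survive]
    pop.birth_year = pop.birth_year[survive]
    pop.sex = pop.sex[survive]
    pop.gestating_by = pop.gestating_by[survive]


def step_year(pop: Population, year: int, species: SpeciesConfig,
              rng: np.random.Generator, sample_count: int = 0) -> pd.DataFrame:
    """Run one full yearly cycle in place; returns this year's sample records
    (empty frame when ``sample_count`` is 0).  Ageing is implicit: an
    individual's age is always ``year - birth_year``."""
    _birth_stage(pop, year, species, rng)
    if sample_count:
        samples = _sample_stage(pop, year, sample_count, species, rng)
    else:
        samples = pd.DataFrame(
            columns=["individual_id", "capture_year", "sex", "true_age", "measured_length"]
        )
    _survival_stage(pop, year, species, rng)
    return samples


@dataclass
class SimOutput:
    """One replicate's synthetic data set and its ground truth."""

    samples: pd.DataFrame          # one row per capture record
    pop_pairs: np.ndarray          # (n_pop, 2) record indices, i < j
    truth: pd.DataFrame            # year, adult and total abundance by sex
    growth_rate: float             # geometric-mean annual growth of total abundance
    growth_rate_f: float
    growth_rate_m: float
    recapture_count: int           # individuals sampled in both years
    pedigree_mother: np.ndarray    # parent ids indexed by individual id
    pedigree_father: np.ndarray

    @property
    def n_pops(self) -> int:
        return int(self.pop_pairs.shape[0])

    def final_adults(self) -> tuple[int, int]:
        last = self.truth.iloc[-1]
        return int(last["N_f_adult"]), int(last["N_m_adult"])


def identify_kinship(samples: pd.DataFrame, pedigree_mother: np.ndarray,
                     pedigree_father: np.ndarray) -> np.ndarray:
    """True parent-offspring pairs among capture records.

    An unordered pair of records is a POP iff one record's individual is the
    recorded mother or father of the other's.  Every other relationship
    (half-siblings, grandparents, two captures of the same individual,
    unrelated) counts as "not a POP".  Returns an array of record-index pairs
    (row positions in ``samples``), each with the smaller index first.
    """
    rec_ids = samples["individual_id"].to_numpy()
    pairs = []
    # map individual id -> record rows (an individual may be captured twice)
    by_id: dict[int, list[int]] = {}
    for row, ind in enumerate(rec_ids):
        by_id.setdefault(int(ind), []).append(row)
    for row, ind in enumerate(rec_ids):
        for parent in (pedigree_mother[ind], pedigree_father[ind]):
            if parent == NO_PARENT:
                continue
            for prow in by_id.get(int(parent), ()):
                pairs.append((min(row, prow), max(row, prow)))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.asarray(pairs, dtype=np.int64), axis=0)


def run_simulation(species: SpeciesConfig, years: int = 100,
                   sample_years: tuple[int, ...] = (99, 100),
                   n_per_year: int = 375, n0: int = 8500,
                   seed=None) -> SimOutput:
    """Simulate one replicate population and its close-kin sample.

    The population is founded with ``n0`` individuals and stepped through
    ``years`` yearly cycles; ``n_per_year`` individuals are captured
    (non-lethally, uniformly at random, without replacement within a year)
    in each of ``sample_years``.  Requires ``years > a_max`` so that all
    founders -- whose parents are unrecorded -- are dead before sampling.
    """
    if species.phi is None:
        raise ValueError("species.phi must be set (use simple_species()/complex_species())")
    if min(sample_years) <= species.a_max:
        raise ValueError("sampling must happen after all founders have died")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = initialize_population(n0, species, rng)
    sample_frames = []
    truth_rows = []
    for year in range(1, years + 1):
        count = n_per_year if year in sample_years else 0
        _birth_stage(pop, year, species, rng)
        n_f_ad, n_m_ad = pop.adult_count(year, species)
        age = pop.ages(year)
        truth_rows.append(
            (year, n_f_ad, n_m_ad,
             int(np.sum(pop.sex == FEMALE)), int(np.sum(pop.sex == MALE)))
        )
        if count:
            sample_frames.append(_sample_stage(pop, year, count, species, rng))
        _survival_stage(pop, year, species, rng)
        if pop.n_alive == 0 and year < max(sample_years):
            raise ExtinctionError(f"population extinct in year {year}")
    samples = pd.concat(sample_frames, ignore_index=True) if sample_frames else \
        pd.DataFrame(columns=["individual_id", "capture_year", "sex", "true_age", "measured_length"])
    truth = pd.DataFrame(
        truth_rows, columns=["year", "N_f_adult", "N_m_adult", "N_f_total", "N_m_total"]
    )
    mother, father = pop.pedigree()
    pop_pairs = identify_kinship(samples, mother, father)
    tot_first = truth.iloc[0][["N_f_total", "N_m_total"]].sum()
    tot_last = truth.iloc[-1][["N_f_total", "N_m_total"]].sum()
    span = years - 1
    growth = float((tot_last / tot_first) ** (1.0 / span))
    growth_f = float((truth["N_f_total"].iloc[-1] / truth["N_f_total"].iloc[0]) ** (1.0 / span))
    growth_m = float((truth["N_m_total"].iloc[-1] / truth["N_m_total"].iloc[0]) ** (1.0 / span))
    counts = samples["individual_id"].value_counts()
    return SimOutput(
        samples=samples,
        pop_pairs=pop_pairs,
        truth=truth,
        growth_rate=growth,
        growth_rate_f=growth_f,
        growth_rate_m=growth_m,
        recapture_count=int((counts > 1).sum()),
        pedigree_mother=mother,
        pedigree_father=father,
    )
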