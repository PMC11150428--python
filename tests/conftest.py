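import numpy as np
import pandas as pd
import pytest

from ckmrsim import (
    AgeModel,
    complex_species,
    simple_species,
    run_simulation,
    vbgf_length,
)
from ckmrsim.life_history import VBGFParams


@pytest.fixture(scope="session")
def simple_sp():
    return simple_species()


@pytest.fixture(scope="session")
def complex_sp():
    return complex_species()


@pytest.fixture(scope="session")
def small_sim(simple_sp):
    """A reduced but structurally complete replicate (smaller population and
    sample, same 100-year horizon) for pedigree and likelihood tests."""
    return run_simulation(simple_sp, n0=1500, n_per_year=120, seed=42)


@pytest.fixture(scope="session")
def n30_fixture(small_sim):
    """First 30 capture records of the small replicate plus their POPs,
    for exact aggregation-vs-naive equivalence checks."""
    samples = small_sim.samples.iloc[:30].reset_index(drop=True)
    keep = np.all(small_sim.pop_pairs < 30, axis=1) if small_sim.pop_pairs.size else []
    pop_pairs = small_sim.pop_pairs[keep] if small_sim.pop_pairs.size else small_sim.pop_pairs
    return samples, pop_pairs


@pytest.fixture(scope="session")
def known_age_fixture(simple_sp):
    """A synthetic sample whose age posteriors are point masses.

    20 female and 20 male 'parents' aged exactly 12 and 30 age-0 'offspring',
    all captured in year 100 with near-zero assumed measurement error, so
    each parent-offspring comparison has probability exactly 1/N of the
    parent's sex and every other pair has probability zero.  The maximum
    pseudo-likelihood estimates then have the closed binomial form
    N_hat = (number of comparisons) / (number of POPs) per sex.
    """
    len12 = int(np.floor(vbgf_length(12, simple_sp.vbgf) + 0.5))
    len0 = int(np.floor(vbgf_length(0, simple_sp.vbgf) + 0.5))
    rows = []
    for i in range(20):
        rows.append(("F", len12))
    for i in range(20):
        rows.append(("M", len12))
    for i in range(30):
        rows.append(("F", len0))
    samples = pd.DataFrame(
        {
            "individual_id": np.arange(len(rows)),
            "capture_year": 100,
            "sex": [r[0] for r in rows],
            "true_age": [12] * 40 + [0] * 30,
            "measured_length": [r[1] for r in rows],
        }
    )
    # 12 female-parent POPs and 8 male-parent POPs
    pop_pairs = np.array(
        [(i, 40 + i) for i in range(12)] + [(20 + i, 52 + i) for i in range(8)],
        dtype=np.int64,
    )
    model = AgeModel(vbgf=simple_sp.vbgf, sigma=1e-3, phi=simple_sp.phi,
                     a_max=simple_sp.a_max)
    return samples, pop_pairs, model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_vbgf():
    return VBGFParams()
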