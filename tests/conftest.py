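import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from opgp.data import PedigreeTable
from opgp.simulate import SimConfig, simulate_dataset

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_pedigree() -> PedigreeTable:
    """Five individuals: two founder dams, a sire, and related progeny."""
    rows = [
        # individual, dam, sire, family
        ("M1", "", "", "F1"),
        ("M2", "", "", "F2"),
        ("S1", "", "", "F3"),
        ("C1", "M1", "S1", "F1"),
        ("C2", "M1", "", "F1"),
    ]
    df = pd.DataFrame(rows, columns=["individual_id", "dam_id", "sire_id",
                                     "family_id"])
    return PedigreeTable(df)


@pytest.fixture(scope="session")
def family_fixture_sim():
    """28-family OP dataset with hidden full sibs, two sites, genotyped subset."""
    cfg = SimConfig(n_families=28, progeny_per_family=12, n_markers=200,
                    n_qtl=60, n_genotyped_families=28, genotyped_per_family=10,
                    seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
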