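import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def chem_fixture_df():
    """The small synthetic chemistry deck: 3 families x 5 R-groups + 50 decoys."""
    from synergyscreen.benchmark import generate_smiles_fixture

    return generate_smiles_fixture(n_families=3, r_groups_per_family=5, n_decoys=50, seed=2506)


@pytest.fixture(scope="session")
def prepared_chem_library(chem_fixture_df):
    """The chemistry deck pushed through library preparation."""
    from synergyscreen import libprep

    records = [
        libprep.CompoundRecord(r.compound_id, r.smiles, r.activity)
        for r in chem_fixture_df.itertuples(index=False)
    ]
    kept, log = libprep.prepare_library(records)
    assert len(log) == 0, f"fixture compounds must pass all filters: {log}"
    return kept


@pytest.fixture(scope="session")
def small_latent_library():
    """A reduced latent deck for fast structural tests."""
    from synergyscreen import benchmark as bm

    cfg = bm.SyntheticLibraryConfig(
        n_active=60, n_decoy=600, n_families=10, channel_overlap=0.2, seed=7
    )
    return bm.generate_latent_library(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
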