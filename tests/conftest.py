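import numpy as np
import pytest

from itsclip import boundary as bd
from itsclip import synthetic_data as sim


@pytest.fixture(scope="session")
def flank_alignments():
    return sim.default_flank_alignments()


@pytest.fixture(scope="session")
def calibrated_profiles(flank_alignments):
    """The three bundled flank profiles, calibrated once per session."""
    profiles = []
    for i, name in enumerate(bd.FLANK_NAMES):
        profile = bd.build_profile(flank_alignments[name], name=name)
        profiles.append(bd.calibrate_profile(profile, seed=100 + i, n=400, length=400))
    return profiles


@pytest.fixture(scope="session")
def small_simulation():
    """A modest error-carrying merged-read simulation shared across tests."""
    config = sim.SimConfig(seed=11, n_taxa=4, reads_per_taxon=25)
    return sim.simulate_amplicons(config)


@pytest.fixture(scope="session")
def clean_simulation():
    """Error-free merged reads (sequences equal the true inserts)."""
    config = sim.SimConfig(seed=12, n_taxa=3, reads_per_taxon=10, per_base_error_rate=0.0)
    return sim.simulate_amplicons(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
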