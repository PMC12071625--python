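import numpy as np
import pandas as pd
import pytest

from latkit.synthdata import LOC_COLUMNS


def make_locs(rows):
    """Localization table from (frame, x, y, intensity, precision, channel) rows."""
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def bright_assembly_movie():
    """Immobile bright assemblies on a fluorescent cell (shared across tests)."""
    from latkit.synthdata import MembraneSimConfig, simulate_membrane_movie

    cfg = MembraneSimConfig(
        n_molecules=25, frac_confined=0.0, d_free=0.0, d_confined=0.0,
        field_size=96, frame_interval=0.2, n_frames=60,
        photons_per_molecule=3000.0, membrane_photons=30.0,
        baseline=10.0, read_noise_sd=2.0, min_separation=0.8, seed=7)
    return cfg, *simulate_membrane_movie(cfg)
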