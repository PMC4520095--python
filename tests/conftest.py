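import numpy as np
import pytest
from hypothesis import settings

import phosphosig as ps

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_window(window: str, offset: int | None = None, species: str = "sp",
                dataset: str = "d1", protein: str = "P1",
                site: int | None = None) -> ps.PhosphopeptideWindow:
    """Convenience constructor used across the suite."""
    if offset is None:
        offset = (len(window) - 1) // 2
    if site is None:
        site = offset + 1
    return ps.PhosphopeptideWindow(species=species, dataset_id=dataset,
                                   protein_id=protein, site_pos=site,
                                   window=window, offset_of_site=offset)


@pytest.fixture(scope="session")
def default_study():
    """The full default synthetic study (5 train x 2 datasets + 5 test, 500
    windows each, insertion probability 0.3, seed 1)."""
    return ps.generate_study(ps.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_study):
    """Full pipeline on the default study, 1000 bootstrap replicates."""
    train, test, design, _ = default_study
    return ps.run_study(train, test, design,
                        ps.PipelineParams(n_boot=1000, seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (150 windows per dataset) for fast module tests."""
    return ps.generate_study(ps.SimulationConfig(seed=7,
                                                 windows_per_dataset=150))


@pytest.fixture(scope="session")
def small_run(small_study):
    train, test, design, _ = small_study
    return ps.run_study(train, test, design,
                        ps.PipelineParams(n_boot=100, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
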