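import warnings

import pytest

from aimchip.simulate import (
    PeakSpec,
    RepeatSpec,
    SimulationConfig,
    generate_fixture,
)

warnings.filterwarnings("ignore", category=DeprecationWarning)


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A reduced study design for fast unit tests.

    Keeps the structural features (all gap orientations, repeat family,
    planted AIMs) at a fraction of the default scale.
    """
    defaults = dict(
        rng_seed=seed,
        n_contigs=3,
        genes_per_contig=12,
        peak_spec=PeakSpec(
            core_single=4,
            core_divergent=4,
            core_tail_to_tail=2,
            extra_loci_per_experiment=3,
            n_control_peaks=5,
        ),
        repeat_spec=RepeatSpec(n_copies=4),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def study():
    """The full-scale synthetic study at the default design (seed 1)."""
    return generate_fixture(SimulationConfig(rng_seed=1))


@pytest.fixture(scope="session")
def small_study():
    return generate_fixture(small_config())


@pytest.fixture(scope="session")
def contig_lengths(study):
    return {c.contig_id: len(c) for c in study.contigs}
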