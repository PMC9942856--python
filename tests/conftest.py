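import numpy as np
import pytest
from hypothesis import settings

from ieslandscape.synthetic_data import (
    FamilySimConfig,
    IesSimConfig,
    SimConfig,
    TimepointSimConfig,
    simulate,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_config(seed: int = 11) -> SimConfig:
    """A fast, reduced-scale simulation for unit tests."""
    return SimConfig(
        seed=seed,
        n_contigs=2,
        contig_length=150_000,
        ies=IesSimConfig(
            n=300,
            n_spurious=12,
            periodic_peaks={65: 0.2, 75: 0.2},
            nonperiodic_peaks={150: 0.1},
        ),
        families=[
            FamilySimConfig(name="BogoMITE", n_mobile=30, n_nested=5, n_partial=5),
            FamilySimConfig(
                name="BstTc1",
                n_mobile=5,
                n_nested=2,
                element_len=520,
                host_len=1100,
                microsat_unit="GGGAAGGACT",
                p_microsat=1.0,
            ),
        ],
        srna=[
            TimepointSimConfig(label="t1", n_reads=3000),
            TimepointSimConfig(
                label="t2",
                n_reads=3000,
                origin_weights={
                    24: {"IES": 0.5, "CDS": 0.3, "NON": 0.2},
                    "default": {"IES": 0.05, "CDS": 0.57, "NON": 0.36, "EXCLUDED": 0.02},
                },
                p_five_prime_u={24: 1.0, "default": 0.25},
            ),
        ],
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
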