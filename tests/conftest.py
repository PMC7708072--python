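import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# a 151-nt amplicon with the guide at [28, 48) and primer footprints at the ends
AMPLICON_REFERENCE = (
    "ATGCCTGAGTCCGTTAACGGCATTCGGA"
    "GTCACCTCCAATGACTAGGGTGGAATCAGCTTACGGCTAGCATCGATACCGTGGAACT"
    "TCTAGGACATCGTTGCCAATGCATCGGATCCGAAGTTCGACCTGTACTTAGCGGTCAATGCCGTA"
)


@pytest.fixture(scope="session")
def amplicon_reference() -> str:
    return AMPLICON_REFERENCE


@pytest.fixture(scope="session")
def experiment():
    from pamscreen import AmpliconExperiment

    ref = AMPLICON_REFERENCE
    return AmpliconExperiment(
        reference=ref,
        guide_start=28,
        guide_end=48,
        primer_regions=((0, 20), (len(ref) - 20, len(ref))),
    )


@pytest.fixture(scope="session")
def small_screen():
    """One modest in vitro screen simulation shared across tests."""
    from pamscreen import PamRule, ScreenSimConfig, simulate_screen

    config = ScreenSimConfig(
        rule=PamRule(("NNNNRTN",), cleave_prob=0.95),
        depth_control=200_000,
        depth_selected=200_000,
        seed=0,
    )
    return config, simulate_screen(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
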