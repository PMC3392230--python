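import numpy as np
import pytest

from radsexscan.simcross import ChromosomeSpec, SexModel, SimulationConfig, simulate_cross


@pytest.fixture(scope="session")
def tiny_config():
    """Two small chromosomes, 60 F2 fish, a fully penetrant-ish sex locus on chr2."""
    return SimulationConfig(
        n_f2=60,
        chromosomes=(
            ChromosomeSpec("chr1", 20_000_000, 12, 60.0),
            ChromosomeSpec("chr2", 24_000_000, 12, 60.0),
        ),
        sex_model=SexModel(loci=(("chr2", 22_000_000),),
                           table={"G1G1": 1.0, "G1G2": 0.16, "G2G2": 0.0}),
        p_missing=0.05,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate_cross(tiny_config, np.random.default_rng(1234))
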