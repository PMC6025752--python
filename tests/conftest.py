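import numpy as np
import pytest

from ocrdyn.simulate import SimulationConfig, demo_pwms, run_simulation


@pytest.fixture(scope="session")
def small_sim():
    """A compact full simulation shared by read-only tests: 300 peaks,
    60 genes, 4 TFs bound in different stages."""
    pwms = demo_pwms(4, seed=11)
    config = SimulationConfig(
        genome_length=2_000_000,
        n_peaks=300,
        n_genes=60,
        seed=3,
        motif_fraction=0.4,
        tf_bound_stages={
            "TF1": ("N-d41",),
            "TF2": ("N-d41",),
            "TF3": ("hiPSC",),
            "TF4": ("N-d30",),
        },
    )
    return run_simulation(config, pwms=pwms)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
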