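import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_cohort():
    """Default simulated cohort (documented seed 1), shared across tests."""
    from organotrope.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def cytoband_file(tmp_path):
    """Tiny synthetic cytoband table (chr8 and chr13) for arm calling."""
    lines = [
        ("chr8", 0, 20_000_000, "p23.1", "gneg"),
        ("chr8", 20_000_000, 40_000_000, "p11.2", "gpos50"),
        ("chr8", 40_000_000, 80_000_000, "q11", "gneg"),
        ("chr8", 80_000_000, 140_000_000, "q24", "gpos25"),
        ("chr13", 0, 16_000_000, "p11", "gvar"),
        ("chr13", 16_000_000, 100_000_000, "q14", "gneg"),
    ]
    path = tmp_path / "cytoBand.txt"
    path.write_text(
        "\n".join("\t".join(map(str, row)) for row in lines) + "\n"
    )
    return path
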