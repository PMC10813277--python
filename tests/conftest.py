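import numpy as np
import pytest

import implantrom as ir


@pytest.fixture(scope="session")
def space():
    return ir.build_default_space("anterior")


@pytest.fixture(scope="session")
def emulator(space):
    return ir.build_anchored_emulator(space)


@pytest.fixture(scope="session")
def l25_table(space, emulator):
    """Noise-free emulator responses on the L25 orthogonal array."""
    return ir.run_doe(emulator, ir.taguchi_l25(space))


@pytest.fixture(scope="session")
def random_table(space, emulator):
    """Noise-free emulator responses on 60 seeded random in-range placements."""
    rng = np.random.default_rng(7)
    rows = [
        ir.PlacementConfig(
            {v.name: float(rng.uniform(v.lower, v.upper)) for v in space.variables},
            "anterior",
        )
        for _ in range(60)
    ]
    return ir.run_doe(emulator, ir.DesignMatrix(rows, "custom"))


def baseline_config(space):
    from implantrom.fea_emulator import BASELINE_VALUES

    return ir.PlacementConfig(BASELINE_VALUES, region=space.region)
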