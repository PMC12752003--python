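import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vspgrid as vg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: TIP3P-ish water geometry, Å (O–H 0.9572, H–O–H 104.52°).
WATER_COORDS = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.9572, 0.0, 0.0],
        [-0.2399872, 0.92662721, 0.0],
    ]
)

METHANE_COORDS = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.6291, 0.6291, 0.6291],
        [-0.6291, -0.6291, 0.6291],
        [-0.6291, 0.6291, -0.6291],
        [0.6291, -0.6291, -0.6291],
    ]
)


@pytest.fixture
def water():
    return vg.MolecularFrame.from_arrays(["O", "H", "H"], WATER_COORDS)


@pytest.fixture
def methane():
    return vg.MolecularFrame.from_arrays(["C", "H", "H", "H", "H"], METHANE_COORDS)


@pytest.fixture
def water_xyz_text():
    lines = ["3", "water"]
    for el, (x, y, z) in zip(["O", "H", "H"], WATER_COORDS):
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"
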