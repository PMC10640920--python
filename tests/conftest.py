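import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from gave.selection import default_menu  # noqa: E402


@pytest.fixture
def menu():
    return default_menu()


@pytest.fixture
def landmarks68():
    """A valid 68-point landmark set with hand-placed eye landmarks.

    Image-left eye: corners x=100/140 at y=125, upper-lid y 118/120,
    lower-lid y 130/132 (so eyelid midlines are 119 and 131).
    Image-right eye mirrored at x=180..220.
    """
    pts = np.zeros((68, 2))
    pts[:, 0] = np.linspace(60, 260, 68)  # harmless filler spread
    pts[:, 1] = 200.0
    pts[36] = (100, 125)
    pts[37] = (112, 118)
    pts[38] = (126, 120)
    pts[39] = (140, 125)
    pts[40] = (126, 132)
    pts[41] = (112, 130)
    pts[42] = (180, 125)
    pts[43] = (192, 118)
    pts[44] = (206, 120)
    pts[45] = (220, 125)
    pts[46] = (206, 132)
    pts[47] = (192, 130)
    return pts
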