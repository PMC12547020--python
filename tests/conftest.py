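import numpy as np
import pytest

from gpcrquant.io import RunConfig
from gpcrquant.synth import builtin_presets


@pytest.fixture(scope="session")
def presets():
    return builtin_presets()


@pytest.fixture(scope="session")
def small_cfg():
    """Config scaled for tiny test masks (size filter relaxed)."""
    return RunConfig(min_component_px=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_diamond_erosion(mask: np.ndarray, radius: int) -> np.ndarray:
    """Independent L1-ball containment oracle for diamond erosion."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in range(-radius, radius + 1):
                for dc in range(-radius + abs(dr), radius - abs(dr) + 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out
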