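import numpy as np
import pytest
from hypothesis import settings

from larvascreen.kinematics import KinematicThresholds
from larvascreen.protocol import Protocol, build_default_protocol

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol() -> Protocol:
    return build_default_protocol()


@pytest.fixture(scope="session")
def thresholds() -> KinematicThresholds:
    return KinematicThresholds()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def brute_force_bouts(disp, thresh=0.7, k=2):
    """Independent exhaustive bout finder used as the oracle for detect_bouts.

    Scans every frame; a bout opens at the first frame of a run of >= k
    consecutive supra-threshold frames and closes on the frame before the
    first subsequent run of k consecutive sub-threshold frames (bouts cut off
    by the end of the series close at the last supra-threshold frame).
    """
    disp = [0.0 if d != d else d for d in disp]  # NaN -> below threshold
    n = len(disp)
    above = [d > thresh for d in disp]
    spans = []
    i = 0
    while i < n:
        if all(above[i:i + k]) and i + k <= n:
            start = i
            end = None
            for j in range(start + 1, n - k + 1):
                if not any(above[j:j + k]):
                    end = j - 1
                    break
            if end is None:
                last = max(m for m in range(start, n) if above[m])
                spans.append((start, last))
                break
            spans.append((start, end))
            i = end + 1
        else:
            i += 1
    return spans
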