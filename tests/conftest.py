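import numpy as np
import pytest

from somnoscope import GenParams, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One default 10-min synthetic session, shared across tests (seed 7)."""
    return generate_session(GenParams(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def matched_fraction(detected, truth, key, tol=0.25):
    """Greedy one-to-one matching of detected to truth events.

    `key` maps an event to its matching time (trough for slow-waves, interval
    midpoint for bursts).  Returns (recall, precision).
    """
    if not truth:
        return float("nan"), float("nan")
    if not detected:
        return 0.0, float("nan")
    dt = np.array([key(e) for e in detected])
    used = np.zeros(dt.size, dtype=bool)
    tp = 0
    for e in truth:
        d = np.abs(dt - key(e))
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol:
            used[i] = True
            tp += 1
    return tp / len(truth), tp / len(detected)


def midpoint(e):
    return 0.5 * (e.start + e.end)


def trough(e):
    return e.peak_time
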