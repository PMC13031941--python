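import numpy as np
import pandas as pd
import pytest

import finpulse as fp


@pytest.fixture(scope="session")
def tone_frame():
    """A 30-s 200-Hz frame holding a pure 20-Hz tone."""
    t = np.arange(6000) / 200.0
    return np.sin(2 * np.pi * 20.0 * t)


@pytest.fixture(scope="session")
def small_count_table():
    """Hourly count table simulated from the NB mixed model (small)."""
    return fp.simulate_counts(fp.CountSimConfig(seed=11))


@pytest.fixture(scope="session")
def no_re_count_table():
    """Counts with both random-effect SDs at zero (plain NB regression truth)."""
    return fp.simulate_counts(
        fp.CountSimConfig(sigma_instrument=0.0, sigma_day=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def detections_table():
    """A small synthetic per-frame detections table spanning two days."""
    rng = np.random.default_rng(5)
    rows = []
    for instrument in ("OBS18", "OBS46"):
        for jd in (156, 174):
            for k in range(120 * 24):
                rows.append(
                    {
                        "instrument": instrument,
                        "jd": jd,
                        "time_s": 30.0 * k,
                        "label": int(rng.random() < 0.3),
                    }
                )
    return pd.DataFrame(rows)
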