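import numpy as np
import pandas as pd
import pytest

from memtopo import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_table(x, y, frames=None, unit="pixel", extent=None, **extra):
    """Build a LocalizationTable from bare coordinate arrays."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if frames is None:
        frames = np.arange(1, len(x) + 1)
    df = pd.DataFrame({"frame": np.asarray(frames, int), "x": x, "y": y, **extra})
    if extent is None:
        if len(x):
            extent = (
                float(min(x.min(), 0)),
                float(np.nextafter(x.max(), np.inf)),
                float(min(y.min(), 0)),
                float(np.nextafter(y.max(), np.inf)),
            )
        else:
            extent = (0, 1, 0, 1)
    return LocalizationTable(df, unit, extent)


@pytest.fixture
def csr_table(rng):
    """20k CSR points on a 2048 x 2048 pixel field."""
    n = 20000
    return make_table(
        rng.uniform(0, 2048, n), rng.uniform(0, 2048, n), extent=(0, 2048, 0, 2048)
    )
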