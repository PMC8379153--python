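import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


def make_table(points: np.ndarray, frame: int = 1) -> pd.DataFrame:
    """Wrap an (n, 2) coordinate array as a molecule-list DataFrame."""
    points = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {"x_nm": points[:, 0], "y_nm": points[:, 1], "frame": frame}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_emitter_field():
    """Factory: Gaussian localization clouds around given emitter positions."""

    def _make(emitters, sigma=3.0, n_locs=30, seed=0):
        r = np.random.default_rng(seed)
        pts = np.vstack(
            [e + r.normal(0.0, sigma, (n_locs, 2)) for e in np.asarray(emitters, float)]
        )
        return make_table(pts)

    return _make
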