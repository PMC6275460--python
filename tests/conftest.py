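import numpy as np
import pytest

from covroi import CoverageTrack


def naive_rolling(values, W, circular, stat):
    """Brute-force centered rolling statistic: per-window sort/mean oracle.

    Linear tracks truncate windows at the edges (median of an even
    number of points averages the two central order statistics);
    circular tracks wrap indices.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    v = (W - 1) // 2
    out = np.empty(n)
    for i in range(n):
        if circular:
            idx = (np.arange(i - v, i + v + 1)) % n
            window = values[idx]
        else:
            window = values[max(i - v, 0): min(i + v + 1, n)]
        out[i] = np.median(window) if stat == "median" else window.mean()
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def poisson_track(rng):
    """Trend-free 30 kb linear track at 100X."""
    return CoverageTrack("chr1", rng.poisson(100, 30_000))
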