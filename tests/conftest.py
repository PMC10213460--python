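import numpy as np
import pandas as pd
import pytest

from ctfrac.electropherogram import Trace


def make_trace(values_fn, start=15.0, stop=1700.0, step=1.0, sample_id="t"):
    """Trace on a regular grid with fluorescence from a vectorized callable."""
    x = np.arange(start, stop + step / 2, step)
    y = np.asarray(values_fn(x), dtype=float)
    return Trace(sample_id=sample_id, size_bp=x, fluorescence=y)


@pytest.fixture
def rectangle_trace():
    """Unit rectangle on [100, 200] bp, zero elsewhere."""
    return make_trace(lambda x: ((x >= 100) & (x <= 200)).astype(float))


@pytest.fixture
def random_calls():
    """Random per-CpG call table straddling every filter boundary."""
    rng = np.random.default_rng(123)
    n = 1000
    total = rng.integers(0, 600, size=n)
    methylated = rng.binomial(total, 0.7)
    return pd.DataFrame({
        "chrom": rng.choice(["chr1", "chr2"], size=n),
        "start": rng.integers(0, 50_000, size=n),
        "end": 0,
        "methylated": methylated,
        "total": total,
        "phred": rng.integers(0, 60, size=n),
    }).assign(end=lambda d: d["start"] + 1)
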