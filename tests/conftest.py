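import numpy as np
import pytest

from poremod.signal_model import EventSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_read(
    read_id: str,
    start: int,
    bases: str,
    counts,
    rng: np.random.Generator,
    loc: float = 0.0,
    scale: float = 1.0,
    normalized: bool = True,
) -> EventSequence:
    """A clean position-anchored read with Gaussian signals per event."""
    counts = np.asarray(counts, dtype=np.int64)
    signals = rng.normal(loc, scale, size=int(counts.sum()))
    return EventSequence(
        read_id, "+", start, bases, signals, counts, normalized=normalized
    )


@pytest.fixture
def make_read_factory(rng):
    def _make(read_id="r0", start=0, bases="ACGT", counts=(5, 5, 5, 5), **kw):
        return make_read(read_id, start, bases, counts, rng, **kw)

    return _make
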