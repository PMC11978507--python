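import numpy as np
import pytest

import poresig as ps
from poresig.simulate import SimParams


@pytest.fixture(scope="session")
def model5():
    """Synthetic normalized 5-mer truth model, central base at position 2."""
    return ps.make_truth_model(5, seed=11)


@pytest.fixture(scope="session")
def model3():
    return ps.make_truth_model(3, seed=7)


@pytest.fixture(scope="session")
def ref2k():
    """2 kb reference with a De Bruijn(4,5) core (every 5-mer present)."""
    return ps.random_reference(2000, seed=5, ensure_kmers=5)


@pytest.fixture(scope="session")
def ref500():
    return ps.random_reference(500, seed=9)


def noiseless_params(**kw):
    """Identifiability regime: every dwell at least the long t-test window
    so every event boundary is detectable in noiseless signal."""
    base = dict(noise_sd=0.0, skip_prob=0.0, move_jitter=0, scale_sd=0.0,
                shift_sd=0.0, quantize=False, dwell_min=6, dwell_mean=9.0)
    base.update(kw)
    return SimParams(**base)


@pytest.fixture(scope="session")
def noiseless_aligned(model5, ref500):
    sim = ps.simulate_read(ref500, model5, noiseless_params(), seed=21, read_id="nl")
    aln = ps.align_read(sim.raw, sim.meta(), ref500, model5, ps.AlignParams())
    return sim, aln
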