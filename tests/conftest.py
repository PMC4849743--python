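import numpy as np
import pytest

from homburden.cohort import GenotypeMatrix, Marker, Sample, compute_freqs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def build_gm(calls, positions=None, chroms=None, statuses=None, spacing_bp=20_000):
    """Assemble a GenotypeMatrix from a raw call array (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [(j + 1) * spacing_bp for j in range(m)]
    if chroms is None:
        chroms = [1] * m
    if statuses is None:
        statuses = ["case" if i < n // 2 else "control" for i in range(n)]
    markers = [
        Marker(id=f"rs{j + 1}", chrom=int(chroms[j]), pos_bp=int(positions[j]))
        for j in range(m)
    ]
    samples = [Sample(id=f"S{i + 1}", status=statuses[i]) for i in range(n)]
    gm = GenotypeMatrix(samples, markers, calls)
    compute_freqs(gm)
    return gm


@pytest.fixture
def random_gm(rng):
    calls = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
    return build_gm(calls)


@pytest.fixture
def clean_roh_cohort():
    from homburden.sim import make_fixture

    return make_fixture("clean_roh")
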