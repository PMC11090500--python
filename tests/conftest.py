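import numpy as np
import pytest

import tn5foot as t


@pytest.fixture(scope="session")
def genome():
    return t.generate_genome(5000, gc_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def uniform_landscape(genome):
    return t.plant_landscape(genome)


def make_profile(counts, contig="synth", start=0, library_size=None, state="raw", sample_id=None):
    counts = np.asarray(counts)
    if library_size is None:
        library_size = float(counts.sum())
    return t.CutProfile(
        contig=contig,
        start=start,
        counts=counts,
        library_size=library_size,
        state=state,
        sample_id=sample_id,
    )


@pytest.fixture
def profile_factory():
    return make_profile
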