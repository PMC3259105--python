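from __future__ import annotations

import numpy as np
import pytest

from pirnakit.model import Assembly, Library


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def toy_assembly():
    """Two small contigs with a known embedded structure."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    seqs = {
        "chrA": "".join(bases[rng.integers(0, 4, size=3000)]),
        "chrB": "".join(bases[rng.integers(0, 4, size=1500)]),
    }
    return Assembly(seqs)


def make_library(sequences, library_id="lib1", **kwargs):
    lib = Library(id=library_id, **kwargs)
    for item in sequences:
        if isinstance(item, tuple):
            seq, count = item
            lib.add(seq, count)
        else:
            lib.add(item)
    return lib


@pytest.fixture
def library_factory():
    return make_library
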