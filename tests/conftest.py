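import numpy as np
import pytest

from rodstab import HelixBundle, Residue
from rodstab.structure import DEFAULT_HELIX_RANGES


def random_bundle(rng: np.random.Generator) -> HelixBundle:
    """A bundle with one CA per residue at random coordinates."""
    residues = []
    for lo, hi in DEFAULT_HELIX_RANGES.values():
        for num in range(lo, hi + 1):
            residues.append(Residue(num, "DUM", (("CA", rng.normal(size=3)),)))
    return HelixBundle(residues, dict(DEFAULT_HELIX_RANGES))


@pytest.fixture
def rng():
    return np.random.default_rng(20170615)
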