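import numpy as np
import pytest

from mtagmap import find_sites
from mtagmap.sequences import (
    AMPLICON_SITE_LAYOUT,
    synthetic_plasmid,
    synthetic_sequence,
)


@pytest.fixture(scope="session")
def amplicon_map():
    """Nine-site reference map on a synthetic 5 kb fragment."""
    seq = synthetic_sequence(5000, "TCGA", AMPLICON_SITE_LAYOUT, seed=1)
    return find_sites(seq, "TCGA", name="synthetic-fragment")


@pytest.fixture(scope="session")
def plasmid_map():
    """Four-site reference map on a synthetic 2686 bp plasmid stand-in."""
    return find_sites(synthetic_plasmid(seed=0), "TCGA", name="synthetic-plasmid")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
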