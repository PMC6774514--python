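import pytest

from hlassoc.nomenclature import AlleleCall
from hlassoc.phasing import Haplotype
from hlassoc.simulate import ANCHOR_LABEL, default_pool


@pytest.fixture(scope="session")
def pool():
    return default_pool()


@pytest.fixture(scope="session")
def anchor():
    return Haplotype.from_label(ANCHOR_LABEL)


def genotype_of(h1: Haplotype, h2: Haplotype) -> dict:
    """Unphased genotype (canonical per-slot pairs) from a haplotype pair."""
    g = {}
    for slot in h1.slots:
        calls = sorted((h1.call_at(slot), h2.call_at(slot)))
        g[slot] = (calls[0], calls[1])
    return g
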