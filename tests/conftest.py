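import random

import pytest

from sairna.designer import TargetSite, build_hairpin, build_sairna
from sairna.seqcore import NucSeq

#: 21-nt probe-common target window used throughout (a real siRNA target
#: sequence printed in the field's Northern-blot ladder oligos).
PROBE_WINDOW = "AACUUCAGGGUCAGCUUGCCG"


def random_rna(n: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGU") for _ in range(n))


def make_site(window: str, source_id: str = "target", start: int = 1) -> TargetSite:
    w = NucSeq(window, "RNA")
    return TargetSite(source_id, start, w, w.gc_fraction())


def site_for(stem: int, loop: int, seed: int = 1) -> TargetSite:
    """A random valid window sized for the requested stem+loop."""
    return make_site(random_rna(stem + loop, seed))


@pytest.fixture
def probe_site() -> TargetSite:
    return make_site(PROBE_WINDOW)


@pytest.fixture
def sairna_design(probe_site):
    """The canonical 17-bp-stem / 4-nt-loop saiRNA built on the probe window."""
    return build_sairna(probe_site, stem_len=17, loop_len=4)
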