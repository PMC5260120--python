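import numpy as np
import pytest

from multiscaf.scaffolds import make_scaffold
from multiscaf.single_ref import ReferenceScaffolding


@pytest.fixture
def worked_example():
    """The four-reference, four-contig example with unit weights whose
    merged result is the single scaffold (+1,+2,+3,+4)."""
    scaffolds = {
        "R1": make_scaffold(["+1", "+2", "+3"]),
        "R2": make_scaffold(["+2", "+3", "+4"]),
        "R3": make_scaffold(["-1", "-4", "-3", "-2"]),
        "R4": make_scaffold(["+1", "-4", "+2", "-3"]),
    }
    scaffoldings = [ReferenceScaffolding(r, 1.0, [s]) for r, s in scaffolds.items()]
    return {
        "contigs": {"1", "2", "3", "4"},
        "scaffolds": scaffolds,
        "scaffoldings": scaffoldings,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
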