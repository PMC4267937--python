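import numpy as np
import pytest

from dhdup.config import PipelineConfig, SimConfig
from dhdup.qc import Read


@pytest.fixture
def cfg():
    """Default analysis thresholds (Q13/26bp trim, Q20 map, 99%, 4/2/10%)."""
    return PipelineConfig()


@pytest.fixture
def small_sim():
    """A small but realistic simulation: genes long enough for planted sites."""
    return SimConfig(
        n_genes=30,
        dup_fraction=0.2,
        psv_per_dup=(1, 4),
        isoform_fraction=0.1,
        exon_count_range=(4, 6),
        exon_len_range=(150, 250),
        mean_coverage=30.0,
        error_rate=0.0,
        seed=11,
    )


def make_read(bases, quals=None, rid="r"):
    if quals is None:
        quals = [30] * len(bases)
    return Read(rid, bases, np.asarray(quals))


@pytest.fixture
def read_factory():
    return make_read
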