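import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pycnvlite.binned_signals import BinGrid, CNTrack
from pycnvlite.vcf_ingest import ContigMap

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def contigs_1mb() -> ContigMap:
    return ContigMap({"chr1": 1_000_000})


def make_cn_track(values, bin_size=100_000, chrom="chr1") -> CNTrack:
    """CN track over one contig from a plain array (NaN = masked)."""
    values = np.asarray(values, dtype=float)
    contigs = ContigMap({chrom: len(values) * bin_size})
    return CNTrack(grid=BinGrid(contigs, bin_size), values={chrom: values.copy()})
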