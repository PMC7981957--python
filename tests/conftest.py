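import numpy as np
import pytest

from lowpasskit.panel_io import HaplotypePanel, Site


def make_panel(alleles, positions=None, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.uint8)
    M = alleles.shape[1]
    if positions is None:
        positions = [1000 * (m + 1) for m in range(M)]
    sites = [Site(chrom, int(p), "A", "G") for p in positions]
    return HaplotypePanel(sites=sites, alleles=alleles)


@pytest.fixture
def small_panel():
    """K=4, M=5 panel with both alleles segregating at every site."""
    return make_panel(
        [
            [0, 0, 1, 0, 1],
            [1, 0, 0, 1, 1],
            [0, 1, 1, 0, 0],
            [1, 1, 0, 1, 0],
        ],
        positions=[100, 5_000, 60_000, 900_000, 2_000_000],
    )
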