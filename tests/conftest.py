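import numpy as np
import pytest

from enhancerdnm.genomic_io import Region
from enhancerdnm.rates import GridEntry, RateTable, SiteAlleleGrid, demo_rate_table


def make_grid(lams, weights, region=None, n_trios=1):
    """Assemble a SiteAlleleGrid directly from intensity/weight vectors."""
    region = region or Region("chr1", 0, 10_000_000)
    entries = [
        GridEntry(pos=i + 1, ref="A", alt="C", lam=float(l), w=float(w))
        for i, (l, w) in enumerate(zip(lams, weights))
    ]
    return SiteAlleleGrid(region=region, entries=entries, n_trios=n_trios)


@pytest.fixture(scope="session")
def rate_table() -> RateTable:
    return demo_rate_table()


@pytest.fixture(scope="session")
def uniform_table() -> RateTable:
    """All 192 rates equal to 1e-8: makes lambda closed-form."""
    return RateTable({k: 1e-8 for k in demo_rate_table().entries}, strand_closed=True)


@pytest.fixture()
def random_sequence():
    rng = np.random.default_rng(7)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
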