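
import pandas as pd
import pytest

from sescape.intervals import ChromSizes, RegionSet
from sescape.simulate import SyntheticConfig, generate, worked_example


def region_set(rows, chromsizes=None, **kw):
    """rows: list of (chrom, start, end) or (chrom, start, end, name)."""
    df = pd.DataFrame(
        [r if len(r) == 4 else (*r, "") for r in rows],
        columns=["chrom", "start", "end", "name"],
    )
    return RegionSet(df, chromsizes=chromsizes, **kw)


@pytest.fixture(scope="session")
def genome():
    return ChromSizes({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def fixture_dataset():
    """One default synthetic landscape shared across tests (seed 7)."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_dataset():
    return worked_example()


def random_regions(rng, n, chroms=("chr1", "chr2"), max_pos=900_000,
                   max_width=5_000, chromsizes=None):
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, max_pos, size=n)
    width = rng.integers(1, max_width, size=n)
    df = pd.DataFrame(
        {"chrom": chrom, "start": start, "end": start + width}
    )
    return RegionSet(df, chromsizes=chromsizes)
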