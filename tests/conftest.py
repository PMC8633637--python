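import numpy as np
import pandas as pd
import pytest

from pyrodiv.genotype_core import MISSING, GenotypeTable


def make_table(rows, loci, calls) -> GenotypeTable:
    """Build a table from (id, block, plot, timepoint) tuples and a call array."""
    df = pd.DataFrame(rows, columns=["id", "block", "plot", "timepoint"])
    return GenotypeTable(df, loci, np.asarray(calls))


def random_table(
    rng: np.random.Generator,
    n_blocks: int = 2,
    plots_per_block: int = 2,
    n_ind_per_plot: int = 3,
    n_loci: int = 4,
    n_alleles: int = 4,
    missing_rate: float = 0.1,
) -> GenotypeTable:
    """Unstructured random table for property tests (uniform alleles)."""
    rows = []
    for b in range(n_blocks):
        for p in range(plots_per_block):
            for i in range(n_ind_per_plot):
                rows.append(
                    (f"b{b}p{p}i{i}", f"B{b}", f"B{b}-P{p}", "none")
                )
    n = len(rows)
    calls = 100 + 2 * rng.integers(0, n_alleles, size=(n, n_loci, 2))
    miss = rng.random((n, n_loci)) < missing_rate
    calls[miss] = MISSING
    return make_table(rows, [f"L{j + 1}" for j in range(n_loci)], calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """Two individuals, two loci, one missing genotype."""
    calls = [
        [[100, 100], [102, 104]],
        [[100, 102], [MISSING, MISSING]],
    ]
    return make_table(
        [("i1", "B1", "P1", "pre"), ("i2", "B1", "P1", "pre")],
        ["LocA", "LocB"],
        calls,
    )
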