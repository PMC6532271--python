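import numpy as np
import pandas as pd
import pytest

from chicmax import (
    FragmentMap,
    InteractionTable,
    RestrictionFragment,
    INTERACTION_COLUMNS,
)


@pytest.fixture(scope="session")
def tiling_map() -> FragmentMap:
    """20 fragments tiling chr1:0-20000 in 1-kb steps."""
    return FragmentMap(
        RestrictionFragment("chr1", i * 1000, (i + 1) * 1000, i)
        for i in range(20)
    )


def make_table(rows, label="toy") -> InteractionTable:
    """Rows of (bait_id, oe_id, n_reads) resolved against the tiling map."""
    recs = []
    for bait, oe, n in rows:
        recs.append({
            "ID_Bait": bait, "chr_Bait": "chr1",
            "start_Bait": bait * 1000, "end_Bait": (bait + 1) * 1000,
            "Bait_name": f"bait_{bait}",
            "ID_OE": oe, "chr_OE": "chr1",
            "start_OE": oe * 1000, "end_OE": (oe + 1) * 1000,
            "N": n,
        })
    return InteractionTable(pd.DataFrame(recs, columns=INTERACTION_COLUMNS),
                            label=label)


@pytest.fixture
def toy_table(tiling_map) -> InteractionTable:
    return make_table([(5, 2, 3), (5, 9, 7), (12, 14, 1)])


def random_map(n: int, rng: np.random.Generator, chrom="chr1") -> FragmentMap:
    """Random non-overlapping digest of n fragments with gaps."""
    lengths = rng.integers(200, 5000, size=n)
    gaps = rng.integers(0, 3, size=n) * rng.integers(0, 500, size=n)
    starts = np.cumsum(gaps + lengths) - lengths
    return FragmentMap(
        RestrictionFragment(chrom, int(s), int(s + l), i)
        for i, (s, l) in enumerate(zip(starts, lengths))
    )
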