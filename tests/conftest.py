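import numpy as np
import pandas as pd
import pytest

from phyllodyn.otu_io import RANKS, OtuTable


def make_table(counts: dict, months=None, taxonomy=None, metadata=None) -> OtuTable:
    """Build a small OtuTable from a {taxon: [counts...]} dict."""
    df = pd.DataFrame(counts).T
    n = df.shape[1]
    df.columns = [f"s{i+1}" for i in range(n)]
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {r: ["x"] * len(df) for r in RANKS}, index=df.index
        )
        taxonomy["kingdom"] = "bacteria"
    if metadata is None:
        months = months or ["Nov"] * n
        metadata = pd.DataFrame({
            "experiment": ["E1"] * n,
            "month": months,
            "ecotype": ["Col-0"] * n,
            "plant": [f"p{i+1}" for i in range(n)],
        }, index=df.columns)
    return OtuTable(counts=df.astype(np.int64), taxonomy=taxonomy,
                    samples=metadata)


@pytest.fixture
def toy_table() -> OtuTable:
    """3 taxa x 4 samples over two months."""
    return make_table(
        {"otuA": [5, 0, 2, 1], "otuB": [0, 3, 3, 3], "otuC": [10, 10, 0, 6]},
        months=["Nov", "Nov", "Dec", "Dec"],
    )


@pytest.fixture
def random_table() -> OtuTable:
    rng = np.random.default_rng(11)
    counts = {f"otu{i}": rng.integers(0, 40, size=12).tolist() for i in range(15)}
    months = ["Nov"] * 4 + ["Dec"] * 4 + ["Jan"] * 4
    return make_table(counts, months=months)
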