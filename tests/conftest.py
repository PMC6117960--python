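import numpy as np
import pandas as pd
import pytest

from dmcap import GenomicRegion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tss_table():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["chr1", "chr1", "chr1"],
            "strand": ["+", "-", "+"],
            "tss": [10000, 30000, 2000],
            "exon1_start": [10000, 29800, 2000],
            "exon1_end": [10200, 30000, 2100],
        }
    )


@pytest.fixture
def chrom_sizes():
    return {"chr1": 100_000}


def make_sites(positions, chrom="chr1"):
    return [
        GenomicRegion(chrom, p, p + 1, ".", "cpg_site", f"s{i}")
        for i, p in enumerate(positions)
    ]


@pytest.fixture
def sites_factory():
    return make_sites
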