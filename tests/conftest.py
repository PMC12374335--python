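import numpy as np
import pandas as pd
import pytest

from methinherit.methylome import MethylomeSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sample(rows, sample_id="s", group="g"):
    """rows: (chrom, pos, strand, context, n_meth, n_total)."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )
    return MethylomeSample(sample_id, group, df)


@pytest.fixture
def tiny_report(tmp_path):
    path = tmp_path / "tiny.cx.tsv"
    path.write_text(
        "chr1\t10\t+\t9\t1\tCpG\tCGA\n"
        "chr1\t15\t-\t0\t0\tCHG\tCAG\n"
        "chr1\t20\t+\t2\t48\tCHH\tCTT\n"
    )
    return path
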