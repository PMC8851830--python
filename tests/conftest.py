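import numpy as np
import pandas as pd
import pytest

from snp3d.genomic import Bin, ElementIndex, Gene, GenomicInterval, RegulatoryElement, SNP


def make_element(
    eid,
    chrom="chr1",
    start=0,
    end=1000,
    kind="enhancer",
    da=1.0,
    flag=None,
    tf_name=None,
    targets=(),
):
    """Small-fixture element constructor with sensible defaults."""
    if kind == "tfbs" and tf_name is None:
        tf_name = "TFX"
    if flag is not None and da is None:
        pass
    return RegulatoryElement(
        id=eid,
        kind=kind,
        interval=GenomicInterval(chrom, start, end),
        da_score=da,
        disease_associated=flag,
        tf_name=tf_name,
        target_genes=tuple(targets),
    )


def contact_row(chrom1, bin1, chrom2, bin2, count, resolution=10_000, qvalue=None):
    half = resolution // 2
    row = {
        "chrom1": chrom1,
        "mid1": bin1 * resolution + half,
        "chrom2": chrom2,
        "mid2": bin2 * resolution + half,
        "count": count,
    }
    if qvalue is not None:
        row["qvalue"] = qvalue
    return row


def contact_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_genes():
    return {
        "MAP3K1": Gene("MAP3K1", 5.3),
        "GENE_A": Gene("GENE_A", 2.0),
        "GENE_B": Gene("GENE_B", 4.0),
    }
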