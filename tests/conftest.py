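import numpy as np
import pandas as pd
import pytest

from crossmeth.methylation import M_CONSTANT, MethMatrix


def make_matrix(beta, groups, coverage=None, meth=None, positions=None, chrom="chr1"):
    """Build a MethMatrix from a 2-D beta array (loci x samples)."""
    beta = np.asarray(beta, dtype=float)
    n_loci, n_samples = beta.shape
    samples = list(groups)
    if positions is None:
        positions = list(range(1, n_loci + 1))
    idx = pd.MultiIndex.from_arrays(
        [[chrom] * n_loci, list(positions)], names=["chrom", "pos"]
    )
    bdf = pd.DataFrame(beta, index=idx, columns=samples)
    mdf = np.log2((bdf + M_CONSTANT) / (1 - bdf + M_CONSTANT))
    cov = None if coverage is None else pd.DataFrame(coverage, index=idx, columns=samples)
    mth = None if meth is None else pd.DataFrame(meth, index=idx, columns=samples)
    return MethMatrix(beta=bdf, m=mdf, groups=pd.Series(groups), coverage=cov, meth=mth)


@pytest.fixture
def two_group_labels():
    return {"c1": "control", "c2": "control", "c3": "control",
            "t1": "tumour", "t2": "tumour", "t3": "tumour"}
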