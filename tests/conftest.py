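import numpy as np
import pytest

from episnp.genotype_io import GenotypeMatrix, SNPRecord


def make_gm(values, chroms=None, positions=None, sample_ids=None):
    """Build a GenotypeMatrix from an integer array with default metadata."""
    values = np.asarray(values, dtype=np.int8)
    n, p = values.shape
    chroms = chroms or ["1"] * p
    positions = positions or [1000 * (j + 1) for j in range(p)]
    snps = []
    for j in range(p):
        col = values[:, j]
        obs = col[col >= 0]
        maf = float(obs.sum()) / (2 * obs.size) if obs.size else 0.0
        snps.append(
            SNPRecord(
                snp_id=f"snp{j:05d}", chrom=chroms[j], pos_bp=positions[j],
                allele_a="A", allele_b="G", minor_allele="A",
                maf=min(maf, 1 - maf),
            )
        )
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(n)]
    return GenotypeMatrix(values, snps, sample_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_gm():
    # 4 samples x 3 SNPs, no missing
    return make_gm(
        [
            [0, 1, 2],
            [1, 0, 1],
            [2, 1, 0],
            [0, 0, 1],
        ]
    )
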