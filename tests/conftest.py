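import numpy as np
import pandas as pd
import pytest

from stackprs.io_formats import GenotypeMatrix, SummaryStats, VariantInfo


def toy_matrix(genotypes, chrom="1", pos_start=100, pos_step=1000, alleles=("A", "G")):
    """GenotypeMatrix from a plain nested list / array of dosages."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n, m = geno.shape
    variants = [
        VariantInfo(chrom=chrom, pos=pos_start + j * pos_step, vid=f"v{j}",
                    allele1=alleles[0], allele2=alleles[1])
        for j in range(m)
    ]
    return GenotypeMatrix(geno, variants, [f"s{i}" for i in range(n)])


def stats_for(g, p=None, beta=None, se=None):
    """SummaryStats aligned with a GenotypeMatrix's variants."""
    m = g.n_variants
    rng = np.random.default_rng(0)
    t = pd.DataFrame(
        {
            "vid": g.vids,
            "chrom": [v.chrom for v in g.variants],
            "pos": [v.pos for v in g.variants],
            "a1": [v.allele1 for v in g.variants],
            "a2": [v.allele2 for v in g.variants],
            "beta": beta if beta is not None else np.zeros(m),
            "se": se if se is not None else np.ones(m),
            "p": p if p is not None else rng.uniform(1e-6, 1, m),
            "freq": [max(np.mean(g.genotypes[:, j][g.genotypes[:, j] >= 0]) / 2, 0.0) for j in range(m)],
            "n": g.n_samples,
        }
    )
    return SummaryStats(table=t)


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)
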