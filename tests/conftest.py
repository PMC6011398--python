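import numpy as np
import pytest

from ddascan import GenotypeData, SnpGroup, SnpInfo


@pytest.fixture
def small_genotypes() -> GenotypeData:
    """Deterministic 6-sample x 4-SNP matrix with one missing call."""
    matrix = np.array(
        [
            [0, 1, 2, 0],
            [1, 0, 2, 1],
            [2, 1, 0, 0],
            [0, 0, 1, 2],
            [1, 2, 0, -1],
            [2, 2, 1, 0],
        ],
        dtype=np.int8,
    )
    snps = [
        SnpInfo(id=f"rs{i}", chrom="1", pos=1000 * (i + 1), alleles=("A", "G"))
        for i in range(4)
    ]
    return GenotypeData(matrix, snps, [f"s{i}" for i in range(6)])


@pytest.fixture
def null_dataset():
    """n=500, m=20 genotypes with labels independent of genotype."""
    from ddascan import SimSpec, simulate_genotypes

    G = simulate_genotypes(SimSpec(n_samples=500, n_snps=20, seed=11))
    rng = np.random.default_rng(7)
    labels = np.zeros(500, dtype=np.int8)
    labels[rng.choice(500, 250, replace=False)] = 1
    return G, labels


@pytest.fixture
def whole_group():
    def _make(n_snps: int, name: str = "grp") -> SnpGroup:
        return SnpGroup(name=name, source="custom", snp_indices=np.arange(n_snps))

    return _make
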