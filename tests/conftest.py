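import numpy as np
import pytest

from popscan.genotype_io import MISSING, GenotypeDataset


@pytest.fixture
def toy_dataset():
    """4 samples x 6 SNPs on two chromosomes, one missing call."""
    geno = np.array(
        [
            [0, 1, 2, 0, 1, 2],
            [1, 1, 0, 2, 0, 1],
            [2, 0, 1, 1, 2, 0],
            [0, 2, MISSING, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeDataset(
        sample_ids=["a1", "a2", "b1", "b2"],
        populations=["A", "A", "B", "B"],
        chrom=np.array(["1", "1", "1", "2", "2", "2"], dtype=object),
        pos=np.array([100, 2000, 50_000, 100, 5000, 900_000]),
        snp_ids=[f"s{i}" for i in range(6)],
        genotypes=geno,
    )


@pytest.fixture(scope="session")
def neutral_haplotypes():
    """Session-wide neutral Wright-Fisher haplotypes for LD / EHH checks."""
    from popscan.synthetic_data import simulate_haplotypes

    haps, truth = simulate_haplotypes(
        n_haps=100, L=600, chrom_length=6_000_000, Ne=300, generations=900, seed=11
    )
    return haps, truth


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Session-wide miniature study bundle (small sizes for test speed)."""
    from popscan.synthetic_data import BundleConfig, make_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    config = BundleConfig(
        n_samples_per_pop=25,
        n_snps=1200,
        n_chromosomes=3,
        chrom_length=8_000_000,
        ne=1000,
        generations=120,
        split_generations=150,
        sweep_chrom="1",
        sweep_position=4_000_000,
        sweep_final_freq=0.7,
        n_genes=30,
    )
    paths = make_fixture_bundle(config, seed=7, out_dir=out / "bundle")
    return paths, config
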