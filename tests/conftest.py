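import numpy as np
import pytest

import sdrmap as sm


@pytest.fixture(scope="session")
def chrom():
    """18 Mb chromosome, terminal 5.5 Mb SDR, uniform 14 cM/Mb PAR."""
    return sm.ChromosomeModel.uniform_par(14.0)


@pytest.fixture(scope="session")
def family(chrom):
    """Error-free 87-progeny family with SNP and SSR panels."""
    rng = np.random.default_rng(20_200)
    mother, father = sm.make_testcross_parents(chrom, n_snps=120, rng=rng)
    sm.attach_ssr_panel(mother, father, chrom, rng=rng)
    return sm.simulate_family(mother, father, chrom, n_progeny=87, rng=rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def parent_matrix(mother, father):
    from sdrmap.containers import GenotypeMatrix

    return GenotypeMatrix(
        samples=["mother", "father"],
        positions=mother.snp_positions,
        genotypes=np.vstack([mother.snp_dosage, father.snp_dosage]),
    )
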