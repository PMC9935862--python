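import numpy as np
import pandas as pd
import pytest

from pqtl import simulate as sim


@pytest.fixture(scope="session")
def small_genotypes():
    """600 samples x 80 SNPs in 10 LD blocks (r_adj = 0.4)."""
    return sim.simulate_genotypes(
        600, 80, ld_block_sizes=[8] * 10, r_adj=0.4, seed=11, maf_range=(0.1, 0.5)
    )


@pytest.fixture(scope="session")
def cohort_with_cis(small_genotypes):
    """Proteome runs for one strong cis protein plus pure-noise features."""
    tss_pos = int(small_genotypes.variants["pos"].iloc[20])
    prots = [
        sim.ProteinArchitecture(
            "P1", cis_variant="snp20", beta_cis=0.6, tss_chrom="1", tss_pos=tss_pos
        )
    ] + [sim.ProteinArchitecture(f"N{i}") for i in range(9)]
    truth = sim.ArchitectureTruth(proteins=prots)
    runs, rep_map, sub = sim.simulate_proteome(
        small_genotypes, truth, n_subcohorts=4, replicate_fraction=0.3, seed=5
    )
    tss = pd.DataFrame(
        {"feature": [p.name for p in prots], "chrom": "1",
         "tss": [tss_pos] + [500_000] * 9}
    )
    return runs, rep_map, sub, tss, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
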