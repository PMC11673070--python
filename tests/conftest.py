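import numpy as np
import pandas as pd
import pytest

import lipidprs as lp


@pytest.fixture(scope="session")
def block_genotypes() -> lp.GenotypeMatrix:
    """Medium cohort with moderate block LD, shared across read-only tests."""
    spec = lp.LDBlockSpec(n_blocks=50, variants_per_block=5, within_block_r=0.5)
    return lp.simulate_genotypes(800, spec, seed=11)


@pytest.fixture(scope="session")
def tiny_genotypes() -> lp.GenotypeMatrix:
    """10 samples x 5 variants with one missing call, for IO round trips."""
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2", "2"],
            "pos": [101, 202, 303, 104, 205],
            "id": [f"v{i}" for i in range(5)],
            "ref": ["A", "C", "G", "T", "A"],
            "alt": ["G", "T", "A", "C", "C"],
        }
    )
    rng = np.random.default_rng(3)
    dosages = rng.integers(0, 3, size=(10, 5)).astype(float)
    dosages[0, 1] = np.nan
    samples = [f"P{i}" for i in range(10)]
    return lp.GenotypeMatrix(samples, variants, dosages)


def make_sumstats(genotypes: lp.GenotypeMatrix, beta, se=0.01, pval=None, eaf=None, n=100_000):
    """Summary-statistic table aligned to a genotype panel (effect allele = alt)."""
    beta = np.asarray(beta, dtype=float)
    var = genotypes.variants
    table = pd.DataFrame(
        {
            "chrom": var["chrom"],
            "pos": var["pos"],
            "effect_allele": var["alt"],
            "other_allele": var["ref"],
            "beta": beta,
            "se": se,
            "pval": pval if pval is not None else 1.0,
            "eaf": eaf if eaf is not None else np.clip(genotypes.allele_freq(), 0.01, 0.99),
            "n": n,
        }
    )
    return lp.SummaryStats(table)
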