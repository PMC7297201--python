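import numpy as np
import pandas as pd
import pytest

from chronoprs import (
    GenotypeMatrix,
    scaled_down_config,
    score_genotypes,
    simulate_cohort,
    simulate_summary_stats,
)


def make_sumstats(
    betas,
    pvals,
    eafs=None,
    effect_alleles=None,
    other_alleles=None,
    true_effects=None,
) -> pd.DataFrame:
    m = len(betas)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(m)],
            "effect_allele": effect_alleles if effect_alleles is not None else ["A"] * m,
            "other_allele": other_alleles if other_alleles is not None else ["G"] * m,
            "beta": np.asarray(betas, dtype=float),
            "p": np.asarray(pvals, dtype=float),
            "eaf": np.asarray(eafs, dtype=float) if eafs is not None else np.full(m, 0.3),
            "true_effect": np.asarray(true_effects, dtype=float)
            if true_effects is not None
            else np.zeros(m),
        }
    )


def make_genotypes(dosage, counted=None, other=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "counted_allele": counted if counted is not None else ["A"] * m,
            "other_allele": other if other is not None else ["G"] * m,
        }
    )
    ids = np.array([f"i{k}" for k in range(n)])
    return GenotypeMatrix(individual_ids=ids, variants=variants, dosage=dosage)


@pytest.fixture(scope="session")
def scaled_cohort():
    """One scaled-down simulated cohort shared across tests."""
    cfg = scaled_down_config(seed=42)
    sumstats = simulate_summary_stats(cfg)
    genotypes, pheno, covars = simulate_cohort(cfg, sumstats)
    grps = score_genotypes(genotypes, sumstats, pt=0.05)
    return {
        "config": cfg,
        "sumstats": sumstats,
        "genotypes": genotypes,
        "pheno": pheno,
        "covars": covars,
        "grps": grps,
    }
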