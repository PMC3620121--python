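import numpy as np
import pytest

import stonegene as sg


@pytest.fixture(scope="session")
def study_cohort():
    """Pseudo-cohort reconstructed from the built-in printed count tables."""
    return sg.study.pseudo_cohort()


@pytest.fixture(scope="session")
def synthetic_study_cohort():
    """Retrospective synthetic cohort emulating the study design."""
    return sg.simulate_cohort(sg.study.cohort_spec(seed=11))


@pytest.fixture
def two_snp_manifest():
    return [
        sg.SnpDef("snpA", "GENE1", "other", "C", "T"),
        sg.SnpDef("snpB", "GENE2", "other", "A", "G"),
    ]


def make_cohort(genotypes, status, snps=None, covariates=None):
    """Small-cohort helper for hand-built fixtures."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if snps is None:
        snps = [sg.SnpDef(f"s{j + 1}", "G", "other", "A", "B")
                for j in range(genotypes.shape[1])]
    ids = [f"i{k}" for k in range(genotypes.shape[0])]
    return sg.Cohort(ids=ids, snps=snps, genotypes=genotypes,
                     status=np.asarray(status, dtype=np.int8),
                     covariates=covariates)
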