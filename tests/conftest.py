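import numpy as np
import pandas as pd
import pytest

from hornpred import GenotypeMatrix, Pedigree, SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared across tests (~1000 offspring)."""
    return simulate_study(SimConfig(seed=11, n_sires=40))


@pytest.fixture(scope="session")
def small_bundle(small_study):
    """Aligned arrays for the phenotyped animals of the small study."""
    study = small_study
    ids = list(study.study_animals)
    geno = study.genotypes.subset(animals=ids)
    sex = study.pedigree.sex_of(ids)
    return {
        "study": study,
        "ids": ids,
        "geno": geno,
        "sex": sex,
        "pnp": study.phenotypes.trait("pnp"),
        "hnh": study.phenotypes.trait("hnh"),
        "causal": study.causal_genotype(),
    }


@pytest.fixture()
def tiny_geno():
    """5 animals x 3 phased markers, handmade."""
    hap1 = np.array([[0, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 0], [0, 1, 1]], dtype=np.int8)
    hap2 = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1], [0, 0, 0], [0, 1, 0]], dtype=np.int8)
    return GenotypeMatrix(
        animal_ids=np.array([f"a{i}" for i in range(5)], dtype=object),
        marker_ids=np.array(["m1", "m2", "m3"], dtype=object),
        chrom=np.array(["1", "1", "1"], dtype=object),
        pos_bp=np.array([100, 200, 300]),
        alleles=np.array([("A", "T")] * 3, dtype=object),
        dosage=(hap1 + hap2).astype(np.int16),
        phased=True,
        hap1=hap1,
        hap2=hap2,
    )


@pytest.fixture()
def trio_pedigree():
    return Pedigree(
        pd.DataFrame(
            {
                "animal": ["s1", "d1", "o1"],
                "sire": [None, None, "s1"],
                "dam": [None, None, "d1"],
                "sex": ["wether", "female", "female"],
            }
        )
    )
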