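import numpy as np
import pandas as pd
import pytest

import driftgarden as dg


@pytest.fixture()
def toy_genotype_csv(tmp_path):
    """3 individuals x 2 loci, one missing call."""
    path = tmp_path / "geno.csv"
    path.write_text(
        "individual_id,population,snp1,snp2\n"
        "i1,popA,0,1\n"
        "i2,popA,2,NA\n"
        "i3,popB,1,1\n"
    )
    return path


@pytest.fixture(scope="session")
def small_truth():
    """8 populations, moderate drift, the recovery-test variance components."""
    return dg.star_scenario(8, 0.05, seed=42, sigma2_A=0.4, sigma2_E=0.6)


@pytest.fixture(scope="session")
def small_family_data(small_truth):
    ped = dg.simulate_pedigree(small_truth, mothers_per_pop=15, offspring_per_mother=10)
    pheno = dg.simulate_phenotypes(small_truth, ped)
    return ped, pheno


@pytest.fixture()
def tiny_pedigree():
    """One mother with two offspring, one unrelated founder."""
    return dg.Pedigree(pd.DataFrame([
        {"individual_id": "m1", "mother_id": None, "population": "A", "generation": "founder"},
        {"individual_id": "f2", "mother_id": None, "population": "A", "generation": "founder"},
        {"individual_id": "o1", "mother_id": "m1", "population": "A", "generation": "offspring"},
        {"individual_id": "o2", "mother_id": "m1", "population": "A", "generation": "offspring"},
    ]))
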