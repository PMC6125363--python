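import numpy as np
import pandas as pd
import pytest

import prognosig as pg
from prognosig import srm

#: the three peptides carrying the planted N+ downshift in fixtures
PLANTED_TRIO = ("Pep12_CSTB", "Pep8_LTA4H", "Pep9_COL6A1")
_PLANTED_IDX = (7, 8, 11)  # positions of the trio in the canonical peptide list


def planted_effects(shift: float = -1.0) -> list[float]:
    eff = [0.0] * 14
    for i in _PLANTED_IDX:
        eff[i] = shift
    return eff


def feature_table_from(cohort) -> tuple[pd.DataFrame, np.ndarray]:
    """Patients x peptides L/H table + group labels from an SRM cohort."""
    rt = srm.compute_ratio_table(cohort.records)
    X = rt.pivot_table(index="patient", columns="peptide", values="lh_ratio")
    y = (
        rt.drop_duplicates("patient")
        .set_index("patient")["group"]
        .reindex(X.index)
        .to_numpy()
    )
    return X, y


@pytest.fixture(scope="session")
def tissue_cohort():
    return pg.gen_tissue_cohort(
        pg.TissueSimConfig(n_patients=20, n_proteins=100, seed=1)
    )


@pytest.fixture(scope="session")
def srm_cohort_planted():
    return pg.gen_srm_cohort(
        pg.SrmSimConfig(seed=11, group_effect_log2=planted_effects(), noise_cv=0.3)
    )


@pytest.fixture(scope="session")
def planted_features(srm_cohort_planted):
    return feature_table_from(srm_cohort_planted)


@pytest.fixture(scope="session")
def ihc_cohort():
    return pg.gen_ihc_cohort(pg.IHCSimConfig(n_cases=60, raters=3, seed=3))


@pytest.fixture()
def small_quant_matrix():
    """4 proteins x (3 ITF + 3 inner) complete matrix, patients matched."""
    rng = np.random.default_rng(0)
    cols = ["P1:ITF", "P2:ITF", "P3:ITF", "P1:inner", "P2:inner", "P3:inner"]
    values = pd.DataFrame(
        rng.normal(25, 1, (4, 6)), index=[f"prot{i}" for i in range(4)], columns=cols
    )
    samples = pd.DataFrame(
        {
            "patient": ["P1", "P2", "P3"] * 2,
            "region": ["ITF"] * 3 + ["inner"] * 3,
        },
        index=cols,
    )
    return pg.QuantMatrix(values=values, samples=samples)
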