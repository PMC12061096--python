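import numpy as np
import pandas as pd
import pytest

import glycopipe as gp


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down simulation config for fast end-to-end tests."""
    return gp.SimulationConfig(n_features=300, n_proteins=60)


@pytest.fixture(scope="session")
def cohort(small_cfg):
    return gp.simulate_cohort(small_cfg, seed=11)


@pytest.fixture(scope="session")
def sim_matrix(small_cfg, cohort):
    m, truth = gp.simulate_intensity_matrix(cohort, small_cfg, seed=11)
    return m, truth


@pytest.fixture(scope="session")
def glycan_db():
    return gp.builtin_glycan_database()


@pytest.fixture()
def toy_matrix():
    """4 features x 4 samples with a known missing pattern."""
    samples = ["a_T1", "b_T1", "c_T1", "d_T1"]
    vals = pd.DataFrame(
        [
            [20.0, 21.0, 19.0, 20.0],
            [18.0, np.nan, 18.5, 19.0],
            [np.nan, np.nan, 22.0, 21.0],
            [25.0, 24.0, np.nan, np.nan],
        ],
        index=["f1", "f2", "f3", "f4"],
        columns=samples,
    )
    obs = vals.notna()
    feats = pd.DataFrame(
        {
            "protein_accession": ["P1", "P1", "P2", "P3"],
            "site_1based": [10, 20, 5, 7],
            "residue": ["K", "N", "N", "K"],
            "mod_class": ["glycation", "glycosylation", "glycosylation", "glycation"],
            "glycan": ["Hex(1)", "HexNAc(2)Hex(5)", "HexNAc(2)Hex(6)", "Hex(1)"],
            "peptide": [""] * 4,
        },
        index=vals.index,
    )
    return gp.IntensityMatrix(values=vals, observed=obs, features=feats)


@pytest.fixture()
def toy_meta():
    rows = []
    for i, (subj, grp) in enumerate(
        [("a", "decliner"), ("b", "decliner"), ("c", "non-decliner"), ("d", "non-decliner")]
    ):
        rows.append(
            {
                "sample_id": f"{subj}_T1",
                "subject_id": subj,
                "group": grp,
                "timepoint": "T1",
                "baseline_age": 70 + i,
                "mean_hba1c": 6.0 + 0.1 * i,
            }
        )
    return pd.DataFrame(rows)
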