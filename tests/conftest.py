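from datetime import date

import numpy as np
import pandas as pd
import pytest

from disnet.cohort import ExposureMatrix, WindowConfig
from disnet.simulate import (DiseaseSpec, PopulationSpec, ProgressionSpec,
                             generate_cohort)


@pytest.fixture(scope="session")
def windows():
    return WindowConfig()


@pytest.fixture(scope="session")
def flat_pop():
    """10k patients, balanced sexes, default age mix."""
    return PopulationSpec(n_patients=10_000)


@pytest.fixture(scope="session")
def two_disease_cohort(windows):
    """A00 (prev 0.3) -> A01 (prev 0.05) with planted RR 5."""
    pop = PopulationSpec(n_patients=20_000)
    diseases = [DiseaseSpec("A00", 0.3), DiseaseSpec("A01", 0.05)]
    progressions = [ProgressionSpec("A00", "A01", 5.0)]
    return generate_cohort(pop, diseases, progressions, windows, seed=11)


def make_exposure(label, patients, codes, rows):
    """Exposure matrix from a list of per-patient boolean tuples."""
    return ExposureMatrix(label, np.asarray(patients), list(codes),
                          np.asarray(rows, dtype=bool))


@pytest.fixture
def micro_pair():
    """8-patient worked example: 2 exposed acquiring the target, 2 exposed
    not acquiring it, 1 unexposed acquiring it, 3 neither; nobody has the
    target in the observation window."""
    patients = list(range(1, 9))
    codes = ["D01", "D02"]
    obs_rows = [(1, 0)] * 4 + [(0, 0)] * 4
    out_rows = [(0, 1), (0, 1), (0, 0), (0, 0), (0, 1), (0, 0), (0, 0),
                (0, 0)]
    obs = make_exposure("observation", patients, codes, obs_rows)
    out = make_exposure("outcome", patients, codes, out_rows)
    return obs, out


def claims_frame(rows):
    """rows: (patient_id, code, iso_date) triples."""
    return pd.DataFrame(
        {"patient_id": [r[0] for r in rows],
         "code": [r[1] for r in rows],
         "date": pd.to_datetime([r[2] for r in rows])}
    )


@pytest.fixture
def demographics_frame():
    def make(patients, sexes=None, birth_years=None):
        n = len(patients)
        return pd.DataFrame({
            "patient_id": patients,
            "sex": sexes if sexes is not None else ["F"] * n,
            "birth_year": birth_years if birth_years is not None
            else [1970] * n,
        })
    return make
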