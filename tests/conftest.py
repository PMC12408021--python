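import pandas as pd
import pytest

from gutstrain import (CohortTable, FeatureTable, PlantedClade,
                       SimulationConfig, generate_abundances, generate_cohort,
                       generate_strain_data)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_infants=40, case_fraction=0.5, seed=7,
                            n_clade_genomes=20,
                            planted_clade=PlantedClade(clade_size=8),
                            sequencing_depth=20_000)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_tables(small_cohort, small_config):
    return generate_abundances(small_cohort, small_config)


@pytest.fixture(scope="session")
def small_strain(small_cohort, small_config):
    return generate_strain_data(small_cohort, small_config, with_sequences=False)


def make_cohort(infant_rows, sample_rows):
    """Construct a CohortTable from terse tuples.

    infant_rows: (infant_id, group) or full dicts;
    sample_rows: (sample_id, infant_id, age, state).
    """
    infants = []
    for row in infant_rows:
        if isinstance(row, dict):
            d = {"sex": "female", "delivery_mode": "vaginal",
                 "initial_feeding": "exclusive", "probiotic_first_year": False}
            d.update(row)
        else:
            iid, group = row
            d = {"infant_id": iid, "group": group, "sex": "female",
                 "delivery_mode": "vaginal", "initial_feeding": "exclusive",
                 "probiotic_first_year": False}
        infants.append(d)
    samples = [{"sample_id": s, "infant_id": i, "age_months": a,
                "symptom_state": st} for s, i, a, st in sample_rows]
    return CohortTable(pd.DataFrame(infants),
                       pd.DataFrame(samples, columns=["sample_id", "infant_id",
                                                      "age_months",
                                                      "symptom_state"]))


def make_table(values: dict, kind="relative", **kw) -> FeatureTable:
    """values: feature -> list of per-sample abundances."""
    df = pd.DataFrame(values).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return FeatureTable(df, kind=kind, **kw)
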