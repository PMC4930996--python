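import numpy as np
import pandas as pd
import pytest

from isoniche.types import Dataset


def make_dataset(samples_rows, traits_rows=None, env_rows=None, study_years=None):
    samples = pd.DataFrame(
        samples_rows, columns=["individual_id", "year", "tissue", "d15N", "d13C"]
    )
    if traits_rows is None:
        traits = pd.DataFrame(
            columns=[
                "individual_id", "year", "body_mass", "clutch_initiation_date",
                "a_egg_mass", "b_egg_mass", "total_clutch_mass",
            ]
        )
    else:
        traits = pd.DataFrame(
            traits_rows,
            columns=[
                "individual_id", "year", "body_mass", "clutch_initiation_date",
                "a_egg_mass", "b_egg_mass",
            ],
        )
        traits["total_clutch_mass"] = traits["a_egg_mass"] + traits["b_egg_mass"]
    env = pd.DataFrame(env_rows or [], columns=["index_name", "year", "month", "value"])
    years = study_years or sorted(set(samples["year"])) or [2006]
    return Dataset(samples=samples, traits=traits, env=env, study_years=list(years))


@pytest.fixture
def two_bird_ds():
    """Bird A sampled twice (10, 12), bird B three times (11, 13, 15)."""
    rows = [
        ("A", 2006, "red_blood_cell", 10.0, -21.0),
        ("A", 2007, "red_blood_cell", 12.0, -21.5),
        ("B", 2006, "red_blood_cell", 11.0, -20.0),
        ("B", 2007, "red_blood_cell", 13.0, -22.0),
        ("B", 2008, "red_blood_cell", 15.0, -21.0),
    ]
    return make_dataset(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
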