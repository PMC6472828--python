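import pandas as pd
import pytest
from hypothesis import settings

import isoniche as iso

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def scenario():
    return iso.load_scenario()


@pytest.fixture(scope="session")
def survey_tables(scenario):
    """One seeded simulation of the packaged survey community."""
    return scenario.simulate(seed=20150501)


@pytest.fixture(scope="session")
def isotopes_with_classes(survey_tables):
    return iso.assign_size_class(survey_tables["isotopes"])


@pytest.fixture()
def three_stomachs():
    """Three non-empty stomachs: prey X in one (count 2, mass 4 g), prey Y
    in all three (total count 6, mass 4 g)."""
    rows = [
        ("s1", "cod", "R", 50.0, "X", 2, 4.0),
        ("s1", "cod", "R", 50.0, "Y", 2, 2.0),
        ("s2", "cod", "R", 55.0, "Y", 2, 1.0),
        ("s3", "cod", "R", 60.0, "Y", 2, 1.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["stomach_id", "predator_species", "region",
                 "predator_length_cm", "prey_taxon", "prey_count",
                 "prey_mass_g"],
    )
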