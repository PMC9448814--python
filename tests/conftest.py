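import numpy as np
import pandas as pd
import pytest

from famclust import IncidenceReference, SimulationConfig
from famclust.simulate import _demo_sites


@pytest.fixture
def two_site_config():
    """Tiny deterministic configuration: two sites, fixed family size."""
    return SimulationConfig(
        n_families=40,
        family_size={"kind": "fixed", "size": 6},
        sites={
            "stomach": {"male": 0.0005, "female": 0.0004},
            "thyroid": {"male": 0.0001, "female": 0.0003},
        },
        high_risk_fraction=0.0,
        theta_low=1.0,
        theta_high=5.0,
        seed=42,
    )


@pytest.fixture
def demo_config():
    return SimulationConfig(n_families=150, sites=_demo_sites(), seed=7)


@pytest.fixture
def flat_reference():
    """Constant-hazard reference: cum incidence = 0.001 * age for all keys."""
    ages = np.arange(81)
    rows = []
    for site in ("stomach",):
        for sex in ("male", "female"):
            for cohort in range(1870, 2011, 10):
                rows.append(
                    pd.DataFrame(
                        {
                            "site": site,
                            "sex": sex,
                            "birth_cohort": cohort,
                            "attained_age": ages,
                            "cum_incidence": 0.001 * ages,
                        }
                    )
                )
    return IncidenceReference(pd.concat(rows, ignore_index=True))


def make_persons(rows):
    """rows: list of (person_id, sex, birth_year, municipality, surname)."""
    return pd.DataFrame(
        rows, columns=["person_id", "sex", "birth_year", "municipality", "surname"]
    )


def make_events(rows):
    """rows: list of (person_id, site, age_at_diagnosis, diagnosis_year)."""
    return pd.DataFrame(
        rows, columns=["person_id", "site", "age_at_diagnosis", "diagnosis_year"]
    )
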