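"""Reference cumulative-incidence tables.

The expected count machinery needs, for every (site, sex, birth cohort),
the cumulative expected number of first primary cancers per person from
birth up to each attained age.  This module holds that table and its
lookups; it is deliberately agnostic about where the numbers came from
(a national registry export or the synthetic generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_AGE = 80  # diagnoses at or above this age are outside the study design

REFERENCE_COLUMNS = ["site", "sex", "birth_cohort", "attained_age", "cum_incidence"]


def cohort_of(birth_year, width: int = 10):
    """Map birth year(s) to the start year of their birth-cohort bin."""
    return (np.asarray(birth_year) // width) * width


@dataclass
class IncidenceReference:
    """Cumulative expected first-primary counts per person.

    ``table`` is long-format with columns site, sex, birth_cohort,
    attained_age (0..MAX_AGE) and cum_incidence (dimensionless expected
    count per person from birth to that age).  Curves must be
    nonnegative and nondecreasing in attained age.
    """

    table: pd.DataFrame
    cohort_width: int = 10
    _curves: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = set(REFERENCE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        if (self.table["cum_incidence"] < 0).any():
            raise ValueError("cumulative incidence must be nonnegative")
        self._curves = {}
        for key, grp in self.table.groupby(["site", "sex", "birth_cohort"], sort=True):
            grp = grp.sort_values("attained_age")
            ages = grp["attained_age"].to_numpy()
            vals = grp["cum_incidence"].to_numpy(dtype=float)
            if np.any(np.diff(vals) < -1e-12):
                raise ValueError(f"cumulative incidence not nondecreasing for {key}")
            curve = np.zeros(MAX_AGE + 1)
            curve[ages] = vals
            self._curves[key] = curve

    # -- lookups ---------------------------------------------------------

    def curve(self, site: str, sex: str, birth_year: int) -> np.ndarray:
        """Cumulative curve (length MAX_AGE+1, indexed by attained age)."""
        cohort = int(cohort_of(birth_year, self.cohort_width))
        key = (site, sex, cohort)
        if key not in self._curves:
            raise KeyError(
                f"no reference entry for site={site!r} sex={sex!r} birth_cohort={cohort}"
            )
        return self._curves[key]

    def cumulative(self, site: str, sex: str, birth_year: int, attained_age: int) -> float:
        """Cumulative expected count from birth to ``attained_age`` (capped)."""
        if attained_age < 0:
            return 0.0
        age = min(int(attained_age), MAX_AGE)
        return float(self.curve(site, sex, birth_year)[age])

    def sites(self) -> list:
        return sorted(self.table["site"].unique())

    # -- round-trip ------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.table[REFERENCE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, cohort_width: int = 10) -> "IncidenceReference":
        return cls(pd.read_csv(path, sep="\t"), cohort_width=cohort_width)
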