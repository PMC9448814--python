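"""Standardised cumulative incidence ratios (SCIR).

The expected count E for an MNS group and site is the sum, over members, of
the reference cumulative incidence from birth to the member's attained age
at the end of follow-up, capped at 80.  Because registry-style data lack
death and emigration dates, no person-years are available: every member is
treated as followed to that attained age, so SCIR = O/E is a cumulative
analogue of the standardised incidence ratio rather than a true SIR.

Conventions: attained age is completed years at the end of the follow-up
year (floor); E accumulates from birth (age 0).  Members born after the end
of follow-up contribute zero with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import MNS_KEY, MnsTabulation
from .incidence import MAX_AGE, IncidenceReference, cohort_of

logger = logging.getLogger(__name__)

SCIR_COLUMNS = MNS_KEY + ["site", "observed", "expected", "scir", "excluded"]


def attained_age(birth_year, follow_up_end: int) -> np.ndarray:
    """Completed years at end of follow-up, capped at MAX_AGE; may be negative."""
    return np.minimum(MAX_AGE, follow_up_end - np.asarray(birth_year))


def compute_expected(
    members: pd.DataFrame,
    reference: IncidenceReference,
    site: str,
    follow_up_end: int,
) -> float:
    """Expected count E for one group: per-member reference lookups, summed."""
    total = 0.0
    for _, row in members.iterrows():
        age = int(attained_age(row["birth_year"], follow_up_end))
        if age < 0:
            logger.warning(
                "person %s born after end of follow-up; contributes 0", row["person_id"]
            )
            continue
        total += reference.cumulative(site, row["sex"], int(row["birth_year"]), age)
    return total


def expected_table(
    tabulation: MnsTabulation,
    reference: IncidenceReference,
    follow_up_end: int,
    sites: list | None = None,
) -> pd.DataFrame:
    """Vectorised E for every retained MNS group and site.

    Equivalent to calling :func:`compute_expected` per group but computed in
    one pass: persons are bucketed by (sex, birth cohort), each bucket's
    cumulative values are read off the reference curve at the members'
    attained ages, and contributions are summed within groups.
    """
    sites = list(sites) if sites is not None else reference.sites()
    ppl = tabulation.persons.copy()
    ppl["attained"] = attained_age(ppl["birth_year"], follow_up_end)
    if (ppl["attained"] < 0).any():
        n = int((ppl["attained"] < 0).sum())
        logger.warning("%d persons born after end of follow-up contribute 0", n)
    ppl["cohort"] = cohort_of(ppl["birth_year"], reference.cohort_width)

    frames = []
    for site in sites:
        contrib = np.zeros(len(ppl))
        for (sex, cohort), idx in ppl.groupby(["sex", "cohort"], sort=True).groups.items():
            curve = reference.curve(site, sex, int(cohort))
            ages = ppl.loc[idx, "attained"].to_numpy()
            vals = np.where(ages >= 0, curve[np.clip(ages, 0, MAX_AGE)], 0.0)
            contrib[ppl.index.get_indexer(idx)] = vals
        e = (
            ppl.assign(expected=contrib)
            .groupby(MNS_KEY, sort=True)["expected"]
            .sum()
            .reset_index()
        )
        e.insert(len(MNS_KEY), "site", site)
        frames.append(e)
    return pd.concat(frames, ignore_index=True)


def compute_scir(observed: float, expected: float) -> float:
    """SCIR = O/E.  E must be strictly positive."""
    if expected <= 0:
        raise ValueError(f"expected count must be > 0, got {expected}")
    return observed / expected


def scir_table(
    counts: pd.DataFrame,
    expected: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (MNS group, site): O, E, SCIR and the exclusion flag.

    Groups with no observed cancer of a site (O = 0) get ``excluded=True``:
    they are kept for audit but left out of the mixture model, matching the
    design in which only combinations with observations are modelled.
    Rows with nonpositive E are dropped with a warning (degenerate
    reference; SCIR undefined).
    """
    merged = expected.merge(counts, on=MNS_KEY + ["site"], how="left")
    merged["observed"] = merged["observed"].fillna(0).astype(int)
    bad = merged["expected"] <= 0
    if bad.any():
        logger.warning("dropping %d group-site rows with E <= 0", int(bad.sum()))
        merged = merged.loc[~bad]
    merged["scir"] = merged["observed"] / merged["expected"]
    merged["excluded"] = merged["observed"] == 0
    return merged[SCIR_COLUMNS].reset_index(drop=True)
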