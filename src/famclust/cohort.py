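"""Cohort eligibility filters and family (MNS) tabulation.

An MNS combination — birth municipality + surname at birth + sex — is the
unit of inferred familiality.  This module applies the eligibility rules
(birth-year window, age-at-onset cap below 80, first primary per site per
person, minimum family size of two), partitions persons into MNS groups,
attaches observed counts, and produces the per-site/per-sex cohort summary
table (cancers, combinations with cancer, average cases per combination,
percent split by sex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .incidence import MAX_AGE

logger = logging.getLogger(__name__)

MNS_KEY = ["municipality", "surname", "sex"]
MN_KEY = ["municipality", "surname"]


@dataclass
class MnsTabulation:
    """Result of partitioning persons into MNS groups.

    ``persons`` holds only retained members (complete sex, group size >= 2);
    ``groups`` has one row per retained MNS group with its size.
    """

    persons: pd.DataFrame
    groups: pd.DataFrame
    n_missing_sex: int
    n_dropped_small_groups: int

    @property
    def exclusions(self) -> dict:
        return {
            "missing_sex": self.n_missing_sex,
            "small_groups": self.n_dropped_small_groups,
        }


def tabulate_mns(persons: pd.DataFrame, min_size: int = 2) -> MnsTabulation:
    """Partition persons by (municipality, surname, sex).

    Persons without sex are excluded with a warning; groups smaller than
    ``min_size`` are dropped and counted.  Retained group sizes always sum
    to the retained person count (a strict partition).
    """
    missing = persons["sex"].isna() | ~persons["sex"].isin(["male", "female"])
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning("excluded %d persons without sex information", n_missing)
    kept = persons.loc[~missing].copy()

    sizes = kept.groupby(MNS_KEY, sort=True).size().rename("group_size").reset_index()
    small = sizes.loc[sizes["group_size"] < min_size]
    n_small = int(small["group_size"].count())
    if n_small:
        logger.info("dropped %d MNS groups below minimum size %d", n_small, min_size)
    groups = sizes.loc[sizes["group_size"] >= min_size].reset_index(drop=True)
    retained = kept.merge(groups[MNS_KEY], on=MNS_KEY, how="inner")
    return MnsTabulation(
        persons=retained.reset_index(drop=True),
        groups=groups,
        n_missing_sex=n_missing,
        n_dropped_small_groups=n_small,
    )


def filter_events(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    birth_year_range: tuple = (1870, 2010),
    age_cap: int = MAX_AGE,
) -> pd.DataFrame:
    """Apply event eligibility rules.

    Drops events of persons born outside ``birth_year_range``, events with
    age at diagnosis at or above ``age_cap`` ("below 80"), and collapses
    multiple same-site events of one person to the earliest.  Events whose
    person_id is absent from ``persons`` are an error (corrupt linkage).
    """
    orphan = ~events["person_id"].isin(persons["person_id"])
    if orphan.any():
        ids = sorted(events.loc[orphan, "person_id"].unique())
        raise ValueError(f"events reference unknown person ids: {ids[:10]}")

    merged = events.merge(
        persons[["person_id", "birth_year"]], on="person_id", validate="m:1"
    )
    lo, hi = birth_year_range
    ok = merged["birth_year"].between(lo, hi) & (merged["age_at_diagnosis"] < age_cap)
    kept = merged.loc[ok].drop(columns="birth_year")
    kept = (
        kept.sort_values(["person_id", "site", "age_at_diagnosis"], kind="stable")
        .drop_duplicates(["person_id", "site"], keep="first")
        .reset_index(drop=True)
    )
    return kept


def observed_counts(tabulation: MnsTabulation, events: pd.DataFrame) -> pd.DataFrame:
    """Per-(MNS group, site) observed counts O.

    Events of persons not in a retained group are ignored (their family was
    too small or lacked sex information).  One row per group-site pair with
    at least one event.
    """
    joined = events.merge(
        tabulation.persons[["person_id"] + MNS_KEY], on="person_id", how="inner"
    )
    counts = (
        joined.groupby(MNS_KEY + ["site"], sort=True)
        .size()
        .rename("observed")
        .reset_index()
    )
    return counts


def average_cases_per_mns(cancers: int, n_mns: int) -> float:
    """Average cancers per affected MNS combination, 3 decimals, half-up."""
    if n_mns <= 0:
        raise ValueError("need at least one MNS combination")
    ratio = Decimal(cancers) / Decimal(n_mns)
    return float(ratio.quantize(Decimal("0.001"), ROUND_HALF_UP))


def summarise_cohort(counts: pd.DataFrame) -> pd.DataFrame:
    """Per site-and-sex cohort summary.

    For each site and sex: total cancers, number of MNS combinations with at
    least one cancer of that site, average cases per such combination
    (3 decimals, half-up), and the integer percent split of that site's
    cancers by sex.  Sites with zero cancers are omitted.
    """
    if counts.empty:
        return pd.DataFrame(
            columns=["site", "sex", "cancers", "n_mns", "avg_cases_per_mns", "pct_of_site"]
        )
    per = (
        counts.groupby(["site", "sex"], sort=True)
        .agg(cancers=("observed", "sum"), n_mns=("observed", "size"))
        .reset_index()
    )
    per = per.loc[per["cancers"] > 0].copy()
    per["avg_cases_per_mns"] = [
        average_cases_per_mns(int(c), int(n)) for c, n in zip(per["cancers"], per["n_mns"])
    ]
    site_tot = per.groupby("site")["cancers"].transform("sum")
    per["pct_of_site"] = np.rint(100.0 * per["cancers"] / site_tot).astype(int)
    return per.reset_index(drop=True)
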