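"""Synthetic registry generator.

Produces a registry-like cohort with the statistical structure the
downstream analysis assumes: many small inferred families sharing a birth
municipality and surname (median size 12, minimum 2), site- and
sex-specific background incidence, and a latent minority of families whose
cancer risk is multiplied by a high relative-risk coefficient.  Ground
truth (which families are high-risk) is returned so that the mixture model
can be validated by parameter recovery.

Event generation is per-person Bernoulli with probability
``min(1, theta * dLambda)`` per one-year age step, where ``dLambda`` is the
reference cumulative-incidence increment.  At most one event of a given
site is generated per person.  When the per-step increments are small this
makes family counts approximately Poisson(E * theta), which is the
likelihood the mixture model assumes; the approximation error is of order
``(theta * dLambda)**2`` per step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .incidence import MAX_AGE, IncidenceReference, cohort_of

PERSON_COLUMNS = ["person_id", "sex", "birth_year", "municipality", "surname"]
EVENT_COLUMNS = ["person_id", "site", "age_at_diagnosis", "diagnosis_year"]

BIRTH_YEAR_MIN = 1870
BIRTH_YEAR_MAX = 2010


def default_sites() -> dict:
    """27 non-sex-specific site groups with per-sex lifetime cumulative risk.

    Values are illustrative cumulative expected counts per person to age 80,
    with magnitudes and sex contrasts loosely shaped like a Nordic national
    registry (lung strongly male-dominated, thyroid female-dominated,
    gallbladder female-dominated, colon near parity).  Each is converted to
    a piecewise-constant hazard putting 15% of the lifetime risk before age
    50 and the rest after, the usual late-adulthood concentration.
    """
    lifetime = {
        # site code: (male cum risk to 80, female cum risk to 80)
        "lip": (0.0014, 0.0003),
        "pharynx": (0.0008, 0.0003),
        "tongue": (0.0004, 0.0003),
        "salivary_glands": (0.0003, 0.0003),
        "oesophagus": (0.0013, 0.0008),
        "stomach": (0.0053, 0.0036),
        "small_intestine": (0.0004, 0.0003),
        "colon": (0.0049, 0.0054),
        "rectum": (0.0040, 0.0031),
        "anus": (0.0001, 0.0002),
        "liver": (0.0016, 0.0009),
        "gallbladder_bile_ducts": (0.0007, 0.0013),
        "pancreas": (0.0035, 0.0031),
        "nose_sinuses": (0.0002, 0.0002),
        "larynx_epiglottis": (0.0015, 0.0001),
        "lung_trachea": (0.0188, 0.0044),
        "melanoma": (0.0033, 0.0032),
        "kidney": (0.0036, 0.0019),
        "bladder_urinary": (0.0056, 0.0016),
        "cns": (0.0033, 0.0044),
        "thyroid": (0.0008, 0.0027),
        "hodgkin_lymphoma": (0.0009, 0.0007),
        "myeloma": (0.0012, 0.0012),
        "all_leukaemia": (0.0004, 0.0003),
        "cll": (0.0015, 0.0010),
        "aml": (0.0007, 0.0007),
        "cml": (0.0003, 0.0002),
    }
    def _piecewise(total: float) -> list:
        return [[0, 0.15 * total / 50.0], [50, 0.85 * total / (MAX_AGE - 50.0)]]

    return {
        site: {"male": _piecewise(m), "female": _piecewise(f)}
        for site, (m, f) in lifetime.items()
    }


def _demo_sites() -> dict:
    full = default_sites()
    return {s: full[s] for s in ("stomach", "colon", "lung_trachea", "thyroid")}


@dataclass
class SimulationConfig:
    """Everything the generator needs, including ground-truth parameters.

    ``family_size`` is a distribution spec: ``{"kind": "fixed", "size": n}``
    or ``{"kind": "nbinom", "r": r, "mean": mu, "min_size": 2}`` (a shifted
    negative binomial; the default gives a median family size of 12 with a
    hard minimum of 2, mimicking the many small surname-municipality
    families of the target cohort).

    Per-site hazards in ``sites`` are either a constant annual hazard or a
    piecewise-constant list of ``[age_start, hazard]`` pairs.
    """

    n_families: int = 2000
    family_size: dict = field(
        default_factory=lambda: {"kind": "nbinom", "r": 2.0, "mean": 14.0, "min_size": 2}
    )
    birth_year_range: tuple = (BIRTH_YEAR_MIN, BIRTH_YEAR_MAX)
    sites: dict = field(default_factory=default_sites)
    high_risk_fraction: float = 0.10
    theta_low: float = 1.0
    theta_high: float = 5.0
    follow_up_end_year: int = 2016
    cohort_width: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.birth_year_range
        if not (BIRTH_YEAR_MIN <= lo <= hi <= BIRTH_YEAR_MAX):
            raise ValueError(
                f"birth_year_range must lie within [{BIRTH_YEAR_MIN}, {BIRTH_YEAR_MAX}]"
            )
        if not 0 <= self.high_risk_fraction < 1:
            raise ValueError("high_risk_fraction must be in [0, 1)")
        if self.theta_low < 0 or self.theta_high < self.theta_low:
            raise ValueError("need theta_high >= theta_low >= 0")
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        kind = self.family_size.get("kind")
        if kind == "fixed":
            if self.family_size.get("size", 0) < 1:
                raise ValueError("fixed family size must be >= 1")
        elif kind == "nbinom":
            if self.family_size.get("r", 0) <= 0 or self.family_size.get("mean", 0) <= self.family_size.get("min_size", 2):
                raise ValueError("nbinom family size needs r > 0 and mean > min_size")
        else:
            raise ValueError(f"unknown family_size kind: {kind!r}")
        for site, per_sex in self.sites.items():
            for sex in ("male", "female"):
                hz = per_sex[sex]
                rates = [hz] if np.isscalar(hz) else [r for _, r in hz]
                if any(r < 0 for r in rates):
                    raise ValueError(f"negative hazard for site={site!r} sex={sex!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["birth_year_range"] = list(self.birth_year_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "birth_year_range" in d:
            d["birth_year_range"] = tuple(d["birth_year_range"])
        return cls(**d)


def _draw_family_sizes(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec["kind"] == "fixed":
        return np.full(n, int(spec["size"]))
    min_size = int(spec.get("min_size", 2))
    r = float(spec["r"])
    mu = float(spec["mean"]) - min_size
    p = r / (r + mu)
    return min_size + rng.negative_binomial(r, p, size=n)


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate persons grouped into surname-municipality families.

    Each family gets a unique (municipality, surname) pair; member sexes are
    Bernoulli(1/2) so both single-sex and mixed families occur.  Member birth
    years cluster around a family-specific anchor year (SD 18 years, spanning
    roughly two generations) truncated to the configured range.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _draw_family_sizes(config.family_size, config.n_families, rng)
    lo, hi = config.birth_year_range
    n_muni = max(1, config.n_families // 20)
    anchors = rng.integers(lo + 15, hi - 15, size=config.n_families)

    total = int(sizes.sum())
    fam_idx = np.repeat(np.arange(config.n_families), sizes)
    birth = anchors[fam_idx] + np.rint(rng.normal(0.0, 18.0, size=total)).astype(int)
    birth = np.clip(birth, lo, hi)
    sex = np.where(rng.random(total) < 0.5, "male", "female")

    return pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(total)],
            "sex": sex,
            "birth_year": birth,
            "municipality": [f"M{i % n_muni:04d}" for i in fam_idx],
            "surname": [f"S{i:05d}" for i in fam_idx],
        }
    )


def _annual_hazards(hz_spec) -> np.ndarray:
    """Expand a hazard spec to a per-year hazard array over ages 0..MAX_AGE-1."""
    out = np.zeros(MAX_AGE)
    if np.isscalar(hz_spec):
        out[:] = float(hz_spec)
        return out
    pieces = sorted((int(a), float(r)) for a, r in hz_spec)
    if pieces[0][0] != 0:
        raise ValueError("piecewise hazard must start at age 0")
    for i, (start, rate) in enumerate(pieces):
        end = pieces[i + 1][0] if i + 1 < len(pieces) else MAX_AGE
        out[start:end] = rate
    return out


def simulate_incidence_reference(config: SimulationConfig) -> IncidenceReference:
    """Build cumulative-incidence curves from the configured hazards.

    The same curve is reused for every birth cohort in range (no secular
    trend); curves differ by site and sex where the hazards do.
    """
    lo, hi = config.birth_year_range
    cohorts = np.arange(
        int(cohort_of(lo, config.cohort_width)),
        int(cohort_of(hi, config.cohort_width)) + 1,
        config.cohort_width,
    )
    rows = []
    ages = np.arange(MAX_AGE + 1)
    for site in sorted(config.sites):
        for sex in ("male", "female"):
            hazards = _annual_hazards(config.sites[site][sex])
            cum = np.concatenate([[0.0], np.cumsum(hazards)])
            for cohort in cohorts:
                rows.append(
                    pd.DataFrame(
                        {
                            "site": site,
                            "sex": sex,
                            "birth_cohort": cohort,
                            "attained_age": ages,
                            "cum_incidence": cum,
                        }
                    )
                )
    return IncidenceReference(pd.concat(rows, ignore_index=True), config.cohort_width)


def simulate_cancers(
    persons: pd.DataFrame,
    reference: IncidenceReference,
    config: SimulationConfig,
):
    """Generate cancer events plus the latent family risk labels.

    Families are assigned high risk with probability ``high_risk_fraction``;
    a high family's hazard is multiplied by ``theta_high`` for every site,
    a low family's by ``theta_low``.  Follow-up runs from birth to
    ``min(MAX_AGE, follow_up_end_year - birth_year)``; at most one event per
    (person, site).

    Returns ``(events, ground_truth)`` where ``ground_truth`` has one row per
    family: municipality, surname, component ("low"/"high").
    """
    rng = np.random.default_rng(config.seed + 1)
    families = (
        persons[["municipality", "surname"]].drop_duplicates().sort_values(
            ["municipality", "surname"]
        )
    ).reset_index(drop=True)
    high = rng.random(len(families)) < config.high_risk_fraction
    ground_truth = families.assign(component=np.where(high, "high", "low"))

    ppl = persons.merge(ground_truth, on=["municipality", "surname"], validate="m:1")
    ppl["attained"] = np.minimum(
        MAX_AGE, config.follow_up_end_year - ppl["birth_year"]
    )
    ppl["cohort"] = cohort_of(ppl["birth_year"], config.cohort_width)

    out = []
    for site in sorted(config.sites):
        for (sex, cohort, comp), cell in ppl.groupby(
            ["sex", "cohort", "component"], sort=True
        ):
            theta = config.theta_high if comp == "high" else config.theta_low
            try:
                curve = reference.curve(site, sex, int(cohort))
            except KeyError as err:
                raise KeyError(str(err)) from None
            p_step = np.clip(theta * np.diff(curve), 0.0, 1.0)
            # F[a] = P(event by end of age a) under the per-step Bernoulli scheme
            cum_f = 1.0 - np.exp(np.cumsum(np.log1p(-p_step)))
            attained = cell["attained"].to_numpy()
            u = rng.random(len(cell))
            p_event = np.where(attained > 0, cum_f[np.maximum(attained, 1) - 1], 0.0)
            hit = u < p_event
            if not hit.any():
                continue
            age = np.searchsorted(cum_f, u[hit], side="right")
            sub = cell.loc[hit]
            out.append(
                pd.DataFrame(
                    {
                        "person_id": sub["person_id"].to_numpy(),
                        "site": site,
                        "age_at_diagnosis": age,
                        "diagnosis_year": sub["birth_year"].to_numpy() + age,
                    }
                )
            )
    if out:
        events = pd.concat(out, ignore_index=True).sort_values(
            ["person_id", "site"], kind="stable"
        ).reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return events, ground_truth


def simulate_scir_records(
    n_groups: int,
    high_risk_fraction: float,
    theta_low: float,
    theta_high: float,
    expected_range: tuple = (0.05, 2.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Directly generate group-level (O, E) records from the count model.

    Used for model validation: each group gets an expected count E uniform in
    ``expected_range``, a latent component, and O ~ Poisson(E * theta).
    Returns columns group_id, observed, expected, true_high.
    """
    rng = np.random.default_rng(seed)
    e = rng.uniform(*expected_range, size=n_groups)
    z = rng.random(n_groups) < high_risk_fraction
    theta = np.where(z, theta_high, theta_low)
    o = rng.poisson(e * theta)
    return pd.DataFrame(
        {
            "group_id": [f"G{i:05d}" for i in range(n_groups)],
            "observed": o,
            "expected": e,
            "true_high": z,
        }
    )
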