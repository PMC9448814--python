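"""Posterior summaries: per-family probabilities, normalised SCIRs,
analysis-level aggregates, male-female ratios, cluster flags and the
concordant-family extraction.

All credible intervals are central (equal-tailed) 95% intervals; SCIR
posteriors are summarised by the median because they can be strongly
right-skewed for small families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MN_KEY, MNS_KEY
from .mixture import PosteriorDraws

logger = logging.getLogger(__name__)

CI_LEVEL = 0.95


def _central_ci(x: np.ndarray, level: float = CI_LEVEL) -> tuple:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def summarise_groups(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-group posterior summary: p_high, SCIR median and central 95% CI.

    ``p_high`` is the fraction of stored draws in which the group used the
    high-risk coefficient.  Identifier columns from the fitted records are
    carried through.
    """
    if draws.n_draws == 0:
        raise ValueError("empty posterior draws")
    med = np.median(draws.theta, axis=0)
    lo, hi = np.quantile(draws.theta, [0.025, 0.975], axis=0)
    out = draws.groups.copy()
    out["p_high"] = draws.z.mean(axis=0)
    out["scir_median"] = med
    out["scir_ci_low"] = lo
    out["scir_ci_high"] = hi
    return out


def normalise_scirs(summaries: pd.DataFrame) -> pd.DataFrame:
    """Add the normalised SCIR: SD units above the analysis-set median.

    normalised_j = (median_j - median over groups of medians) / sample SD
    (ddof=1) of the medians, so that high-risk clusters come out positive.
    If the medians have zero spread every value is 0 (with a warning).
    """
    if len(summaries) < 2:
        raise ValueError("need at least two groups to normalise")
    med = summaries["scir_median"].to_numpy()
    centre = np.median(med)
    sd = med.std(ddof=1)
    out = summaries.copy()
    if sd == 0:
        logger.warning("zero SD of SCIR medians; normalised SCIRs set to 0")
        out["normalised_scir"] = 0.0
    else:
        out["normalised_scir"] = (med - centre) / sd
    return out


@dataclass
class AnalysisSummary:
    """Posterior aggregates for one site-and-sex analysis.

    Each field is a dict with keys median, ci_low, ci_high summarising the
    per-iteration functional across stored draws.  ``scir_ratio`` is the
    mean coefficient among high-assigned groups over the mean across all
    groups; iterations with no high assignment contribute no ratio value
    (their count is in ``n_ratio_dropped``).
    """

    site: str | None
    sex: str | None
    group_proportion: dict
    scir_avg_overall: dict
    scir_avg_high: dict
    scir_ratio: dict
    n_ratio_dropped: int

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "sex": self.sex,
            "group_proportion": self.group_proportion,
            "scir_avg_overall": self.scir_avg_overall,
            "scir_avg_high": self.scir_avg_high,
            "scir_ratio": self.scir_ratio,
            "n_ratio_dropped": self.n_ratio_dropped,
        }


def _summ(x: np.ndarray) -> dict:
    lo, hi = _central_ci(x)
    return {"median": float(np.median(x)), "ci_low": lo, "ci_high": hi}


def analysis_series(draws: PosteriorDraws, weight_by_cancers: bool = False) -> pd.DataFrame:
    """Per-iteration aggregate functionals (one row per stored draw).

    Columns: group_proportion, scir_avg_overall, scir_avg_high, scir_ratio
    (NaN where no group was high-assigned).  With ``weight_by_cancers`` the
    proportion counts cancers in high-assigned groups rather than groups.
    """
    z = draws.z
    theta = draws.theta
    if weight_by_cancers:
        o = draws.groups["observed"].to_numpy(dtype=float)
        prop = (z * o).sum(axis=1) / o.sum()
    else:
        prop = z.mean(axis=1)
    avg_all = theta.mean(axis=1)
    n_high = z.sum(axis=1)
    with np.errstate(invalid="ignore"):
        avg_high = np.where(n_high > 0, (theta * z).sum(axis=1) / np.maximum(n_high, 1), np.nan)
    ratio = avg_high / avg_all
    return pd.DataFrame(
        {
            "group_proportion": prop,
            "scir_avg_overall": avg_all,
            "scir_avg_high": avg_high,
            "scir_ratio": ratio,
        }
    )


def summarise_analysis(
    draws: PosteriorDraws,
    site: str | None = None,
    sex: str | None = None,
    weight_by_cancers: bool = False,
) -> AnalysisSummary:
    """Aggregate the posterior into the analysis-level report."""
    ser = analysis_series(draws, weight_by_cancers=weight_by_cancers)
    ratio = ser["scir_ratio"].to_numpy()
    ok = np.isfinite(ratio)
    return AnalysisSummary(
        site=site,
        sex=sex,
        group_proportion=_summ(ser["group_proportion"].to_numpy()),
        scir_avg_overall=_summ(ser["scir_avg_overall"].to_numpy()),
        scir_avg_high=_summ(ser["scir_avg_high"].to_numpy()[ok]) if ok.any() else
        {"median": float("nan"), "ci_low": float("nan"), "ci_high": float("nan")},
        scir_ratio=_summ(ratio[ok]) if ok.any() else
        {"median": float("nan"), "ci_low": float("nan"), "ci_high": float("nan")},
        n_ratio_dropped=int((~ok).sum()),
    )


def compare_sexes(
    draws_male: PosteriorDraws,
    draws_female: PosteriorDraws,
    site: str | None = None,
    seed: int = 0,
) -> dict:
    """Male-female ratios of group proportion and SCIR ratio with 95% CIs.

    Iteration t of the male chain is paired with iteration t of the female
    chain (the two posteriors are independent, so any exhaustive pairing is
    valid; index pairing keeps it deterministic).  Unequal stored lengths
    are reconciled by a seeded bootstrap of the shorter chain, with a
    warning.  Iterations where either sex has an undefined SCIR ratio (no
    high assignment) are dropped from that ratio.
    """
    sm = analysis_series(draws_male)
    sf = analysis_series(draws_female)
    nm, nf = len(sm), len(sf)
    if nm != nf:
        logger.warning("draw length mismatch (%d vs %d); bootstrapping shorter", nm, nf)
        rng = np.random.default_rng(seed)
        n = max(nm, nf)
        if nm < n:
            sm = sm.iloc[rng.integers(0, nm, size=n)].reset_index(drop=True)
        else:
            sf = sf.iloc[rng.integers(0, nf, size=n)].reset_index(drop=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        prop_ratio = sm["group_proportion"].to_numpy() / sf["group_proportion"].to_numpy()
        scir_ratio = sm["scir_ratio"].to_numpy() / sf["scir_ratio"].to_numpy()
    prop_ratio = prop_ratio[np.isfinite(prop_ratio)]
    scir_ratio = scir_ratio[np.isfinite(scir_ratio)]
    return {
        "site": site,
        "ratio_group_proportion": _summ(prop_ratio),
        "ratio_scir_ratio": _summ(scir_ratio),
    }


def flag_clusters(summaries: pd.DataFrame, thresholds=(0.9, 0.95)) -> pd.DataFrame:
    """Families whose posterior high-risk probability strictly exceeds a threshold.

    One row per (group, threshold) exceeded, carrying p_high, the SCIR
    posterior median/CI and (if present) the normalised SCIR.
    """
    frames = []
    for thr in sorted(thresholds):
        hit = summaries.loc[summaries["p_high"] > thr].copy()
        hit["threshold"] = thr
        frames.append(hit)
    if not frames:
        return summaries.iloc[0:0].assign(threshold=np.nan)
    return pd.concat(frames, ignore_index=True)


def extract_concordant(
    scir_records: pd.DataFrame,
    summaries_male: pd.DataFrame,
    summaries_female: pd.DataFrame,
) -> pd.DataFrame:
    """MN families with concordant cancer of a site in both sexes.

    An MN (municipality + surname, sexless) pair qualifies for a site when
    both its male and its female MNS arm have at least one observed cancer
    of that site.  Returns one row per qualifying (MN, site) with the two
    posterior high-risk probabilities, the shape used for the
    male-versus-female probability contour comparison.
    """
    obs = scir_records.loc[scir_records["observed"] >= 1, MNS_KEY + ["site"]]
    male = obs.loc[obs["sex"] == "male", MN_KEY + ["site"]]
    female = obs.loc[obs["sex"] == "female", MN_KEY + ["site"]]
    both = male.merge(female, on=MN_KEY + ["site"])

    pm = summaries_male[MN_KEY + ["site", "p_high"]].rename(
        columns={"p_high": "p_high_male"}
    )
    pf = summaries_female[MN_KEY + ["site", "p_high"]].rename(
        columns={"p_high": "p_high_female"}
    )
    out = both.merge(pm, on=MN_KEY + ["site"]).merge(pf, on=MN_KEY + ["site"])
    return out.sort_values(MN_KEY + ["site"]).reset_index(drop=True)
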