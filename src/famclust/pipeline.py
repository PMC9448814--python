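"""Stage-wise pipeline orchestration.

Each stage reads the previous stage's TSV artifacts from an output
directory, writes its own, and drops a JSON manifest (config hash, seed,
package versions, row counts) so a run can be reproduced exactly.  Stages:

    simulate -> cohort -> scir -> fit -> summarise

Configuration is a plain dict (normally loaded from YAML) with sections
``simulation``, ``filters``, ``model`` and optional ``fit_sites``; a top
level ``seed`` feeds every stage unless a section provides its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    MNS_KEY,
    filter_events,
    observed_counts,
    summarise_cohort,
    tabulate_mns,
)
from .incidence import IncidenceReference
from .mixture import MixtureModelSpec, PosteriorDraws, fit
from .scir import expected_table, scir_table
from .simulate import (
    SimulationConfig,
    _demo_sites,
    simulate_cancers,
    simulate_incidence_reference,
    simulate_population,
)
from .summaries import (
    compare_sexes,
    extract_concordant,
    flag_clusters,
    normalise_scirs,
    summarise_analysis,
    summarise_groups,
)

logger = logging.getLogger(__name__)


def demo_config(seed: int = 11) -> dict:
    """A small four-site configuration that runs end-to-end in under a minute."""
    sim = SimulationConfig(
        n_families=400,
        sites=_demo_sites(),
        high_risk_fraction=0.08,
        theta_low=1.0,
        theta_high=8.0,
        seed=seed,
    )
    model = MixtureModelSpec(iterations=2500, burn_in=1000, thin=3, chains=2, seed=seed)
    return {
        "seed": seed,
        "simulation": sim.to_dict(),
        "filters": {"birth_year_range": [1870, 2010], "age_cap": 80, "min_group_size": 2},
        "model": model.to_dict(),
        "fit_sites": None,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "simulation" not in cfg or "model" not in cfg:
        raise ValueError("config must be a mapping with 'simulation' and 'model' sections")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(out_dir: Path, stage: str, cfg: dict, seed, outputs: dict) -> None:
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "versions": {
            "famclust": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": outputs,
    }
    with open(out_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(out_dir: Path, filename: str, stage_hint: str) -> Path:
    path = out_dir / filename
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {filename!r}; run the {stage_hint!r} stage first"
        )
    return path


def _tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_simulate(cfg: dict, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = dict(cfg["simulation"])
    sim_cfg.setdefault("seed", cfg.get("seed", 0))
    sim = SimulationConfig.from_dict(sim_cfg)

    persons = simulate_population(sim)
    reference = simulate_incidence_reference(sim)
    events, truth = simulate_cancers(persons, reference, sim)

    outputs = {
        "persons.tsv": _tsv(persons, out_dir / "persons.tsv"),
        "events.tsv": _tsv(events, out_dir / "events.tsv"),
        "ground_truth.tsv": _tsv(truth, out_dir / "ground_truth.tsv"),
    }
    reference.to_tsv(out_dir / "reference.tsv")
    outputs["reference.tsv"] = len(reference.table)
    _write_manifest(out_dir, "simulate", cfg, sim.seed, outputs)
    return outputs


def run_cohort(cfg: dict, out_dir) -> dict:
    out_dir = Path(out_dir)
    persons = pd.read_csv(_require(out_dir, "persons.tsv", "simulate"), sep="\t")
    events = pd.read_csv(_require(out_dir, "events.tsv", "simulate"), sep="\t")

    filt = cfg.get("filters", {})
    kept_events = filter_events(
        events,
        persons,
        birth_year_range=tuple(filt.get("birth_year_range", (1870, 2010))),
        age_cap=int(filt.get("age_cap", 80)),
    )
    lo, hi = tuple(filt.get("birth_year_range", (1870, 2010)))
    persons_in_range = persons.loc[persons["birth_year"].between(lo, hi)]
    tab = tabulate_mns(persons_in_range, min_size=int(filt.get("min_group_size", 2)))
    counts = observed_counts(tab, kept_events)
    summary = summarise_cohort(counts)

    outputs = {
        "cohort_persons.tsv": _tsv(tab.persons, out_dir / "cohort_persons.tsv"),
        "mns_groups.tsv": _tsv(tab.groups, out_dir / "mns_groups.tsv"),
        "filtered_events.tsv": _tsv(kept_events, out_dir / "filtered_events.tsv"),
        "observed_counts.tsv": _tsv(counts, out_dir / "observed_counts.tsv"),
        "cohort_summary.tsv": _tsv(summary, out_dir / "cohort_summary.tsv"),
    }
    _write_manifest(
        out_dir, "cohort", cfg, cfg.get("seed"), {**outputs, **tab.exclusions}
    )
    return outputs


def run_scir(cfg: dict, out_dir) -> dict:
    out_dir = Path(out_dir)
    reference = IncidenceReference.from_tsv(
        _require(out_dir, "reference.tsv", "simulate"),
        cohort_width=int(cfg["simulation"].get("cohort_width", 10)),
    )
    persons = pd.read_csv(_require(out_dir, "cohort_persons.tsv", "cohort"), sep="\t")
    counts = pd.read_csv(_require(out_dir, "observed_counts.tsv", "cohort"), sep="\t")
    groups = pd.read_csv(_require(out_dir, "mns_groups.tsv", "cohort"), sep="\t")

    from .cohort import MnsTabulation

    tab = MnsTabulation(persons=persons, groups=groups, n_missing_sex=0, n_dropped_small_groups=0)
    follow_up = int(cfg["simulation"].get("follow_up_end_year", 2016))
    expected = expected_table(tab, reference, follow_up)
    table = scir_table(counts, expected)

    outputs = {"scir_table.tsv": _tsv(table, out_dir / "scir_table.tsv")}
    _write_manifest(out_dir, "scir", cfg, cfg.get("seed"), outputs)
    return outputs


def _analysis_sets(table: pd.DataFrame, fit_sites) -> list:
    included = table.loc[~table["excluded"]]
    sets = []
    for (site, sex), grp in included.groupby(["site", "sex"], sort=True):
        if fit_sites is not None and site not in fit_sites:
            continue
        if len(grp) >= 2:
            sets.append((site, sex, grp.reset_index(drop=True)))
    return sets


def run_fit(cfg: dict, out_dir) -> dict:
    out_dir = Path(out_dir)
    table = pd.read_csv(_require(out_dir, "scir_table.tsv", "scir"), sep="\t")
    fit_dir = out_dir / "fits"
    fit_dir.mkdir(exist_ok=True)

    base = MixtureModelSpec.from_dict(dict(cfg["model"]))
    outputs = {}
    for i, (site, sex, records) in enumerate(
        _analysis_sets(table, cfg.get("fit_sites"))
    ):
        spec = MixtureModelSpec.from_dict({**base.to_dict(), "seed": base.seed + i})
        draws = fit(records, spec)
        stem = f"{site}__{sex}"
        np.savez(
            fit_dir / f"{stem}.npz",
            theta=draws.theta,
            z=draws.z,
            pi=draws.pi,
            hyper=draws.hyper,
            log_posterior=draws.log_posterior,
            chain_id=draws.chain_id,
        )
        _tsv(draws.groups, fit_dir / f"{stem}_groups.tsv")
        outputs[stem] = {
            "n_groups": draws.n_groups,
            "n_draws": draws.n_draws,
            "diagnostics": {k: float(v) for k, v in draws.diagnostics.items()},
        }
    _write_manifest(out_dir, "fit", cfg, base.seed, {"analyses": outputs})
    return outputs


def load_draws(out_dir, site: str, sex: str) -> PosteriorDraws:
    fit_dir = Path(out_dir) / "fits"
    stem = f"{site}__{sex}"
    path = _require(fit_dir, f"{stem}.npz", "fit")
    arrs = np.load(path)
    groups = pd.read_csv(fit_dir / f"{stem}_groups.tsv", sep="\t")
    return PosteriorDraws(
        theta=arrs["theta"],
        z=arrs["z"].astype(bool),
        pi=arrs["pi"],
        hyper=arrs["hyper"],
        log_posterior=arrs["log_posterior"],
        chain_id=arrs["chain_id"],
        groups=groups,
    )


def run_summarise(cfg: dict, out_dir) -> dict:
    out_dir = Path(out_dir)
    table = pd.read_csv(_require(out_dir, "scir_table.tsv", "scir"), sep="\t")
    fit_dir = _require(out_dir, "fits", "fit")
    stems = sorted(p.stem for p in Path(fit_dir).glob("*.npz"))

    all_summaries = []
    analysis_report = []
    by_site_sex = {}
    for stem in stems:
        site, sex = stem.rsplit("__", 1)
        draws = load_draws(out_dir, site, sex)
        summ = normalise_scirs(summarise_groups(draws))
        all_summaries.append(summ)
        by_site_sex[(site, sex)] = (draws, summ)
        analysis_report.append(summarise_analysis(draws, site=site, sex=sex).to_dict())

    summaries = pd.concat(all_summaries, ignore_index=True)
    flagged = flag_clusters(summaries)

    sex_rows = []
    sites = sorted({s for s, _ in by_site_sex})
    for site in sites:
        if (site, "male") in by_site_sex and (site, "female") in by_site_sex:
            comp = compare_sexes(
                by_site_sex[(site, "male")][0],
                by_site_sex[(site, "female")][0],
                site=site,
                seed=int(cfg.get("seed", 0)),
            )
            sex_rows.append(
                {
                    "site": site,
                    "ratio_group_proportion": comp["ratio_group_proportion"]["median"],
                    "ratio_group_proportion_ci_low": comp["ratio_group_proportion"]["ci_low"],
                    "ratio_group_proportion_ci_high": comp["ratio_group_proportion"]["ci_high"],
                    "ratio_scir_ratio": comp["ratio_scir_ratio"]["median"],
                    "ratio_scir_ratio_ci_low": comp["ratio_scir_ratio"]["ci_low"],
                    "ratio_scir_ratio_ci_high": comp["ratio_scir_ratio"]["ci_high"],
                }
            )
    sex_comparison = pd.DataFrame(sex_rows)

    pm = summaries.loc[summaries["sex"] == "male"] if "sex" in summaries else summaries.iloc[0:0]
    pf = summaries.loc[summaries["sex"] == "female"] if "sex" in summaries else summaries.iloc[0:0]
    if len(pm) and len(pf):
        concordant = extract_concordant(table, pm, pf)
    else:
        concordant = pd.DataFrame(
            columns=["municipality", "surname", "site", "p_high_male", "p_high_female"]
        )

    outputs = {
        "mns_summaries.tsv": _tsv(summaries, out_dir / "mns_summaries.tsv"),
        "flagged_clusters.tsv": _tsv(flagged, out_dir / "flagged_clusters.tsv"),
        "sex_comparison.tsv": _tsv(sex_comparison, out_dir / "sex_comparison.tsv"),
        "concordant_pairs.tsv": _tsv(concordant, out_dir / "concordant_pairs.tsv"),
    }
    with open(out_dir / "analysis_summary.json", "w") as fh:
        json.dump(analysis_report, fh, indent=2, sort_keys=True)
    outputs["analysis_summary.json"] = len(analysis_report)
    _write_manifest(out_dir, "summarise", cfg, cfg.get("seed"), outputs)
    return outputs


STAGES = {
    "simulate": run_simulate,
    "cohort": run_cohort,
    "scir": run_scir,
    "fit": run_fit,
    "summarise": run_summarise,
}


def run_all(cfg: dict, out_dir) -> dict:
    """Run every stage in order; returns per-stage output row counts."""
    report = {}
    for name in ("simulate", "cohort", "scir", "fit", "summarise"):
        logger.info("running stage %s", name)
        report[name] = STAGES[name](cfg, out_dir)
    return report
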