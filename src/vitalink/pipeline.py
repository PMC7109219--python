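"""End-to-end orchestration: simulate -> link -> rates / causes / compare.

``run_pipeline`` executes the stages in order, writes every output table
under a run directory, and finishes with a manifest (config hash, seed,
stage row counts, per-file checksums) so that identical config + seed
yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .causes import ICEMapping, cause_specific_rates
from .compare import characteristics_table
from .config import PipelineConfig
from .io import _json_default, write_manifest, write_registry_csv
from .linkage import evaluate_linkage, run_period_linkage
from .rates import StratumDefinition, crude_rates, rate_table, specific_rates

log = logging.getLogger("vitalink")


def default_strata(config: PipelineConfig) -> list[StratumDefinition]:
    c = config.cohort
    return [
        StratumDefinition("maternal_age", "maternal_age",
                          labels=list(c.maternal_age_dist)),
        StratumDefinition("parity", "parity", labels=list(c.parity_dist)),
        StratumDefinition("sex", "sex", labels=list(c.sex_dist)),
        StratumDefinition("plurality", "plurality",
                          labels=list(c.plurality_dist)),
        StratumDefinition("income_quintile", "income_quintile",
                          labels=list(c.income_quintile_dist)),
        StratumDefinition("region", "region", labels=list(c.region_dist)),
        StratumDefinition("rurality", "rurality", labels=["rural", "urban"]),
    ]


def bw_stratum(config: PipelineConfig) -> StratumDefinition:
    return StratumDefinition(
        "birthweight_bin", "birthweight_g",
        edges=[(b.label, b.lo, b.hi) for b in config.cohort.birthweight_bins])


def ga_stratum(config: PipelineConfig) -> StratumDefinition:
    return StratumDefinition(
        "ga_bin", "ga_weeks",
        edges=[(b.label, b.lo, b.hi) for b in config.cohort.ga_bins])


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write all tables under ``out_dir``.

    Returns the in-memory results: the period linked file, truth map,
    linkage evaluation, and every rate table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})

    log.info("stage simulate: n_births=%d", cohort_cfg.n_births)
    try:
        reference, death_file, truth = synth.simulate(cohort_cfg,
                                                      config.corruption)
    except Exception as exc:  # pragma: no cover - stage naming only
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    reference = reference.copy()
    reference["rurality"] = np.where(reference["rural"], "rural", "urban")

    write_registry_csv(reference, out_dir / "reference.csv")
    write_registry_csv(death_file, out_dir / "deaths.csv")
    write_registry_csv(truth.table, out_dir / "truth.csv")

    log.info("stage link: %d deaths vs %d reference records",
             len(death_file), len(reference))
    try:
        plf = run_period_linkage(death_file, reference, config.linkage,
                                 death_years=cohort_cfg.death_years)
    except Exception as exc:
        raise RuntimeError(f"stage 'link' failed: {exc}") from exc
    evaluation = evaluate_linkage(plf, truth)

    write_registry_csv(plf.links, out_dir / "links.csv")
    write_registry_csv(plf.possible, out_dir / "possible_pairs.csv")
    write_registry_csv(plf.unlinked, out_dir / "unlinked_deaths.csv")
    report = {"summary": plf.summary, "evaluation": evaluation}
    with open(out_dir / "linkage_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(out_dir / "linkage_report.txt", "w", encoding="utf-8") as fh:
        for k, v in plf.summary.items():
            fh.write(f"{k}: {v}\n")
        for k, v in evaluation.items():
            fh.write(f"{k}: {v}\n")

    kw = dict(alpha=config.alpha, suppress_at=config.suppress_at,
              method=config.ci_method)
    try:
        crude = crude_rates(plf, **kw)
    except Exception as exc:
        raise RuntimeError(f"stage 'rates' failed: {exc}") from exc
    crude_df = pd.DataFrame(
        [{"measure": k, **v.as_dict()} for k, v in crude.items()])
    write_registry_csv(crude_df, out_dir / "crude_rates.csv")

    bw_table = specific_rates(
        plf, bw_stratum(config),
        restrict=None,
        cumulative=[(">= 500 g", lambda df: df["birthweight_g"] >= 500),
                    (">= 1000 g", lambda df: df["birthweight_g"] >= 1000)],
        **kw)
    write_registry_csv(bw_table, out_dir / "birthweight_rates.csv")
    ga_table = specific_rates(plf, ga_stratum(config), **kw)
    write_registry_csv(ga_table, out_dir / "gestational_age_rates.csv")

    strata_tables = {}
    for stratum in default_strata(config):
        t = specific_rates(plf, stratum, **kw)
        t.insert(0, "stratifier", stratum.name)
        strata_tables[stratum.name] = t
    write_registry_csv(pd.concat(strata_tables.values(), ignore_index=True),
                       out_dir / "stratified_rates.csv")

    mapping = (ICEMapping.from_yaml(config.ice_mapping_path)
               if config.ice_mapping_path else ICEMapping.default())
    try:
        cause_table = cause_specific_rates(
            plf.deaths, len(plf.denominator), mapping, **kw)
    except Exception as exc:
        raise RuntimeError(f"stage 'causes' failed: {exc}") from exc
    write_registry_csv(cause_table, out_dir / "cause_rates.csv")

    linked_d = plf.deaths[plf.deaths["death_id"].isin(set(plf.links["death_id"]))]
    char_table = characteristics_table(linked_d, plf.unlinked)
    write_registry_csv(char_table, out_dir / "characteristics.csv")

    stage_counts = {
        "reference_records": len(reference),
        "registered_deaths": len(death_file),
        "linked": int(len(plf.links)),
        "unlinked": int(len(plf.unlinked)),
        "denominator_live_births": int(len(plf.denominator)),
    }
    write_manifest(out_dir, config.config_hash(), config.seed, stage_counts)

    return {
        "plf": plf, "truth": truth, "evaluation": evaluation, "crude": crude,
        "birthweight_table": bw_table, "ga_table": ga_table,
        "strata_tables": strata_tables, "cause_table": cause_table,
        "characteristics": char_table, "out_dir": out_dir,
    }

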