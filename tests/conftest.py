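"""Shared fixtures: synthetic cohorts at several scales.

Session-scoped so the expensive full-scale run (used by the acceptance
checks) is paid once.
"""

from __future__ import annotations

import warnings

import pytest

import vitalink as vl

SEED = 1


@pytest.fixture(scope="session")
def clean_run():
    """Mid-size cohort with corruption fully off: identifiers intact, no
    removed births; deterministic linkage alone should recover the truth."""
    cohort = vl.CohortConfig(n_births=30_000, seed=2)
    reference, deaths, truth = vl.simulate(cohort, vl.CorruptionConfig.clean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plf = vl.run_period_linkage(deaths, reference,
                                    death_years=cohort.death_years)
    return {"reference": reference, "deaths": deaths, "truth": truth,
            "plf": plf, "evaluation": vl.evaluate_linkage(plf, truth)}


@pytest.fixture(scope="session")
def small_run():
    """Default calibrated corruption at a small scale for fast unit checks."""
    cfg = vl.PipelineConfig.demo(scale=0.05, seed=SEED)
    cohort = cfg.cohort
    reference, deaths, truth = vl.simulate(cohort, cfg.corruption)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plf = vl.run_period_linkage(deaths, reference, cfg.linkage,
                                    death_years=cohort.death_years)
    return {"config": cfg, "reference": reference, "deaths": deaths,
            "truth": truth, "plf": plf,
            "evaluation": vl.evaluate_linkage(plf, truth)}


@pytest.fixture(scope="session")
def full_run():
    """Full-scale cohort (~421k births over 2009-2011, ~281k in the 2010-2011
    denominator) with default calibrated corruption and a fixed seed."""
    cfg = vl.PipelineConfig.demo(scale=1.0, seed=SEED)
    cohort = cfg.cohort
    reference, deaths, truth = vl.simulate(cohort, cfg.corruption)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plf = vl.run_period_linkage(deaths, reference, cfg.linkage,
                                    death_years=cohort.death_years)
    return {"config": cfg, "reference": reference, "deaths": deaths,
            "truth": truth, "plf": plf,
            "evaluation": vl.evaluate_linkage(plf, truth)}
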