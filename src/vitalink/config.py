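"""Configuration models for the synthetic cohort, linkage and rates stages.

All tunable parameters of the pipeline live here as validated pydantic
models.  The default cohort reproduces the published Ontario 2009-2011
birthweight / gestational-age structure: bin proportions and per-bin
infant-mortality probabilities are taken from the province-wide
birthweight-specific and GA-specific mortality table, and the joint
birthweight x gestational-age distribution is completed by iterative
proportional fitting (IPF) of a plausible support matrix to both margins.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

PROP_TOL = 1e-9

# ---------------------------------------------------------------------------
# Calibration constants: Ontario 2010-2011 linked-file structure
# ---------------------------------------------------------------------------

# (label, lower edge g, upper edge g (exclusive), live births, infant deaths)
BIRTHWEIGHT_TABLE = [
    ("<500", 0, 500, 375, 331),
    ("500-999", 500, 1000, 1150, 363),
    ("1000-1499", 1000, 1500, 1683, 77),
    ("1500-1999", 1500, 2000, 3691, 71),
    ("2000-2499", 2000, 2500, 12153, 72),
    ("2500-2999", 2500, 3000, 47132, 114),
    ("3000-3499", 3000, 3500, 104457, 126),
    (">=3500", 3500, 5500, 110283, 109),
]

# (label, lower edge wk, upper edge wk (exclusive), live births, infant deaths)
GESTAGE_TABLE = [
    ("<25", 16, 25, 745, 595),
    ("25-29", 25, 30, 1535, 139),
    ("30-31", 30, 32, 1324, 41),
    ("32-33", 32, 34, 2768, 41),
    ("34-36", 34, 37, 16664, 100),
    ("37-39", 37, 40, 152124, 248),
    (">=40", 40, 43, 105706, 99),
]

#: Live births 2010-2011 = sum of the birthweight table's denominator column.
DENOMINATOR_BIRTHS = sum(r[3] for r in BIRTHWEIGHT_TABLE)  # 280,924
#: Cohort covers three birth years but the death-registration window covers
#: two, so the full-scale cohort is 3/2 the two-year denominator.
N_BIRTHS_FULL = round(DENOMINATOR_BIRTHS * 3 / 2)  # 421,386

# Plausible birthweight x GA support, IPF-seeded; rows follow
# BIRTHWEIGHT_TABLE order, columns GESTAGE_TABLE order.
_BW_GA_SEED = np.array(
    [
        [1.0, 0.10, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.50, 1.0, 0.10, 0.02, 0.0, 0.0, 0.0],
        [0.02, 1.0, 0.50, 0.30, 0.05, 0.0, 0.0],
        [0.0, 0.10, 0.50, 1.0, 0.50, 0.02, 0.0],
        [0.0, 0.01, 0.05, 0.30, 1.0, 0.30, 0.02],
        [0.0, 0.0, 0.01, 0.05, 0.50, 1.0, 0.20],
        [0.0, 0.0, 0.0, 0.01, 0.10, 1.0, 0.50],
        [0.0, 0.0, 0.0, 0.0, 0.02, 0.80, 1.0],
    ]
)

# Integer-week distribution inside the "<25" GA bin (weeks 16..24).  The
# sub-20-week tail (probability 0.05) is what the reference file's
# >=500 g / >=20 wk collection rule removes for sub-500-g births.
GA_WEEK_WEIGHTS_LT25 = {
    16: 0.005, 17: 0.010, 18: 0.015, 19: 0.020,
    20: 0.050, 21: 0.100, 22: 0.200, 23: 0.300, 24: 0.300,
}
# Inside ">=40": term skew.
GA_WEEK_WEIGHTS_GE40 = {40: 0.75, 41: 0.22, 42: 0.03}

# Age-at-death mixture over (<24 h, 1-6 d, 7-27 d, 28-364 d), from the
# registered-death timing distribution (660/167/181/303 of 1311).
AGE_AT_DEATH_DEFAULT = [660 / 1311, 167 / 1311, 181 / 1311, 303 / 1311]

# Ontario-flavoured regions: (code, population share, postal first letter).
REGION_TABLE = [
    ("TOR", 0.35, "M"),
    ("CEN", 0.17, "L"),
    ("WES", 0.25, "N"),
    ("EAS", 0.15, "K"),
    ("NOR", 0.08, "P"),
]

# Underlying-cause mix over ICD-10 codes, conditional on death; calibrated so
# immaturity-related conditions lead and congenital anomalies come second.
CAUSE_MIX_DEFAULT = {
    "P07": 0.20, "P22": 0.10, "P77": 0.04,           # immaturity-related
    "Q24": 0.08, "Q21": 0.05, "Q89": 0.05, "Q00": 0.05,  # congenital anomalies
    "P21": 0.08,                                      # asphyxia
    "P36": 0.04, "A41": 0.02, "J18": 0.01,            # infection
    "R95": 0.09,                                      # SIDS
    "W75": 0.03, "V43": 0.01,                         # external
    "R99": 0.08, "P96": 0.05, "G93": 0.02,            # other / ill-defined
}

MATERNAL_AGE_DEFAULT = {
    "<20": 0.03, "20-24": 0.13, "25-29": 0.31,
    "30-34": 0.33, "35-39": 0.16, ">=40": 0.04,
}
PARITY_DEFAULT = {"nulliparous": 0.45, "parous": 0.55}
SEX_DEFAULT = {"M": 0.512, "F": 0.486, "U": 0.002}
PLURALITY_DEFAULT = {"singleton": 0.967, "multiple": 0.033}
INCOME_QUINTILE_DEFAULT = {"Q1": 0.2, "Q2": 0.2, "Q3": 0.2, "Q4": 0.2, "Q5": 0.2}


def ipf_joint(seed: np.ndarray, row_marg: np.ndarray, col_marg: np.ndarray,
              n_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Iterative proportional fitting of ``seed`` to the given margins.

    Returns a joint probability table with row sums ``row_marg`` and column
    sums ``col_marg`` and the support pattern of ``seed``.
    """
    j = seed.astype(float).copy()
    j /= j.sum()
    for _ in range(n_iter):
        rs = j.sum(axis=1)
        j *= np.where(rs > 0, row_marg / np.where(rs > 0, rs, 1.0), 0.0)[:, None]
        cs = j.sum(axis=0)
        j *= np.where(cs > 0, col_marg / np.where(cs > 0, cs, 1.0), 0.0)[None, :]
        if np.abs(j.sum(axis=1) - row_marg).max() < tol:
            break
    return j


class Bin(BaseModel):
    """One histogram bin with an occupancy proportion and, for birthweight
    bins, the per-birth infant-mortality probability."""

    label: str
    lo: float
    hi: float
    proportion: float = Field(ge=0.0, le=1.0)
    mortality: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _edges(self) -> "Bin":
        if not self.hi > self.lo:
            raise ValueError(f"bin '{self.label}': hi must exceed lo")
        return self


def _check_simplex(name: str, values) -> None:
    total = float(np.sum(list(values)))
    if abs(total - 1.0) > PROP_TOL:
        raise ValueError(f"{name}: proportions must sum to 1 (got {total!r})")
    if np.any(np.asarray(list(values)) < 0):
        raise ValueError(f"{name}: proportions must be non-negative")


class CohortConfig(BaseModel):
    """Parameters of the synthetic birth cohort and its infant deaths."""

    n_births: int = Field(default=N_BIRTHS_FULL, ge=1)
    years: tuple[int, int] = (2009, 2011)
    death_years: tuple[int, int] = (2010, 2011)
    birthweight_bins: list[Bin] = None  # type: ignore[assignment]
    ga_bins: list[Bin] = None  # type: ignore[assignment]
    #: P(ga bin | birthweight bin); rows follow birthweight_bins order.
    ga_given_bw: list[list[float]] = None  # type: ignore[assignment]
    age_at_death_model: list[float] = Field(
        default_factory=lambda: list(AGE_AT_DEATH_DEFAULT)
    )
    stillbirth_fraction: float = Field(default=0.006, ge=0.0, le=1.0)
    maternal_age_dist: dict[str, float] = Field(
        default_factory=lambda: dict(MATERNAL_AGE_DEFAULT))
    parity_dist: dict[str, float] = Field(
        default_factory=lambda: dict(PARITY_DEFAULT))
    sex_dist: dict[str, float] = Field(default_factory=lambda: dict(SEX_DEFAULT))
    plurality_dist: dict[str, float] = Field(
        default_factory=lambda: dict(PLURALITY_DEFAULT))
    income_quintile_dist: dict[str, float] = Field(
        default_factory=lambda: dict(INCOME_QUINTILE_DEFAULT))
    region_dist: dict[str, float] = Field(
        default_factory=lambda: {code: p for code, p, _ in REGION_TABLE})
    rural_fraction: float = Field(default=0.14, ge=0.0, le=1.0)
    cause_mix: dict[str, float] = Field(
        default_factory=lambda: dict(CAUSE_MIX_DEFAULT))
    seed: int = 0

    @model_validator(mode="before")
    @classmethod
    def _fill_defaults(cls, data):
        if isinstance(data, dict):
            if data.get("birthweight_bins") is None:
                total = sum(r[3] for r in BIRTHWEIGHT_TABLE)
                data["birthweight_bins"] = [
                    Bin(label=lab, lo=lo, hi=hi, proportion=b / total,
                        mortality=d / b)
                    for lab, lo, hi, b, d in BIRTHWEIGHT_TABLE
                ]
            if data.get("ga_bins") is None:
                total = sum(r[3] for r in GESTAGE_TABLE)
                data["ga_bins"] = [
                    Bin(label=lab, lo=lo, hi=hi, proportion=b / total,
                        mortality=d / b)
                    for lab, lo, hi, b, d in GESTAGE_TABLE
                ]
            if data.get("ga_given_bw") is None:
                bw = data["birthweight_bins"]
                ga = data["ga_bins"]
                row = np.array([b.proportion if isinstance(b, Bin)
                                else b["proportion"] for b in bw])
                col = np.array([g.proportion if isinstance(g, Bin)
                                else g["proportion"] for g in ga])
                joint = ipf_joint(_BW_GA_SEED, row / row.sum(), col / col.sum())
                cond = joint / joint.sum(axis=1, keepdims=True)
                data["ga_given_bw"] = cond.tolist()
        return data

    @model_validator(mode="after")
    def _validate(self) -> "CohortConfig":
        if self.years[0] > self.years[1]:
            raise ValueError("years: start must not exceed end")
        if self.death_years[0] > self.death_years[1]:
            raise ValueError("death_years: start must not exceed end")
        _check_simplex("birthweight_bins", [b.proportion for b in self.birthweight_bins])
        _check_simplex("ga_bins", [b.proportion for b in self.ga_bins])
        _check_simplex("age_at_death_model", self.age_at_death_model)
        if len(self.age_at_death_model) != 4:
            raise ValueError("age_at_death_model: four mixture components required")
        for name in ("maternal_age_dist", "parity_dist", "sex_dist",
                     "plurality_dist", "income_quintile_dist", "region_dist",
                     "cause_mix"):
            _check_simplex(name, getattr(self, name).values())
        for bins, name in ((self.birthweight_bins, "birthweight_bins"),
                           (self.ga_bins, "ga_bins")):
            edges = [b.lo for b in bins] + [bins[-1].hi]
            if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
                raise ValueError(f"{name}: bin edges must be strictly increasing")
        cond = np.asarray(self.ga_given_bw, dtype=float)
        if cond.shape != (len(self.birthweight_bins), len(self.ga_bins)):
            raise ValueError("ga_given_bw: shape must be (n bw bins, n ga bins)")
        if np.abs(cond.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("ga_given_bw: each row must sum to 1")
        return self


class CorruptionConfig(BaseModel):
    """Field-corruption and record-removal probabilities applied when the
    cohort is split into the reference and death-registration files.

    The three removal mechanisms mirror the reasons an infant death
    registration can have no hospital birth record: births below the
    >=500 g / >=20 wk collection thresholds, births out of province or
    outside a hospital, and live births following a late termination.
    """

    p_identifier_missing_on_death: float = Field(default=0.15, ge=0, le=1)
    p_postal_typo: float = Field(default=0.05, ge=0, le=1)
    p_dob_shift: float = Field(default=0.02, ge=0, le=1)
    p_sex_missing: float = Field(default=0.01, ge=0, le=1)
    p_out_of_hospital: float = Field(default=0.02, ge=0, le=1)
    subthreshold_rule: bool = True
    p_stillbirth_misclass: float = Field(default=0.01, ge=0, le=1)
    p_late_termination: float = Field(default=0.005, ge=0, le=1)

    @classmethod
    def clean(cls) -> "CorruptionConfig":
        """No corruption at all: deterministic linkage alone recovers truth."""
        return cls(
            p_identifier_missing_on_death=0.0, p_postal_typo=0.0,
            p_dob_shift=0.0, p_sex_missing=0.0, p_out_of_hospital=0.0,
            subthreshold_rule=False, p_stillbirth_misclass=0.0,
            p_late_termination=0.0,
        )


class LinkageConfig(BaseModel):
    """Blocking, EM and decision-threshold settings for the probabilistic pass."""

    blocking_scheme: str = "dob1"  # {"dob_year_fsa", "dob1", "none"}
    upper_posterior: float = Field(default=0.9, gt=0, lt=1)
    lower_posterior: float = Field(default=0.1, gt=0, lt=1)
    em_tol: float = Field(default=1e-6, gt=0)
    em_max_iter: int = Field(default=200, ge=1)
    #: When True, a missing field gets its own agreement level with fitted
    #: m/u instead of the default zero-weight convention.
    model_missing_level: bool = False

    @model_validator(mode="after")
    def _order(self) -> "LinkageConfig":
        if self.blocking_scheme not in ("dob_year_fsa", "dob1", "none"):
            raise ValueError("blocking_scheme: unknown scheme")
        if self.lower_posterior > self.upper_posterior:
            raise ValueError("lower_posterior must not exceed upper_posterior")
        return self


class PipelineConfig(BaseModel):
    """Top-level configuration for the simulate -> link -> tables pipeline."""

    model_config = {"extra": "forbid"}

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    corruption: CorruptionConfig = Field(default_factory=CorruptionConfig)
    linkage: LinkageConfig = Field(default_factory=LinkageConfig)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    suppress_at: int = Field(default=5, ge=0)
    ci_method: str = "midp"  # {"midp", "clopper-pearson"}
    ice_mapping_path: Optional[str] = None
    seed: int = 0

    @field_validator("ci_method")
    @classmethod
    def _ci(cls, v: str) -> str:
        if v not in ("midp", "clopper-pearson"):
            raise ValueError("ci_method: must be 'midp' or 'clopper-pearson'")
        return v

    @classmethod
    def demo(cls, scale: float = 0.1, seed: int = 0) -> "PipelineConfig":
        """Full calibrated structure at ``scale`` times the full cohort size."""
        return cls(cohort=CohortConfig(n_births=max(1, round(N_BIRTHS_FULL * scale)),
                                       seed=seed),
                   seed=seed)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
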