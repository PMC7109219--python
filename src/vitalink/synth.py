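"""Synthetic birth-reference and infant-death registration files.

Emulates the two registries the linkage consumes: a hospital birth
reference file (live births, orphan records and stillbirths, 2009-2011)
and an infant death registration file (deaths under 365 days registered
in 2010-2011), plus a ground-truth map from each registered death to its
birth record (or to none, with the removal reason).

Three mechanisms create deaths that genuinely cannot be linked, mirroring
the ways a hospital discharge database misses a birth: records below the
>=500 g / >=20 week collection thresholds, births out of province or
outside any hospital, and live births following late terminations.
Field-level corruption (missing identifiers, postal typos, +/-1 day date
shifts, missing sex) forces the probabilistic pass to do real work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    GA_WEEK_WEIGHTS_GE40,
    GA_WEEK_WEIGHTS_LT25,
    REGION_TABLE,
    CohortConfig,
    CorruptionConfig,
)

BIRTH_COLUMNS = [
    "birth_id", "encoded_identifier", "dob", "sex", "place_code",
    "postal_code", "birthweight_g", "ga_weeks", "maternal_age", "parity",
    "plurality", "income_quintile", "region", "rural",
    "stillbirth_flag", "orphan_flag", "bw_bin", "ga_bin",
]

DEATH_COLUMNS = [
    "death_id", "encoded_identifier", "dob", "dod", "place_of_death_code",
    "sex", "postal_code", "icd10_cause", "age_at_death_days",
]

TRUTH_COLUMNS = ["death_id", "birth_id", "reason"]

#: truth-map reason codes for deaths whose birth record is absent
REASON_SUBTHRESHOLD = "subthreshold"
REASON_OUT_OF_HOSPITAL = "out_of_hospital"
REASON_LATE_TERMINATION = "late_termination"
REASON_STILLBIRTH_MISCLASS = "stillbirth_misclass"

_HOSPITALS_PER_REGION = 12
_FSAS_PER_REGION = 30
_ORPHAN_FRACTION = 0.02
#: P(death registered at the birth hospital / another hospital / elsewhere / missing)
_PLACE_OF_DEATH_MIX = (0.80, 0.12, 0.05, 0.03)


@dataclass
class TruthMap:
    """Ground truth: one row per registered death with its true birth record
    (``birth_id`` = <NA> when that record was removed) and a reason code."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.table.columns) != TRUTH_COLUMNS:
            raise ValueError(f"truth map columns must be {TRUTH_COLUMNS}")
        if self.table["death_id"].duplicated().any():
            raise ValueError("truth map: duplicate death_id")

    def lookup(self) -> dict:
        return dict(zip(self.table["death_id"], self.table["birth_id"]))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _sample_cat(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    keys = np.array(list(dist.keys()), dtype=object)
    p = np.asarray(list(dist.values()), dtype=float)
    return keys[rng.choice(len(keys), size=n, p=p / p.sum())]


def _weeks_within_bin(rng: np.random.Generator, lo: int, hi: int, label: str,
                      n: int) -> np.ndarray:
    """Integer gestational weeks inside [lo, hi); extreme bins are skewed."""
    if label == "<25":
        weeks = np.array(list(GA_WEEK_WEIGHTS_LT25), dtype=int)
        w = np.array(list(GA_WEEK_WEIGHTS_LT25.values()))
    elif label == ">=40":
        weeks = np.array(list(GA_WEEK_WEIGHTS_GE40), dtype=int)
        w = np.array(list(GA_WEEK_WEIGHTS_GE40.values()))
    else:
        weeks = np.arange(int(lo), int(hi))
        w = np.ones(len(weeks))
    return weeks[rng.choice(len(weeks), size=n, p=w / w.sum())]


def _postal_codes(rng: np.random.Generator, regions: np.ndarray) -> np.ndarray:
    """Canadian-format postal codes (A1A 1A1) with region-dependent first
    letter, drawn from a finite per-region FSA pool so that partial
    (first-three-character) agreement between unrelated records is possible
    but rare."""
    letters = np.array(list("ABCEGHJKLMNPRSTVWXYZ"))
    first = {code: letter for code, _, letter in REGION_TABLE}
    pools = {}
    for code, _, letter in REGION_TABLE:
        d = rng.integers(0, 10, size=_FSAS_PER_REGION)
        l2 = letters[rng.integers(0, len(letters), size=_FSAS_PER_REGION)]
        pools[code] = np.array([f"{letter}{di}{li}" for di, li in zip(d, l2)])
    n = len(regions)
    fsa = np.empty(n, dtype=object)
    for code in first:
        mask = regions == code
        k = int(mask.sum())
        if k:
            fsa[mask] = pools[code][rng.integers(0, _FSAS_PER_REGION, size=k)]
    ldu = np.array(
        [f"{a}{b}{c}" for a, b, c in zip(
            rng.integers(0, 10, size=n),
            letters[rng.integers(0, len(letters), size=n)],
            rng.integers(0, 10, size=n))],
        dtype=object)
    return np.array([f"{f} {l}" for f, l in zip(fsa, ldu)], dtype=object)


def _age_at_death(rng: np.random.Generator, mixture: list, n: int) -> np.ndarray:
    """Days of life at death: mixture over <24 h / 1-6 d / 7-27 d / 28-364 d,
    uniform inside the neonatal buckets and truncated-exponential (mean 80 d)
    in the post-neonatal bucket."""
    comp = rng.choice(4, size=n, p=np.asarray(mixture) / np.sum(mixture))
    days = np.zeros(n, dtype=int)
    m = comp == 1
    days[m] = rng.integers(1, 7, size=int(m.sum()))
    m = comp == 2
    days[m] = rng.integers(7, 28, size=int(m.sum()))
    m = comp == 3
    k = int(m.sum())
    scale, span = 80.0, 364 - 28
    u = rng.random(k)
    days[m] = 28 + np.floor(
        -scale * np.log1p(-u * (1 - np.exp(-span / scale)))).astype(int)
    return days


def generate_cohort(config: CohortConfig):
    """Generate the full true cohort before any corruption.

    Returns ``(births, deaths, truth)``: all birth records (live births plus
    stillbirths), all infant deaths among the live births (whatever their
    death date), and the truth map linking each death to its birth record.
    Deterministic for a fixed ``config.seed``.
    """
    n = config.n_births
    rng = _rng(config.seed, 1)

    bw_bins = config.birthweight_bins
    ga_bins = config.ga_bins
    bw_idx = rng.choice(len(bw_bins), size=n,
                        p=np.array([b.proportion for b in bw_bins]))
    cond = np.asarray(config.ga_given_bw)
    ga_idx = np.empty(n, dtype=int)
    for i in range(len(bw_bins)):
        mask = bw_idx == i
        k = int(mask.sum())
        if k:
            ga_idx[mask] = rng.choice(len(ga_bins), size=k, p=cond[i] / cond[i].sum())

    bw_g = np.empty(n, dtype=int)
    for i, b in enumerate(bw_bins):
        mask = bw_idx == i
        k = int(mask.sum())
        if k:
            bw_g[mask] = rng.integers(int(b.lo), int(b.hi), size=k)
    ga_wk = np.empty(n, dtype=int)
    for j, g in enumerate(ga_bins):
        mask = ga_idx == j
        k = int(mask.sum())
        if k:
            ga_wk[mask] = _weeks_within_bin(rng, int(g.lo), int(g.hi), g.label, k)

    y0, y1 = config.years
    start = np.datetime64(f"{y0}-01-01")
    ndays = int((np.datetime64(f"{y1 + 1}-01-01") - start) / np.timedelta64(1, "D"))
    dob = start + rng.integers(0, ndays, size=n).astype("timedelta64[D]")

    regions = _sample_cat(rng, config.region_dist, n)
    hosp_no = rng.integers(1, _HOSPITALS_PER_REGION + 1, size=n)
    place = np.array([f"{r}{h:02d}" for r, h in zip(regions, hosp_no)], dtype=object)
    postal = _postal_codes(rng, regions)

    live = pd.DataFrame({
        "birth_id": [f"B{i:07d}" for i in range(n)],
        "encoded_identifier": [f"E{i:09d}" for i in range(n)],
        "dob": dob,
        "sex": _sample_cat(rng, config.sex_dist, n),
        "place_code": place,
        "postal_code": postal,
        "birthweight_g": bw_g,
        "ga_weeks": ga_wk,
        "maternal_age": _sample_cat(rng, config.maternal_age_dist, n),
        "parity": _sample_cat(rng, config.parity_dist, n),
        "plurality": _sample_cat(rng, config.plurality_dist, n),
        "income_quintile": _sample_cat(rng, config.income_quintile_dist, n),
        "region": regions,
        "rural": rng.random(n) < config.rural_fraction,
        "stillbirth_flag": False,
        "orphan_flag": rng.random(n) < _ORPHAN_FRACTION,
        "bw_bin": np.array([bw_bins[i].label for i in bw_idx], dtype=object),
        "ga_bin": np.array([ga_bins[j].label for j in ga_idx], dtype=object),
    })

    births = pd.concat(
        [live, _stillbirths(config, rng, n)], ignore_index=True)[BIRTH_COLUMNS]

    # infant deaths among the live births, per birthweight-bin probability
    mort = np.array([b.mortality for b in bw_bins])[bw_idx]
    died = rng.random(n) < mort
    idx = np.flatnonzero(died)
    nd = len(idx)
    age = _age_at_death(_rng(config.seed, 2), config.age_at_death_model, nd)
    drng = _rng(config.seed, 3)
    pod = _place_of_death(drng, place[idx])
    deaths = pd.DataFrame({
        "death_id": [f"D{i:06d}" for i in range(nd)],
        "encoded_identifier": live["encoded_identifier"].to_numpy()[idx],
        "dob": dob[idx],
        "dod": dob[idx] + age.astype("timedelta64[D]"),
        "place_of_death_code": pod,
        "sex": live["sex"].to_numpy()[idx],
        "postal_code": postal[idx],
        "icd10_cause": _sample_cat(drng, config.cause_mix, nd),
        "age_at_death_days": age,
    })[DEATH_COLUMNS]

    truth = TruthMap(pd.DataFrame({
        "death_id": deaths["death_id"],
        "birth_id": pd.array(live["birth_id"].to_numpy()[idx], dtype="string"),
        "reason": "",
    })[TRUTH_COLUMNS])
    return births, deaths, truth


def _stillbirths(config: CohortConfig, rng: np.random.Generator,
                 n_live: int) -> pd.DataFrame:
    """Maternal stillbirth records added to the reference file (skewed toward
    low birthweight); never a live-birth denominator member."""
    n_sb = int(round(config.stillbirth_fraction * n_live))
    if n_sb == 0:
        return pd.DataFrame(columns=BIRTH_COLUMNS)
    bw_bins = config.birthweight_bins
    w = np.array([b.mortality + 1e-3 for b in bw_bins])
    bw_idx = rng.choice(len(bw_bins), size=n_sb, p=w / w.sum())
    bw_g = np.array([rng.integers(int(bw_bins[i].lo), int(bw_bins[i].hi))
                     for i in bw_idx])
    ga_wk = np.clip(20 + (bw_g // 150), 20, 42)
    y0, y1 = config.years
    start = np.datetime64(f"{y0}-01-01")
    ndays = int((np.datetime64(f"{y1 + 1}-01-01") - start) / np.timedelta64(1, "D"))
    regions = _sample_cat(rng, config.region_dist, n_sb)
    hosp_no = rng.integers(1, _HOSPITALS_PER_REGION + 1, size=n_sb)
    return pd.DataFrame({
        "birth_id": [f"S{i:07d}" for i in range(n_sb)],
        "encoded_identifier": [f"ES{i:08d}" for i in range(n_sb)],
        "dob": start + rng.integers(0, ndays, size=n_sb).astype("timedelta64[D]"),
        "sex": _sample_cat(rng, config.sex_dist, n_sb),
        "place_code": [f"{r}{h:02d}" for r, h in zip(regions, hosp_no)],
        "postal_code": _postal_codes(rng, regions),
        "birthweight_g": bw_g,
        "ga_weeks": ga_wk,
        "maternal_age": _sample_cat(rng, config.maternal_age_dist, n_sb),
        "parity": _sample_cat(rng, config.parity_dist, n_sb),
        "plurality": _sample_cat(rng, config.plurality_dist, n_sb),
        "income_quintile": _sample_cat(rng, config.income_quintile_dist, n_sb),
        "region": regions,
        "rural": rng.random(n_sb) < config.rural_fraction,
        "stillbirth_flag": True,
        "orphan_flag": False,
        "bw_bin": np.array([bw_bins[i].label for i in bw_idx], dtype=object),
        "ga_bin": "",
    })


def _place_of_death(rng: np.random.Generator,
                    birth_place: np.ndarray) -> np.ndarray:
    """Most infants die at the birth hospital; some at another facility,
    elsewhere, or with the field missing."""
    n = len(birth_place)
    comp = rng.choice(4, size=n, p=np.array(_PLACE_OF_DEATH_MIX))
    out = birth_place.astype(object).copy()
    m = comp == 1
    k = int(m.sum())
    if k:
        regions = np.array([p[:3] for p in birth_place[m]])
        out[m] = [f"{r}{h:02d}" for r, h in
                  zip(regions, rng.integers(1, _HOSPITALS_PER_REGION + 1, size=k))]
    out[comp == 2] = "OTHER"
    out[comp == 3] = ""
    return out


def corrupt_and_split(births: pd.DataFrame, deaths: pd.DataFrame,
                      truth: TruthMap, corruption: CorruptionConfig,
                      seed: int, death_years: tuple[int, int] = (2010, 2011)):
    """Apply the collection rules and field corruption, producing the two
    registry files the linkage actually sees.

    Returns ``(reference, death_file, truth_out)`` where ``reference``
    excludes sub-threshold and out-of-hospital/late-termination births but
    includes stillbirth and orphan records, ``death_file`` holds deaths
    registered within ``death_years`` with fields perturbed, and
    ``truth_out`` covers exactly the registered deaths (birth_id <NA> plus a
    reason code where the birth record was removed).
    """
    rng = _rng(seed, 11)
    births = births.copy()
    deaths = deaths.copy()
    truth_tab = truth.table.set_index("death_id")

    reason = pd.Series("", index=births["birth_id"], dtype=object)

    if corruption.subthreshold_rule:
        sub = (births["birthweight_g"] < 500) & (births["ga_weeks"] < 20)
        reason.loc[births.loc[sub, "birth_id"]] = REASON_SUBTHRESHOLD

    live_ids = births.loc[~births["stillbirth_flag"], "birth_id"]
    ooh = live_ids[rng.random(len(live_ids)) < corruption.p_out_of_hospital]
    unset = reason.loc[ooh] == ""
    reason.loc[ooh[unset.to_numpy()]] = REASON_OUT_OF_HOSPITAL

    lt_deaths = deaths.loc[rng.random(len(deaths)) < corruption.p_late_termination,
                           "death_id"]
    lt_births = truth_tab.loc[truth_tab.index.intersection(lt_deaths), "birth_id"]
    lt_births = lt_births.dropna()
    unset = reason.loc[lt_births] == ""
    reason.loc[lt_births[unset.to_numpy()]] = REASON_LATE_TERMINATION

    removed = reason[reason != ""].index
    reference = births[~births["birth_id"].isin(removed)].copy()

    # borderline-viability deaths recorded as stillbirths in the reference
    bw_by_birth = births.set_index("birth_id")["birthweight_g"]
    death_birth = truth_tab.reindex(deaths["death_id"])["birth_id"].to_numpy(dtype=object)
    death_bw = bw_by_birth.reindex(pd.Index(death_birth)).to_numpy(dtype=float)
    cand = deaths["death_id"][
        (death_bw < 1000)
        & (rng.random(len(deaths)) < corruption.p_stillbirth_misclass)]
    misclass_births = truth_tab.loc[truth_tab.index.intersection(cand), "birth_id"].dropna()
    keep = misclass_births.isin(reference["birth_id"])
    misclass_births = misclass_births[keep.to_numpy()]
    reference.loc[reference["birth_id"].isin(misclass_births), "stillbirth_flag"] = True

    # registration window
    dod_year = pd.to_datetime(deaths["dod"]).dt.year
    registered = deaths[(dod_year >= death_years[0])
                        & (dod_year <= death_years[1])].copy().reset_index(drop=True)

    # truth for registered deaths
    tr = truth_tab.reindex(registered["death_id"]).reset_index()
    birth_reason = reason.reindex(tr["birth_id"].astype(object)).to_numpy(dtype=object)
    removed_mask = pd.Series(birth_reason).fillna("").to_numpy(dtype=object) != ""
    tr.loc[removed_mask, "reason"] = birth_reason[removed_mask]
    tr["birth_id"] = tr["birth_id"].astype("string")
    tr.loc[removed_mask, "birth_id"] = pd.NA
    mis = tr["birth_id"].isin(misclass_births).to_numpy()
    tr.loc[mis, "reason"] = REASON_STILLBIRTH_MISCLASS

    nd = len(registered)
    # deaths with no hospital birth never carry a hospital identifier
    registered.loc[removed_mask, "encoded_identifier"] = ""
    blank = rng.random(nd) < corruption.p_identifier_missing_on_death
    registered.loc[blank, "encoded_identifier"] = ""

    shift = rng.random(nd) < corruption.p_dob_shift
    direction = rng.choice(np.array([-1, 1]), size=nd)
    dob = pd.to_datetime(registered["dob"]).to_numpy()
    dob[shift] = dob[shift] + (direction[shift]).astype("timedelta64[D]")
    registered["dob"] = dob

    typo = rng.random(nd) < corruption.p_postal_typo
    registered.loc[typo, "postal_code"] = [
        _postal_typo(rng, pc) for pc in registered.loc[typo, "postal_code"]]

    registered.loc[rng.random(nd) < corruption.p_sex_missing, "sex"] = ""

    # out-of-hospital births more often die outside hospital
    ooh_death = (tr["reason"] == REASON_OUT_OF_HOSPITAL).to_numpy()
    flip = ooh_death & (rng.random(nd) < 0.5)
    registered.loc[flip, "place_of_death_code"] = "OTHER"

    return reference, registered, TruthMap(tr[TRUTH_COLUMNS])


def _postal_typo(rng: np.random.Generator, pc: str) -> str:
    """Perturb one character of the last (non-FSA) half of a postal code."""
    if not isinstance(pc, str) or len(pc) < 7:
        return pc
    pos = int(rng.integers(4, 7))
    ch = pc[pos]
    if ch.isdigit():
        new = str((int(ch) + int(rng.integers(1, 10))) % 10)
    else:
        letters = "ABCEGHJKLMNPRSTVWXYZ".replace(ch, "")
        new = letters[int(rng.integers(0, len(letters)))]
    return pc[:pos] + new + pc[pos + 1:]


def simulate(cohort_cfg: CohortConfig, corruption: CorruptionConfig,
             seed: int | None = None):
    """Convenience wrapper: generate the cohort and apply corruption.

    Returns ``(reference, death_file, truth)`` ready for linkage.
    """
    if seed is not None:
        cohort_cfg = cohort_cfg.model_copy(update={"seed": seed})
    births, deaths, truth = generate_cohort(cohort_cfg)
    return corrupt_and_split(births, deaths, truth, corruption,
                             cohort_cfg.seed, cohort_cfg.death_years)
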