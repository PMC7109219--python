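"""Deterministic + Fellegi-Sunter probabilistic linkage of infant death
registrations to hospital birth records.

The linkage runs in two passes.  A deterministic pass joins on the unique
encoded identifier where it is present on both files (demoting any
ambiguous identifier).  Residual deaths then go through classical
Fellegi-Sunter probabilistic linkage on the four fields shared by both
registries -- infant date of birth, place of death, infant sex, and
residential postal code -- with multi-level agreement (dates agree
exactly or within one day; postal codes agree fully or on the forward
sortation area only).  The m/u probabilities and the match prior lambda
are fitted by EM on the candidate comparison vectors under conditional
independence of fields given match status; pairs are scored with
log2(m/u) agreement weights, classified by two posterior-derived weight
thresholds, and assigned one-to-one greedily by descending weight.

By convention a missing field contributes zero weight (m = u).  The day
of birth is day 0, so a death on the date of birth is age 0 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import LinkageConfig

FIELDS = ("dob", "place", "sex", "postal")
#: number of informative (non-missing) levels per field; the missing level
#: is always coded as this value
N_LEVELS = {"dob": 3, "place": 2, "sex": 2, "postal": 3}

# dob levels
DOB_EXACT, DOB_ADJACENT, DOB_DISAGREE = 0, 1, 2
# place / sex levels
AGREE, DISAGREE = 0, 1
# postal levels
POSTAL_EXACT, POSTAL_FSA, POSTAL_DISAGREE = 0, 1, 2

PARAM_CLAMP = 1e-6

LINK_COLUMNS = ["death_id", "birth_id", "weight", "stage", "decision"]


@dataclass(frozen=True)
class ComparisonVector:
    """Agreement levels of one death-birth pair on the four linkage fields.

    Each level is an integer code; ``N_LEVELS[field]`` encodes missing,
    which is distinct from disagreement.
    """

    dob: int
    place: int
    sex: int
    postal: int

    def as_array(self) -> np.ndarray:
        return np.array([self.dob, self.place, self.sex, self.postal], dtype=int)


@dataclass
class FSParams:
    """Fellegi-Sunter parameters: per field and agreement level,
    m = P(level | true match), u = P(level | non-match), and the prior
    match probability lambda for a candidate pair."""

    m: dict[str, np.ndarray]
    u: dict[str, np.ndarray]
    lam: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def validate(self) -> None:
        for f in FIELDS:
            for probs, name in ((self.m[f], "m"), (self.u[f], "u")):
                if abs(float(np.sum(probs)) - 1.0) > 1e-9:
                    raise ValueError(f"{name}[{f}] must sum to 1")
                if np.any(probs < 0) or np.any(probs > 1):
                    raise ValueError(f"{name}[{f}] out of [0,1]")
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lambda must lie in (0,1)")

    def weight_tables(self) -> dict[str, np.ndarray]:
        """Per-field log2(m/u) with a trailing 0 entry for the missing level."""
        out = {}
        for f in FIELDS:
            w = np.log2(np.clip(self.m[f], PARAM_CLAMP, None)
                        / np.clip(self.u[f], PARAM_CLAMP, None))
            out[f] = np.append(w, 0.0)
        return out


@dataclass
class PeriodLinkedFile:
    """Linked death-birth pairs, unlinked deaths, and the live-birth
    denominator for one death-registration period."""

    links: pd.DataFrame            # decision == "link" rows only
    possible: pd.DataFrame         # reported, not linked
    unlinked: pd.DataFrame         # death records without a link
    deaths: pd.DataFrame           # every registered death
    reference: pd.DataFrame        # full reference file used
    denominator: pd.DataFrame      # live births inside the death window
    death_years: tuple[int, int]
    birth_years: tuple[int, int]
    summary: dict
    params: FSParams | None = None

    def linked_deaths(self) -> pd.DataFrame:
        """Registered deaths joined with the attributes of their linked birth
        record (live-birth links only; stillbirth reclassifications excluded)."""
        live_links = self.links[~self.links["reclassified"]]
        merged = self.deaths.merge(
            live_links[["death_id", "birth_id"]], on="death_id", how="inner")
        return merged.merge(
            self.reference.drop(columns=["encoded_identifier"]),
            on="birth_id", how="left", suffixes=("", "_birth"))

    def unlinked_deaths(self) -> pd.DataFrame:
        return self.unlinked


# ---------------------------------------------------------------------------
# deterministic pass
# ---------------------------------------------------------------------------

def deterministic_link(deaths: pd.DataFrame, reference: pd.DataFrame):
    """Exact join on the encoded identifier.

    A pair is emitted iff the identifier is present on both sides, equal,
    and unique within each file; ambiguous identifiers are demoted to the
    residual set with a warning.  Returns ``(matches, residual_deaths)``.
    """
    d_id = deaths["encoded_identifier"].fillna("").astype(str)
    r_id = reference["encoded_identifier"].fillna("").astype(str)

    d_dupes = d_id[(d_id != "") & d_id.duplicated(keep=False)]
    if len(d_dupes):
        warnings.warn(
            f"{d_dupes.nunique()} duplicate identifier(s) in the death file; "
            "all occurrences demoted to the probabilistic pass")
    r_counts = r_id[r_id != ""].value_counts()
    ambiguous_ref = set(r_counts[r_counts > 1].index)
    if ambiguous_ref:
        warnings.warn(
            f"{len(ambiguous_ref)} identifier(s) map to multiple reference "
            "records; demoted")

    usable = (d_id != "") & ~d_id.isin(set(d_dupes)) & ~d_id.isin(ambiguous_ref)
    ref_map = reference.loc[r_id != "", ["encoded_identifier", "birth_id"]]
    ref_map = ref_map[~ref_map["encoded_identifier"].isin(ambiguous_ref)]
    merged = deaths.loc[usable, ["death_id", "encoded_identifier"]].merge(
        ref_map, on="encoded_identifier", how="inner")

    matches = pd.DataFrame({
        "death_id": merged["death_id"],
        "birth_id": merged["birth_id"],
        "weight": np.inf,
        "stage": "deterministic",
        "decision": "link",
    })[LINK_COLUMNS]
    residual = deaths[~deaths["death_id"].isin(set(matches["death_id"]))].copy()
    return matches, residual


# ---------------------------------------------------------------------------
# blocking and comparison
# ---------------------------------------------------------------------------

def _fsa(pc) -> str:
    return pc[:3] if isinstance(pc, str) and len(pc) >= 3 else ""


def block_candidates(death, reference: pd.DataFrame,
                     blocking_scheme: str = "dob1") -> pd.DataFrame:
    """Reference records sharing any blocking key with one death record.

    Schemes: ``dob1`` (birth date within one day), ``dob_year_fsa`` (same
    birth year or same postal forward sortation area), ``none`` (whole file).
    """
    if blocking_scheme == "none":
        return reference
    ref_dob = pd.to_datetime(reference["dob"])
    dob = pd.to_datetime(death["dob"])
    if blocking_scheme == "dob1":
        keep = (ref_dob - dob).abs() <= pd.Timedelta(days=1)
    elif blocking_scheme == "dob_year_fsa":
        keep = ref_dob.dt.year == dob.year
        fsa = _fsa(death.get("postal_code", ""))
        if fsa:
            keep |= reference["postal_code"].astype(str).str[:3] == fsa
    else:
        raise ValueError(f"unknown blocking scheme: {blocking_scheme!r}")
    return reference[keep]


def candidate_pairs(deaths: pd.DataFrame, reference: pd.DataFrame,
                    blocking_scheme: str = "dob1") -> pd.DataFrame:
    """All (death index, reference index) candidate pairs under the scheme,
    as positional indices into the two frames."""
    di, ri = [], []
    ref_dob = pd.to_datetime(reference["dob"]).to_numpy(dtype="datetime64[D]")
    if blocking_scheme == "dob1":
        by_day: dict = {}
        for j, d in enumerate(ref_dob):
            by_day.setdefault(d, []).append(j)
        d_dob = pd.to_datetime(deaths["dob"]).to_numpy(dtype="datetime64[D]")
        one = np.timedelta64(1, "D")
        for i, d in enumerate(d_dob):
            cand: list = []
            for key in (d - one, d, d + one):
                cand.extend(by_day.get(key, ()))
            di.extend([i] * len(cand))
            ri.extend(cand)
    elif blocking_scheme == "dob_year_fsa":
        ref_year = ref_dob.astype("datetime64[Y]").astype(int)
        ref_fsa = reference["postal_code"].astype(str).str[:3].to_numpy()
        by_year: dict = {}
        for j, y in enumerate(ref_year):
            by_year.setdefault(y, []).append(j)
        by_fsa: dict = {}
        for j, f in enumerate(ref_fsa):
            by_fsa.setdefault(f, []).append(j)
        d_dob = pd.to_datetime(deaths["dob"]).to_numpy(dtype="datetime64[D]")
        d_year = d_dob.astype("datetime64[Y]").astype(int)
        for i in range(len(deaths)):
            cand = set(by_year.get(d_year[i], ()))
            fsa = _fsa(deaths["postal_code"].iloc[i])
            if fsa:
                cand |= set(by_fsa.get(fsa, ()))
            cand = sorted(cand)
            di.extend([i] * len(cand))
            ri.extend(cand)
    elif blocking_scheme == "none":
        n, m = len(deaths), len(reference)
        di = np.repeat(np.arange(n), m)
        ri = np.tile(np.arange(m), n)
    else:
        raise ValueError(f"unknown blocking scheme: {blocking_scheme!r}")
    return pd.DataFrame({"death_idx": np.asarray(di, dtype=int),
                         "birth_idx": np.asarray(ri, dtype=int)})


def compare(death, birth) -> ComparisonVector:
    """Field-agreement pattern for one death-birth pair.

    Dates compare exact / within one day / disagree; postal codes compare
    exact / FSA-only (first three characters) / disagree; a missing or
    unparseable value on either side yields that field's missing level.
    """
    arr = compare_arrays(
        np.array([_to_day(death.get("dob"))], dtype="datetime64[D]"),
        np.array([_to_day(birth.get("dob"))], dtype="datetime64[D]"),
        np.array([death.get("place_of_death_code", "")], dtype=object),
        np.array([birth.get("place_code", "")], dtype=object),
        np.array([death.get("sex", "")], dtype=object),
        np.array([birth.get("sex", "")], dtype=object),
        np.array([death.get("postal_code", "")], dtype=object),
        np.array([birth.get("postal_code", "")], dtype=object),
    )[0]
    return ComparisonVector(*(int(x) for x in arr))


def _to_day(value):
    try:
        ts = pd.to_datetime(value)
        if pd.isna(ts):
            return np.datetime64("NaT")
        return np.datetime64(ts, "D")
    except (ValueError, TypeError):
        return np.datetime64("NaT")


def compare_arrays(d_dob, b_dob, d_place, b_place, d_sex, b_sex,
                   d_postal, b_postal) -> np.ndarray:
    """Vectorized comparison: one (n, 4) array of level codes."""
    n = len(d_dob)
    out = np.empty((n, 4), dtype=int)

    delta = (d_dob - b_dob) / np.timedelta64(1, "D")
    dob_missing = np.isnat(d_dob) | np.isnat(b_dob)
    with np.errstate(invalid="ignore"):
        out[:, 0] = np.where(dob_missing, N_LEVELS["dob"],
                             np.where(delta == 0, DOB_EXACT,
                                      np.where(np.abs(delta) == 1,
                                               DOB_ADJACENT, DOB_DISAGREE)))

    def _clean(a):
        s = pd.Series(a, dtype=object).fillna("").astype(str)
        return s.str.strip().to_numpy(dtype=object)

    dp, bp = _clean(d_place), _clean(b_place)
    missing = (dp == "") | (bp == "")
    out[:, 1] = np.where(missing, N_LEVELS["place"],
                         np.where(dp == bp, AGREE, DISAGREE))

    ds, bs = _clean(d_sex), _clean(b_sex)
    missing = (ds == "") | (bs == "")
    out[:, 2] = np.where(missing, N_LEVELS["sex"],
                         np.where(ds == bs, AGREE, DISAGREE))

    dpc, bpc = _clean(d_postal), _clean(b_postal)
    missing = (dpc == "") | (bpc == "")
    exact = dpc == bpc
    fsa = np.array([a[:3] == b[:3] and len(a) >= 3 for a, b in zip(dpc, bpc)])
    out[:, 3] = np.where(missing, N_LEVELS["postal"],
                         np.where(exact, POSTAL_EXACT,
                                  np.where(fsa, POSTAL_FSA, POSTAL_DISAGREE)))
    return out


def compare_pairs(deaths: pd.DataFrame, reference: pd.DataFrame,
                  pairs: pd.DataFrame) -> np.ndarray:
    """Comparison vectors for every candidate pair (rows align with pairs)."""
    di = pairs["death_idx"].to_numpy()
    ri = pairs["birth_idx"].to_numpy()
    return compare_arrays(
        pd.to_datetime(deaths["dob"]).to_numpy(dtype="datetime64[D]")[di],
        pd.to_datetime(reference["dob"]).to_numpy(dtype="datetime64[D]")[ri],
        deaths["place_of_death_code"].to_numpy(dtype=object)[di],
        reference["place_code"].to_numpy(dtype=object)[ri],
        deaths["sex"].to_numpy(dtype=object)[di],
        reference["sex"].to_numpy(dtype=object)[ri],
        deaths["postal_code"].to_numpy(dtype=object)[di],
        reference["postal_code"].to_numpy(dtype=object)[ri],
    )


# ---------------------------------------------------------------------------
# EM estimation of m, u, lambda
# ---------------------------------------------------------------------------

def default_init(vectors: np.ndarray, lam: float = 0.01) -> FSParams:
    """Moment-style start: m puts 0.9 on each field's top agreement level
    (remainder spread uniformly), u equals the empirical level frequencies
    over all candidate pairs."""
    m, u = {}, {}
    for k, f in enumerate(FIELDS):
        L = N_LEVELS[f]
        mk = np.full(L, 0.1 / (L - 1)) if L > 1 else np.array([1.0])
        mk[0] = 0.9
        m[f] = mk
        obs = vectors[:, k]
        obs = obs[obs < L]
        if len(obs):
            counts = np.bincount(obs, minlength=L).astype(float)
            counts = np.clip(counts, 0.5, None)
            u[f] = counts / counts.sum()
        else:
            u[f] = np.full(L, 1.0 / L)
    return FSParams(m=m, u=u, lam=float(np.clip(lam, PARAM_CLAMP, 1 - PARAM_CLAMP)))


def _pattern_counts(vectors: np.ndarray):
    pats, counts = np.unique(vectors, axis=0, return_counts=True)
    return pats, counts.astype(float)


def _class_loglik(pats: np.ndarray, probs: dict[str, np.ndarray]) -> np.ndarray:
    """log P(pattern | class); missing levels contribute nothing."""
    ll = np.zeros(len(pats))
    for k, f in enumerate(FIELDS):
        L = N_LEVELS[f]
        p = np.log(np.clip(probs[f], PARAM_CLAMP, None))
        lev = pats[:, k]
        informative = lev < L
        ll[informative] += p[lev[informative]]
    return ll


def estimate_fs_params(vectors: np.ndarray, init: FSParams | None = None,
                       tol: float = 1e-6, max_iter: int = 200) -> FSParams:
    """Fit m, u and lambda by EM on comparison vectors.

    Two-class latent mixture with conditional independence of fields given
    class; missing levels are treated as uninformative.  The log-likelihood
    is non-decreasing across iterations; parameters that converge to a
    boundary are clamped into [1e-6, 1 - 1e-6] with a warning.
    """
    vectors = np.asarray(vectors, dtype=int)
    if vectors.ndim != 2 or vectors.shape[1] != len(FIELDS) or not len(vectors):
        raise ValueError("vectors must be a non-empty (n, 4) integer array")
    pats, counts = _pattern_counts(vectors)
    params = init if init is not None else default_init(vectors)
    params.validate()
    m = {f: params.m[f].astype(float).copy() for f in FIELDS}
    u = {f: params.u[f].astype(float).copy() for f in FIELDS}
    lam = params.lam
    trace: list[float] = []
    clamped = False
    n_iter = 0
    converged = False

    for n_iter in range(1, max_iter + 1):
        log_m = _class_loglik(pats, m) + np.log(lam)
        log_u = _class_loglik(pats, u) + np.log1p(-lam)
        mx = np.maximum(log_m, log_u)
        denom = mx + np.log(np.exp(log_m - mx) + np.exp(log_u - mx))
        g = np.exp(log_m - denom)  # posterior match probability per pattern
        trace.append(float(np.sum(counts * denom)))

        new_lam = float(np.sum(counts * g) / np.sum(counts))
        new_m, new_u = {}, {}
        for k, f in enumerate(FIELDS):
            L = N_LEVELS[f]
            lev = pats[:, k]
            informative = lev < L
            wm = counts * g
            wu = counts * (1.0 - g)
            mk = np.array([wm[informative & (lev == l)].sum() for l in range(L)])
            uk = np.array([wu[informative & (lev == l)].sum() for l in range(L)])
            mk = mk / mk.sum() if mk.sum() > 0 else np.full(L, 1.0 / L)
            uk = uk / uk.sum() if uk.sum() > 0 else np.full(L, 1.0 / L)
            if np.any(mk < PARAM_CLAMP) or np.any(mk > 1 - PARAM_CLAMP) \
                    or np.any(uk < PARAM_CLAMP) or np.any(uk > 1 - PARAM_CLAMP):
                clamped = True
            # clamp after normalizing; the simplex deviates by at most a few
            # parts in 1e6, which the likelihood tolerates
            new_m[f] = np.clip(mk, PARAM_CLAMP, 1 - PARAM_CLAMP)
            new_u[f] = np.clip(uk, PARAM_CLAMP, 1 - PARAM_CLAMP)
        if not (PARAM_CLAMP < new_lam < 1 - PARAM_CLAMP):
            clamped = True
            new_lam = float(np.clip(new_lam, PARAM_CLAMP, 1 - PARAM_CLAMP))

        delta = abs(new_lam - lam)
        for f in FIELDS:
            delta = max(delta, float(np.abs(new_m[f] - m[f]).max()),
                        float(np.abs(new_u[f] - u[f]).max()))
        m, u, lam = new_m, new_u, new_lam
        if delta < tol:
            converged = True
            break

    if clamped:
        warnings.warn("EM: parameter(s) hit the [1e-6, 1-1e-6] boundary and "
                      "were clamped")
    return FSParams(m=m, u=u, lam=lam, loglik_trace=trace,
                    n_iter=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# scoring and classification
# ---------------------------------------------------------------------------

def score_pair(vector, params: FSParams) -> float:
    """Total log2 agreement weight of one comparison vector."""
    if isinstance(vector, ComparisonVector):
        vector = vector.as_array()
    return float(score_vectors(np.asarray(vector, dtype=int)[None, :], params)[0])


def score_vectors(vectors: np.ndarray, params: FSParams) -> np.ndarray:
    """Vectorized log2 sum of m/u weights; missing levels contribute 0."""
    tables = params.weight_tables()
    w = np.zeros(len(vectors))
    for k, f in enumerate(FIELDS):
        w += tables[f][vectors[:, k]]
    return w


def posterior_weight_threshold(params: FSParams, posterior: float) -> float:
    """Weight w such that P(match | w) equals ``posterior`` under the fitted
    prior: w = log2(odds(posterior) / odds(lambda))."""
    odds_post = posterior / (1.0 - posterior)
    odds_prior = params.lam / (1.0 - params.lam)
    return float(np.log2(odds_post / odds_prior))


def classify_and_assign(scored: pd.DataFrame, upper_threshold: float,
                        lower_threshold: float) -> pd.DataFrame:
    """Fellegi-Sunter decision rule plus greedy one-to-one assignment.

    Pairs with weight >= upper become candidate links; weight < lower are
    non-links; in between are reported as ``possible`` (not linked).
    Candidate links are assigned one-to-one in descending weight order,
    ties broken by (death_id, birth_id); already-assigned records are
    skipped, and skipped candidates fall back to ``possible``.
    """
    if lower_threshold > upper_threshold:
        raise ValueError("lower_threshold must not exceed upper_threshold")
    cand = scored[scored["weight"] >= upper_threshold].sort_values(
        ["weight", "death_id", "birth_id"], ascending=[False, True, True])
    used_d: set = set()
    used_b: set = set()
    link_rows = []
    demoted = []
    for row in cand.itertuples(index=False):
        if row.death_id in used_d or row.birth_id in used_b:
            demoted.append((row.death_id, row.birth_id, row.weight))
            continue
        used_d.add(row.death_id)
        used_b.add(row.birth_id)
        link_rows.append((row.death_id, row.birth_id, row.weight))

    links = pd.DataFrame(link_rows, columns=["death_id", "birth_id", "weight"])
    links["stage"] = "probabilistic"
    links["decision"] = "link"

    mid = scored[(scored["weight"] >= lower_threshold)
                 & (scored["weight"] < upper_threshold)]
    parts = [df for df in
             (mid[["death_id", "birth_id", "weight"]],
              pd.DataFrame(demoted, columns=["death_id", "birth_id", "weight"]))
             if len(df)]
    possible = (pd.concat(parts, ignore_index=True) if parts
                else pd.DataFrame(columns=["death_id", "birth_id", "weight"]))
    possible["stage"] = "probabilistic"
    possible["decision"] = "possible"
    parts = [df[LINK_COLUMNS] for df in (links, possible) if len(df)]
    if not parts:
        return pd.DataFrame(columns=LINK_COLUMNS)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# period linkage driver
# ---------------------------------------------------------------------------

def run_period_linkage(death_file: pd.DataFrame, reference_file: pd.DataFrame,
                       config: LinkageConfig | None = None,
                       death_years: tuple[int, int] = (2010, 2011)
                       ) -> PeriodLinkedFile:
    """Full two-pass linkage producing a period linked file.

    The live-birth denominator comprises reference live births whose birth
    date falls inside the death-registration window; earlier births stay in
    the reference (linkable) but outside the denominator.  Links to
    stillbirth records are reported as reclassifications and never counted
    as live-birth links; every registered death appears exactly once in the
    output, linked or unlinked.
    """
    config = config or LinkageConfig()
    if reference_file.empty:
        raise ValueError("reference file is empty")
    ref_years = pd.to_datetime(reference_file["dob"]).dt.year
    birth_years = (int(ref_years.min()), int(ref_years.max()))
    if not (birth_years[0] <= death_years[0] - 1
            and birth_years[1] >= death_years[1]):
        warnings.warn("reference birth years do not fully cover the period "
                      "linked file window (first death year - 1 .. last death year)")

    dod_year = pd.to_datetime(death_file["dod"]).dt.year
    in_period = (dod_year >= death_years[0]) & (dod_year <= death_years[1])
    if (~in_period).any():
        warnings.warn(f"{int((~in_period).sum())} death(s) outside the "
                      "registration period excluded")
    deaths = death_file[in_period].reset_index(drop=True)

    det_links, residual = deterministic_link(deaths, reference_file)

    params = None
    prob = pd.DataFrame(columns=LINK_COLUMNS)
    if len(residual):
        used_births = set(det_links["birth_id"])
        open_ref = reference_file[
            ~reference_file["birth_id"].isin(used_births)].reset_index(drop=True)
        pairs = candidate_pairs(residual, open_ref, config.blocking_scheme)
        if len(pairs):
            vectors = compare_pairs(residual, open_ref, pairs)
            lam0 = min(max(len(residual) / len(pairs), PARAM_CLAMP), 0.5)
            params = estimate_fs_params(
                vectors, init=default_init(vectors, lam=lam0),
                tol=config.em_tol, max_iter=config.em_max_iter)
            scored = pd.DataFrame({
                "death_id": residual["death_id"].to_numpy()[pairs["death_idx"]],
                "birth_id": open_ref["birth_id"].to_numpy()[pairs["birth_idx"]],
                "weight": score_vectors(vectors, params),
            })
            upper = posterior_weight_threshold(params, config.upper_posterior)
            lower = posterior_weight_threshold(params, config.lower_posterior)
            prob = classify_and_assign(scored, upper, lower)

    parts = [df for df in (det_links, prob) if len(df)]
    all_pairs = (pd.concat(parts, ignore_index=True) if parts
                 else pd.DataFrame(columns=LINK_COLUMNS))
    links = all_pairs[all_pairs["decision"] == "link"].reset_index(drop=True)
    possible = all_pairs[all_pairs["decision"] == "possible"].reset_index(drop=True)

    sb = reference_file.set_index("birth_id")["stillbirth_flag"]
    links["reclassified"] = links["birth_id"].map(sb).fillna(False).astype(bool)

    unlinked = deaths[~deaths["death_id"].isin(set(links["death_id"]))].copy()

    live = reference_file[~reference_file["stillbirth_flag"]]
    live_year = pd.to_datetime(live["dob"]).dt.year
    denominator = live[(live_year >= death_years[0])
                       & (live_year <= death_years[1])].reset_index(drop=True)

    n = len(deaths)
    summary = {
        "n_registered_deaths": n,
        "n_linked": int(len(links)),
        "n_linked_deterministic": int((links["stage"] == "deterministic").sum()),
        "n_linked_probabilistic": int((links["stage"] == "probabilistic").sum()),
        "n_possible_pairs": int(len(possible)),
        "n_unlinked": int(len(unlinked)),
        "n_reclassified_stillbirth": int(links["reclassified"].sum()),
        "prop_linked": float(len(links) / n) if n else float("nan"),
        "prop_unlinked": float(len(unlinked) / n) if n else float("nan"),
        "n_denominator_live_births": int(len(denominator)),
        "death_years": list(death_years),
        "birth_years": list(birth_years),
        "em_iterations": params.n_iter if params else 0,
        "em_converged": bool(params.converged) if params else None,
        "em_lambda": float(params.lam) if params else None,
    }
    return PeriodLinkedFile(
        links=links, possible=possible, unlinked=unlinked, deaths=deaths,
        reference=reference_file, denominator=denominator,
        death_years=death_years, birth_years=birth_years,
        summary=summary, params=params)


def evaluate_linkage(plf: PeriodLinkedFile, truth) -> dict:
    """Precision and recall of the linkage against a ground-truth map,
    overall and per stage.

    Recall denominators: overall and deterministic use every registered
    death whose true birth record is present in the reference; the
    probabilistic stage uses the subset of those left unresolved by the
    deterministic pass.
    """
    truth_tab = truth.table if hasattr(truth, "table") else truth
    tmap = dict(zip(truth_tab["death_id"], truth_tab["birth_id"]))
    linkable = {d for d, b in tmap.items() if pd.notna(b)}

    def _pr(links: pd.DataFrame, eligible: set) -> tuple[float, float]:
        if len(links) == 0:
            return float("nan"), (1.0 if not eligible else 0.0)
        correct = sum(tmap.get(d) == b
                      for d, b in zip(links["death_id"], links["birth_id"]))
        precision = correct / len(links)
        recall = (correct / len(eligible)) if eligible else float("nan")
        return precision, recall

    det = plf.links[plf.links["stage"] == "deterministic"]
    prob = plf.links[plf.links["stage"] == "probabilistic"]
    residual_linkable = linkable - set(det["death_id"])
    p_all, r_all = _pr(plf.links, linkable)
    p_det, r_det = _pr(det, linkable)
    p_prob, r_prob = _pr(prob, residual_linkable)
    return {
        "precision": p_all, "recall": r_all,
        "precision_deterministic": p_det, "recall_deterministic": r_det,
        "precision_probabilistic": p_prob, "recall_probabilistic": r_prob,
        "n_linkable": len(linkable),
        "n_linkable_residual": len(residual_linkable),
    }
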