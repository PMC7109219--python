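"""Linked-vs-unlinked death comparisons: characteristic table and tests.

Chi-square tests (no continuity correction) for categorical rows and
Mann-Whitney tests (normal approximation, tie-corrected variance, no
continuity correction) for continuous rows, mirroring the standard
linked/unlinked characteristics table of a record-linkage evaluation.
Quartiles use linear interpolation on the sorted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rates import NEONATAL_MAX_DAYS


@dataclass
class ContingencyTable:
    """r x c non-negative integer counts with labels."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] < 2 \
                or self.counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def chi_square(table: ContingencyTable | np.ndarray):
    """Pearson chi-square test of independence: statistic sum (O-E)^2/E with
    E from the margins, df = (r-1)(c-1), upper-tail p; no continuity
    correction.  A zero row/column margin is a domain error."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need at least a 2 x 2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mann_whitney(a, b):
    """Mann-Whitney U (midrank ties) with a two-sided normal-approximation
    p-value using the tie-corrected variance; identical constant samples
    give p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return len(a) * len(b) / 2.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return float(res.statistic), p


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation on sorted values."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def format_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.2g}"


def _binary_row(name: str, yes_u: int, n_u: int, yes_l: int, n_l: int,
                run_tests: bool) -> list[dict]:
    p = np.nan
    if run_tests:
        tbl = np.array([[n_u - yes_u, n_l - yes_l], [yes_u, yes_l]])
        try:
            _, _, p = chi_square(tbl)
        except ValueError:
            p = np.nan
    pct = lambda k, n: 100.0 * k / n if n else np.nan
    return [
        {"characteristic": name, "level": "No",
         "unlinked_n": n_u - yes_u, "unlinked_pct": pct(n_u - yes_u, n_u),
         "linked_n": n_l - yes_l, "linked_pct": pct(n_l - yes_l, n_l), "p": p},
        {"characteristic": name, "level": "Yes",
         "unlinked_n": yes_u, "unlinked_pct": pct(yes_u, n_u),
         "linked_n": yes_l, "linked_pct": pct(yes_l, n_l), "p": p},
    ]


def characteristics_table(linked: pd.DataFrame,
                          unlinked: pd.DataFrame) -> pd.DataFrame:
    """Characteristics of unlinked vs linked infant death records.

    Rows: calendar year of death, median (IQR) age at death, death within
    24 h, early neonatal (0-6 d), neonatal (0-27 d), post-neonatal
    (28-364 d), and location of death; each with n (%) per group and the
    test p-value.  If either group is empty the table is still emitted with
    the tests skipped.
    """
    n_l, n_u = len(linked), len(unlinked)
    run_tests = n_l > 0 and n_u > 0
    if not run_tests:
        warnings.warn("one comparison group is empty; tests skipped")

    rows: list[dict] = []

    def _years(df):
        return pd.to_datetime(df["dod"]).dt.year if len(df) else pd.Series(dtype=int)

    y_l, y_u = _years(linked), _years(unlinked)
    years = sorted(set(y_l) | set(y_u))
    p_year = np.nan
    if run_tests and len(years) >= 2:
        tbl = np.array([[int((y_u == y).sum()) for y in years],
                        [int((y_l == y).sum()) for y in years]]).T
        try:
            _, _, p_year = chi_square(tbl)
        except ValueError:
            p_year = np.nan
    for y in years:
        rows.append({
            "characteristic": "calendar year", "level": str(y),
            "unlinked_n": int((y_u == y).sum()),
            "unlinked_pct": 100.0 * (y_u == y).mean() if n_u else np.nan,
            "linked_n": int((y_l == y).sum()),
            "linked_pct": 100.0 * (y_l == y).mean() if n_l else np.nan,
            "p": p_year})

    age_l = linked["age_at_death_days"].astype(float) if n_l else np.array([])
    age_u = unlinked["age_at_death_days"].astype(float) if n_u else np.array([])
    p_age = np.nan
    if run_tests:
        _, p_age = mann_whitney(age_u, age_l)
    for name, vals, n in (("unlinked", age_u, n_u), ("linked", age_l, n_l)):
        med, q1, q3 = median_iqr(vals) if n else (np.nan, np.nan, np.nan)
        rows.append({
            "characteristic": "median (IQR) age at death (days)", "level": name,
            "unlinked_n": np.nan, "unlinked_pct": np.nan,
            "linked_n": np.nan, "linked_pct": np.nan,
            "median": med, "q1": q1, "q3": q3, "p": p_age})

    def _count(df, lo, hi):
        if not len(df):
            return 0
        a = df["age_at_death_days"].astype(int)
        return int(((a >= lo) & (a <= hi)).sum())

    for name, lo, hi in (
            ("death within 24 h", 0, 0),
            ("early neonatal death at 0-6 days", 0, 6),
            ("neonatal death at 0-27 days", 0, NEONATAL_MAX_DAYS),
            ("post-neonatal death at 28-364 days", NEONATAL_MAX_DAYS + 1, 364)):
        rows.extend(_binary_row(name, _count(unlinked, lo, hi), n_u,
                                _count(linked, lo, hi), n_l, run_tests))

    def _in_hosp(df):
        if not len(df):
            return 0
        place = df["place_of_death_code"].fillna("").astype(str)
        return int(((place != "") & (place != "OTHER")).sum())

    rows.extend(_binary_row("location of death: hospital",
                            _in_hosp(unlinked), n_u, _in_hosp(linked), n_l,
                            run_tests))
    out = pd.DataFrame(rows)
    out["p_display"] = out["p"].map(
        lambda p: "" if pd.isna(p) else format_p(float(p)))
    return out
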