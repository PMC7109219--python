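"""Infant mortality rates with exact binomial confidence intervals.

Rates are reported per 1000 live births (post-neonatal rates per 1000
neonatal survivors).  Two exact binomial interval flavours are provided:

``midp``
    The mid-p exact interval, obtained by inverting the binomial tail sums
    with the boundary outcome counted at half weight.  This is the default
    and is what reproduces the published rate tables this package is
    calibrated against.
``clopper-pearson``
    The classical Clopper-Pearson interval via Beta-quantile inversion of
    the full binomial tails: low = Beta(x, n-x+1) alpha/2 quantile (0 when
    x = 0), high = Beta(x+1, n-x) 1-alpha/2 quantile (1 when x = n).

Cells with numerator <= 5 are flagged suppressed (display masking for
small counts); the row and its values are retained for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

NEONATAL_MAX_DAYS = 27  # death at 0-27 days; post-neonatal is 28-364
INFANT_MAX_DAYS = 364


@dataclass
class RateEstimate:
    """A mortality rate: numerator, denominator, per-``scale`` rate and
    exact binomial CI, with a small-count suppression flag."""

    numerator: int
    denominator: int
    scale: float = 1000.0
    rate: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    alpha: float = 0.05
    suppressed: bool = False

    def as_dict(self) -> dict:
        return {
            "deaths": self.numerator, "denominator": self.denominator,
            "rate": self.rate, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "suppressed": self.suppressed,
        }


@dataclass
class StratumDefinition:
    """A stratifier with its bins: either categorical labels or numeric
    (label, lo, hi) edges over a birth-record attribute."""

    name: str
    column: str
    labels: list[str] = field(default_factory=list)
    edges: list[tuple[str, float, float]] = field(default_factory=list)

    def assign(self, values: pd.Series) -> pd.Series:
        if self.edges:
            out = pd.Series("missing", index=values.index, dtype=object)
            v = pd.to_numeric(values, errors="coerce")
            for label, lo, hi in self.edges:
                out[(v >= lo) & (v < hi)] = label
            return out
        vals = values.astype(object).where(values.notna(), "missing")
        known = set(self.labels)
        return vals.map(lambda x: x if x in known else "missing")

    def bin_labels(self) -> list[str]:
        return [e[0] for e in self.edges] if self.edges else list(self.labels)


def exact_binomial_ci(x: int, n: int, alpha: float = 0.05,
                      method: str = "midp") -> tuple[float, float]:
    """Exact binomial CI for a proportion, on the probability scale.

    ``method='midp'`` inverts the mid-p tail sums; ``'clopper-pearson'``
    uses the Beta-quantile form of the classical exact interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if method == "clopper-pearson":
        low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
        high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
        return low, high
    if method != "midp":
        raise ValueError("method must be 'midp' or 'clopper-pearson'")
    half = alpha / 2
    p_hat = x / n

    def upper_tail(p):  # P(X > x) + 0.5 P(X = x)
        return 0.5 * stats.binom.pmf(x, n, p) + stats.binom.sf(x, n, p)

    def lower_tail(p):  # P(X < x) + 0.5 P(X = x)
        return 0.5 * stats.binom.pmf(x, n, p) + stats.binom.cdf(x - 1, n, p)

    low = 0.0 if x == 0 else float(
        optimize.brentq(lambda p: upper_tail(p) - half, 1e-15, max(p_hat, 1e-14)))
    high = 1.0 if x == n else float(
        optimize.brentq(lambda p: lower_tail(p) - half, min(p_hat, 1 - 1e-14),
                        1 - 1e-15))
    return low, high


def mortality_rate(x: int, n: int, scale: float = 1000.0,
                   suppress_at: int = 5, alpha: float = 0.05,
                   method: str = "midp") -> RateEstimate:
    """Rate per ``scale`` with exact binomial CI; numerators <= ``suppress_at``
    are flagged suppressed (values still computed)."""
    low, high = exact_binomial_ci(x, n, alpha=alpha, method=method)
    return RateEstimate(
        numerator=int(x), denominator=int(n), scale=scale,
        rate=x / n * scale, ci_low=low * scale, ci_high=high * scale,
        alpha=alpha, suppressed=bool(x <= suppress_at))


def crude_rates(plf, scale: float = 1000.0, suppress_at: int = 5,
                alpha: float = 0.05, method: str = "midp") -> dict:
    """Crude infant, neonatal and post-neonatal mortality rates.

    The infant and neonatal numerators count ALL registered deaths (linked
    and unlinked) over live births; the post-neonatal denominator is the
    neonatal survivors (live births minus neonatal deaths).
    """
    n = len(plf.denominator)
    if n == 0:
        raise ValueError("empty live-birth denominator")
    age = plf.deaths["age_at_death_days"].astype(int)
    total = len(plf.deaths)
    neo = int((age <= NEONATAL_MAX_DAYS).sum())
    post = total - neo
    kw = dict(scale=scale, suppress_at=suppress_at, alpha=alpha, method=method)
    return {
        "infant": mortality_rate(total, n, **kw),
        "neonatal": mortality_rate(neo, n, **kw),
        "postneonatal": mortality_rate(post, n - neo, **kw),
    }


def rate_table(rows: list[tuple[str, int, int]], scale: float = 1000.0,
               suppress_at: int = 5, alpha: float = 0.05,
               method: str = "midp") -> pd.DataFrame:
    """Build a display table from (label, deaths, denominator) rows; rows
    with a zero denominator are emitted with the rate flagged undefined."""
    recs = []
    for label, x, n in rows:
        if n <= 0:
            recs.append({"bin": label, "deaths": int(x), "denominator": 0,
                         "rate": float("nan"), "ci_low": float("nan"),
                         "ci_high": float("nan"), "suppressed": x <= suppress_at,
                         "undefined": True})
            continue
        est = mortality_rate(x, n, scale=scale, suppress_at=suppress_at,
                             alpha=alpha, method=method)
        recs.append({"bin": label, **est.as_dict(), "undefined": False})
    return pd.DataFrame(recs)


def specific_rates(plf, stratum: StratumDefinition,
                   restrict=None, cumulative: list | None = None,
                   scale: float = 1000.0, suppress_at: int = 5,
                   alpha: float = 0.05, method: str = "midp") -> pd.DataFrame:
    """Stratum-specific mortality rates among the LINKED deaths.

    Numerators are linked deaths carrying the stratifying attribute; deaths
    lacking it contribute an ``excluded (missing attribute)`` line.  The
    denominator for each bin is the live-birth denominator in that bin.
    ``restrict`` optionally filters both numerator and denominator (e.g.
    birthweight >= 500 g); ``cumulative`` adds restricted summary rows as
    (label, predicate) pairs.
    """
    linked = plf.linked_deaths()
    denom = plf.denominator
    if stratum.column not in denom.columns:
        raise KeyError(f"stratifier column {stratum.column!r} absent from the "
                       "reference schema")
    if restrict is not None:
        linked = linked[restrict(linked)]
        denom = denom[restrict(denom)]

    # on the linked side, birth attributes shadowed by death fields carry a
    # _birth suffix (e.g. the infant's sex)
    num_col = (stratum.column if stratum.column in linked.columns
               else f"{stratum.column}_birth")
    num_bins = stratum.assign(linked[num_col])
    den_bins = stratum.assign(denom[stratum.column])
    n_missing = int((num_bins == "missing").sum())

    rows = []
    for label in stratum.bin_labels():
        rows.append((label, int((num_bins == label).sum()),
                     int((den_bins == label).sum())))
    for label, pred in (cumulative or []):
        rows.append((label, int(pred(linked).sum()), int(pred(denom).sum())))
    table = rate_table(rows, scale=scale, suppress_at=suppress_at,
                       alpha=alpha, method=method)
    table.attrs["n_excluded_missing"] = n_missing
    table.attrs["stratifier"] = stratum.name
    return table


def format_rate(est: RateEstimate, decimals: int = 1) -> str:
    """Display form: 'rate (low-high)' rounded per-1000 to one decimal, or
    'suppressed' for masked cells."""
    if est.suppressed:
        return "suppressed"
    return (f"{est.rate:.{decimals}f} "
            f"({est.ci_low:.{decimals}f}-{est.ci_high:.{decimals}f})")
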