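"""Rate engine: exact binomial CIs, suppression, crude and specific rates."""

import math

import numpy as np
import pandas as pd
import pytest

import vitalink as vl
from vitalink.rates import (StratumDefinition, crude_rates, exact_binomial_ci,
                            mortality_rate, rate_table, specific_rates)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def binom_sf_exact(x, n, p):
    """P(X >= x) by exhaustive summation with exact binomial coefficients."""
    return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k)
               for k in range(x, n + 1))


def cp_bounds_bruteforce(x, n, alpha=0.05, iters=80):
    """Clopper-Pearson bounds by bisection on the exhaustive tail sums."""
    if x == 0:
        low = 0.0
    else:
        lo, hi = 0.0, 1.0
        for _ in range(iters):  # find p with P(X >= x | p) = alpha/2
            mid = (lo + hi) / 2
            if binom_sf_exact(x, n, mid) < alpha / 2:
                lo = mid
            else:
                hi = mid
        low = (lo + hi) / 2
    if x == n:
        high = 1.0
    else:
        lo, hi = 0.0, 1.0
        for _ in range(iters):  # find p with P(X <= x | p) = alpha/2
            mid = (lo + hi) / 2
            if 1 - binom_sf_exact(x + 1, n, mid) > alpha / 2:
                lo = mid
            else:
                hi = mid
        high = (lo + hi) / 2
    return low, high


class TestExactBinomialCI:
    def test_boundary_closed_forms(self):
        n, alpha = 100, 0.05
        low, high = exact_binomial_ci(0, n, method="clopper-pearson")
        assert low == 0.0
        assert high == pytest.approx(1 - (alpha / 2) ** (1 / n), abs=1e-12)
        low, high = exact_binomial_ci(n, n, method="clopper-pearson")
        assert high == 1.0
        assert low == pytest.approx((alpha / 2) ** (1 / n), abs=1e-12)

    def test_clopper_pearson_matches_bruteforce_small_n(self):
        for n in range(1, 9):
            for x in range(n + 1):
                got = exact_binomial_ci(x, n, method="clopper-pearson")
                want = cp_bounds_bruteforce(x, n)
                assert got == pytest.approx(want, abs=1e-9), (x, n)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_ci(0, 0)
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 10, method="nope")

    def test_midp_interval_nested_inside_clopper_pearson(self):
        for x, n in [(3, 50), (20, 200), (0, 30), (30, 30), (363, 1150)]:
            lo_m, hi_m = exact_binomial_ci(x, n, method="midp")
            lo_c, hi_c = exact_binomial_ci(x, n, method="clopper-pearson")
            assert lo_m >= lo_c - 1e-12
            assert hi_m <= hi_c + 1e-12
            assert lo_m <= x / n <= hi_m


class TestMortalityRate:
    def test_published_row_reproduced(self):
        est = mortality_rate(595, 745)
        assert round(est.rate, 1) == 798.7
        assert round(est.ci_low, 1) == 768.7
        assert round(est.ci_high, 1) == 826.3

    def test_suppression_flag_rule(self):
        assert mortality_rate(3, 1000).suppressed
        assert not mortality_rate(6, 1000).suppressed
        est = mortality_rate(3, 1000)
        assert est.rate == pytest.approx(3.0)  # still computed

    def test_zero_numerator(self):
        est = mortality_rate(0, 1000)
        assert est.rate == 0.0
        assert est.ci_low == 0.0


class TestCrudeRates:
    def _plf(self, ages, n_denom):
        deaths = pd.DataFrame({
            "death_id": [f"D{i}" for i in range(len(ages))],
            "age_at_death_days": ages})
        denom = pd.DataFrame({"birth_id": [f"B{i}" for i in range(n_denom)]})

        class Stub:
            pass

        plf = Stub()
        plf.deaths = deaths
        plf.denominator = denom
        return plf

    def test_numerators_and_denominators(self):
        # 6 deaths: 4 neonatal (0-27 d), 2 post-neonatal
        plf = self._plf([0, 1, 10, 27, 28, 364], 3000)
        out = crude_rates(plf)
        assert out["infant"].numerator == 6
        assert out["infant"].denominator == 3000
        assert out["neonatal"].numerator == 4
        assert out["postneonatal"].numerator == 2
        assert out["postneonatal"].denominator == 3000 - 4  # neonatal survivors

    def test_all_neonatal_gives_zero_postneonatal(self):
        out = crude_rates(self._plf([0, 5, 20], 1000))
        assert out["postneonatal"].rate == 0.0

    def test_empty_denominator_is_domain_error(self):
        with pytest.raises(ValueError):
            crude_rates(self._plf([0], 0))


class TestSpecificRates:
    def test_zero_birth_bin_row_flagged_undefined(self):
        table = rate_table([("empty", 0, 0), ("ok", 2, 100)])
        row = table[table["bin"] == "empty"].iloc[0]
        assert row["undefined"]
        assert np.isnan(row["rate"])

    def test_bin_sums_conserve(self, small_run):
        """Bin numerators sum to linked live-birth deaths minus missing-
        attribute exclusions; bin denominators sum to the denominator size."""
        plf = small_run["plf"]
        cfg = small_run["config"]
        stratum = StratumDefinition(
            "bw", "birthweight_g",
            edges=[(b.label, b.lo, b.hi) for b in cfg.cohort.birthweight_bins])
        table = specific_rates(plf, stratum)
        n_linked_live = int((~plf.links["reclassified"]).sum())
        assert table["deaths"].sum() + table.attrs["n_excluded_missing"] \
            == n_linked_live
        assert table["denominator"].sum() == len(plf.denominator)

    def test_restriction_and_cumulative_rows(self, small_run):
        plf = small_run["plf"]
        cfg = small_run["config"]
        stratum = StratumDefinition(
            "bw", "birthweight_g",
            edges=[(b.label, b.lo, b.hi) for b in cfg.cohort.birthweight_bins])
        table = specific_rates(
            plf, stratum,
            cumulative=[(">= 500 g", lambda df: df["birthweight_g"] >= 500)])
        row = table[table["bin"] == ">= 500 g"].iloc[0]
        ge500 = (plf.denominator["birthweight_g"] >= 500).sum()
        assert row["denominator"] == ge500

    def test_unknown_stratifier_is_config_error(self, small_run):
        with pytest.raises(KeyError, match="no_such_column"):
            specific_rates(small_run["plf"],
                           StratumDefinition("x", "no_such_column",
                                             labels=["a"]))

    def test_implied_ga_rates_monotone_decreasing(self):
        """The calibrated joint birthweight x GA structure implies
        gestational-age-specific mortality that decreases with age."""
        cfg = vl.CohortConfig(n_births=1000)
        cond = np.asarray(cfg.ga_given_bw)
        bw_p = np.array([b.proportion for b in cfg.birthweight_bins])
        mort = np.array([b.mortality for b in cfg.birthweight_bins])
        joint = cond * bw_p[:, None]
        ga_rate = (joint * mort[:, None]).sum(axis=0) / joint.sum(axis=0)
        assert np.all(np.diff(ga_rate) < 0)
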