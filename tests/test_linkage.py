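"""Linkage engine: comparison levels, EM, scoring, assignment, conservation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vitalink as vl
from vitalink.linkage import (FIELDS, N_LEVELS, block_candidates,
                              candidate_pairs, classify_and_assign, compare,
                              default_init, deterministic_link,
                              estimate_fs_params, posterior_weight_threshold,
                              run_period_linkage, score_pair, score_vectors)


def _birth(bid="B1", ident="E1", dob="2010-03-01", sex="M", place="TOR01",
           postal="M1A 1A1", **kw):
    row = {"birth_id": bid, "encoded_identifier": ident, "dob": dob,
           "sex": sex, "place_code": place, "postal_code": postal,
           "stillbirth_flag": False}
    row.update(kw)
    return row


def _death(did="D1", ident="E1", dob="2010-03-01", dod="2010-03-05",
           sex="M", place="TOR01", postal="M1A 1A1", **kw):
    row = {"death_id": did, "encoded_identifier": ident, "dob": dob,
           "dod": dod, "place_of_death_code": place, "sex": sex,
           "postal_code": postal, "icd10_cause": "P07",
           "age_at_death_days": 4}
    row.update(kw)
    return row


# ---------------------------------------------------------------------------
# field comparison
# ---------------------------------------------------------------------------

class TestCompare:
    def test_identical_records_agree_on_all_fields(self):
        v = compare(_death(), _birth())
        assert (v.dob, v.place, v.sex, v.postal) == (0, 0, 0, 0)

    def test_postal_fsa_only_level(self):
        v = compare(_death(postal="K1H 8L1"), _birth(postal="K1H 8L9"))
        assert v.postal == 1  # FSA-only

    def test_dob_within_one_day(self):
        v = compare(_death(dob="2010-03-02"), _birth(dob="2010-03-01"))
        assert v.dob == 1
        v = compare(_death(dob="2010-03-09"), _birth(dob="2010-03-01"))
        assert v.dob == 2

    def test_missing_is_distinct_from_disagree(self):
        v = compare(_death(sex=""), _birth(sex="M"))
        assert v.sex == N_LEVELS["sex"]
        v = compare(_death(sex="F"), _birth(sex="M"))
        assert v.sex == 1
        v = compare(_death(dob="not-a-date"), _birth())
        assert v.dob == N_LEVELS["dob"]


# ---------------------------------------------------------------------------
# deterministic pass
# ---------------------------------------------------------------------------

class TestDeterministic:
    def test_exact_unique_identifier_links(self):
        deaths = pd.DataFrame([_death()])
        ref = pd.DataFrame([_birth(), _birth(bid="B2", ident="E2")])
        matches, residual = deterministic_link(deaths, ref)
        assert list(matches["birth_id"]) == ["B1"]
        assert matches["stage"].iloc[0] == "deterministic"
        assert len(residual) == 0

    def test_missing_identifier_goes_to_residual(self):
        deaths = pd.DataFrame([_death(ident="")])
        ref = pd.DataFrame([_birth()])
        matches, residual = deterministic_link(deaths, ref)
        assert len(matches) == 0
        assert list(residual["death_id"]) == ["D1"]

    def test_ambiguous_identifiers_demoted_with_warning(self):
        deaths = pd.DataFrame([_death(), _death(did="D2", ident="E9")])
        ref = pd.DataFrame([_birth(), _birth(bid="B2", ident="E9"),
                            _birth(bid="B3", ident="E9")])
        with pytest.warns(UserWarning, match="multiple reference"):
            matches, residual = deterministic_link(deaths, ref)
        assert list(matches["death_id"]) == ["D1"]
        assert "D2" in set(residual["death_id"])

    def test_duplicate_death_identifiers_both_demoted(self):
        deaths = pd.DataFrame([_death(), _death(did="D2")])
        ref = pd.DataFrame([_birth()])
        with pytest.warns(UserWarning, match="duplicate identifier"):
            matches, residual = deterministic_link(deaths, ref)
        assert len(matches) == 0
        assert len(residual) == 2

    def test_clean_cohort_recovers_truth_exactly(self, clean_run):
        ev = clean_run["evaluation"]
        assert ev["precision_deterministic"] == 1.0
        assert ev["recall_deterministic"] == 1.0


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------

class TestBlocking:
    @pytest.fixture()
    def reference(self):
        return pd.DataFrame([
            _birth(bid=f"B{i}", ident=f"E{i}",
                   dob=d, postal=p)
            for i, (d, p) in enumerate([
                ("2010-03-01", "M1A 1A1"), ("2010-03-02", "K1H 8L1"),
                ("2010-07-01", "M1A 1A1"), ("2009-03-01", "M9Z 9Z9"),
                ("2011-01-01", "K1H 8L9")])])

    def test_none_scheme_returns_full_file(self, reference):
        death = _death(dob="2010-03-01")
        assert len(block_candidates(death, reference, "none")) == len(reference)

    def test_dob1_contains_true_match_despite_postal_typo(self, reference):
        # true record B1 (dob 2010-03-02); death has corrupted postal, exact dob
        death = _death(dob="2010-03-02", postal="Z9Z 9Z9")
        cand = block_candidates(death, reference, "dob1")
        assert "B1" in set(cand["birth_id"])

    def test_union_scheme_is_superset_of_each_key(self, reference):
        death = _death(dob="2010-03-01", postal="M1A 1A1")
        union = set(block_candidates(death, reference, "dob_year_fsa")["birth_id"])
        ref_year = pd.to_datetime(reference["dob"]).dt.year
        year_only = set(reference.loc[ref_year == 2010, "birth_id"])
        fsa_only = set(
            reference.loc[reference["postal_code"].str[:3] == "M1A", "birth_id"])
        assert union >= year_only
        assert union >= fsa_only

    def test_bulk_pairs_match_per_death_blocking(self, reference):
        deaths = pd.DataFrame([_death(dob="2010-03-02", did="D1"),
                               _death(dob="2011-01-01", did="D2")])
        for scheme in ("dob1", "dob_year_fsa", "none"):
            pairs = candidate_pairs(deaths, reference, scheme)
            for i, (_, death) in enumerate(deaths.iterrows()):
                got = set(reference["birth_id"].to_numpy()[
                    pairs.loc[pairs["death_idx"] == i, "birth_idx"]])
                want = set(block_candidates(death, reference, scheme)["birth_id"])
                assert got == want, scheme


# ---------------------------------------------------------------------------
# EM and scoring
# ---------------------------------------------------------------------------

def _simulate_vectors(rng, n, m, u, lam):
    """Direct sampler from the two-class model (independent of the EM code)."""
    is_match = rng.random(n) < lam
    out = np.empty((n, 4), dtype=int)
    for k, f in enumerate(FIELDS):
        probs = np.where(is_match[:, None], m[f], u[f])
        c = probs.cumsum(axis=1)
        r = rng.random(n)[:, None]
        out[:, k] = (r > c).sum(axis=1)
    return out, is_match


TRUE_M = {"dob": np.array([0.95, 0.03, 0.02]),
          "place": np.array([0.90, 0.10]),
          "sex": np.array([0.98, 0.02]),
          "postal": np.array([0.90, 0.06, 0.04])}
TRUE_U = {"dob": np.array([0.004, 0.008, 0.988]),
          "place": np.array([0.02, 0.98]),
          "sex": np.array([0.50, 0.50]),
          "postal": np.array([0.001, 0.01, 0.989])}


class TestEM:
    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(7)
        vectors, _ = _simulate_vectors(rng, 5000, TRUE_M, TRUE_U, 0.05)
        params = estimate_fs_params(vectors, tol=1e-9, max_iter=100)
        trace = np.array(params.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_degenerate_all_agree_input_clamps_with_warning(self):
        vectors = np.zeros((200, 4), dtype=int)
        with pytest.warns(UserWarning, match="clamp"):
            params = estimate_fs_params(vectors, max_iter=50)
        for f in FIELDS:
            assert np.all(params.m[f] >= 1e-6)
            assert np.all(params.u[f] >= 1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_fs_params(np.empty((0, 4), dtype=int))


class TestScoring:
    def test_four_field_agreement_closed_form(self):
        m = {f: np.array([0.9] + [0.1 / (N_LEVELS[f] - 1)] * (N_LEVELS[f] - 1))
             for f in FIELDS}
        u = {f: np.array([0.1] + [0.9 / (N_LEVELS[f] - 1)] * (N_LEVELS[f] - 1))
             for f in FIELDS}
        params = vl.FSParams(m=m, u=u, lam=0.01)
        w = score_pair(vl.ComparisonVector(0, 0, 0, 0), params)
        assert w == pytest.approx(4 * np.log2(9), abs=1e-9)

    def test_all_missing_scores_zero(self):
        params = default_init(np.zeros((10, 4), dtype=int))
        v = vl.ComparisonVector(*(N_LEVELS[f] for f in FIELDS))
        assert score_pair(v, params) == 0.0

    def test_weights_equal_bruteforce_sum(self):
        rng = np.random.default_rng(3)
        vectors, _ = _simulate_vectors(rng, 500, TRUE_M, TRUE_U, 0.2)
        params = vl.FSParams(m=TRUE_M, u=TRUE_U, lam=0.1)
        got = score_vectors(vectors, params)
        for i in range(len(vectors)):
            expect = 0.0
            for k, f in enumerate(FIELDS):
                lev = vectors[i, k]
                if lev < N_LEVELS[f]:
                    expect += np.log2(TRUE_M[f][lev] / TRUE_U[f][lev])
            assert got[i] == pytest.approx(expect, abs=1e-9)


# ---------------------------------------------------------------------------
# classification / assignment
# ---------------------------------------------------------------------------

class TestAssignment:
    def test_single_pair_above_upper_links(self):
        scored = pd.DataFrame({"death_id": ["D1"], "birth_id": ["B1"],
                               "weight": [15.0]})
        out = classify_and_assign(scored, 10.0, 0.0)
        assert list(out.loc[out["decision"] == "link", "death_id"]) == ["D1"]

    def test_competition_resolved_by_descending_weight(self):
        # two deaths best-match the same birth; the heavier pair wins and the
        # loser falls back to its next candidate
        scored = pd.DataFrame({
            "death_id": ["D1", "D2", "D2"],
            "birth_id": ["B1", "B1", "B2"],
            "weight": [14.0, 12.0, 11.0]})
        out = classify_and_assign(scored, 10.0, 0.0)
        links = dict(zip(out.loc[out["decision"] == "link", "death_id"],
                         out.loc[out["decision"] == "link", "birth_id"]))
        assert links == {"D1": "B1", "D2": "B2"}

    def test_between_thresholds_reported_possible(self):
        scored = pd.DataFrame({"death_id": ["D1"], "birth_id": ["B1"],
                               "weight": [5.0]})
        out = classify_and_assign(scored, 10.0, 2.0)
        assert list(out["decision"]) == ["possible"]

    @given(st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 8),
                  st.floats(0, 30, allow_nan=False)),
        min_size=1, max_size=60))
    @settings(deadline=None, max_examples=100)
    def test_assignment_is_one_to_one(self, raw):
        scored = pd.DataFrame(
            [(f"D{d}", f"B{b}", w) for d, b, w in raw],
            columns=["death_id", "birth_id", "weight"])
        out = classify_and_assign(scored, 10.0, 1.0)
        links = out[out["decision"] == "link"]
        assert not links["death_id"].duplicated().any()
        assert not links["birth_id"].duplicated().any()


# ---------------------------------------------------------------------------
# period linkage driver
# ---------------------------------------------------------------------------

class TestPeriodLinkage:
    def test_clean_data_fully_linked(self, clean_run):
        s = clean_run["plf"].summary
        assert s["n_unlinked"] == 0
        assert s["prop_linked"] == 1.0

    def test_every_death_exactly_once(self, small_run):
        plf = small_run["plf"]
        linked = set(plf.links["death_id"])
        unlinked = set(plf.unlinked["death_id"])
        assert linked | unlinked == set(plf.deaths["death_id"])
        assert not linked & unlinked
        assert len(plf.links) + len(plf.unlinked) == len(plf.deaths)

    def test_one_to_one_overall(self, small_run):
        links = small_run["plf"].links
        assert not links["death_id"].duplicated().any()
        assert not links["birth_id"].duplicated().any()

    def test_deterministic_links_survive_probabilistic_pass(self, small_run):
        plf = small_run["plf"]
        det, _ = deterministic_link(plf.deaths, small_run["reference"])
        det_map = dict(zip(det["death_id"], det["birth_id"]))
        final = dict(zip(plf.links["death_id"], plf.links["birth_id"]))
        for d, b in det_map.items():
            assert final.get(d) == b

    def test_denominator_excludes_stillbirths_and_prior_year(self, small_run):
        denom = small_run["plf"].denominator
        assert not denom["stillbirth_flag"].any()
        years = pd.to_datetime(denom["dob"]).dt.year
        assert years.between(2010, 2011).all()

    def test_empty_reference_is_hard_error(self):
        deaths = pd.DataFrame([_death()])
        with pytest.raises(ValueError, match="empty"):
            run_period_linkage(deaths, deaths.iloc[0:0])

    def test_death_outside_period_excluded_with_warning(self):
        deaths = pd.DataFrame([_death(),
                               _death(did="D2", dob="2013-01-01",
                                      dod="2013-01-05", ident="")])
        ref = pd.DataFrame([_birth(dob="2009-06-01"),
                            _birth(bid="B2", ident="E2", dob="2010-03-01"),
                            _birth(bid="B3", ident="E3", dob="2011-12-31")])
        with pytest.warns(UserWarning, match="outside the registration"):
            plf = run_period_linkage(deaths, ref)
        assert "D2" not in set(plf.deaths["death_id"])

    def test_posterior_threshold_roundtrip(self):
        params = vl.FSParams(m=TRUE_M, u=TRUE_U, lam=0.01)
        w = posterior_weight_threshold(params, 0.9)
        post = params.lam * 2 ** w / (params.lam * 2 ** w + 1 - params.lam)
        assert post == pytest.approx(0.9, abs=1e-12)
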