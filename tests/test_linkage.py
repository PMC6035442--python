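"""Linkage engine: weights, comparison, blocking oracle, EM, decisions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aliaslink import (
    ComparisonConfig,
    ConfigError,
    GeneratorConfig,
    MUParameters,
    NonIdentifiableError,
    aggregate_to_person_links,
    block_candidates,
    compare_candidates,
    compute_weight,
    compute_weights,
    decide_links,
    estimate_mu_em,
    exhaustive_candidates,
    generate_fixture,
)
from aliaslink.linkage import AGREE, DISAGREE, MISSING

#: Fixed parameters for unit-for-unit reproducible engine tests.
TEST_MU = MUParameters(
    m={"given_name": 0.93, "surname": 0.92, "sex": 0.999,
       "dob_day": 0.94, "dob_month": 0.94, "dob_year": 0.97},
    u={"given_name": 0.008, "surname": 0.009, "sex": 0.5,
       "dob_day": 1 / 28, "dob_month": 1 / 12, "dob_year": 0.02},
)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

class TestWeights:
    def test_single_field_agreement_weight(self):
        mu = MUParameters(m={"f": 0.9}, u={"f": 0.01})
        assert compute_weight({"f": AGREE}, mu) == pytest.approx(6.4919, abs=1e-4)

    def test_single_field_disagreement_weight(self):
        mu = MUParameters(m={"f": 0.9}, u={"f": 0.01})
        assert compute_weight({"f": DISAGREE}, mu) == pytest.approx(-3.3074, abs=1e-4)

    def test_all_missing_gives_zero(self):
        mu = MUParameters(m={"f": 0.9, "g": 0.8}, u={"f": 0.01, "g": 0.1})
        assert compute_weight({"f": MISSING, "g": MISSING}, mu) == 0.0

    def test_total_weight_is_sum_of_field_contributions(self):
        outcomes = {"given_name": AGREE, "surname": DISAGREE, "sex": AGREE,
                    "dob_day": MISSING, "dob_month": AGREE, "dob_year": AGREE}
        total = compute_weight(outcomes, TEST_MU)
        parts = sum(
            compute_weight({f: o}, MUParameters(m={f: TEST_MU.m[f]},
                                                u={f: TEST_MU.u[f]}))
            for f, o in outcomes.items()
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_vectorised_weights_match_scalar(self):
        df = pd.DataFrame(
            {
                "cmp_given_name": [1, 0, -1],
                "cmp_surname": [1, 1, 0],
                "cmp_sex": [1, 1, 1],
                "cmp_dob_day": [1, -1, 0],
                "cmp_dob_month": [1, -1, 1],
                "cmp_dob_year": [1, 1, 1],
            }
        )
        vec = compute_weights(df, TEST_MU)
        for i in range(len(df)):
            outcomes = {f: int(df.loc[i, "cmp_" + f]) for f in TEST_MU.m}
            assert vec[i] == pytest.approx(compute_weight(outcomes, TEST_MU))

    @settings(deadline=None, max_examples=100)
    @given(
        m=st.floats(0.5, 0.999),
        u=st.floats(1e-4, 0.4),
        data=st.data(),
    )
    def test_flipping_disagreement_to_agreement_raises_weight(self, m, u, data):
        fields = ["a", "b", "c"]
        mu = MUParameters(m={f: m for f in fields}, u={f: u for f in fields})
        outcomes = {
            f: data.draw(st.sampled_from([AGREE, DISAGREE, MISSING]), label=f)
            for f in fields
        }
        base = compute_weight(outcomes, mu)
        for f in fields:
            if outcomes[f] == DISAGREE:
                flipped = dict(outcomes, **{f: AGREE})
                assert compute_weight(flipped, mu) > base

    def test_uninformative_parameters_rejected(self):
        with pytest.raises(ConfigError):
            MUParameters(m={"f": 0.1}, u={"f": 0.5})


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def _pair_frame(cohort_row: dict, registry_row: dict):
    cohort = pd.DataFrame([{
        "record_id": "r1", "person_id": "p1", "record_status": "birth",
        **cohort_row,
    }])
    for c in ("dob_day", "dob_month", "dob_year"):
        cohort[c] = pd.array([cohort_row.get(c)], dtype="Int64")
    registry = pd.DataFrame([{"death_id": "d1", **registry_row}])
    for c in ("dob_day", "dob_month", "dob_year"):
        registry[c] = pd.array([registry_row.get(c)], dtype="Int64")
    pairs = pd.DataFrame({"record_id": ["r1"], "death_id": ["d1"]})
    return pairs, cohort, registry


class TestComparison:
    BASE = {"given_name": "JESSICA", "surname": "SMITH", "sex": "F",
            "dob_day": 4, "dob_month": 7, "dob_year": 1990}

    def test_identical_records_agree_everywhere(self):
        pairs, cohort, registry = _pair_frame(self.BASE, self.BASE)
        cmp_df = compare_candidates(pairs, cohort, registry, ComparisonConfig())
        for f in ComparisonConfig().fields:
            assert cmp_df.loc[0, "cmp_" + f] == AGREE

    def test_missing_day_month_compared_as_missing_year_normally(self):
        reg = dict(self.BASE, dob_day=None, dob_month=None)
        pairs, cohort, registry = _pair_frame(self.BASE, reg)
        cmp_df = compare_candidates(pairs, cohort, registry, ComparisonConfig())
        assert cmp_df.loc[0, "cmp_dob_day"] == MISSING
        assert cmp_df.loc[0, "cmp_dob_month"] == MISSING
        assert cmp_df.loc[0, "cmp_dob_year"] == AGREE

    @pytest.mark.parametrize(
        ("threshold", "expected"), [(0.88, AGREE), (0.95, DISAGREE)]
    )
    def test_approximate_surname_threshold(self, threshold, expected):
        # SMITH vs SMYTH: Jaro-Winkler similarity 0.8933
        from aliaslink.config import FieldComparator

        config = ComparisonConfig()
        config.comparators["surname"] = FieldComparator("approximate", threshold)
        reg = dict(self.BASE, surname="SMYTH")
        pairs, cohort, registry = _pair_frame(self.BASE, reg)
        cmp_df = compare_candidates(pairs, cohort, registry, config)
        assert cmp_df.loc[0, "cmp_surname"] == expected
        assert not cmp_df.loc[0, "exact_surname"]


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------

class TestBlocking:
    def test_empty_registry_gives_empty_pairs(self):
        fx = generate_fixture(GeneratorConfig(
            n_individuals=20, death_rate=0, registry_background_size=0,
            post_death_contact_count=0, duplicate_person_id_count=0, seed=2,
        ))
        pairs = block_candidates(fx.cohort, fx.registry,
                                 ComparisonConfig().blocking)
        assert pairs.empty

    def test_empty_blocking_scheme_rejected(self, desk_fixture):
        with pytest.raises(ConfigError):
            block_candidates(desk_fixture.cohort, desk_fixture.registry, [])

    def test_record_with_missing_year_reachable_via_phonetic_pass(self):
        cohort = pd.DataFrame({
            "record_id": ["r1"], "person_id": ["p1"], "record_status": ["birth"],
            "given_name": ["MICHAEL"], "surname": ["SMITH"], "sex": ["M"],
            "dob_day": pd.array([None], dtype="Int64"),
            "dob_month": pd.array([None], dtype="Int64"),
            "dob_year": pd.array([None], dtype="Int64"),
            "last_contact_date": ["2000-01-01"],
        })
        registry = pd.DataFrame({
            "death_id": ["d1"], "given_name": ["MICHAEL"], "surname": ["SMITH"],
            "sex": ["M"],
            "dob_day": pd.array([1], dtype="Int64"),
            "dob_month": pd.array([1], dtype="Int64"),
            "dob_year": pd.array([1990], dtype="Int64"),
            "death_date": ["2005-01-01"], "registration_state": ["QLD"],
        })
        pairs = block_candidates(cohort, registry, ComparisonConfig().blocking)
        assert len(pairs) == 1

    def test_blocked_equals_exhaustive_on_small_instance(self):
        """Every exhaustively-accepted pair is found by the blocked run."""
        from aliaslink.linkage import accepted_pairs

        fx = generate_fixture(GeneratorConfig(
            n_individuals=50, death_rate=0.2, registry_background_size=900,
            post_death_contact_count=0, duplicate_person_id_count=0, seed=21,
        ))
        assert len(fx.cohort) <= 100 and len(fx.registry) <= 1000
        config = ComparisonConfig()
        blocked = accepted_pairs(
            block_candidates(fx.cohort, fx.registry, config.blocking),
            fx.cohort, fx.registry, config, TEST_MU,
        )
        exhaustive = accepted_pairs(
            exhaustive_candidates(fx.cohort, fx.registry),
            fx.cohort, fx.registry, config, TEST_MU,
        )
        assert blocked == exhaustive
        assert exhaustive  # the instance actually contains links


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------

def _simulate_vectors(rng, n, m, u, match_fraction, missing_rate=0.0):
    k = len(m)
    is_match = rng.random(n) < match_fraction
    probs = np.where(is_match[:, None], m, u)
    x = (rng.random((n, k)) < probs).astype(np.int8)
    if missing_rate:
        x[rng.random((n, k)) < missing_rate] = MISSING
    return x, is_match


class TestEM:
    def test_all_identical_vectors_not_identifiable(self):
        X = np.ones((100, 3), dtype=np.int8)
        with pytest.raises(NonIdentifiableError):
            estimate_mu_em(X, ("a", "b", "c"))

    def test_empty_input_rejected(self):
        with pytest.raises(NonIdentifiableError):
            estimate_mu_em(np.empty((0, 2), dtype=np.int8), ("a", "b"))

    def test_recovers_planted_parameters(self):
        rng = np.random.default_rng(42)
        m = np.array([0.95, 0.9, 0.85])
        u = np.array([0.05, 0.1, 0.02])
        X, _ = _simulate_vectors(rng, 50_000, m, u, 0.05)
        em = estimate_mu_em(X, ("a", "b", "c"))
        assert em.converged and not em.violations
        for f, mt, ut in zip(("a", "b", "c"), m, u):
            assert em.m[f] == pytest.approx(mt, abs=0.02)
            assert em.u[f] == pytest.approx(ut, abs=0.02)
        assert em.match_proportion == pytest.approx(0.05, abs=0.01)

    def test_missing_outcomes_ignored_fieldwise(self):
        rng = np.random.default_rng(7)
        m = np.array([0.95, 0.9, 0.85])
        u = np.array([0.05, 0.1, 0.02])
        X, _ = _simulate_vectors(rng, 50_000, m, u, 0.05, missing_rate=0.2)
        em = estimate_mu_em(X, ("a", "b", "c"))
        for f, mt in zip(("a", "b", "c"), m):
            assert em.m[f] == pytest.approx(mt, abs=0.03)

    def test_fixed_point_satisfies_stationarity(self):
        """At convergence the M-step applied to the posteriors is a no-op."""
        rng = np.random.default_rng(3)
        X, _ = _simulate_vectors(
            rng, 20_000, np.array([0.9, 0.9, 0.9]), np.array([0.1, 0.05, 0.2]),
            0.1,
        )
        fields = ("a", "b", "c")
        em = estimate_mu_em(X, fields, tol=1e-10)
        m = np.array([em.m[f] for f in fields])
        u = np.array([em.u[f] for f in fields])
        p = em.match_proportion
        agree = X == AGREE
        log_r = (
            np.log(p / (1 - p))
            + agree @ np.log(m) + (~agree) @ np.log(1 - m)
            - (agree @ np.log(u) + (~agree) @ np.log(1 - u))
        )
        g = 1 / (1 + np.exp(-log_r))
        m_next = (g @ agree) / g.sum()
        u_next = ((1 - g) @ agree) / (1 - g).sum()
        assert np.allclose(m_next, m, atol=1e-6)
        assert np.allclose(u_next, u, atol=1e-6)
        assert g.mean() == pytest.approx(p, abs=1e-6)


# ---------------------------------------------------------------------------
# decisions and aggregation
# ---------------------------------------------------------------------------

def _decision_frame(weight, exact=True, sex=AGREE, year=AGREE):
    return pd.DataFrame({
        "record_id": ["r1"], "death_id": ["d1"], "person_id": ["p1"],
        "record_status": ["birth"], "weight": [weight],
        "exact_given_name": [exact], "exact_surname": [exact],
        "cmp_sex": [sex], "cmp_dob_year": [year],
    })


class TestDecisions:
    def test_below_band_rejected(self):
        out = decide_links(_decision_frame(10.0), ComparisonConfig())
        assert out.decision.iloc[0] == "reject"

    def test_above_threshold_accepted(self):
        out = decide_links(_decision_frame(30.0, exact=False), ComparisonConfig())
        assert out.decision.iloc[0] == "accept"

    def test_band_with_exact_names_accepted(self):
        out = decide_links(_decision_frame(20.0), ComparisonConfig())
        assert out.decision.iloc[0] == "accept"

    def test_band_without_exact_names_declined(self):
        out = decide_links(_decision_frame(20.0, exact=False), ComparisonConfig())
        assert out.decision.iloc[0] == "review"

    def test_band_with_year_disagreement_declined(self):
        out = decide_links(
            _decision_frame(20.0, year=DISAGREE), ComparisonConfig()
        )
        assert out.decision.iloc[0] == "review"


class TestAggregation:
    def test_two_records_same_death_collapse_to_one_link(self):
        acc = pd.DataFrame({
            "person_id": ["p1", "p1"], "death_id": ["d1", "d1"],
            "record_status": ["birth", "alias"], "weight": [25.0, 27.0],
        })
        links = aggregate_to_person_links(acc)
        assert len(links) == 1
        assert links.max_weight.iloc[0] == 27.0
        assert links.contributing_statuses.iloc[0] == "alias+birth"
        assert not links.duplicate_flag.iloc[0]

    def test_two_persons_one_death_both_flagged(self):
        acc = pd.DataFrame({
            "person_id": ["p1", "p2"], "death_id": ["d1", "d1"],
            "record_status": ["birth", "birth"], "weight": [25.0, 24.0],
        })
        links = aggregate_to_person_links(acc)
        assert len(links) == 2
        assert links.duplicate_flag.all()
        assert not links.conflict_flag.any()

    def test_one_person_two_deaths_conflict_flagged(self):
        acc = pd.DataFrame({
            "person_id": ["p1", "p1"], "death_id": ["d1", "d2"],
            "record_status": ["birth", "alias"], "weight": [25.0, 24.0],
        })
        links = aggregate_to_person_links(acc)
        assert links.conflict_flag.all()

    def test_no_accepted_pairs_gives_empty_links(self):
        links = aggregate_to_person_links(pd.DataFrame())
        assert links.empty
        assert "contributing_statuses" in links.columns
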