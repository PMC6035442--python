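"""Evaluation statistics: provenance, sensitivity, audits, subgroup tests."""

import numpy as np
import pandas as pd
import pytest

from aliaslink import (
    DataError,
    classify_link_provenance,
    compare_false_positive_rates,
    compute_sensitivity,
    detect_duplicate_deaths,
    detect_post_death_contacts,
    evaluate,
    subgroup_rates,
)


def _links(statuses, **extra):
    n = len(statuses)
    base = {
        "person_id": [f"p{i}" for i in range(n)],
        "death_id": [f"d{i}" for i in range(n)],
        "max_weight": 25.0,
        "contributing_statuses": statuses,
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestProvenance:
    @pytest.mark.parametrize(
        ("statuses", "expected"),
        [
            ("birth", "verified"),
            ("legal", "verified"),
            ("alias+birth", "verified"),  # alias superfluous
            ("alias", "alias_only"),
            ("alias+alias", "alias_only"),
        ],
    )
    def test_classification(self, statuses, expected):
        out = classify_link_provenance(_links([statuses]))
        assert out.classification.iloc[0] == expected

    def test_empty_contributors_rejected(self):
        with pytest.raises(DataError):
            classify_link_provenance(_links([""]))

    def test_labels_partition_links(self):
        out = classify_link_provenance(
            _links(["birth", "alias", "alias+legal", "alias+alias"])
        )
        assert set(out.classification) <= {"verified", "alias_only"}
        assert out.classification.notna().all()


class TestSensitivity:
    def test_published_counts(self):
        s = compute_sensitivity(1309, 209)
        assert round(100 * s.estimate, 1) == 86.2
        assert s.ci_low == pytest.approx(0.8441, abs=1e-4)
        assert s.ci_high == pytest.approx(0.8787, abs=1e-4)
        assert (round(100 * s.ci_low, 1), round(100 * s.ci_high, 1)) == (84.4, 87.9)
        assert round(s.pct_increase, 1) == 16.0
        assert round(s.pct_missed, 1) == 13.8

    def test_boundary_values(self):
        assert compute_sensitivity(10, 0).estimate == 1.0
        assert compute_sensitivity(10, 0).pct_increase == 0.0
        assert compute_sensitivity(0, 10).estimate == 0.0

    def test_ci_brackets_estimate(self):
        s = compute_sensitivity(50, 17)
        assert s.ci_low < s.estimate < s.ci_high

    def test_zero_counts_rejected(self):
        with pytest.raises(DataError):
            compute_sensitivity(0, 0)


class TestDuplicates:
    def test_one_to_one_links_have_no_groups(self):
        links, groups = detect_duplicate_deaths(_links(["birth", "birth"]))
        assert groups.empty
        assert not links.duplicate_flag.any()

    def test_death_linked_to_three_persons_is_one_group(self):
        links = _links(["birth"] * 3)
        links["death_id"] = "d0"
        links, groups = detect_duplicate_deaths(links)
        assert len(groups) == 1
        assert groups.n_persons.iloc[0] == 3
        assert links.duplicate_flag.all()

    def test_flagged_links_are_retained(self):
        links = _links(["birth", "alias"])
        links["death_id"] = "d0"
        out, _ = detect_duplicate_deaths(links)
        assert len(out) == 2


class TestPostDeathContacts:
    def _frames(self, contact, death):
        links = _links(["birth"])
        cohort = pd.DataFrame({
            "person_id": ["p0"], "record_id": ["r0"], "record_status": ["birth"],
            "last_contact_date": [contact],
        })
        registry = pd.DataFrame({"death_id": ["d0"], "death_date": [death]})
        return links, cohort, registry

    def test_contact_on_death_date_not_anomalous(self):
        links, cohort, registry = self._frames("2005-06-01", "2005-06-01")
        out = detect_post_death_contacts(links, cohort, registry)
        assert not out.anomaly_flag.iloc[0]

    def test_contact_after_death_flagged(self):
        links, cohort, registry = self._frames("2005-06-02", "2005-06-01")
        out = detect_post_death_contacts(links, cohort, registry)
        assert out.anomaly_flag.iloc[0]

    def test_latest_contact_over_all_records_is_used(self):
        links = _links(["birth"])
        cohort = pd.DataFrame({
            "person_id": ["p0", "p0"], "record_id": ["r0", "r1"],
            "record_status": ["birth", "alias"],
            "last_contact_date": ["2004-01-01", "2006-01-01"],
        })
        registry = pd.DataFrame({"death_id": ["d0"], "death_date": ["2005-06-01"]})
        out = detect_post_death_contacts(links, cohort, registry)
        assert out.anomaly_flag.iloc[0]

    def test_unparseable_date_names_the_record(self):
        links, cohort, registry = self._frames("not-a-date", "2005-06-01")
        with pytest.raises(DataError, match="r0"):
            detect_post_death_contacts(links, cohort, registry)

    def test_no_links_no_anomalies(self):
        out = detect_post_death_contacts(
            _links([]).iloc[:0], pd.DataFrame(), pd.DataFrame()
        )
        assert out.empty


class TestFalsePositiveComparison:
    def test_published_counts(self):
        c = compare_false_positive_rates(13, 209, 84, 1309)
        assert round(100 * c.rate_alias, 1) == 6.2
        assert round(100 * c.rate_verified, 1) == 6.4
        assert c.chi2 == pytest.approx(0.0117, abs=5e-4)
        assert c.p_value == pytest.approx(0.914, abs=1e-3)

    def test_identical_rates_give_null_statistic(self):
        c = compare_false_positive_rates(10, 100, 30, 300)
        assert c.chi2 == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DataError):
            compare_false_positive_rates(0, 0, 5, 100)

    def test_fp_exceeding_n_rejected(self):
        with pytest.raises(DataError):
            compare_false_positive_rates(300, 209, 84, 1309)


class TestSubgroups:
    def _classified(self):
        links = _links(
            ["birth"] * 88 + ["alias"] * 12 + ["birth"] * 76 + ["alias"] * 24
        )
        links["sex"] = ["M"] * 100 + ["F"] * 100
        links["birth_year"] = [1980] * 100 + [1990] * 100
        return classify_link_provenance(links)

    def test_constructed_sex_proportions(self):
        out = subgroup_rates(self._classified(), "sex")
        assert out["groups"]["M"]["verified_pct"] == pytest.approx(88.0)
        assert out["groups"]["F"]["verified_pct"] == pytest.approx(76.0)
        assert out["test"]["p_value"] < 0.05

    def test_birth_year_dichotomy_at_1985(self):
        out = subgroup_rates(self._classified(), "birth_year")
        assert out["groups"]["born_pre_1985"]["n_links"] == 100
        assert out["groups"]["born_1985_plus"]["n_links"] == 100

    def test_single_group_has_undefined_test(self):
        links = classify_link_provenance(_links(["birth", "alias"]))
        links["sex"] = "F"
        out = subgroup_rates(links, "sex")
        assert out["test"]["p_value"] is None
        assert out["groups"]["F"]["verified_pct"] == pytest.approx(50.0)

    def test_unknown_grouping_rejected(self):
        with pytest.raises(DataError):
            subgroup_rates(self._classified(), "postcode")


class TestEvaluate:
    def test_empty_links_give_zero_counts(self):
        cohort = pd.DataFrame({
            "person_id": ["p0"], "record_id": ["r0"], "record_status": ["birth"],
            "sex": ["F"], "dob_year": [1990],
            "last_contact_date": ["2000-01-01"],
        })
        registry = pd.DataFrame(
            {"death_id": [], "death_date": []}, dtype=object
        )
        report = evaluate(_links([]).iloc[:0], cohort, registry)
        assert report.n_total_links == 0
        assert report.sensitivity is None
        assert report.false_positive_comparison is None

    def test_report_is_deterministic(self, desk_fixture, desk_linkage):
        fx = desk_fixture
        all_arm, _ = desk_linkage
        r1 = evaluate(all_arm.links, fx.cohort, fx.registry, truth=fx.truth)
        r2 = evaluate(all_arm.links, fx.cohort, fx.registry, truth=fx.truth)
        assert r1.to_json() == r2.to_json()

    def test_counts_partition(self, desk_fixture, desk_linkage):
        fx = desk_fixture
        all_arm, _ = desk_linkage
        r = evaluate(all_arm.links, fx.cohort, fx.registry)
        assert r.n_verified_links + r.n_alias_only_links == r.n_total_links

    def test_planted_female_alias_excess_is_detected(self):
        """Alias-only links oversampled among females yield a significant test."""
        rng = np.random.default_rng(0)
        n = 1200
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        alias = np.where(
            sex == "F", rng.random(n) < 0.30, rng.random(n) < 0.10
        )
        links = _links(np.where(alias, "alias", "birth").tolist())
        links["sex"] = sex
        links["birth_year"] = 1980
        out = subgroup_rates(classify_link_provenance(links), "sex")
        assert (
            out["groups"]["F"]["verified_pct"] < out["groups"]["M"]["verified_pct"]
        )
        assert out["test"]["p_value"] < 0.05
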