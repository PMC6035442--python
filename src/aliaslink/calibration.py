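"""Published statistics of the Queensland youth-justice mortality linkage.

The generator defaults and the worked-example evaluation are calibrated
against the published linkage of the Queensland Youth Justice cohort
(1993-2014; 94,921 identity records for 51,263 young people) to the
Australian National Death Index. This module records those figures in
one place and can construct a link table realising the published counts
exactly, so the evaluation stage can be exercised against known printed
results without any linkage run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Cohort structure statistics (percentages of records or individuals).
COHORT_STATS = {
    "n_records": 94_921,
    "n_individuals": 51_263,
    "status_pct": {"birth": 52.7, "legal": 2.1, "alias": 45.2},
    "single_record_pct": 56.3,
    "four_plus_records_pct": 10.4,
    "max_records_per_person": 22,
    "variation_pct": {"surname": 29.9, "first_name": 16.7, "dob": 9.1},
    "surname_variation_pct_by_sex": {"F": 39.6, "M": 26.7},
    "firstname_variation_pct_by_sex": {"F": 24.9, "M": 14.0},
    "multi_record_pct_by_sex": {"F": 54.5, "M": 40.2},
}

#: Link-level results of the published study.
LINKAGE_STATS = {
    "n_verified_links": 1309,
    "n_alias_only_links": 209,
    "n_total_links": 1518,
    "sensitivity_pct": 86.2,
    "sensitivity_ci_pct": (84.4, 87.9),
    "increase_pct": 16.0,
    "ascertainment_pct": (2.6, 3.0),
    "n_duplicate_deaths": 14,
    "n_anomalies": 69,
    "n_anomalies_alias_only": 12,
    "fp_alias": 13,
    "fp_verified": 84,
    "verified_pct_by_sex": {"M": 88.0, "F": 76.0},
    "alias_pct_by_birth_year": {"pre_1985": 12.0, "post_1985": 21.0},
}


def reference_study_fixture() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Links, cohort and registry tables realising the published counts.

    Constructs 1309 verified and 209 alias-only person-death links over
    a 51,263-person cohort, with 69 post-death-contact anomalies (12 of
    them alias-only), 14 deaths each linked to two identifiers (one of
    the 28 links alias-only), and sex / birth-year compositions matching
    the published subgroup rates. Feeding these to
    :func:`aliaslink.evaluation.evaluate` reproduces every published
    link statistic.
    """
    nv = LINKAGE_STATS["n_verified_links"]
    na = LINKAGE_STATS["n_alias_only_links"]
    n_links = nv + na

    cls = np.array(["verified"] * nv + ["alias_only"] * na, dtype=object)

    # sex composition: 88% of male links and 76% of female links verified
    sex = np.empty(n_links, dtype=object)
    sex[:1139] = "M"            # verified male
    sex[1139:nv] = "F"          # verified female (170)
    sex[nv:nv + 155] = "M"      # alias-only male
    sex[nv + 155:] = "F"        # alias-only female (54)

    # birth-year composition: 12% alias-only among pre-1985, 21% among later
    birth_year = np.empty(n_links, dtype=int)
    birth_year[:1074] = 1980                # verified, born before 1985
    birth_year[1074:nv] = 1990              # verified, born 1985+ (235)
    birth_year[nv:nv + 146] = 1980          # alias-only, pre-1985
    birth_year[nv + 146:] = 1990            # alias-only, 1985+ (63)

    person_id = np.array([f"X{i:06d}" for i in range(n_links)], dtype=object)

    # 14 duplicate-linked deaths: 13 verified+verified pairs, 1 verified+alias
    death_id = np.array([f"Y{i:06d}" for i in range(n_links)], dtype=object)
    for j in range(13):
        death_id[2 * j + 1] = death_id[2 * j]          # verified pairs
    death_id[nv] = death_id[26]                        # one alias joins a 14th death

    # 69 post-death contacts: 57 verified, 12 alias-only, clear of duplicates
    anomaly = np.zeros(n_links, dtype=bool)
    anomaly[30:87] = True               # 57 verified links
    anomaly[nv + 1:nv + 13] = True      # 12 alias-only links

    links = pd.DataFrame(
        {
            "person_id": person_id,
            "death_id": death_id,
            "max_weight": 25.0,
            "contributing_statuses": np.where(cls == "verified", "birth", "alias"),
        }
    )

    contact = np.where(anomaly, "2010-06-01", "2000-06-01")
    linked_cohort = pd.DataFrame(
        {
            "person_id": person_id,
            "record_id": [f"Z{i:06d}" for i in range(n_links)],
            "record_status": "birth",
            "given_name": "REF",
            "surname": "REF",
            "sex": sex,
            "dob_day": pd.array([1] * n_links, dtype="Int64"),
            "dob_month": pd.array([1] * n_links, dtype="Int64"),
            "dob_year": pd.array(birth_year, dtype="Int64"),
            "last_contact_date": contact,
        }
    )
    n_fill = COHORT_STATS["n_individuals"] - n_links
    filler = pd.DataFrame(
        {
            "person_id": [f"F{i:06d}" for i in range(n_fill)],
            "record_id": [f"G{i:06d}" for i in range(n_fill)],
            "record_status": "birth",
            "given_name": "REF",
            "surname": "REF",
            "sex": "M",
            "dob_day": pd.array([1] * n_fill, dtype="Int64"),
            "dob_month": pd.array([1] * n_fill, dtype="Int64"),
            "dob_year": pd.array([1980] * n_fill, dtype="Int64"),
            "last_contact_date": "2000-06-01",
        }
    )
    cohort = pd.concat([linked_cohort, filler], ignore_index=True)

    unique_deaths = pd.unique(death_id)
    registry = pd.DataFrame(
        {
            "death_id": unique_deaths,
            "given_name": "REF",
            "surname": "REF",
            "sex": "M",
            "dob_day": pd.array([1] * len(unique_deaths), dtype="Int64"),
            "dob_month": pd.array([1] * len(unique_deaths), dtype="Int64"),
            "dob_year": pd.array([1980] * len(unique_deaths), dtype="Int64"),
            "death_date": "2005-06-01",
            "registration_state": "QLD",
        }
    )
    return links, cohort, registry
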