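"""Linkage-quality evaluation: provenance, sensitivity and audit statistics.

Given person-level links, this module classifies each link by the
records that supported it (verified = at least one birth/legal record;
alias-only = supported solely by alias records), estimates the
sensitivity of a verified-records-only linkage by treating alias-only
links as its false negatives, and runs the audits that stand in for an
external gold standard: deaths linked to multiple cohort identifiers
(duplicate-ID detection) and justice contact dates that post-date the
supposed death (possible false positives). When a synthetic truth table
is available, true recall and precision of each arm are also reported —
the validation a real study of this kind cannot perform.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

from .linkage import VERIFIED_STATUSES

__all__ = [
    "DataError",
    "SensitivityResult",
    "FalsePositiveComparison",
    "EvaluationReport",
    "classify_link_provenance",
    "compute_sensitivity",
    "detect_duplicate_deaths",
    "detect_post_death_contacts",
    "compare_false_positive_rates",
    "subgroup_rates",
    "truth_metrics",
    "evaluate",
]


class DataError(ValueError):
    """Input records violate the schema the evaluation relies on."""


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def classify_link_provenance(links: pd.DataFrame) -> pd.DataFrame:
    """Label each link ``verified`` or ``alias_only`` from its supporters.

    A single verified (birth or legal) record among the contributors
    suffices for ``verified`` — alias records that co-identified the
    same link are superfluous. The two labels partition the links.
    """
    links = links.copy()
    statuses = links["contributing_statuses"].astype("string")
    if statuses.isna().any() or (statuses.str.len() == 0).any():
        bad = links.loc[
            statuses.isna() | (statuses.str.len() == 0), "person_id"
        ].tolist()
        raise DataError(f"links with empty contributing statuses: {bad[:5]}")
    has_verified = statuses.str.split("+").map(
        lambda parts: bool(set(parts) & VERIFIED_STATUSES)
    )
    links["classification"] = np.where(has_verified, "verified", "alias_only")
    return links


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Sensitivity of a verified-only linkage against the all-records one."""

    n_verified: int
    n_alias_only: int
    estimate: float          # n_verified / total
    ci_low: float
    ci_high: float
    pct_increase: float      # 100 * alias_only / verified
    pct_missed: float        # 100 * alias_only / total


def compute_sensitivity(n_verified: int, n_alias_only: int) -> SensitivityResult:
    """Sensitivity with a 95% Wilson score interval.

    The linkage run with all records is taken as the gold standard, so
    alias-only links are exactly the false negatives of the
    verified-only run and sensitivity is verified / total.
    """
    total = n_verified + n_alias_only
    if total == 0:
        raise DataError("sensitivity is undefined with zero links in both classes")
    est = n_verified / total
    lo, hi = proportion_confint(n_verified, total, alpha=0.05, method="wilson")
    increase = 100.0 * n_alias_only / n_verified if n_verified else math.inf
    return SensitivityResult(
        n_verified=n_verified,
        n_alias_only=n_alias_only,
        estimate=est,
        ci_low=float(lo),
        ci_high=float(hi),
        pct_increase=increase,
        pct_missed=100.0 * n_alias_only / total,
    )


# ---------------------------------------------------------------------------
# audits
# ---------------------------------------------------------------------------

def detect_duplicate_deaths(links: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deaths linked to more than one cohort identifier.

    Returns ``(links, groups)``: the links with ``duplicate_flag``
    (re)filled, and one row per affected death with the identifiers it
    links to. Flagged links are never removed — duplicate linkages are
    an indicator of cohort data quality in their own right.
    """
    links = links.copy()
    if links.empty:
        links["duplicate_flag"] = pd.Series(dtype=bool)
        return links, pd.DataFrame(columns=["death_id", "n_persons", "person_ids"])
    sizes = links.groupby("death_id")["person_id"].nunique()
    links["duplicate_flag"] = links["death_id"].map(sizes) > 1
    dup = links[links["duplicate_flag"]]
    groups = (
        dup.groupby("death_id")["person_id"]
        .agg(["nunique", lambda s: sorted(set(s))])
        .reset_index()
    )
    groups.columns = ["death_id", "n_persons", "person_ids"]
    return links, groups


def detect_post_death_contacts(
    links: pd.DataFrame,
    cohort: pd.DataFrame,
    registry: pd.DataFrame,
) -> pd.DataFrame:
    """Flag links whose last justice contact falls strictly after the death.

    A contact on the death date itself is not anomalous. The person's
    latest contact over all their records is compared against the
    linked registry death date.
    """
    links = links.copy()
    if links.empty:
        links["anomaly_flag"] = pd.Series(dtype=bool)
        return links
    contact = pd.to_datetime(cohort["last_contact_date"], errors="coerce")
    if contact.isna().any():
        bad = cohort.loc[contact.isna(), "record_id"].tolist()
        raise DataError(f"unparseable last_contact_date on record(s) {bad[:5]}")
    last = (
        pd.DataFrame({"person_id": cohort["person_id"], "contact": contact})
        .groupby("person_id")["contact"]
        .max()
    )
    death = pd.to_datetime(registry.set_index("death_id")["death_date"],
                           errors="coerce")
    if death.loc[death.index.intersection(links["death_id"])].isna().any():
        bad = death[death.isna()].index.tolist()
        raise DataError(f"unparseable death_date on registry record(s) {bad[:5]}")
    links["anomaly_flag"] = (
        links["person_id"].map(last).to_numpy()
        > links["death_id"].map(death).to_numpy()
    )
    return links


@dataclass
class FalsePositiveComparison:
    """Two-arm false-positive rate comparison on a 2x2 table."""

    fp_alias: int
    n_alias: int
    fp_verified: int
    n_verified: int
    rate_alias: float
    rate_verified: float
    chi2: float
    p_value: float


def compare_false_positive_rates(
    fp_alias: int, n_alias: int, fp_verified: int, n_verified: int
) -> FalsePositiveComparison:
    """Pearson chi-squared (1 df, no continuity correction) on FP rates."""
    if n_alias == 0 or n_verified == 0:
        raise DataError("false-positive comparison needs links in both classes")
    if fp_alias > n_alias or fp_verified > n_verified:
        raise DataError("false-positive counts exceed link counts")
    table = np.array(
        [[fp_alias, n_alias - fp_alias], [fp_verified, n_verified - fp_verified]]
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = chi2_contingency(table, correction=False)
    return FalsePositiveComparison(
        fp_alias=fp_alias,
        n_alias=n_alias,
        fp_verified=fp_verified,
        n_verified=n_verified,
        rate_alias=fp_alias / n_alias,
        rate_verified=fp_verified / n_verified,
        chi2=float(chi2),
        p_value=float(p),
    )


def subgroup_rates(links: pd.DataFrame, by: str) -> dict[str, Any]:
    """Verified / alias-only proportions by subgroup, with a chi-squared test.

    ``by`` is ``"sex"`` or ``"birth_year"``; the latter dichotomises at
    1985 (born 1985 or later forms the second group), the cut that most
    evenly divides a cohort of this age structure. Groups with zero
    links are reported with an undefined proportion and excluded from
    the test.
    """
    if by == "birth_year":
        year = pd.to_numeric(links["birth_year"], errors="coerce")
        group = np.where(year < 1985, "born_pre_1985", "born_1985_plus")
    elif by == "sex":
        group = links["sex"].to_numpy()
    else:
        raise DataError(f"unknown grouping {by!r}")
    df = pd.DataFrame({"group": group, "cls": links["classification"]})
    tab = (
        df.groupby("group")["cls"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["verified", "alias_only"], fill_value=0)
    )
    rows = {}
    for g, row in tab.iterrows():
        n = int(row.sum())
        rows[str(g)] = {
            "n_links": n,
            "n_verified": int(row["verified"]),
            "n_alias_only": int(row["alias_only"]),
            "verified_pct": 100.0 * row["verified"] / n if n else None,
        }
    nonzero = tab[tab.sum(axis=1) > 0]
    if len(nonzero) >= 2 and nonzero.to_numpy().sum(axis=0).min() > 0:
        chi2, p, _, _ = chi2_contingency(nonzero.to_numpy(), correction=False)
        test = {"chi2": float(chi2), "p_value": float(p)}
    else:
        test = {"chi2": None, "p_value": None}
    return {"groups": rows, "test": test}


def truth_metrics(links: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Recall and precision of a link set against the ground-truth table."""
    found = set(zip(links["person_id"], links["death_id"]))
    true = set(zip(truth["person_id"], truth["death_id"]))
    tp = len(found & true)
    return {
        "n_links": len(found),
        "n_truth": len(true),
        "true_positives": tp,
        "recall": tp / len(true) if true else float("nan"),
        "precision": tp / len(found) if found else float("nan"),
    }


# ---------------------------------------------------------------------------
# the full report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """All statistics of one linkage evaluation, JSON-serialisable."""

    n_individuals: int
    n_total_links: int
    n_verified_links: int
    n_alias_only_links: int
    sensitivity: SensitivityResult | None
    ascertainment_verified_pct: float | None
    ascertainment_all_pct: float | None
    n_duplicate_groups: int
    n_duplicate_links: int
    n_anomalies: int
    anomaly_rate_pct: float | None
    n_anomalies_alias_only: int
    anomaly_alias_share_pct: float | None
    false_positive_comparison: FalsePositiveComparison | None
    by_sex: dict[str, Any] | None
    by_birth_year: dict[str, Any] | None
    truth_all_records: dict[str, float] | None = None
    truth_verified_only: dict[str, float] | None = None
    duplicate_groups: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, default=str, **kwargs)

    def summary(self) -> str:
        lines = [
            f"individuals: {self.n_individuals}",
            f"links: {self.n_total_links} "
            f"(verified {self.n_verified_links}, alias-only {self.n_alias_only_links})",
        ]
        if self.sensitivity:
            s = self.sensitivity
            lines += [
                f"sensitivity of verified-only linkage: {100 * s.estimate:.1f}% "
                f"(95% CI {100 * s.ci_low:.1f}-{100 * s.ci_high:.1f})",
                f"links added by aliases: +{s.pct_increase:.1f}% "
                f"({s.pct_missed:.1f}% of deaths missed without aliases)",
            ]
        if self.ascertainment_verified_pct is not None:
            lines.append(
                "ascertainment: "
                f"{self.ascertainment_verified_pct:.1f}% -> "
                f"{self.ascertainment_all_pct:.1f}% of individuals"
            )
        lines.append(
            f"duplicate-linked deaths: {self.n_duplicate_groups} groups "
            f"covering {self.n_duplicate_links} links"
        )
        if self.anomaly_rate_pct is not None:
            lines.append(
                f"post-death contacts: {self.n_anomalies} "
                f"({self.anomaly_rate_pct:.1f}% of links), "
                f"{self.n_anomalies_alias_only} alias-only "
                f"({self.anomaly_alias_share_pct:.0f}% of anomalies)"
            )
        if self.false_positive_comparison:
            f = self.false_positive_comparison
            lines.append(
                f"assumed false positives: alias {f.fp_alias}/{f.n_alias} "
                f"({100 * f.rate_alias:.1f}%) vs verified "
                f"{f.fp_verified}/{f.n_verified} ({100 * f.rate_verified:.1f}%), "
                f"chi2 p = {f.p_value:.3f}"
            )
        for name, grp in (("sex", self.by_sex), ("birth year", self.by_birth_year)):
            if grp:
                parts = [
                    f"{g}: {v['verified_pct']:.0f}% verified"
                    for g, v in grp["groups"].items()
                    if v["verified_pct"] is not None
                ]
                p = grp["test"]["p_value"]
                ptxt = f", p = {p:.3g}" if p is not None else ""
                lines.append(f"by {name}: " + "; ".join(parts) + ptxt)
        if self.truth_all_records:
            t, v = self.truth_all_records, self.truth_verified_only
            lines.append(
                f"against truth: all-records recall {t['recall']:.3f} / "
                f"precision {t['precision']:.3f}"
                + (
                    f"; verified-only recall {v['recall']:.3f} / "
                    f"precision {v['precision']:.3f}"
                    if v
                    else ""
                )
            )
        return "\n".join(lines)


def _attach_person_attributes(links: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach sex and birth year (from the birth record where available)."""
    links = links.copy()
    c = cohort.copy()
    c["_is_birth"] = (c["record_status"] == "birth").astype(int)
    c = c.sort_values(["person_id", "_is_birth"], ascending=[True, False])
    first = c.groupby("person_id", sort=False).first()
    links["sex"] = links["person_id"].map(first["sex"])
    links["birth_year"] = links["person_id"].map(first["dob_year"])
    return links


def evaluate(
    links: pd.DataFrame,
    cohort: pd.DataFrame,
    registry: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    verified_only_links: pd.DataFrame | None = None,
) -> EvaluationReport:
    """Produce the full evaluation report for one all-records linkage.

    ``links`` must carry person_id, death_id and contributing_statuses.
    The verified / alias-only classification is derived here, so the
    sensitivity analysis needs no second linkage run; an explicit
    ``verified_only_links`` table (the actual comparison arm) is used
    only for the truth-based arm comparison.
    """
    n_individuals = int(cohort["person_id"].nunique())
    if links.empty:
        return EvaluationReport(
            n_individuals=n_individuals,
            n_total_links=0,
            n_verified_links=0,
            n_alias_only_links=0,
            sensitivity=None,
            ascertainment_verified_pct=None,
            ascertainment_all_pct=None,
            n_duplicate_groups=0,
            n_duplicate_links=0,
            n_anomalies=0,
            anomaly_rate_pct=None,
            n_anomalies_alias_only=0,
            anomaly_alias_share_pct=None,
            false_positive_comparison=None,
            by_sex=None,
            by_birth_year=None,
            truth_all_records=truth_metrics(links, truth) if truth is not None else None,
        )

    links = classify_link_provenance(links)
    links, dup_groups = detect_duplicate_deaths(links)
    links = detect_post_death_contacts(links, cohort, registry)
    links = _attach_person_attributes(links, cohort)

    n_total = len(links)
    n_verified = int((links["classification"] == "verified").sum())
    n_alias = n_total - n_verified
    sens = compute_sensitivity(n_verified, n_alias)

    anomalies = links[links["anomaly_flag"]]
    n_anom = len(anomalies)
    n_anom_alias = int((anomalies["classification"] == "alias_only").sum())

    # the maximally conservative false-positive accounting: every
    # post-death contact and every duplicate-linked case is assumed false
    assumed_fp = links["anomaly_flag"] | links["duplicate_flag"]
    fp_alias = int((assumed_fp & (links["classification"] == "alias_only")).sum())
    fp_verified = int((assumed_fp & (links["classification"] == "verified")).sum())
    fp_cmp = (
        compare_false_positive_rates(fp_alias, n_alias, fp_verified, n_verified)
        if n_alias and n_verified
        else None
    )

    report = EvaluationReport(
        n_individuals=n_individuals,
        n_total_links=n_total,
        n_verified_links=n_verified,
        n_alias_only_links=n_alias,
        sensitivity=sens,
        ascertainment_verified_pct=100.0 * n_verified / n_individuals
        if n_individuals
        else None,
        ascertainment_all_pct=100.0 * n_total / n_individuals
        if n_individuals
        else None,
        n_duplicate_groups=len(dup_groups),
        n_duplicate_links=int(links["duplicate_flag"].sum()),
        n_anomalies=n_anom,
        anomaly_rate_pct=100.0 * n_anom / n_total,
        n_anomalies_alias_only=n_anom_alias,
        anomaly_alias_share_pct=100.0 * n_anom_alias / n_anom if n_anom else None,
        false_positive_comparison=fp_cmp,
        by_sex=subgroup_rates(links, "sex"),
        by_birth_year=subgroup_rates(links, "birth_year"),
        duplicate_groups=dup_groups.to_dict("records"),
    )
    if truth is not None:
        report.truth_all_records = truth_metrics(links, truth)
        if verified_only_links is not None:
            report.truth_verified_only = truth_metrics(verified_only_links, truth)
    return report
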