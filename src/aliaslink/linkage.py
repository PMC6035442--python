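"""Fellegi-Sunter probabilistic linkage of cohort records to a death registry.

Every identity record of a person — birth, legal or alias — is compared
independently against the registry; record status plays no role in
matching. Candidate pairs are produced by a union of blocking passes,
compared field by field into agree/disagree/missing outcomes, weighted
with base-2 log likelihood ratios log2(m/u) (agreement) and
log2((1-m)/(1-u)) (disagreement), and decided against an accept
threshold with a clerical-review band resolved by a deterministic rule.
Accepted record pairs are then aggregated to person-level links, keeping
many-to-many relationships (flagged, never dropped) because duplicate
identifiers in the cohort are themselves a quantity of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._strings import jaro_winkler, soundex
from .config import (
    DEFAULT_M_PROBABILITIES,
    ComparisonConfig,
    ConfigError,
    MUParameters,
)

__all__ = [
    "AGREE",
    "DISAGREE",
    "MISSING",
    "LinkageError",
    "NonIdentifiableError",
    "EMResult",
    "LinkageResult",
    "block_candidates",
    "exhaustive_candidates",
    "compare_candidates",
    "compute_weight",
    "compute_weights",
    "estimate_mu_em",
    "estimate_parameters",
    "decide_links",
    "aggregate_to_person_links",
    "run_linkage",
]

AGREE, DISAGREE, MISSING = 1, 0, -1

VERIFIED_STATUSES = frozenset({"birth", "legal"})


class LinkageError(RuntimeError):
    """A linkage-stage invariant was violated."""


class NonIdentifiableError(LinkageError):
    """The comparison vectors carry no information to separate two classes."""


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------

def _blocking_key(df: pd.DataFrame, spec: str, offsets: bool) -> pd.DataFrame:
    """Derive one blocking key column; rows with a missing key are dropped.

    ``spec`` is a field name, ``soundex(field)``, or ``field±1`` (the
    latter expands the *cohort* side to the value and its two integer
    neighbours so off-by-one years still share a block).
    """
    if spec.endswith("±1"):
        base = spec[:-2]
        vals = pd.to_numeric(df[base], errors="coerce")
        if offsets:
            out = pd.DataFrame(
                {
                    "__row__": np.tile(np.arange(len(df)), 3),
                    "key": np.concatenate([vals - 1, vals, vals + 1]),
                }
            )
        else:
            out = pd.DataFrame({"__row__": np.arange(len(df)), "key": vals})
        return out.dropna(subset=["key"])
    if spec.startswith("soundex(") and spec.endswith(")"):
        base = spec[8:-1]
        vals = df[base].astype("string")
        codes, uniques = pd.factorize(vals)
        mapped = np.array(
            [soundex(u) if isinstance(u, str) else "" for u in uniques] + [""],
            dtype=object,
        )
        key = pd.Series(mapped[codes], index=df.index).replace("", pd.NA)
        return pd.DataFrame({"__row__": np.arange(len(df)), "key": key.to_numpy()}).dropna(
            subset=["key"]
        )
    vals = df[spec]
    out = pd.DataFrame({"__row__": np.arange(len(df)), "key": vals.to_numpy()})
    return out[~pd.isna(out["key"])]


def block_candidates(
    cohort: pd.DataFrame,
    registry: pd.DataFrame,
    blocking,
) -> pd.DataFrame:
    """Union of candidate (record_id, death_id) pairs over all blocking passes."""
    if not blocking:
        raise ConfigError("at least one blocking pass is required")
    pieces = []
    for bp in blocking:
        keys = bp.keys if hasattr(bp, "keys") else tuple(bp)
        left = None
        for i, spec in enumerate(keys):
            kc = _blocking_key(cohort, spec, offsets=True).rename(
                columns={"key": f"k{i}"}
            )
            left = kc if left is None else left.merge(kc, on="__row__")
        right = None
        for i, spec in enumerate(keys):
            kr = _blocking_key(registry, spec, offsets=False).rename(
                columns={"key": f"k{i}", "__row__": "__rrow__"}
            )
            right = kr if right is None else right.merge(kr, on="__rrow__")
        if left is None or right is None or left.empty or right.empty:
            continue
        kcols = [f"k{i}" for i in range(len(keys))]
        merged = left.merge(right, on=kcols)[["__row__", "__rrow__"]]
        pieces.append(merged)
    if not pieces:
        return pd.DataFrame({"record_id": pd.Series(dtype=object),
                             "death_id": pd.Series(dtype=object)})
    pairs = pd.concat(pieces, ignore_index=True).drop_duplicates()
    return pd.DataFrame(
        {
            "record_id": cohort["record_id"].to_numpy()[pairs["__row__"].to_numpy()],
            "death_id": registry["death_id"].to_numpy()[pairs["__rrow__"].to_numpy()],
        }
    ).reset_index(drop=True)


def exhaustive_candidates(cohort: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """All cross-product pairs — the brute-force oracle for small instances."""
    return pd.DataFrame(
        {
            "record_id": np.repeat(cohort["record_id"].to_numpy(), len(registry)),
            "death_id": np.tile(registry["death_id"].to_numpy(), len(cohort)),
        }
    )


# ---------------------------------------------------------------------------
# field comparison
# ---------------------------------------------------------------------------

def _similarity_agree(a: pd.Series, b: pd.Series, threshold: float) -> np.ndarray:
    """Jaro-Winkler >= threshold, evaluated once per distinct string pair.

    Missing values yield False here; the caller masks them to MISSING.
    """
    sa = pd.Series(a).fillna("").astype(str).str.upper().to_numpy(dtype=object)
    sb = pd.Series(b).fillna("").astype(str).str.upper().to_numpy(dtype=object)
    combo = np.char.add(np.char.add(sa.astype(str), "\x1f"), sb.astype(str))
    codes, uniques = pd.factorize(combo)
    agree_u = np.empty(len(uniques), dtype=bool)
    for i, u in enumerate(uniques):
        s1, s2 = u.split("\x1f", 1)
        agree_u[i] = bool(s1) and bool(s2) and jaro_winkler(s1, s2) >= threshold
    return agree_u[codes]


def compare_candidates(
    pairs: pd.DataFrame,
    cohort: pd.DataFrame,
    registry: pd.DataFrame,
    config: ComparisonConfig,
) -> pd.DataFrame:
    """Comparison vectors for candidate pairs.

    Returns one row per pair with ``cmp_<field>`` outcome codes
    (1 agree / 0 disagree / -1 missing) plus exact-equality indicators
    for the name fields, which the review rule needs irrespective of the
    configured (possibly approximate) comparators.
    """
    cohort_cols = ["record_id", "person_id", "record_status"] + list(config.fields)
    df = pairs.merge(
        cohort[[c for c in cohort_cols if c in cohort.columns]],
        on="record_id", how="left",
    ).merge(
        registry[["death_id", *config.fields]],
        on="death_id", how="left", suffixes=("_a", "_b"),
    )
    for f in config.fields:
        a, b = df[f + "_a"], df[f + "_b"]
        missing = pd.isna(a).to_numpy() | pd.isna(b).to_numpy()
        comp = config.comparators[f]
        if comp.kind == "exact":
            if str(a.dtype).startswith(("Int", "int", "Float", "float")):
                agree = (
                    pd.to_numeric(a, errors="coerce").to_numpy(dtype=float)
                    == pd.to_numeric(b, errors="coerce").to_numpy(dtype=float)
                )
            else:
                agree = (
                    a.astype(str).str.upper() == b.astype(str).str.upper()
                ).to_numpy()
        else:
            agree = _similarity_agree(a, b, comp.threshold)
        out = np.where(missing, MISSING, np.where(agree, AGREE, DISAGREE))
        df["cmp_" + f] = out.astype(np.int8)
    for f in ("given_name", "surname"):
        if f in config.fields:
            eq = (
                df[f + "_a"].astype(str).str.upper()
                == df[f + "_b"].astype(str).str.upper()
            ).to_numpy()
            df["exact_" + f] = eq & ~pd.isna(df[f + "_a"]).to_numpy() & ~pd.isna(
                df[f + "_b"]
            ).to_numpy()
    return df


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def compute_weight(outcomes: dict[str, int], params: MUParameters) -> float:
    """Total weight of a single comparison vector (sum of field contributions)."""
    total = 0.0
    for f, o in outcomes.items():
        if o == MISSING:
            continue
        if f not in params.m:
            raise ConfigError(f"no m/u parameters for field {f!r}")
        if o == AGREE:
            total += params.agreement_weight(f)
        else:
            total += params.disagreement_weight(f)
    return total


def compute_weights(cmp_df: pd.DataFrame, params: MUParameters) -> np.ndarray:
    """Vectorised total weights for a comparison-vector table."""
    total = np.zeros(len(cmp_df))
    for f in params.m:
        o = cmp_df["cmp_" + f].to_numpy()
        wa = params.agreement_weight(f)
        wd = params.disagreement_weight(f)
        total += np.where(o == AGREE, wa, np.where(o == DISAGREE, wd, 0.0))
    return total


# ---------------------------------------------------------------------------
# m/u estimation
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    """Outcome of the two-class mixture EM over comparison vectors."""

    m: dict[str, float]
    u: dict[str, float]
    match_proportion: float
    converged: bool
    n_iter: int
    #: fields where the fitted m does not exceed u (uninformative)
    violations: list[str] = field(default_factory=list)

    def parameters(self) -> MUParameters:
        if self.violations:
            raise LinkageError(
                f"m <= u after EM for field(s) {self.violations}; "
                "these fields are uninformative on this data"
            )
        return MUParameters(m=dict(self.m), u=dict(self.u))


def estimate_mu_em(
    vectors: np.ndarray,
    fields: tuple[str, ...],
    init_m: float = 0.9,
    init_u: float = 0.1,
    init_p: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
    fixed_u: dict[str, float] | None = None,
) -> EMResult:
    """Estimate m/u and the match proportion by a two-class latent mixture EM.

    ``vectors`` is an (n_pairs, n_fields) array of outcome codes
    (1/0/-1); missing outcomes are ignored field-wise, which is the
    conditional-independence model's standard treatment of partially
    observed comparisons. Identical vectors are collapsed to weighted
    patterns first, so the iteration cost is independent of n_pairs.

    When ``fixed_u`` is given those u-probabilities are held constant
    and only m and the match proportion are updated. This is the stable
    mode for blocked candidate sets, where true matches are so rare that
    a fully free mixture tends to split on the blocking structure
    instead of match status.
    """
    X = np.asarray(vectors, dtype=np.int8)
    if X.ndim != 2 or X.shape[1] != len(fields):
        raise ValueError("vectors must be (n_pairs, n_fields)")
    if len(X) == 0:
        raise NonIdentifiableError("no comparison vectors supplied")
    patterns, counts = np.unique(X, axis=0, return_counts=True)
    if len(patterns) < 2:
        raise NonIdentifiableError(
            "all comparison vectors are identical; a two-class mixture "
            "is not identifiable"
        )
    w = counts.astype(float)
    k = len(fields)
    agree = patterns == AGREE
    disagree = patterns == DISAGREE
    observed = patterns != MISSING

    m = np.full(k, init_m)
    if fixed_u is not None:
        u = np.array([fixed_u[f] for f in fields], dtype=float)
    else:
        u = np.full(k, init_u)
    p = init_p
    eps = 1e-10
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_m = agree @ np.log(m + eps) + disagree @ np.log(1 - m + eps)
        log_u = agree @ np.log(u + eps) + disagree @ np.log(1 - u + eps)
        ratio = np.log(p + eps) + log_m - (np.log(1 - p + eps) + log_u)
        g = 1.0 / (1.0 + np.exp(-np.clip(ratio, -700, 700)))

        gw = g * w
        hw = (1.0 - g) * w
        denom_m = gw @ observed
        denom_u = hw @ observed
        new_m = np.where(denom_m > 0, (gw @ agree) / np.maximum(denom_m, eps), m)
        if fixed_u is None:
            new_u = np.where(denom_u > 0, (hw @ agree) / np.maximum(denom_u, eps), u)
            new_u = np.clip(new_u, 1e-6, 1 - 1e-6)
        else:
            new_u = u
        new_p = gw.sum() / w.sum()
        new_m = np.clip(new_m, 1e-6, 1 - 1e-6)
        new_p = float(np.clip(new_p, 1e-9, 1 - 1e-9))
        delta = max(
            np.abs(new_m - m).max(), np.abs(new_u - u).max(), abs(new_p - p)
        )
        m, u, p = new_m, new_u, new_p
        if delta < tol:
            converged = True
            break

    # label switching: the "match" class must be the high-agreement one
    # (not applicable when u is pinned — the classes cannot swap)
    if fixed_u is None and m.mean() < u.mean():
        m, u, p = u, m, 1.0 - p
    violations = [f for f, mi, ui in zip(fields, m, u) if mi <= ui]
    if len(violations) == len(fields):
        raise NonIdentifiableError(
            "m <= u on every field after EM; the two classes did not separate"
        )
    return EMResult(
        m={f: float(v) for f, v in zip(fields, m)},
        u={f: float(v) for f, v in zip(fields, u)},
        match_proportion=p,
        converged=converged,
        n_iter=it,
        violations=violations,
    )


def estimate_parameters(
    cmp_df: pd.DataFrame,
    cohort: pd.DataFrame,
    registry: pd.DataFrame,
    config: ComparisonConfig,
    seed: int = 0,
    n_random_pairs: int = 200_000,
    m_source: str = "prior",
) -> tuple[MUParameters, EMResult | None]:
    """Estimate m/u for the pipeline without any ground truth.

    The u-probabilities are field agreement rates over uniformly random
    cohort x registry pairs, because u measures agreement between
    *random* pairs and the blocked candidates are anything but random —
    estimating u on them would fold the blocking keys' enforced
    agreement into the weights.

    For m there are two sources. The default (``m_source="prior"``)
    uses the documented data-quality assumptions in
    :data:`aliaslink.config.DEFAULT_M_PROBABILITIES`: at realistic match
    prevalence (true matches are ~1e-5 of blocked candidates) the
    two-class mixture is effectively unidentifiable from the candidate
    vectors alone, and treating m as a prior while estimating u from the
    data is the stable operating mode. ``m_source="em"`` instead runs
    u-pinned EM sessions on high-agreement candidate subsets (pairs
    agreeing exactly on both names estimate the date-of-birth m's; pairs
    agreeing on the full date of birth estimate the name and sex m's);
    this is fully data-driven but sharpens m toward exact agreement when
    partial-agreement matches are rare, yielding a more conservative
    linkage.
    """
    fields = config.fields
    if m_source not in ("prior", "em"):
        raise ConfigError(f"unknown m_source {m_source!r}")
    rng = np.random.default_rng(seed)
    nc, nr = len(cohort), len(registry)
    if nc == 0 or nr == 0:
        raise LinkageError("cannot estimate u-probabilities on empty inputs")
    size = min(n_random_pairs, nc * nr)
    sample = pd.DataFrame(
        {
            "record_id": cohort["record_id"].to_numpy()[rng.integers(0, nc, size)],
            "death_id": registry["death_id"].to_numpy()[rng.integers(0, nr, size)],
        }
    )
    rcmp = compare_candidates(sample, cohort, registry, config)
    u = {}
    for f in fields:
        o = rcmp["cmp_" + f].to_numpy()
        observed = o != MISSING
        u[f] = float((o[observed] == AGREE).mean()) if observed.sum() else 0.5
    u = {f: min(max(v, 1e-4), 1 - 1e-4) for f, v in u.items()}

    if m_source == "prior":
        try:
            m = {f: DEFAULT_M_PROBABILITIES[f] for f in fields}
        except KeyError as exc:
            raise ConfigError(
                f"no default m-probability for field {exc.args[0]!r}; "
                "supply explicit m/u parameters"
            ) from exc
        bad = [f for f in fields if m[f] <= u[f]]
        if bad:
            raise LinkageError(
                f"estimated u exceeds the assumed m for field(s) {bad}; "
                "they carry no signal and cannot be weighted"
            )
        return MUParameters(m=m, u=dict(u)), None

    dob_fields = tuple(f for f in fields if f.startswith("dob_"))
    name_fields = tuple(f for f in fields if not f.startswith("dob_"))

    sessions = []
    if {"given_name", "surname"} <= set(fields) and dob_fields:
        both_names = (
            cmp_df["exact_given_name"].to_numpy()
            & cmp_df["exact_surname"].to_numpy()
        )
        sessions.append((both_names, dob_fields))
    if dob_fields and name_fields:
        full_dob = np.ones(len(cmp_df), dtype=bool)
        for f in dob_fields:
            full_dob &= cmp_df["cmp_" + f].to_numpy() == AGREE
        sessions.append((full_dob, name_fields))
    if not sessions:
        raise LinkageError(
            "parameter estimation needs both name and date-of-birth fields; "
            "supply explicit m/u parameters instead"
        )

    m: dict[str, float] = {}
    converged = True
    n_iter = 0
    props = []
    for mask, sess_fields in sessions:
        if mask.sum() < 50:
            raise LinkageError(
                "too few high-agreement candidate pairs to estimate m "
                f"({int(mask.sum())} in one estimation session); supply "
                "explicit m/u parameters"
            )
        X = cmp_df.loc[mask, ["cmp_" + f for f in sess_fields]].to_numpy()
        em = estimate_mu_em(
            X, sess_fields, init_m=0.9, init_p=0.2,
            fixed_u={f: u[f] for f in sess_fields},
        )
        converged &= em.converged
        n_iter = max(n_iter, em.n_iter)
        props.append(em.match_proportion * mask.mean())
        for f in sess_fields:
            m.setdefault(f, em.m[f])

    m = {f: min(max(m[f], 1e-4), 1 - 1e-4) for f in fields}
    bad = [f for f in fields if m[f] <= u[f]]
    if bad:
        raise LinkageError(
            f"estimated m <= u for field(s) {bad}; they carry no signal "
            "and cannot be weighted"
        )
    combined = EMResult(
        m=m, u=dict(u), match_proportion=float(np.mean(props)),
        converged=converged, n_iter=n_iter, violations=[],
    )
    return MUParameters(m=m, u=dict(u)), combined


# ---------------------------------------------------------------------------
# decisions and aggregation
# ---------------------------------------------------------------------------

def decide_links(cmp_df: pd.DataFrame, config: ComparisonConfig) -> pd.DataFrame:
    """Assign accept / review / reject decisions from total weights.

    Weight >= accept_threshold accepts outright. Inside the review band
    a deterministic stand-in for clerical review applies: accept iff
    both names agree exactly, sex agrees, and year of birth is not in
    disagreement (missing is tolerated — registry records missing day
    and month of birth can still be year-only matches).
    """
    df = cmp_df.copy()
    w = df["weight"].to_numpy()
    lo, hi = config.review_band
    in_band = (w >= lo) & (w < hi)
    review_ok = np.ones(len(df), dtype=bool)
    for f in ("given_name", "surname"):
        col = "exact_" + f
        review_ok &= df[col].to_numpy() if col in df else False
    if "cmp_sex" in df:
        review_ok &= df["cmp_sex"].to_numpy() == AGREE
    if "cmp_dob_year" in df:
        review_ok &= df["cmp_dob_year"].to_numpy() != DISAGREE
    decision = np.where(
        w >= config.accept_threshold,
        "accept",
        np.where(in_band, np.where(review_ok, "accept", "review"), "reject"),
    )
    # "review" marks band pairs the deterministic review examined and declined
    df["decision"] = decision
    df["in_review_band"] = in_band
    return df


def aggregate_to_person_links(accepted: pd.DataFrame) -> pd.DataFrame:
    """Collapse accepted record pairs to person-death links.

    One link per (person_id, death_id) keeping the maximum weight and
    the set of record statuses that supported it. Many-to-many links are
    kept: a person matching several deaths gets ``conflict_flag``; a
    death matching several persons gets ``duplicate_flag`` (the
    duplicate-identifier audit depends on seeing these).
    """
    cols = [
        "person_id", "death_id", "max_weight", "contributing_statuses",
        "duplicate_flag", "conflict_flag",
    ]
    if accepted.empty:
        return pd.DataFrame(columns=cols)
    g = accepted.groupby(["person_id", "death_id"], sort=True)
    links = g.agg(
        max_weight=("weight", "max"),
        contributing_statuses=(
            "record_status",
            lambda s: "+".join(sorted(set(s))),
        ),
    ).reset_index()
    links["duplicate_flag"] = links.groupby("death_id")["person_id"].transform(
        "nunique"
    ) > 1
    links["conflict_flag"] = links.groupby("person_id")["death_id"].transform(
        "nunique"
    ) > 1
    return links[cols]


def accepted_pairs(
    pairs: pd.DataFrame,
    cohort: pd.DataFrame,
    registry: pd.DataFrame,
    config: ComparisonConfig,
    mu: MUParameters,
) -> set[tuple[str, str]]:
    """(record_id, death_id) pairs accepted from a given candidate set.

    A diagnostic building block: running it on the blocked candidates
    and on :func:`exhaustive_candidates` verifies on a small instance
    that the blocking scheme loses no acceptable pair.
    """
    if pairs.empty:
        return set()
    cmp_df = compare_candidates(pairs, cohort, registry, config)
    cmp_df["weight"] = compute_weights(cmp_df, mu)
    decided = decide_links(cmp_df, config)
    acc = decided[decided["decision"] == "accept"]
    return set(zip(acc["record_id"], acc["death_id"]))


@dataclass
class LinkageResult:
    """Everything one linkage arm produces."""

    links: pd.DataFrame
    pairs: pd.DataFrame
    mu: MUParameters
    em: EMResult | None
    verified_only: bool


def run_linkage(
    cohort: pd.DataFrame,
    registry: pd.DataFrame,
    config: ComparisonConfig | None = None,
    mu: MUParameters | None = None,
    verified_only: bool = False,
    seed: int = 0,
    m_source: str = "prior",
) -> LinkageResult:
    """Block, compare, weight, decide and aggregate in one call.

    ``verified_only=True`` drops alias records before matching — the
    comparison arm of the study design. When ``mu`` is None the
    parameters come from :func:`estimate_parameters` (u from random
    pairs; m from the configured ``m_source``); passing explicit
    parameters makes the run fully reproducible unit-for-unit.
    """
    config = config or ComparisonConfig()
    if verified_only:
        cohort = cohort[cohort["record_status"].isin(VERIFIED_STATUSES)].reset_index(
            drop=True
        )
    pairs = block_candidates(cohort, registry, config.blocking)
    if pairs.empty:
        return LinkageResult(
            links=aggregate_to_person_links(pd.DataFrame()),
            pairs=pd.DataFrame(),
            mu=mu if mu is not None else MUParameters(m={}, u={}),
            em=None,
            verified_only=verified_only,
        )
    cmp_df = compare_candidates(pairs, cohort, registry, config)
    em = None
    if mu is None:
        mu, em = estimate_parameters(
            cmp_df, cohort, registry, config, seed=seed, m_source=m_source
        )
    cmp_df["weight"] = compute_weights(cmp_df, mu)
    decided = decide_links(cmp_df, config)
    accepted = decided[decided["decision"] == "accept"]
    links = aggregate_to_person_links(accepted)
    return LinkageResult(links=links, pairs=decided, mu=mu, em=em,
                         verified_only=verified_only)
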