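"""Configuration objects for the generator, linkage engine and pipeline.

All configuration is plain dataclasses with eager validation, loadable
from YAML. Unknown keys are rejected so that a typo in a config file
fails loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "FieldComparator",
    "BlockingPass",
    "ComparisonConfig",
    "MUParameters",
    "RunConfig",
    "load_config",
    "dump_config",
]

#: Fields compared between a cohort record and a death-registry record.
COMPARISON_FIELDS = ("given_name", "surname", "sex", "dob_day", "dob_month", "dob_year")


class ConfigError(ValueError):
    """A configuration value violates its documented constraint."""


def _check_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic identity-population generator.

    Defaults are calibrated to the published structure of the Queensland
    Youth Justice cohort (51,263 individuals, 94,921 identity records)
    and a scaled-down national death-registry stand-in. Sex-specific
    multi-record probabilities and mean record counts reproduce the
    published 56.3% single-record share and 10.4% four-plus-record
    share; the variation probabilities are person-level rates among all
    individuals of each sex (the generator conditions them internally on
    having more than one record).
    """

    n_individuals: int = 51_263
    female_fraction: float = 0.246
    multi_record_prob_female: float = 0.545
    multi_record_prob_male: float = 0.402
    #: Mean TOTAL records per multi-record individual (>= 2 implied by
    #: definition is not required; the truncated count model only needs > 1).
    mean_records_multi_female: float = 3.3
    mean_records_multi_male: float = 2.8
    max_records_per_person: int = 22
    #: Dispersion of the zero-truncated negative-binomial extra-record
    #: count; fitted so four-plus-record individuals are ~10.4 % overall.
    extra_records_dispersion: float = 1.425710
    #: Fraction of non-birth records that are legally documented name
    #: changes rather than aliases (2.1 % of all records).
    legal_record_fraction: float = 0.0457
    #: Probability that a single-record individual's only record is not a
    #: birth record (97.5 % of single-record individuals had one).
    single_nonbirth_prob: float = 0.025
    surname_variation_prob_female: float = 0.396
    surname_variation_prob_male: float = 0.267
    firstname_variation_prob_female: float = 0.249
    firstname_variation_prob_male: float = 0.140
    dob_variation_prob: float = 0.091
    death_rate: float = 0.0296
    registry_background_size: int = 200_000
    missing_dob_day_month_prob: float = 0.03
    duplicate_person_id_count: int = 14
    post_death_contact_count: int = 69
    birth_year_range: tuple[int, int] = (1971, 1998)
    #: Probability that a drawn surname variant is a replacement
    #: (marriage-style) rather than a spelling slip, by sex.
    surname_replace_prob_female: float = 0.75
    surname_replace_prob_male: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "female_fraction",
            "multi_record_prob_female",
            "multi_record_prob_male",
            "legal_record_fraction",
            "single_nonbirth_prob",
            "surname_variation_prob_female",
            "surname_variation_prob_male",
            "firstname_variation_prob_female",
            "firstname_variation_prob_male",
            "dob_variation_prob",
            "death_rate",
            "missing_dob_day_month_prob",
            "surname_replace_prob_female",
            "surname_replace_prob_male",
        ):
            _check_proportion(name, getattr(self, name))
        for name in (
            "n_individuals",
            "registry_background_size",
            "duplicate_person_id_count",
            "post_death_contact_count",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.max_records_per_person < 1:
            raise ConfigError("max_records_per_person must be >= 1")
        for name in ("mean_records_multi_female", "mean_records_multi_male"):
            if not (1.0 < getattr(self, name) <= self.max_records_per_person):
                raise ConfigError(
                    f"{name} must lie in (1, max_records_per_person]"
                )
        if self.extra_records_dispersion <= 0:
            raise ConfigError("extra_records_dispersion must be positive")
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ConfigError("birth_year_range must be (low, high) with low <= high")
        self.birth_year_range = (int(lo), int(hi))


@dataclass
class FieldComparator:
    """How one field is compared: exactly, or by string similarity."""

    kind: str = "exact"  # "exact" | "approximate"
    threshold: float = 0.88  # similarity at or above which approximate agrees

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "approximate"):
            raise ConfigError(f"unknown comparator kind {self.kind!r}")
        _check_proportion("comparator threshold", self.threshold)


@dataclass
class BlockingPass:
    """One blocking pass: candidate pairs must share the derived keys.

    ``keys`` entries are field names, optionally transformed:
    ``soundex(field)`` takes the phonetic code, ``field±1`` also joins
    on the integer value one above and one below (used for birth year).
    """

    keys: tuple[str, ...]


@dataclass
class ComparisonConfig:
    """Comparators, blocking scheme and decision thresholds.

    Weights are base-2 log likelihood ratios, so ``accept_threshold``
    and the review band are in bits. Pairs with weight at or above
    ``accept_threshold`` are accepted outright; pairs inside the review
    band are resolved by a deterministic stand-in for clerical review
    (exact agreement on both names and sex, with year of birth not in
    disagreement); everything below the band is rejected.
    """

    comparators: dict[str, FieldComparator] = field(
        default_factory=lambda: {
            "given_name": FieldComparator("approximate", 0.88),
            "surname": FieldComparator("approximate", 0.88),
            "sex": FieldComparator("exact"),
            "dob_day": FieldComparator("exact"),
            "dob_month": FieldComparator("exact"),
            "dob_year": FieldComparator("exact"),
        }
    )
    blocking: tuple[BlockingPass, ...] = (
        BlockingPass(("sex", "dob_year")),
        BlockingPass(("soundex(surname)", "dob_year±1")),
        BlockingPass(("soundex(given_name)", "sex")),
    )
    accept_threshold: float = 24.0
    review_band: tuple[float, float] = (18.0, 24.0)

    def __post_init__(self) -> None:
        unknown = set(self.comparators) - set(COMPARISON_FIELDS)
        if unknown:
            raise ConfigError(f"comparators for unknown fields: {sorted(unknown)}")
        if not self.blocking:
            raise ConfigError("at least one blocking pass is required")
        self.blocking = tuple(
            bp if isinstance(bp, BlockingPass) else BlockingPass(tuple(bp))
            for bp in self.blocking
        )
        lo, hi = self.review_band
        if lo > hi:
            raise ConfigError("review_band must be (low, high) with low <= high")
        if self.accept_threshold < hi:
            raise ConfigError(
                "accept_threshold must sit at or above the review band ceiling"
            )

    @property
    def fields(self) -> tuple[str, ...]:
        return tuple(f for f in COMPARISON_FIELDS if f in self.comparators)


#: Default m-probabilities: the assumed per-field agreement rates among
#: true matches, reflecting administrative data quality (names carry
#: alias/typo variation; sex is essentially always right; year of birth
#: is the most reliable date component). Used when no explicit m/u is
#: configured; the u-probabilities are always estimated from the data.
DEFAULT_M_PROBABILITIES = {
    "given_name": 0.93,
    "surname": 0.92,
    "sex": 0.999,
    "dob_day": 0.94,
    "dob_month": 0.94,
    "dob_year": 0.97,
}


@dataclass
class MUParameters:
    """Per-field m- and u-probabilities of the Fellegi-Sunter model.

    ``m[f]`` is the probability the field agrees given the pair is a
    true match; ``u[f]`` given the pair is random. A field is
    informative only when m > u; estimation flags violations.
    """

    m: dict[str, float]
    u: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.m) != set(self.u):
            raise ConfigError("m and u must cover the same fields")
        for f in self.m:
            if not (0.0 < self.u[f] < self.m[f] < 1.0):
                raise ConfigError(
                    f"field {f!r}: need 0 < u < m < 1, got u={self.u[f]:.4g}, m={self.m[f]:.4g}"
                )

    def agreement_weight(self, field_name: str) -> float:
        import math

        return math.log2(self.m[field_name] / self.u[field_name])

    def disagreement_weight(self, field_name: str) -> float:
        import math

        return math.log2((1.0 - self.m[field_name]) / (1.0 - self.u[field_name]))


@dataclass
class RunConfig:
    """Top-level pipeline configuration: one section per stage."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    #: "prior" uses the default m-probabilities with u estimated from
    #: random pairs; "em" estimates m by EM sessions on the candidate
    #: vectors as well; a mapping {"m": {...}, "u": {...}} pins the
    #: parameters outright for exactly reproducible runs.
    mu_source: Any = "prior"
    seed: int = 0
    log_level: str = "INFO"

    def resolved_mu(self) -> MUParameters | None:
        if self.mu_source in ("prior", "em"):
            return None
        if isinstance(self.mu_source, MUParameters):
            return self.mu_source
        if isinstance(self.mu_source, dict):
            return MUParameters(m=dict(self.mu_source["m"]), u=dict(self.mu_source["u"]))
        raise ConfigError(f"unrecognised mu_source: {self.mu_source!r}")


def _from_mapping(cls, data: dict[str, Any], path: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {path!r}")
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name == "generator":
            value = _from_mapping(GeneratorConfig, value, "generator")
        elif f.name == "comparison":
            value = _comparison_from_mapping(value)
        elif f.name == "birth_year_range" or f.name == "review_band":
            value = tuple(value)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def _comparison_from_mapping(data: dict[str, Any]) -> ComparisonConfig:
    data = dict(data)
    if "comparators" in data:
        comps = {}
        for name, spec in data["comparators"].items():
            if isinstance(spec, str):
                comps[name] = FieldComparator(spec)
            else:
                comps[name] = FieldComparator(**spec)
        data["comparators"] = comps
    if "blocking" in data:
        data["blocking"] = tuple(BlockingPass(tuple(keys)) for keys in data["blocking"])
    if "review_band" in data:
        data["review_band"] = tuple(data["review_band"])
    return _from_mapping(ComparisonConfig, data, "comparison")


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; an empty file means all defaults."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return _from_mapping(RunConfig, data, "<root>")


def dump_config(config: RunConfig) -> str:
    """Serialise a RunConfig back to YAML (inverse of :func:`load_config`)."""

    def encode(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            if isinstance(obj, BlockingPass):
                return list(obj.keys)
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    payload = {
        "generator": encode(config.generator),
        "comparison": {
            "comparators": {
                k: {"kind": c.kind, "threshold": c.threshold}
                for k, c in config.comparison.comparators.items()
            },
            "blocking": [list(bp.keys) for bp in config.comparison.blocking],
            "accept_threshold": config.comparison.accept_threshold,
            "review_band": list(config.comparison.review_band),
        },
        "mu_source": encode(config.mu_source),
        "seed": config.seed,
        "log_level": config.log_level,
    }
    return yaml.safe_dump(payload, sort_keys=False)
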