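"""Shared desk-scale study configuration for the analysis scripts.

3,000 individuals against a 20,000-record registry keeps every
structural phenomenon of the full-size problem (alias-only links,
duplicate identifiers, post-death contacts, partial dates) at a scale
that links in under a minute on one CPU. Scripts regenerate the fixture
deterministically from this configuration rather than passing files
around, so each script runs standalone.
"""

from pathlib import Path

from aliaslink import GeneratorConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

DESK_CONFIG = GeneratorConfig(
    n_individuals=3_000,
    registry_background_size=20_000,
    duplicate_person_id_count=4,
    post_death_contact_count=6,
    seed=11,
)
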