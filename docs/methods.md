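# Methods

## Scope and design

The package has three layers: a synthetic identity-population generator
(`aliaslink.synthetic`), a Fellegi–Sunter linkage engine
(`aliaslink.linkage`), and a linkage-quality evaluation layer
(`aliaslink.evaluation`), glued by schema-validated CSV I/O and a CLI.
The generator exists because the data this design was built for —
justice-system identity records and a national death index — cannot be
distributed; it emits a ground-truth table alongside the files so the
engine's recall and precision can be measured directly, which is the
validation the original study design cannot perform on real data.

## The synthetic population

Each individual receives a sex (24.6% female), a birth identity (given
name, surname, full date of birth), and a last justice-contact date
inside the 1993–2014 window. Birth years are uniform over 1971–1998,
chosen so the 1985 dichotomy used in subgroup analyses splits the
cohort evenly.

**Record counts.** An individual is multi-record with probability 0.545
(female) / 0.402 (male). Among multi-record individuals the number of
*extra* records follows a zero-truncated negative binomial truncated at
21 (22 records total at most), with the success probability solved per
sex so the mean total records are 3.3 (F) / 2.8 (M) and a shared
dispersion of 1.4257 fitted once so that 10.4% of all individuals carry
four or more records. The overdispersion matters: most multi-record
people have one or two extras while a small minority accumulates many,
and a Poisson count at the same mean would put 12% rather than 10.4% in
the four-plus tail.

**Variation.** Whether a person's records vary in surname, first name
or date of birth is drawn at the person level, with rates conditioned
on being multi-record so the population-level rates hit the calibration
targets (surname 29.9%, first name 16.7%, DOB 9.1%; surname variation
39.6% F vs 26.7% M). One variant value per varying field is generated
per person and reused across their alias records (people reuse
aliases): surnames are replaced outright (marriage-style, dominant in
females) or perturbed by a single-character slip; first names become
nicknames from a built-in table, slips, or replacements; dates of birth
get a day/month swap, a ±1 on one component, or a ±1 year. Every extra
record realises each of its person's variant fields with probability
0.8 (forced on the first extra so the person-level indicator is always
expressed). Non-birth records are legally documented changes with
probability 0.0457 (2.1% of all records) and aliases otherwise; 2.5% of
single-record individuals hold a non-birth record as their only one.

**The registry.** A death is planted for 2.96% of individuals. Each
death record copies one *uniformly chosen* identity record of the
person — this single choice is what makes alias-only links possible —
with a 2% per-name chance of a registry-side slip, and a death date
after the person's last contact, capped at the 2017-01-31 observation
end. Three audit scenarios are planted: an exact share (default 3%) of
cohort-death records get day and month of birth blanked jointly (year
is never missing); a configurable number of deceased persons (default
scaled from 69/1518) keep a last-contact date *after* the death date,
with their registry copy taken verbatim so the names match exactly; and
a configurable number of multi-record deceased persons (default scaled
from 14) have their records split across two person identifiers sharing
one true death. Background decoys (default 200,000; a desk-scale
stand-in for a ~5M-record national index) are drawn from the same name
pools with birth years 1950–2000 and death dates 1980–2017.

**What the generator does not emulate.** Name pools are a few hundred
values with a mild rank-frequency skew, so exact-name collision
probabilities are ~1e-4 per random pair where real name frequency
tables give 1e-6–1e-8; twins, siblings at the same address, true
cultural naming systems, migration between states, and correlated
field errors are all absent. Consequences for interpretation: the
absolute precision measured here understates what the same engine
achieves on real data (decoy "name twins" are far too common), while
recall, the arm comparison, and all calibration statistics transfer.
Passing tests demonstrate internal correctness of the machinery and
faithfulness to the published cohort structure, not field performance.

## The linkage engine

All records of a person match independently; record status is never an
input to matching. Comparison fields are given name, surname (both
approximate: Jaro–Winkler ≥ 0.88 counts as agreement), sex, and day,
month, year of birth (exact). A field missing on either side yields a
*missing* outcome contributing zero weight — the neutral treatment that
lets year-only matches (registry missing day/month) survive to review
rather than being penalised as disagreements.

Weights are base-2 log likelihood ratios, so each field's contribution
is readable in bits (full agreement at default parameters totals
≈ 28.5). Blocking is the union of three passes — (sex, birth year),
(surname Soundex, birth year ± 1), (given-name Soundex, sex) — and the
suite verifies on a ≤ 100 × 1,000 instance that no pair acceptable
under the decision rule is lost relative to the exhaustive
cross-product: any acceptable pair must agree on sex, and either on
year (pass 1) or, failing exact year, on enough of a name for a
phonetic pass to hold it.

**Decision rule.** Accept at ≥ 24 bits. The band [18, 24) models the
clerical review of the original design as a deterministic rule: accept
iff both names agree exactly, sex agrees, and year of birth is not in
disagreement. This encodes the observed behaviour of manual review on
this data type — partial-DOB matches are acceptable only on the
strength of exact name identity. Year-only matches are therefore
accepted, exactly as a human reviewer accepts them; some are wrong, and
it is the post-death-contact audit downstream (not the decision rule)
that surfaces them, mirroring the original workflow. Band pairs that
fail the rule keep the decision label `review` for auditability.

**Parameter estimation.** u-probabilities are agreement rates over
200,000 uniformly random cohort × registry pairs — u describes *random*
pairs, and blocked candidates are not random. m-probabilities default
to documented data-quality assumptions (names 0.92–0.93, sex 0.999,
day/month 0.94, year 0.97; `config.DEFAULT_M_PROBABILITIES`), because
at realistic prevalence (true matches ≈ 1e-4 to 1e-5 of blocked
candidates) the two-class conditional-independence mixture is not
identifiable from the candidate vectors: a free EM converges to a split
along the blocking structure (its "match" class becomes "pairs from
pass 1"), and pinning u at the random-pair values makes things worse —
the blocking keys' enforced agreement must then be explained entirely
by the match class, which absorbs everything. Session-based estimation
(pairs agreeing exactly on both names identify the DOB m's; pairs
agreeing on the full DOB identify the name m's) is available via
`m_source="em"`; it is fully data-driven but systematically sharpens m
toward exact agreement whenever partial-agreement matches are rare,
yielding a more conservative linkage (higher precision, lower recall).
The EM itself (`estimate_mu_em`, pattern-compressed, missing outcomes
ignored field-wise, label-switch corrected) recovers planted parameters
to ±0.02 when vectors actually follow the mixture model, which the
suite verifies at n = 100,000; the instability is a property of blocked
candidate data, not of the optimiser. Explicit m/u can always be
supplied for unit-for-unit reproducible runs.

Note the identification caveat: with only two informative fields a
two-class binary product mixture is not identifiable at all (three are
required), so no two-field closed-form cross-check exists; the EM's
correctness is instead checked by parameter recovery and by verifying
its fixed point satisfies the stationarity equations exactly.

**Aggregation.** Accepted pairs collapse to (person, death) links
keeping the maximum weight and the set of contributing record
statuses. Many-to-many structure is flagged (`duplicate_flag` for
deaths with several persons, `conflict_flag` for persons with several
deaths), never resolved away: duplicate linkages are an indicator of
cohort data quality and an output of interest. No one-to-one
assignment step is applied.

## Evaluation

A link is **verified** if any contributing record is birth or legal
(alias contributions are then superfluous), **alias-only** otherwise;
the two labels partition the links. Sensitivity of a verified-only
linkage treats the all-records linkage as the gold standard
(alias-only links = false negatives): estimate v/(v+a) with a 95%
Wilson score interval — the Wilson method is the one that reproduces
the published interval 84.4–87.9 for 1309/1518 (a normal approximation
gives 84.5–88.0). Post-death contact uses strict inequality (a contact
*on* the death date is not anomalous) against the person's latest
contact over all records. The false-positive comparison follows the
maximally conservative accounting: every post-death-contact link and
every duplicate-linked case is assumed false, apportioned by link
class, and compared by Pearson χ² on the 2×2 table without continuity
correction (1 df) — the variant that reproduces the published
p = 0.914 for 13/209 vs 84/1309. Subgroup tables dichotomise birth
year at 1985, with "born 1985 or later" as the second group; groups
with zero links are reported with an undefined proportion and excluded
from the test. When a truth table is supplied, recall and precision of
both arms are appended.

## Numerical and degenerate-input choices

Birth days are generated in 1–28, avoiding calendar-validity edge
cases without affecting any calibration statistic. Proportions are
carried at full precision and rounded only at presentation. EM clips
probabilities to [1e-6, 1−1e-6], converges on a maximum absolute
parameter change < 1e-6 (500-iteration cap), and raises on degenerate
input (no vectors, all vectors identical, or no field with m > u after
label correction). Empty link sets evaluate to a zero-count report with
no tests; zero-denominator statistics raise rather than return NaN.
Fixture generation is deterministic byte-for-byte given a
configuration: one integer seed fans out to independent substreams for
the cohort and registry stages, so either can be regenerated alone.

## Scale

The analysis scripts and test suite run the end-to-end linkage on a
3,000-person cohort against a 20,000-record registry (≈ 1.9M blocked
candidate pairs, under a minute on one CPU), which preserves every
structural phenomenon — alias-only links, duplicate identifiers,
post-death contacts, partial dates — at desk scale. Full-size 51,263-
person cohorts are generated wherever a calibration statistic is
asserted, since generation is vectorised and takes about a second; the
full 200,000-record registry default is exercised through the same code
paths but not in routine test runs.

## Known limitations

Precision measured against synthetic truth is capped near 0.9 at desk
scale by name-pool collision density (see above), and the
review-band ambiguity of year-only matches is irreducible on the
compared fields — both arms inherit it equally, which is why the
package reports the *arm comparison* rather than absolute precision as
its primary specificity evidence. The m-probability defaults are
assumptions, not estimates; a production deployment against real data
should re-derive them from a clerically reviewed sample. Conditional
independence of fields given match status is assumed throughout, as in
the classical model.
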