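# Methods

This note documents the assessment procedure the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not demonstrate.

## Assessment model

The unit of assessment is a *dataset description*: the categorical answers
one respondent gave about one dataset in one survey round.  All scoring is
rule-based over closed vocabularies; there is no fitted model.

**FAIR rubric.**  Twelve criteria adapted to non-scholarly data.  The
adaptation assumes identifiers need only be unique locally (no registry
exists for agri-food operational data), and replaces machine-actionability
with human-actionability (a structure document plus a vocabulary glossary
make a dataset interoperable for a naive user).  Graded criteria use a
three-step scale {0, ½, 1}; binary criteria use {0, 1}:

* F1/F2 — data/metadata identifiable through time: 1 with a unique
  identifier or the complete identifying-element checklist, ½ when exactly
  one element is missing and there is no identifier, else 0.  The
  checklist defaults to {name, version-or-release-date, responsible
  organisation} — the minimal triple used in catalogue practice — and is a
  parameter of every scoring function because survey instruments may
  enumerate a different element list.
* F3 — data–metadata link: automatic updates 1, manual ½, otherwise 0;
  forced to 0 when metadata do not (or are not known to) exist.
* A1/A2 — a documented access protocol or a URL, for data and metadata.
* I1–I4 — documented data structure; comprehensible data vocabulary
  (standard, retrievable glossary, or collaboratively defined); documented
  or standard-schema metadata structure; comprehensible metadata
  vocabulary.
* R1–R3 — elements to (re)construct rich metadata (all / one missing /
  more); collection & quality process documentation (full / partial /
  none); licensing (data and metadata / data only / none).

A criterion is *fulfilled* only at score 1; ½ is reported separately as
*partial*.  "At least half the criteria" means ≥ 6 of the 12 criteria
fulfilled — criteria are counted, not points.

**GDPR accountability.**  Only the accountability principle is assessed,
and only for datasets declaring personal data; the six process-oriented
GDPR principles are data-management properties out of scope for a
description-based audit.  Two binary criteria: both governance roles (data
subject, data controller) identified; both documented.  A score object
enforces documented ⇒ identified: a role cannot count as documented while
unidentified, so the scorer clamps the documented criterion for
inconsistent inputs.

**Unknowns.**  A tristate `unknown` never satisfies any scoring
condition, and an unknown personal-data status makes the GDPR rubric not
applicable (with a logged caveat) rather than scoring it 0 — the dataset
may well contain personal data, and silently scoring would overstate what
the audit established.

**Answer quality.**  Completeness (answer present) and coherence (answer
consistent with its context) are binary human judgments recorded as
input; the package aggregates them.  A question's grade is the obtained
sum divided by 2 × number of respondents; *low* is strict (< 0.75, so a
grade of exactly 75% is acceptable).  An absent answer cannot be coherent:
completeness 0 forces coherence 0 at the type level.

## Harmonisation

Round 2 is the validation round, so the merged record starts from the
round-2 row.  Field-wise: a missing round-2 answer (tokens `unknown`,
`unreported`, `none_or_unknown`, or empty) is filled from round 1; when
both rounds give substantive but different answers, the answer of the
respondent with the higher summed coherence is kept, with ties going to
round 2.  Every fill and resolution is appended to the provenance log, so
the merged table carries a complete edit trail.  Two rows for the same
dataset within one round cannot be merged and raise an integrity error.

Anonymisation draws random IDs as a seeded permutation of 1..N per entity
class (bijective and reproducible by construction), re-keys records,
answer qualities and provenance entries, reclassifies the free-text
columns with rules (`language` → english / not_english / translated; a
data-owner name → "there is an identified data owner"), drops all raw
free text, and redacts provenance values that contain deny-listed
strings.  A deny-list scan utility verifies that no original identifier
survives in the serialised output.

## Synthetic cohorts

The generator emulates the study population the rubrics were designed
for: 30 datasets out of 38 surveyed, described by 19 respondents, with
species quotas swine 10 / salmonids 9 / cattle 9 / poultry 4 including
two swine∩cattle datasets, 11 datasets with personal data, 16 with
identified metadata, 20 not in English (one translated), and
rubric-relevant marginals matching the per-criterion fulfilment counts a
cohort of this kind exhibits (F1 16, F2 4, F3 1, A1 22, A2 8, I1 25,
I2 14, I3 1, I4 1, R1 18, R2 10, R3 1 fulfilled).  Where a published
breakdown over-allocates (the five vocabulary-practice counts sum to 32
over 30 datasets), the largest category was reduced (owner-defined
12 → 10); where only bounds are given ("6 or fewer"), a value was fixed
once (movements 6, economic 5, behaviour 3).  Partial-credit counts
(e.g. F1 = ½) are not published anywhere and were fixed once at
plausible values.

Two modes:

* **Quota mode** (default): every configured count is hit exactly; the
  randomness is in *which* dataset gets which category.  Structural
  constraints hold by construction — metadata-dependent fields are
  assigned only among metadata-holding datasets and forced to their
  absent values elsewhere; governance states are assigned only among
  personal-data datasets; every generated record passes
  `validate_record`.
* **Weights mode**: independent draws with probabilities equal to the
  quota proportions, for statistical tests (the recovery suite checks
  marginals within 3 standard errors at n = 10 000).

Good-practice fields are correlated through a per-dataset standard-normal
latent propensity: each such field ranks datasets by latent + N(0, σ²)
noise and fills its best-first categories down the ranking.  σ defaults
to 1.0 — equal weight to the shared propensity and field-specific noise,
i.e. moderate correlation: well-run datasets tend to score well across
criteria without the joint distribution being forced.  Consequently
*joint* statistics (number of datasets fulfilling ≥ 6 criteria, GDPR
owner/user mean split) are emergent and seed-dependent, not configured;
the per-dataset score vectors of any real cohort cannot be reproduced
from marginals alone, and the package does not pretend otherwise.

Round structure: 25 datasets answered in round 1, 5 new in round 2, and 4
of the round-1 datasets re-answered in round 2 by a second respondent
with a fraction (default 0.2) of substantive fields perturbed.  The
round-2 respondent of a re-answered dataset is the more coherent of the
pair, so merging the generated rounds reproduces the generated cohort
exactly — which is what makes the merge logic testable end to end.

Answer qualities are Bernoulli per survey category, with per-category
(P(answered), P(coherent | answered)) defaults of (.97, .93) governance,
(.92, .87) description, (.75, .67) management, (.70, .64) data model,
(.60, .58) metadata — high-quality governance/description answers and
poor metadata answers, the gradient such surveys show.

What the generator does not emulate: free-text noise beyond the two
reclassifiable columns, respondent-specific answering styles, item
non-response patterns correlated within a record, and real joint
dependence between rubric items beyond one latent factor.  Tests passing
on synthetic cohorts therefore demonstrate the pipeline's correctness and
its exact-count bookkeeping, not distributional realism of any real
survey.

## Numerical and formatting choices

* Percentages: nearest integer, halves away from zero, computed in exact
  integer arithmetic (`(200·n + d) // (2·d)`); this reproduces every
  count/percentage pair the summaries print (30/38 → 79, 6/19 → 32,
  20/30 → 67, 4/30 → 13, …).
* Quality threshold: strict inequality at 0.75.
* Categorical tokens are matched case-insensitively after trimming; an
  unrecognised token falls back to the enum's "don't know" member
  (`unknown` / `unreported` / `none_or_unknown`) with a logged warning
  where one exists, and is a schema error otherwise.
* CSV is UTF-8 with a header; XLSX uses the first sheet; multi-valued
  answers serialise as sorted `;`-joined token lists.
* Outputs contain no timestamps, so a rerun with the same seed and inputs
  is byte-identical.
* Seeds: ID permutation and generator share the run seed; the round
  construction uses an independent stream spawned from it.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
cohort's natural size (30 datasets, 19 respondents, 31 graded questions);
the statistical recovery checks use n = 10 000 weights-mode records, and
the monotonicity suite checks 10 000 single-field-upgrade record pairs.
Everything completes in well under a minute on one CPU.

## Known limitations

* The coherence judgment is human input; the package only aggregates it.
* The identifying-element checklist behind F1/F2/R1 is a configurable
  convention, not a community standard.
* GDPR assessment covers accountability only; a dataset scoring 2/2 may
  still fail the six process-oriented principles.
* Per-dataset results of any specific real cohort require that cohort's
  data; synthetic cohorts reproduce marginal structure only.
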