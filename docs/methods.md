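# Methods

## Screening model

The pipeline operationalizes "the record refers to the product" as the
union of two parallel criteria: a lexical criterion (the text contains a
case-insensitive substring match to a fixed 20-string list of brand-name
spellings, all within Levenshtein distance 1 of the seed term
`sublocade`) and a contextual criterion (the record was posted in the
product's own subreddit).  Cessation relevance is a second lexical gate
over eight keywords, and a date window restricts records to the period of
US commercial availability covered by the study design
(2018-03-01 through 2022-08-31).  Stage order is fixed — referent gate,
deduplication, cessation gate, date window — and per-stage counts form
the attrition table.

Two deliberate matching conventions:

- **Substring, not word-boundary, matching is the default.**  The
  criteria are stated in terms of fields that *contain* a keyword, and we
  reproduce that faithfully, including its false-positive surface
  ("finale" matches *final*, "quite" matches *quit*).  A stricter
  token mode (`match_mode="generative_token"` for the brand name,
  `token_mode=True` for cessation keywords) is available for sensitivity
  analyses; the generative token mode also catches distance-1
  misspellings that are not on the explicit list.
- **The explicit 20-string list is the default operationalization** of
  "within Levenshtein distance 1", because that is how the criterion was
  applied in practice; the exhaustive distance-d enumerator
  (`enumerate_variants`) exists to audit the list and to support the
  generative mode.  For the 9-letter all-distinct seed over a 26-letter
  alphabet the full distance-1 neighborhood has
  25·9 (substitutions) + 9 (deletions) + 26·10 − 9 (distinct insertions)
  + 1 (the seed) = 486 strings; the enumerator is validated against
  exhaustive generate-and-filter brute force on small alphabets and
  against an independent alignment library (edlib) in the test suite.

Edit distance is the classic two-row dynamic program with unit costs.
Case folding is plain ASCII lowercasing throughout — every keyword is
ASCII, so locale-aware folding would add risk without benefit.

## Dates, normalization

Epoch timestamps are interpreted in UTC, the only convention under which
the window boundaries are reproducible across machines.  Submission text
is title and selftext joined by a single newline, so a substring match
can never span the two fields; comment text is the body verbatim.
Records with no text are flagged, not dropped (the contextual criterion
can still retain them).  Malformed JSON lines are counted and skipped:
corpus dumps in the wild contain them, and aborting on line 3 of a
million-line file helps nobody.

## Privacy

Identifiers are tokenized with BLAKE2b keyed by a salt, truncated to 10
base-36 digits (≈52 bits; the birthday bound keeps collision probability
below ~10⁻⁸ at 10⁵ identifiers).  The construction is deterministic per
salt — equality structure (same author ⇒ same token) survives, raw
values do not — and an empty salt is refused rather than silently
producing unsalted tokens.  The salt never appears in any artifact.
Redaction applies ordered regular-expression rules (emails, URLs before
u/-mentions, North-American phone shapes, username mentions), each span
replaced by a labelled placeholder; the phone pattern requires phone-like
separators so dose sequences such as "100, 300, 300, 100" are untouched.
The rule set is a floor: rules are data and can be extended in config.
Redaction is idempotent because no placeholder is matchable by any
default rule.

## Sampling

Simple random sampling without replacement, sample size =
half-up-round(n × fraction) (6082 → 3041 at 50%; the half-up choice only
matters at odd n), seeded via `numpy.random.default_rng`, output in
original corpus order.  The seed is mandatory in the pipeline config and
echoed into artifact provenance, because an irreproducible sample would
make the rest of the pipeline unauditable.

## Codebook validation

Annotations are typed rows (pydantic) whose *logical* consistency is
checked separately, producing violation records rather than exceptions:
contradictions (a cessation subtype without the any-cessation flag, a
construct coded on a record not coded as a product referent, course
length ≠ number of doses, final dose ≠ last course element, inverted
duration nesting) are errors; odd-but-possible values (a dose that is
positive, ≤ 300 mg, but not a marketed 100/300 mg dose) are warnings,
since partially administered doses are a documented practice.  The
300 mg cap is the marketed maximum — a package decision, since the
codebook itself states no bound.  `cessation_timing`
(retrospective/planned) is carried in the schema because the study's
results report that split, though the published field table does not
list the column.

## Summaries

Percentages are half-up rounded at one decimal and always stored beside
their numerator/denominator pair.  Dispersion uses sample conventions:
SD with n−1 (reported as 0 with a flag when only one account exists),
linear-interpolation quantiles, IQR = Q3 − Q1.  The denominator chain is:
referent percent over the coded sample; cessation over confirmed
referents; timing and withdrawal over cessation records.  Author-level
aggregates use the obfuscated account token as the unit, inheriting the
platform's caveat that one person may hold several accounts; no
correction is attempted.  Dose-sequence frequencies count full reported
courses; the final-dose table additionally pools final-dose-only reports.

## Synthetic corpus

The generator emulates the statistical structure the study corpus
exhibits, with every planted property returned as ground truth:

| property | default | rationale |
|---|---|---|
| records per account | lognormal, moment-matched to mean 4.5 / SD 13.6, floored at 1, capped at 275 | observed per-account moments and range; lognormal is the standard heavy-tailed family for user-activity counts |
| target-subreddit share | 0.976 | observed corpus concentration |
| term mention probability | 0.95 (80% exact spelling, else a listed misspelling) | a product-centred candidate corpus is mention-dense |
| decoy probability | 0.05 | distance-2 strings that must *not* match |
| cessation keyword probability | 0.55 | puts real work on the cessation gate |
| genuine-context share among keyword records | 0.438 | observed cessation prevalence among coded referents |
| withdrawal / retrospective given cessation | 0.087 / 0.828 | observed conditional prevalences |
| referent confirmation rate | 0.974 | observed manual-confirmation rate |
| final dose = 100 mg | 0.794 | observed final-dose mode share |
| doses before cessation | 1 + negative binomial (mean 4, SD 2.9 overall) | observed count moments |
| out-of-window fraction | 0.05 | gives the date filter work |
| duplicates | 25 exact copies | exercises deduplication |
| PII probability | 0.03 | plants all four redaction classes |

Flooring and capping the rounded lognormal biases the realized moments
slightly (≈4.7 / ≈12.0 at large n against targets 4.5 / 13.6); the
generator test asserts mean within ±1.0 and SD within ±6 at 3000
accounts — heavy-tailed SDs converge slowly and tighter bounds would
test the RNG, not the model.  Text is template-based with audited
vocabulary: base templates contain no screening keyword or brand
variant, so a keyword appears in a record iff the generator planted it —
either in a genuine cessation sentence or in a non-cessation sense
("the finale of that show…"), which is how the known false-positive
surface of substring matching is made measurable
(`evaluate_recovery` scores the cessation gate against construct truth,
the other gates against lexical truth).  Gold annotations are drawn for
every record that truly passes all gates and satisfy every codebook
invariant by construction.

What the generator does **not** emulate: natural language (templates,
not narratives), construct correlation across an author's records,
thread structure, or real misspelling frequencies.  Passing tests
therefore demonstrate that the *machinery* is correct under the study's
statistical conditions — not that the criteria have any particular
precision/recall on real Reddit text.

## Problem sizes and determinism

Unit tests run on corpora of ~150–400 accounts; the full-scale
acceptance checks use the default 1100 accounts (~5000 records), where
planted prevalences are recovered within 3 binomial SE, and 10,000
random texts for matcher/oracle equivalence.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng` or
`random.Random`; artifact provenance headers deliberately contain no
wall-clock timestamps, so a config + seed pair reproduces every artifact
byte-for-byte.

## Known limitations

- Substring matching's false positives are reproduced by design; the
  token modes are offered but unvalidated against any human standard.
- The published corpus itself cannot be rebuilt (the upstream archive is
  gone); arithmetic relations among published counts are reproduced
  exactly, corpus-level counts are not reproducible and are not claimed.
- One published percentage (97.4% for confirmed referents) is not
  derivable from its stated numerator and the coded-sample denominator
  (2692/3041 = 88.5%); the summary reports computed percentages only.
- Redaction rules are regex floors; free-text PII beyond the four
  classes (names, addresses) is out of scope, as is paraphrasing.
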