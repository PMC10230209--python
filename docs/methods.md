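# Methods

## Identifier derivation

The anonymous identifier is the SHA-256 digest (64 lowercase hex
characters) of the UTF-8 encoding of a canonical string: the optional
salt, then each configured field value, joined by a delimiter
(default `|`). Design choices, each made where the procedure itself is
underdetermined:

- **Hash standard.** SHA-256, the current default of the tooling class
  used for this kind of pseudonymisation; the standard used is recorded
  in every report for provenance.
- **Delimiter joining** rather than bare concatenation, so
  `("M","1A")` and `("M1","A")` cannot collide. A delimiter occurring
  *inside* a field value is a hard error naming the record, never a
  silent ambiguity.
- **Salting.** Default empty so worked examples are reproducible.
  Unsalted digests of a small input space (two genders × a structured
  service-number format) are dictionary-attackable; real deployments
  must set a secret salt, shared by the parties to a linkage.

## Data preparation

Gender is trimmed, case-folded and mapped `{m, male} → M`,
`{f, female} → F`; anything else is *invalid*, blank/absent is
*missing*. Service numbers are trimmed, uppercased and stripped of
internal whitespace, then validated against an anchored pattern.
Records missing either key field are always deleted (listwise, the
reference procedure); format-inconsistent but present service numbers
are kept after canonicalization unless `strict` is set, because the
reference procedure describes format *checking* without an exclusion
count. Each excluded record gets exactly one reason — gender is
checked before service number — so the audit trail satisfies
`|clean| + |excluded| = |raw|`.

The default pattern `^[A-Z0-9]+$` accepts any canonical alphanumeric
value, since no true service-number format is public; stricter presets
(`two-letters-six-digits`, `eight-digits`) ship with the package.

## Primary/duplicate labeling and the 2×2 validation

Under a key, the first record (by roster position) holding each value
is primary, later holders duplicate; a `last` convention exists for
audit against tools whose duplicate-marking defaults differ. All four
cross-tab counts are functions of (N, #gold groups, #hash groups)
only, so they are provably convention-invariant — a property test
checks this.

Because the hash input contains the service number, the hash partition
refines the gold partition: cell c (gold-primary ∧ hash-duplicate) is
structurally zero and sensitivity `a/(a+c)` is structurally 1. The
scientifically informative numbers are cell b — gold-duplicate records
the hash recognises as distinct individuals (cross-gender collisions) —
and specificity `d/(b+d)`.

Statistics:

- **Confidence intervals**: Clopper–Pearson exact, via beta-quantile
  inversion of the binomial tails (`scipy.stats.beta.ppf`), with the
  closed forms `(α/2)^(1/n)` / `1−(α/2)^(1/n)` at the boundaries.
  Chosen because it reproduces the reference results where the Wilson
  score interval does not (e.g. upper bound at 316/326: 98.5% exact vs
  98.3% Wilson); Wilson remains available via `ci_method="wilson"`.
- **Chi-square**: uncorrected Pearson statistic on the 2×2 table
  (integer arithmetic in the numerator; no Yates correction — the
  uncorrected form is what the reference statistics match), p-value
  from χ²(1). Any zero margin leaves the statistic *undefined* in the
  report rather than 0.
- **AUC**: the ROC of a single-threshold binary classifier is the
  polyline (0,0)–(1−spec, sens)–(1,1), whose trapezoidal area is
  exactly `(sens+spec)/2`; the report labels the AUC with this formula
  since no continuous test variable exists in this design.
- **Rounding** only at the formatting layer: percentages to 1 decimal
  place, round-half-up (`decimal`, not banker's rounding), chi-square
  to 3 decimals, `p < 0.001` below that threshold.

Degenerate inputs: an empty margin flags the affected statistic as
undefined; a roster that cleans to zero records raises
`EmptyRosterError`, which the CLI maps to a distinct exit code (3).

## One-to-one linkage

Each roster is collapsed to its primary records (one per uid) and the
match count is the size of the uid-set intersection. Collapsing first
makes the merge total while a `strict` mode errors on duplicate keys,
mimicking a hard one-to-one merge. Matching is exact equality on the
identifier only — no fuzzy fallback. Diagnostics report how many
duplicates each side collapsed.

## Synthetic rosters and the truth oracle

The generator emulates the structure the analysis assumes, not any
real roster: latent persons (default 90% male, reflecting the heavily
male service population), service numbers drawn as two letters + six
digits, and

- **repeat contacts**: every person contributes ≥1 record; the extra
  `n_records − n_persons` contacts are spread by multinomial allocation
  with geometric weights (`contact_geom_p`, default 0.5), giving the
  few-heavy-users tail typical of welfare contact data. Defaults
  (1,000 persons, 2,500 records) sit at the scale of the smaller
  reference rosters; the validation sweeps run smaller rosters
  (tens of persons, low hundreds of records) because every statistic
  checked is an exact count, not an asymptotic quantity.
- **collisions**: `collision_pairs` person pairs share one service
  number with forced discordant gender (default 10, the order of
  magnitude seen in the reference rosters). A separate
  `same_gender_collision_pairs` knob (default 0) plants collisions the
  two-field hash *cannot* resolve, to demonstrate that blind spot.
- **missingness** (default 1% per key field) and **formatting noise**
  (default 10%): noise applies only reversible case/whitespace
  mangling, so normalization provably recovers the canonical value;
  missingness is applied after noise.

All randomness flows from one seeded `numpy.random.Generator`; a fixed
seed yields byte-identical rosters.

The oracle replays cleaning and both dedup passes directly on the
latent canonical fields with a plain first-occurrence scan and counts
the four cells one record at a time — no code shared with the pipeline
— so pipeline-vs-oracle equality over seeded sweeps is a genuine
dual-route check.

What the generator does **not** emulate: real name/DOB fields,
same-person records with *inconsistent* gender entries (data-entry
errors that would split one person into two uids), non-reversible
corruption of service numbers, and within-roster temporal structure.
Passing tests therefore show the pipeline computes its statistics
correctly under the stated model, not that real rosters are this
clean.

Reference rosters are reconstructed from published cross-tabulation
margins by `roster_from_crosstab(n, n_gold, n_hash)`: `n_gold` service
numbers of which `n_hash − n_gold` are held by an M/F pair, padded
with repeat contacts to `n` records and shuffled. Any roster with
those margins yields identical statistics (they depend only on the
margins), so the reconstruction is exact by construction, not by
tuning.

## Known limitations

- A two-field hash cannot separate same-gender individuals sharing a
  service number, and conversely a typo in either field splits one
  person into two identifiers; richer field sets reduce the former at
  the cost of more of the latter.
- The AUC is a deterministic identity of (sensitivity, specificity)
  in this single-threshold design and adds no information beyond them.
- Specificity comparisons across rosters of very different size are
  confounded by the duplicate-margin size `b + d`.
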