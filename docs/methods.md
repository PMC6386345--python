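# Methods

## The classification model

The classifier is a deterministic rule system, not a statistical model.
Its unit of analysis is one free-text treatment record; its output space is
eight mutually exclusive categories: six drug-defined first-line groups
(TKI; pemetrexed+bevacizumab; pemetrexed-based; bevacizumab-based;
platinum doublet; single agent), plus explicit no-treatment and unknown.

Historically this kind of pipeline is run as *sequential elimination*: the
corpus is searched one group at a time in a fixed order, from the most
specific drug sets to the broadest, and records matched at each stage are
removed before the next search. For a single record that procedure is
exactly equivalent to evaluating an ordered precedence over the drug
classes present among its non-negated mentions, which is how
`assign_group` implements it — the per-record formulation yields the same
labels while giving each record an auditable `rule_fired` value. The
precedence is:

1. any TKI mention → `tki`
2. pemetrexed AND bevacizumab → `pem_bev` (platinum/other may co-occur)
3. pemetrexed → `pemetrexed_based`
4. bevacizumab → `bevacizumab_based`
5. platinum AND a distinct other-chemotherapy drug → `platinum_doublet`
6. any remaining drug mention → `single_agent`
7. a whole-record no-treatment statement → `no_treatment`
8. otherwise → `unknown`

Distinctness is by canonical drug name, never by mention count, so
"carboplatin … carboplatin" is a single agent. Because the no-treatment
search runs after all six drug searches, a record with a surviving drug
mention can never be `no_treatment`.

**Catch-all semantics.** The six groups do not cover multi-drug
combinations without platinum, pemetrexed, bevacizumab or a TKI (e.g.
gemcitabine + docetaxel). In the default `faithful` mode these fall into
the stage-6 single-agent catch-all, mirroring how an elimination pipeline
behaves (and why single-agent precision is structurally the weakest
metric). `strict` mode labels them `unknown` instead.

## Matching

Text is normalized (lower-case, whitespace collapsed) before matching; all
reported spans refer to the normalized string. Every lexicon variant is a
case-insensitive pattern; variants are tried longest-first and matching is
non-overlapping, so "carboplatin" is never double-counted as "carbo" +
remainder. Word boundaries are on by default ("carbo" does not fire inside
"carbohydrate"), and internal separators of multi-word variants accept
whitespace, `/`, `+` and `-` interchangeably because registry text is
telegraphic ("carbo/taxol").

Misspellings are curated variant lists, not edit-distance matching: fuzzy
matching would change the error characteristics of the rule system in ways
that are hard to audit, whereas a curated list is reviewable and
extensible per corpus.

**Negation and uncertainty.** Registry phrasing gives no reliable sentence
structure, so scope is a fixed character window (default 40 characters,
configurable) rather than a linguistic unit, and windows deliberately
cross punctuation. Forward phrases ("not a candidate for", "did not
receive") cover mentions starting within the window after the phrase;
backward-capable phrases ("refused", "declined", "never received") also
cover mentions ending within the window before them. Uncertainty phrases
("unknown if given") set an independent flag; by default uncertain
mentions still count as treatment evidence — that choice reproduces the
false-positive behaviour a pure word-matching pipeline exhibits — and
excluding them (`count_uncertain=False`, implied by `--mode strict` on the
CLI) is the documented alternative. 40 characters is roughly one
telegraphic clause; the window is a parameter precisely because it is the
least principled constant in the system.

Dates inside the text are never parsed; only the structured record date
orders records.

## Patient-level aggregation

A patient's first-line group is the group of their earliest treatment
record. Policy details the field convention leaves open, fixed here and
configurable:

- **Undated records** sort before dated ones by default
  (`undated-first`): a missing date may well be the earliest report, and
  preferring it keeps positive drug evidence from being displaced by a
  later dated record. `undated-last` is available.
- **Date ties** break by record id, lexicographically, for determinism.
- **Positive vs negative evidence:** a patient with both a treatment-group
  record and a no-treatment record is labeled by the treatment record
  regardless of dates; an explicit refusal coexisting with a drug report
  usually marks a treatment decision sequence, not an error.
- `no_treatment` beats `unknown`: an explicit statement outweighs absence
  of information.

## Evaluation statistics

Each group is dichotomized one-vs-rest at patient level. With tp = both
methods positive, fp = algorithm-only positive, fn = gold-only positive,
tn = both negative, n = tp+fp+fn+tn:

- percent agreement = (tp+tn)/n
- Cohen's κ = (p_o − p_e)/(1 − p_e), p_o the observed agreement and
  p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)]/n² the chance agreement from the
  marginals; undefined when p_e = 1 (degenerate marginals), which raises.
- sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), PPV = tp/(tp+fp),
  NPV = tn/(tn+fn); a zero denominator raises a named error.
- error counts: fp, fn, fp+fn, also as percentages of n.

95% CIs use the Wilson score interval for proportions (statsmodels
`proportion_confint`; Wald and Clopper–Pearson selectable) and the
asymptotic large-sample standard error of κ (Fleiss–Cohen–Everitt form)
clipped to [−1, 1]. Wilson is the default because it behaves sensibly at
proportions near 0 and 1, where several of these metrics live. The κ point
estimate is validated in the test suite against an independent computation
on expanded label vectors (scikit-learn's implementation) to 1e−12.

Display rounding is decimal half-up: one decimal for percentages, two for
kappa.

## The synthetic corpus generator

The generator produces what the classifier consumes: per patient, a gold
group drawn from a prevalence vector, one informative record rendered from
phrase templates consistent with that group, and a Poisson number of extra
records (blank or repeated-regimen). Defaults are chosen to emulate a
realistic stage IV NSCLC registry cohort of the 2012–2014 era:

- prevalence: 32% untreated, 22% unknown, the remaining 46% split across
  the six groups with platinum doublets (15.5%) and pemetrexed-based
  (12%) most common and single agents rarest (2%);
- records per patient: 1 + Poisson(0.435), mean ≈ 1.44;
- noise rates (per drug rendering / per record): brand 0.20, abbreviation
  0.10, misspelling 0.03, negated distractor 0.05, uncertainty 0.05,
  blank extra record 0.50, undated record 0.05.

Noise channels and their analytic status:

- **Surface swaps** (brand/abbreviation/misspelling) resolve through the
  lexicon back to the same canonical, so they are label-preserving.
- **Negated distractors** append "not a candidate for X" with X from a
  class absent from the gold regimen; the forward negation window always
  covers X, so these are label-preserving — and a regression in negation
  handling shows up as a label flip, which is the point.
- **Blank extra records** classify as unknown and never displace a
  treatment record at patient level.
- **Uncertainty phrasing** adds, to untreated patients only, an extra
  record "D recommended, unknown if given" with D uniform over a fixed
  five-drug list. When uncertain mentions count as evidence this flips the
  patient to D's group; it is the generator's one off-diagonal channel.

`expected_confusion` therefore returns an identity matrix except on the
untreated row, where mass p_uncertainty redistributes over the five
uncertainty drugs' target groups — enumerable exactly from the template
list. Custom template pools fall outside this closed form and raise.

**What the generator does not emulate:** real registry text mixes multiple
treatments discussed over time in one field, misspellings outside the
curated list, facility boilerplate, and gold-standard (reviewer) error.
Passing round-trip tests therefore demonstrates internal consistency of
matcher, classifier and evaluator — not the accuracy the rule system would
achieve on real registry text, which depends on lexicon completeness
against that corpus.

## Problem sizes in the tests

The round-trip and invariant tests run at 400–1,000 synthetic patients;
Monte-Carlo checks of the confusion closed form use 5,000 patients × 3
seeds with tolerance 0.03 on the affected row (binomial 3σ at that n is
about 0.017) and exact identity elsewhere. The published validation tables
are evaluated at their native n = 17,310, which costs nothing since the
metrics are closed-form in the counts.

## Known limitations

- Negation scope is a character window, not a parse; distant or
  discontinuous negation ("erlotinib … ultimately was not given" beyond 40
  characters) is missed, and an intervening drug inside another drug's
  window can be spuriously negated. Window size is configurable but no
  window is right for all phrasing.
- The lexicon is era-specific: immune checkpoint inhibitors and later
  TKIs are deliberately absent; applying the default lexicon outside
  2012–2014 NSCLC will misclassify.
- First-line identification trusts the structured record date; drug start
  dates inside the text are ignored.
- The exact historical search-string lists for this problem are not
  public; the packaged lexicon is a reconstruction faithful to the
  documented procedure (drug classes, variant handling, phrase types)
  rather than a copy of any specific production list.
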