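# Methods

This note documents the models, rule tables and design decisions behind
`senseinv`, and what its synthetic benchmarks do and do not demonstrate.

## Record model and file format

A sense inventory is an ordered table of records `(SF, LF, Source)` plus
derived fields: normalized forms (`NormSF`, `NormLF`), identifiers
(`RecordID`, `SFUI`, `LFUI`, `GroupID`) and the `Modified` flag. Files are
tab-separated UTF-8 with a header and the ten core columns; auxiliary
per-source columns (`SFEUI`, `LFEUI`, `Type`, `PrefSF`, `Count`, `Score`,
`Frequency`, `UMLS.CUI`, …) are appended after `Modified` in the
"auxiliary" variant. Quoting is csv-minimal (fields containing the
delimiter or newlines are quoted); TSV is used because long forms routinely
contain commas. Text is normalized to Unicode NFC on read so identifier
assignment and string metrics do not depend on the encoding of the source
file. Normalized forms that come out empty are serialized as the literal
string `null`.

## Lexical normalization

**Short forms** (CARD-style): lowercase → strip surrounding whitespace →
delete periods → replace every remaining non-alphanumeric, non-space
character with `_` → collapse internal whitespace to `_`. The
transformation is idempotent; an input consisting only of periods and
whitespace yields `null`. Only the period is *deleted*; hyphen, slash and
the rest map to underscore, preserving token boundaries (`D/C` → `d_c`).

**Long forms** follow an LVG-style flow applied in a fixed order with token
order preserved (no alphabetical sorting):
genitives → plurals → punctuation → stop words → lowercase → uninflection →
synonyms. The flow *order* and step semantics are the contract; the rule
tables are deliberately small, pinned, rule-driven approximations of the
full LVG toolset (whose tables are external and version-dependent), and all
of them are overridable through `NormalizationConfig` or a plain-text rule
file:

- stop words: `a an the of and with for in on to by` (10 words, pinned for
  determinism);
- genitive markers: `'s`, `'` (straight and curly);
- plural rules (first match wins): `-ies→-y`, `-sses→-ss`, `-ches→-ch`,
  `-shes→-sh`, `-xes→-x`, `-zes→-z`, `-s→`; words ending `-ss/-us/-is` and a
  short irregular list (`diabetes`, `series`, …) are exempt;
- uninflection: `-ied→-y`, `-ing→`, `-ed→`, with doubled-consonant repair
  (`stopped` → `stop`; `ll`/`ss` kept) and a minimum stem length of 3;
- synonym map: empty by default (a `tumour→tumor`-style table can be
  supplied).

Derivational morphology and UMLS-backed synonym expansion are out of scope;
spelling correction belongs to quality control and is advisory there.

**Pre-pairing normalization** rewrites whole tokens before similarity
comparison: roman numerals `i`–`x` → digits and five common ion symbols
(`na+ k+ ca2+ cl- mg2+`) → element names, on lowercased text. Digits (not
number words) were chosen for romans so that `type II` and `type 2` unify;
the table is user-overridable. Note the side effect that a bare token `x`
becomes `10` — accepted, since single-letter tokens inside long forms are
rare and the rewrite is applied symmetrically to both strings of a pair.

## Identifiers

`R`/`S`/`L`/`G` plus a zero-padded number of at least six digits. Record
ids follow inventory (source) order; S/L ids are keyed on the **raw**
string (so `O.C.` and `OC` get distinct SFUIs even though both normalize to
`oc`) and numbered by first occurrence, which makes assignment
deterministic. Indices past 999,999 widen the field rather than wrap.

## Cross-mapping

Synonymy is only defined within one abbreviation, so candidate pairs are
blocked on the normalized short form. Similarity is computed on the
normalized long form (falling back to the raw long form when normalization
yields `null`), after pre-pairing replacement — normalization removes
exactly the variation (case, plural, genitive, stop words, punctuation)
that should not count against a pair.

Two prefilters follow the stated conventions exactly: the training-data
filter keeps pairs with plain Levenshtein ratio **strictly greater than**
0.8 (same-SF pairs are potential positives, different-SF pairs pertinent
negatives — hard negatives for the classifier), while the prediction-time
candidate filter keeps within-block pairs with partial ratio **at least**
0.5. Annotation sampling uses a ceiling so small strata are never empty and
is seed-reproducible.

### Features

All five features are ratios in [0, 1], symmetric, computed on the
pairing-normalized strings:

1. *Levenshtein ratio*: `1 − indel(a,b)/(|a|+|b|)` with indel distance
   (insert/delete cost 1, substitution cost 2, equivalently
   `|a|+|b|−2·LCS`). This convention is shared by the whole metric family
   for internal consistency.
2. *partial ratio*: best ratio of the shorter string against any
   equal-length contiguous window of the longer.
3. *token-sort ratio*: ratio after whitespace tokenization, lexicographic
   sort, single-space rejoin.
4. *token-set ratio*: with t0 = sorted token intersection, t1/t2 = t0 plus
   the tokens unique to each side, the maximum pairwise ratio among
   t0/t1/t2. Set semantics deduplicate repeated tokens, so
   `token_set ≥ token_sort` holds for duplicate-free token sequences (and
   can fail when tokens repeat).
5. *numeric similarity*: multiset Jaccard of maximal digit runs; two
   digit-free strings score 1 (neutral), `type 1` vs `type 2` score 0.

The tests verify every metric against independent brute-force oracles
(weighted edit-distance DP, exhaustive window enumeration) exhaustively
over a small alphabet and on random pairs.

### Classifier and threshold

The default backend is gradient-boosted trees (LightGBM) with
deterministic, single-threaded settings and small-data-friendly leaf
parameters; a logistic-regression backend exists as a baseline and for
fast tests. The backend is pluggable behind a fixed five-feature interface;
transformer/embedding features are out of scope.

Evaluation is stratified K-fold cross-validation (K = 5 by default)
reporting per-fold precision/recall/F1. Labeled pairs are put into a
canonical order (label, feature vector, pair id) before folding so the
report is invariant to input row order at a fixed seed.

Because a wrong merge contaminates a whole group while a missed merge only
leaves duplication, deployment uses a high-specificity threshold: the
smallest predicted-probability cutoff whose precision on validation pairs
reaches a target (default 0.99). If the target is unattainable the
best-precision threshold is returned with a warning. In the full pipeline
the threshold is selected on the training pairs (an out-of-band validation
set can be supplied instead by calling `select_threshold` directly).

## Grouping

Positive pairs are edges over records; groups are connected components
computed by union-find with path compression (the contract is "connected
components", so any equivalent implementation qualifies). Closure resolves
classifier non-transitivity: if A~B and B~C are accepted, A, B, C share a
group even if A~C was scored negative. Unlinked records become singleton
groups, so groups always partition the records and every normalized short
form contributes at least one group. Groups are ordered by smallest member
record id and numbered `G000001` upward. Correlation clustering honoring
negative edges was deliberately not attempted.

## Quality control

Four flagging heuristics, run in record order (duplicate, punctuation,
character mismatch, spelling per record):

- *duplicate*: identical raw `(Source, SF, LF)` triple; the first
  occurrence is kept, later ones flagged. Raw, not normalized — the rule
  targets exact duplicates.
- *punctuation*: leading punctuation run, trailing run other than a single
  period, or ≥ 2 consecutive punctuation characters. This is a concrete
  operationalization of "excessive or misplaced" punctuation; each
  sub-rule can be toggled.
- *character mismatch*: some alphanumeric character of the SF never occurs
  in the LF (case-insensitive membership, order ignored).
- *spelling*: an alphabetic LF token of length ≥ 4 is absent from a
  supplied word corpus. The length guard avoids flagging short embedded
  abbreviations; the corpus is an input because medically adequate word
  lists derive from licensed resources. The flag is advisory — corrections
  are a human decision, never automatic.

Review actions: *retire* moves the record, fields intact, to a side
inventory; *modify* applies corrected fields, recomputes the normalized
forms and sets `Modified = "modified"`; record ids never change. Actions
whose record id is absent (e.g. already retired) are no-ops, which makes
applying a fixed action list idempotent.

## Statistics

`summarize` counts records, distinct normalized short forms, distinct raw
long forms, distinct raw (SF, LF) pairs, groups, and records in singleton
groups ("without synonyms"); senses per abbreviation is the number of
distinct *groups* per normalized short form (groups, not long forms, are
the unit of meaning after cross-mapping). Percentages round half away from
zero at integer precision; mean senses rounds half away from zero at two
decimals. The lookup-reduction figure is `100·(1 − G/R)` for G groups over
R records.

## Coverage

An annotated corpus is a list of observed abbreviation instances (surface
token, normalized SF, optional sense as normalized-long-form text).
With `covered(instance)` defined per metric:

- abbreviation coverage: the instance's normalized SF occurs in the
  inventory. micro = covered instances / all instances; macro = mean of
  the 0/1 indicator over distinct normalized SFs.
- sense coverage (over sense-labeled instances): some record shares the
  instance's normalized SF and its normalized LF equals the annotated
  sense — or, in group mode, some synonym group contains both the SF and
  the sense. micro = covered labeled instances / all labeled instances;
  macro = mean over distinct SFs of each SF's per-instance covered
  fraction (averaging over abbreviations, not over distinct senses, which
  the macro/micro wording leaves open).

Adding records can only add coverage, so all four metrics are monotone
under inventory growth. Abbreviation detection in raw text is out of
scope; the corpus arrives pre-annotated.

## Synthetic fixtures

The generator emulates the real setting: a bank of concepts (canonical
abbreviation = word initials, canonical long form of 2–4 vocabulary words,
long forms unique), of which a configurable fraction (default ambiguity
0.2) reuse an existing abbreviation with a different long form whose word
initials still spell it (so ambiguity does not masquerade as a
character-mismatch error). Each concept is written canonically by one
"home" source; other sources include it with probability 0.7 and apply
lexical variants at per-record rates: SF lowercasing 0.3 and
period-insertion 0.2; LF pluralization 0.25, genitive 0.05, stop-word
insertion 0.15, adjacent-token swap 0.1, misspelling 0.0 by default. The
first five variants are exactly what normalization removes; token swap and
misspelling are not removable and act as the noise axes. QC errors are
injected at stated rates with ground truth recorded, mutating records
after variant generation so duplicates stay exact. Labeled pairs are
derived transitively from the truth (all within-block pairs labeled by
shared concept, plus sampled cross-block negatives). The spell-check corpus
is derived from the clean generated text plus the vocabulary, so a clean
fixture is flag-free by construction. The annotated corpus draws concepts
with Zipf weights (exponent 1.1) in bank order.

What passing the synthetic benchmarks shows: the pipeline's machinery —
normalization, blocking, features, classifier, thresholding, grouping —
recovers a known synonym structure exactly when all variation is of the
declared kinds, and degrades gracefully (F1 ≥ 0.95 at a 5% misspelling
rate). What it does not show: performance on real clinical lexical
variation (chemical nomenclature, typos beyond single edits, cross-language
forms), realistic error profiles, or classifier scores on
clinician-annotated pairs, all of which require the real data.

## Problem sizes and numerical choices

Recovery benchmarks use 60 concepts × 3 sources (~150 records, ~300
labeled pairs) across 5 seeds; QC benchmarks 50 concepts × 3 sources with
4% error rates per heuristic; the exhaustive metric-oracle check covers
all ~600k string pairs of length ≤ 6 over a 3-character alphabet plus
10,000 random pairs; the grouping-oracle check covers all graphs on ≤ 6
nodes (every edge subset) plus 200 random 30-node graphs. Comparisons of
ratio values use an absolute tolerance of 1e-12; ties in threshold
selection resolve to the smallest threshold; empty-vs-empty string ratios
are defined as 1. All randomness flows through explicit integer seeds;
training is single-threaded and deterministic.

## Known limitations

- The LVG approximation does not reproduce the full toolset (no
  derivational morphology, no lexicon-backed uninflection); rule tables
  are pinned but small.
- All-pairs training-candidate generation is O(n²) and intended for
  desk-scale inventories (the blocked prediction path is the scalable
  one).
- Threshold selection on training predictions can be optimistic for
  heavily overlapping classes; supply held-out validation pairs where that
  matters.
- The punctuation heuristic is a declared rule set, not a learned model;
  genuinely unusual-but-correct short forms will be flagged for review.
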