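# Methods

## The retrieval model

The unit of retrieval is the forum-post **paragraph**. A paragraph is
retrieved iff it contains at least one mention from the products gazetteer
*and* at least one match from the effects lexicon (the tuple filter). Each
retrieved paragraph contributes one **hit** per (distinct product canonical,
effect span) pair. Two consequences are accepted as part of the model rather
than corrected:

* **Attribution ambiguity.** In a multi-product paragraph every effect is
  attributed to every product. The hit unit was chosen so that a product's
  total hit count always equals the sum of its per-category counts and the
  number of its detail-report rows; this conservation law is asserted on
  every synthetic run.
* **Negation blindness.** "geen last van diarree" matches "diarree". The
  package asserts this behaviour in a test and quantifies its cost: with
  negated distractors planted at rate `c` next to genuine co-occurrences at
  rate `p`, paragraph-level recall stays 1 and precision is exactly
  `p/(p+c)` in expectation.

### Matching semantics

Tokenization splits on whitespace and punctuation but keeps internal hyphens
and apostrophes ("No-xplode", "'s", "zo'n" are single tokens); token offsets
reconstruct the source text exactly. All matching is case-insensitive after
NFC normalisation; diacritics are preserved.

*Products.* Whole-token(-sequence) matching of every variant; at a given
position the longest variant wins and shorter overlapping matches are
suppressed; scanning resumes after a match.

*Effects.* Standalone vocabulary items match at every occurrence (bigram
items require adjacent tokens — they model fixed collocations). A
combination rule matches a span iff *some* assignment of vocabulary
occurrences to its ordered slots starts and ends there with at most
`max_gap` unmatched tokens between consecutive slots. Matches are **sets of
(span, source)** — distinct derivations of the same span collapse, and a
token may participate in matches of different sources. This set semantics
was chosen over a greedy leftmost-longest scan because it has a unique,
order-independent answer that an exhaustive window scanner can confirm; the
test suite checks exact hit-set equality against such an independent
brute-force scanner on 100 random corpora.

### Rule formalism

A rule is an ordered list of slot constraints (`lit:<surface>`, `pos:<TAG>`,
`sem:<class>`) with one per-rule gap bound (0–5 tokens, default examples use
0–1). This is the smallest formalism that covers the phrase patterns the
lexicon needs: *sentiment + vague noun* ("fenomenale toename"), *body part +
effect verb* ("lever aantasten", with "lever kan aantasten" reachable at gap
1), *effect adjective + vague noun* ("misselijkmakend effect"). Sentiment
words are deliberately non-standalone: applied on their own they retrieve
enthusiasm about anything; inside a rule they mark a reported effect.

### The `unspecified` label

Effect strings that cannot be assigned a body-system category carry the
label `unspecified`. `effective_lexicon(lex, include_unspecified=False)`
removes every vocabulary item and rule with that label before searching —
the narrowing used when screening for suspect products, where vague strings
only dilute precision. Hit counts are monotone non-increasing under this
narrowing (asserted in the pipeline tests).

## Gazetteer bootstrapping

Trademark extraction collects maximal name-shaped token runs (≤ 4 tokens,
capitalized or containing a digit, optional internal hyphen) glued directly
to a ®/™ symbol. Pattern expansion instantiates the five contextual
templates with known names; the unknown slot accepts one token of
alphanumeric-with-internal-hyphen shape that is not a Dutch function word,
extended over adjacent capitalized/digit-bearing tokens up to four. The
word "van" is matched literally and case-insensitively; no other
prepositions are attempted. Promotion across rounds is frequency-gated
(`min_freq`) and monotone in the number of rounds; both knobs are exposed
because no single correct value exists — harvested candidates are intended
for human review, and the CLI writes them to a candidates file only.

## Evaluation

* Expert comparison is scored at **paragraph level**: confusion counts over
  a fixed paragraph universe, then precision `tp/(tp+fp)`, recall
  `tp/(tp+fn)`, accuracy `(tp+tn)/total`. Undefined ratios are NaN, never 0.
* The multi-annotator study is scored at **match level**: a system match is
  supported by an annotator iff its span overlaps one of that annotator's
  spans in the same paragraph by at least `min_overlap` characters
  (default 1; exposed as a parameter because the right threshold is a
  judgement call). Fractions supported by ≥ k annotators are monotone
  non-decreasing as k decreases — a universal law, asserted as such.
* Cohen's κ uses the closed form (p_o − p_e)/(1 − p_e) with p_e from the
  marginal products. When p_e = 1 (both raters constant on the same label)
  agreement is saturated and κ is 1 if p_o = 1, NaN otherwise. The
  implementation is cross-checked against scikit-learn's
  `cohen_kappa_score` in the tests; scikit-learn is never used as the
  implementation.

## The synthetic-corpus generator

The generator emulates what the retrieval method is sensitive to, and
nothing more. Per paragraph a single categorical draw decides its kind:

| kind | probability | content |
|---|---|---|
| planted | `plant_rate` (default 0.3) | product mention + effect phrase |
| confound | `confound_rate` (default 0) | product + negated effect phrase, or product + bare sentiment word |
| filler | remainder | filler words only |

Within planted paragraphs: the effect phrase is a standalone item or a rule
instantiation (gap fillers drawn uniformly in 0..max_gap) with equal
probability; a second product is added with `multi_product_rate` (default
0.1); the mention is wrapped in a `PRODUCT van BRAND` pattern context with
`pattern_rate` (default 0.2). `confound_negated_fraction` (default 1)
splits confounds between negated and sentiment-only distractors.

Filler text comes from a fixed 64-word Dutch list; every product, brand and
effect surface is a fabricated pseudo-word checked against that list (and
against "geen"/"niet"/"van"), so false matches are impossible by
construction and expectations are analytic: confound-free corpora must give
paragraph precision = recall = 1, negated confounds must cost exactly their
count in precision. Product variants are single distinct tokens, which also
keeps naive occurrence scanning and longest-match scanning equivalent — a
precondition of the brute-force oracle.

What the generator does **not** emulate: real Dutch morphology and spelling
variation, quoted posts, co-reference ("het spul"), creative figurative
language, topic drift, and class imbalance across products. Passing tests
therefore demonstrate correctness of the machinery under the stated planting
model, not field performance on real fora; published measurements on real
data (precision/recall against experts, annotator agreement) depend on
lexicon quality and cannot be reproduced without the original corpora.

Default type labels are the body-system categories named in the package's
report vocabulary (energy, psyche, harm, muscles, belly, body fat, digestive
tract, 'maag, lever en darmen', 'hart en vaatstelsel', 'longen en
luchtwegen') plus `unspecified`; a fuller inventory can be supplied through
the lexicon files.

All randomness flows from one integer seed: numpy streams `[seed, 0]` for
lexicons, `[seed, 1]` for the corpus, `[seed, 2]` for gold annotations.
Simulated annotators mark each true (non-negated) effect span with
probability 1 − noise and add one spurious 5-character span per paragraph
with probability noise/2.

## Numerical and format choices

* Text cleaning decodes HTML entities and strips control characters to a
  fixpoint (the two interact), then NFC-normalises and collapses horizontal
  whitespace; the function is total and idempotent.
* Corpus XML serialization is deterministic (fixed attribute order, UTF-8);
  `parse ∘ write` is a fixpoint after one parse.
* Paragraph-report HTML partitions text into maximal runs of constant
  markup classes, so overlapping spans nest safely and stripping the markup
  reproduces the paragraph byte-for-byte.
* Report rows sort by product, then count descending, then label; rankings
  break ties alphabetically. All TSV output is byte-deterministic; the
  pipeline manifest records input SHA-256 digests, parameters and per-stage
  counts (and deliberately no wall-clock time).
* Problem sizes in tests and in `scripts/acceptance.py`: 2000-paragraph
  corpora for rate-sensitive checks (binomial SE ≈ 1%), 100 small corpora
  (~20 paragraphs, ≤ 30 vocabulary items) for the oracle-equivalence sweep —
  sizes at which exhaustive enumeration is exact yet cheap.

## Known limitations

Negation, co-reference and sentence structure are out of scope by design;
the matcher is a term-list method. Quoted text inside posts is kept (it can
inflate co-occurrence counts). The bootstrap shape heuristics are tuned for
product-name-like tokens and will miss names that look like ordinary
lowercase function words. Dutch is assumed but not enforced; embedded
English text is simply carried along.
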