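# suppsignal

Lexicon-driven mining of internet forum posts for dietary-supplement safety
signals.

Dietary supplements — in particular workout and weight-loss products — are
sometimes adulterated with undeclared pharmacologically active substances.
Chemical analysis of a suspect product usually happens only after users have
been harmed, yet those same users discuss their experiences openly on fitness
fora long before. `suppsignal` implements a retrieval method for exactly this
situation: given a corpus of forum posts, a gazetteer of product and brand
names, and an effects lexicon, it extracts every text **paragraph** in which a
product name co-occurs with a user-reported effect phrase (the *tuple
filter*), aggregates the hits per effect category, and ranks products by
total hit count. Products that float to the top of that ranking are
candidates for laboratory analysis — a risk-based selection instead of a
blind one.

The package is aimed at food-safety / pharmacovigilance analysts and at
text-mining researchers who want a fully testable, deposited implementation
of the method: because real scraped forum data of this kind is
privacy-restricted and transient, a first-class synthetic-corpus generator
with known planted ground truth is part of the package, and every claim in
the test suite is verified against it.

## Method

* **Corpus.** Posts are cleaned (HTML entities, control characters,
  whitespace), segmented into paragraphs at blank lines, and stored in a
  small XML dialect. The paragraph is the retrieval unit: short enough to be
  inspectable, long enough to carry context.
* **Products list.** Canonical names with spelling variants and short forms.
  It can be bootstrapped from the corpus itself: token runs glued to ®/™
  symbols seed the list, and contextual patterns — `X van BRAND`,
  `X (BRAND)`, `X (van BRAND)`, `BRAND X`, `PRODUCT van Y` — are instantiated
  with known names to harvest new product/brand candidates over multiple
  rounds (candidates go to a review file, not silently into the lexicon).
* **Effects lexicon.** A vocabulary of word uni-/bigrams with part-of-speech
  and semantic class (effect nouns/adjectives, vague nouns, sentiment words,
  body parts, effect verbs), plus combination rules: ordered slot sequences
  (literal / POS / semantic-class constraints) with a bounded token gap,
  e.g. *sentiment + vague noun* → "fenomenale toename". Standalone items
  denote an effect on their own; sentiment words fire only inside rules.
  Every effect string carries a type label (mostly organ-system based);
  strings labelled `unspecified` can be opted out for screening.
* **Retrieval.** A paragraph is a hit iff it contains ≥ 1 product mention
  and ≥ 1 effect match. Every effect is attributed to every distinct product
  in the paragraph — the method cannot know which product is meant, and this
  over-attribution is kept deliberately, as is its negation blindness
  ("geen last van diarree" still matches). One hit = (paragraph, unique
  product, effect span), so per-product totals equal the sum of per-category
  counts by construction.
* **Reports.** Level 1: hit counts per product × category; level 2: one row
  per hit with paragraph ids; level 3: full paragraphs as HTML with product
  and effect spans highlighted. `rank` orders products by total hits.
* **Evaluation.** Paragraph-level precision/recall/accuracy against an
  expert's markings; match-level support fractions against multiple
  annotators (share of system matches overlapping ≥ k annotators' spans);
  Cohen's κ = (p_o − p_e)/(1 − p_e) between annotator pairs.

## Worked example

A paragraph discussing creatine that mentions "rpm" in passing:

```python
import io
from suppsignal import Paragraph, load_effects, load_products, search_paragraph

products = load_products(io.StringIO("RPM\tproduct\trpm\ncreatine\tproduct\t\n"))
lexicon = load_effects(
    io.StringIO(
        "meer\tQUANT\tother\t0\t-\n"
        "kracht\tNOUN\tvague_noun\t0\t-\n"
        "explosieve\tADJ\teffect_adj\t0\t-\n"
        "uithoudingsvermogen\tNOUN\teffect_noun\t0\t-\n"
    ),
    io.StringIO(
        "r_meer_kracht\tlit:meer+lit:kracht\t0\tmuscles\n"
        "r_expl_kracht\tlit:explosieve+lit:kracht\t0\tmuscles\n"
        "r_meer_uithou\tlit:meer+lit:uithoudingsvermogen\t0\tmuscles\n"
    ),
)
text = ("Creatine geeft mij vooral meer kracht, (zo’n 10% van mijn rpm erbij) "
        "explosieve kracht, niet veel meer uithoudingsvermogen.")
for hit in search_paragraph(Paragraph("ex#0", 0, text), products, lexicon):
    print(hit.product_canonical, hit.effect.matched_text, hit.effect.source)
```

prints

```
RPM meer kracht rule:r_meer_kracht
RPM explosieve kracht rule:r_expl_kracht
RPM meer uithoudingsvermogen rule:r_meer_uithou
creatine meer kracht rule:r_meer_kracht
creatine explosieve kracht rule:r_expl_kracht
creatine meer uithoudingsvermogen rule:r_meer_uithou
```

Six hits: three genuine creatine attributions and three false RPM ones —
the documented cost of paragraph-level co-occurrence without disambiguation.
Note also that "niet veel meer uithoudingsvermogen" is matched affirmatively:
negation is outside the method's scope.

## Command line

```bash
suppsignal simulate  --config sim.yaml --out-dir fixtures/
suppsignal ingest    --in raw.xml --out corpus.xml
suppsignal bootstrap --corpus corpus.xml --seeds products.tsv --rounds 2 \
                     --min-freq 2 --out candidates.tsv
suppsignal search    --corpus corpus.xml --products products.tsv \
                     --effects effects_vocab.tsv --rules effects_rules.tsv \
                     --out hits.tsv
suppsignal report    --hits hits.tsv --level type --out report_type.tsv
suppsignal rank      --hits hits.tsv --min-hits 2
suppsignal eval      --hits hits.tsv --gold gold.tsv --corpus corpus.xml \
                     --mode expert
suppsignal run       --config run.yaml     # full pipeline + manifest
```

Exit codes: 0 ok, 2 configuration error, 3 data error.

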