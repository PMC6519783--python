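"""Synthetic forum corpora with known planted structure.

Real forum data of this kind is privacy-restricted and transient, so every
component in the package is exercised against generated corpora in which the
ground truth is known by construction.  The generator emulates the features
that matter to the retrieval method, not realistic Dutch:

* posts with metadata (forum, thread, pseudonymous author, timestamp, index)
  and multi-paragraph bodies;
* *planted* paragraphs containing a product mention co-occurring with an
  effect phrase — either a standalone vocabulary item or a phrase assembled
  from a combination rule (with 0..max_gap filler tokens between slots);
* *negated* distractors (``geen``/``niet`` prepended to an effect phrase next
  to a product) that a negation-blind matcher will retrieve anyway;
* *sentiment-only* distractors (a bare sentiment word next to a product) that
  must NOT be retrieved, because sentiment items only fire inside rules;
* multi-product paragraphs, reproducing the attribution ambiguity;
* product mentions wrapped in bootstrap seed-pattern contexts
  (``PRODUCT van BRAND``).

Filler text is drawn from a fixed word list disjoint from every lexicon
surface (product, brand and effect surfaces are fabricated pseudo-words
checked against the filler list), so spurious matches are impossible by
construction and retrieval expectations are analytic.

All randomness flows from ``SimConfig.seed`` through numpy Generator streams
seeded ``[seed, 0]`` (lexicons), ``[seed, 1]`` (corpus) and ``[seed, 2]``
(gold annotations), in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus_io import ForumPost, Paragraph, write_corpus
from .evaluation import GoldAnnotation, dump_gold
from .lexicon import (
    UNSPECIFIED,
    CombinationRule,
    EffectLexicon,
    EffectVocabItem,
    ProductEntry,
    SlotConstraint,
    dump_effects,
    dump_products,
    validate_lexicon,
)

__all__ = [
    "SimConfig",
    "ParagraphTruth",
    "GroundTruth",
    "DEFAULT_TYPE_LABELS",
    "FILLER_WORDS",
    "NEGATIONS",
    "generate_lexicons",
    "generate_corpus",
    "gold_from_truth",
    "write_fixtures",
    "dump_truth",
]

#: effect categories; mostly organ/body-part based to avoid suggesting a
#: medical diagnosis.  'unspecified' is handled separately.
DEFAULT_TYPE_LABELS: Tuple[str, ...] = (
    "energy",
    "psyche",
    "harm",
    "muscles",
    "belly",
    "body fat",
    "digestive tract",
    "maag, lever en darmen",
    "hart en vaatstelsel",
    "longen en luchtwegen",
)

NEGATIONS: Tuple[str, ...] = ("geen", "niet")

#: fixed filler vocabulary; kept disjoint from every generated lexicon
#: surface and from the negation words and "van" (the pattern anchor)
FILLER_WORDS: Tuple[str, ...] = (
    "ik", "vandaag", "weer", "lekker", "getraind", "zwaar", "morgen", "samen",
    "even", "gewoon", "tijdens", "training", "schema", "herhalingen", "sets",
    "rust", "ochtend", "avond", "week", "maand", "keer", "beetje", "flink",
    "aardig", "prima", "redelijk", "gisteren", "straks", "iedereen", "jongens",
    "vraagje", "iemand", "ervaring", "gebruik", "neem", "slik", "koop",
    "bestel", "winkel", "verhaal", "topic", "draadje", "reactie", "bedankt",
    "groeten", "succes", "verder", "daarna", "eerst", "daarnaast", "overigens",
    "trouwens", "namelijk", "natuurlijk", "eigenlijk", "ongeveer", "ruim",
    "bijna", "precies", "uitleg", "mening", "idee", "plan", "doel", "alvast",
)


class SimConfig(BaseModel):
    """Study conditions for one simulated corpus."""

    n_posts: int = Field(200, ge=1)
    paragraphs_per_post: Tuple[int, int] = (3, 8)
    n_products: int = Field(8, ge=1)
    n_brands: int = Field(3, ge=1)
    n_effect_terms: int = Field(12, ge=1)
    n_type_labels: int = Field(len(DEFAULT_TYPE_LABELS), ge=1)
    plant_rate: float = Field(0.3, ge=0.0, le=1.0)
    confound_rate: float = Field(0.0, ge=0.0, le=1.0)
    multi_product_rate: float = Field(0.1, ge=0.0, le=1.0)
    pattern_rate: float = Field(0.2, ge=0.0, le=1.0)
    #: share of confound paragraphs that are negated (vs. sentiment-only)
    confound_negated_fraction: float = Field(1.0, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.paragraphs_per_post
        if not (1 <= lo <= hi):
            raise ValueError("paragraphs_per_post must satisfy 1 <= lo <= hi")
        if self.plant_rate + self.confound_rate > 1.0:
            raise ValueError("plant_rate + confound_rate must be <= 1")
        if self.n_type_labels > len(DEFAULT_TYPE_LABELS):
            raise ValueError(
                f"n_type_labels must be <= {len(DEFAULT_TYPE_LABELS)}"
            )
        return self


@dataclass(frozen=True)
class ParagraphTruth:
    paragraph_id: str
    kind: str  # planted | confound_negated | confound_sentiment | filler
    text: str
    products: Tuple[Tuple[str, Tuple[int, int]], ...] = ()
    effects: Tuple[Tuple[Tuple[int, int], str], ...] = ()  # (span, label)
    negated: bool = False
    pattern: Optional[Tuple[str, str, str]] = None  # (template, product, brand)


@dataclass
class GroundTruth:
    paragraphs: Dict[str, ParagraphTruth] = field(default_factory=dict)

    def ids_of_kind(self, *kinds: str) -> Set[str]:
        return {
            pid for pid, pt in self.paragraphs.items() if pt.kind in kinds
        }

    def positive_ids(self) -> Set[str]:
        """Paragraphs with a genuine product-effect co-occurrence."""
        return self.ids_of_kind("planted")

    def retrievable_ids(self) -> Set[str]:
        """Paragraphs a negation-blind tuple filter will retrieve."""
        return self.ids_of_kind("planted", "confound_negated")

    def all_ids(self) -> Set[str]:
        return set(self.paragraphs)


# ---------------------------------------------------------------------------
# pseudo-word fabrication
# ---------------------------------------------------------------------------

_ONSETS = (
    "b", "d", "f", "g", "h", "k", "l", "m", "n", "p", "r", "s", "t", "v", "w",
    "z", "br", "dr", "gr", "kl", "kr", "pl", "pr", "st", "tr", "zw",
)
_VOWELS = ("a", "e", "i", "o", "u", "aa", "ee", "oo", "oe", "ei", "ui")
_CODAS = ("", "l", "n", "r", "s", "t", "k", "m")


def _choice(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(len(seq)))]


def _pseudo_word(rng: np.random.Generator, n_syllables: int) -> str:
    parts = []
    for i in range(n_syllables):
        parts.append(_choice(rng, _ONSETS))
        parts.append(_choice(rng, _VOWELS))
        if i == n_syllables - 1 or rng.random() < 0.3:
            parts.append(_choice(rng, _CODAS))
    return "".join(parts)


def _new_word(
    rng: np.random.Generator,
    used: Set[str],
    syllables: Tuple[int, int] = (2, 3),
    capitalize: bool = False,
) -> str:
    for _ in range(1000):
        word = _pseudo_word(rng, int(rng.integers(syllables[0], syllables[1] + 1)))
        if capitalize:
            word = word.capitalize()
        if word.casefold() not in used:
            used.add(word.casefold())
            return word
    raise RuntimeError("pseudo-word space exhausted")


# ---------------------------------------------------------------------------
# lexicon generation
# ---------------------------------------------------------------------------

def generate_lexicons(cfg: SimConfig) -> Tuple[List[ProductEntry], EffectLexicon]:
    """Fabricate a products gazetteer and an effects lexicon.

    The effects lexicon spans all semantic classes, has one rule per type
    label (each anchored on a label-specific sentiment word followed by a
    vague noun within one token), one body-part+verb rule, and one rule
    labelled 'unspecified'.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    used: Set[str] = {w.casefold() for w in FILLER_WORDS}
    used |= {w.casefold() for w in NEGATIONS}
    used.add("van")
    labels = list(DEFAULT_TYPE_LABELS[: cfg.n_type_labels])

    products: List[ProductEntry] = []
    for i in range(cfg.n_products):
        name = _new_word(rng, used, (2, 3), capitalize=True)
        if i % 3 == 2:
            name = f"{name}{int(rng.integers(50, 500))}"
            used.add(name.casefold())
        variants = {name.casefold()}
        if len(name) >= 6 and i % 2 == 0:
            short = name[:4].casefold()
            if short not in used:
                used.add(short)
                variants.add(short)
        products.append(ProductEntry(name, "product", frozenset(variants)))
    for _ in range(cfg.n_brands):
        name = _new_word(rng, used, (2, 3), capitalize=True)
        products.append(ProductEntry(name, "brand"))

    vocab: List[EffectVocabItem] = []
    for _ in range(3):
        vocab.append(
            EffectVocabItem(_new_word(rng, used), "NOUN", "vague_noun", False, None)
        )
    for i in range(cfg.n_effect_terms):
        word = _new_word(rng, used)
        if i == 1 and cfg.n_effect_terms >= 2:
            word = f"{word} {_new_word(rng, used)}"  # one bigram collocation
        label = labels[i % len(labels)]
        if i % 3 == 0:
            vocab.append(EffectVocabItem(word, "ADJ", "effect_adj", True, label))
        else:
            vocab.append(EffectVocabItem(word, "NOUN", "effect_noun", True, label))

    rules: List[CombinationRule] = []
    for j, label in enumerate(labels + [UNSPECIFIED]):
        sentiment = _new_word(rng, used)
        vocab.append(
            EffectVocabItem(
                sentiment, "ADV" if j % 2 else "ADJ", "sentiment", False, None
            )
        )
        rules.append(
            CombinationRule(
                f"r{j:02d}",
                (
                    SlotConstraint("literal", sentiment),
                    SlotConstraint("sem", "vague_noun"),
                ),
                1,
                label,
            )
        )
    vocab.append(EffectVocabItem(_new_word(rng, used), "NOUN", "body_part", False))
    vocab.append(EffectVocabItem(_new_word(rng, used), "VERB", "verb_effect", False))
    rules.append(
        CombinationRule(
            "r_bp",
            (SlotConstraint("sem", "body_part"), SlotConstraint("sem", "verb_effect")),
            1,
            labels[0],
        )
    )

    lexicon = EffectLexicon(
        vocab=vocab, rules=rules, labels=set(labels) | {UNSPECIFIED}
    )
    diagnostics = validate_lexicon(lexicon)
    if diagnostics:  # pragma: no cover - generator guarantees validity
        raise RuntimeError(f"generated lexicon invalid: {diagnostics}")
    return products, lexicon


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates space-joined words while tracking character spans."""

    def __init__(self) -> None:
        self.parts: List[str] = []
        self._pos = 0

    def add(self, word: str) -> Tuple[int, int]:
        if self.parts:
            self._pos += 1
        start = self._pos
        self.parts.append(word)
        self._pos += len(word)
        return start, self._pos

    def text(self) -> str:
        return " ".join(self.parts)


def _filler(rng: np.random.Generator) -> str:
    return _choice(rng, FILLER_WORDS)


def _emit_effect(
    builder: _Builder,
    rng: np.random.Generator,
    lexicon: EffectLexicon,
    standalone_items: Sequence[EffectVocabItem],
) -> Tuple[Tuple[int, int], str]:
    """Append a standalone item or a rule-assembled phrase; return its span
    (first slot start .. last slot end) and type label."""
    if standalone_items and rng.random() < 0.5:
        item = standalone_items[int(rng.integers(len(standalone_items)))]
        spans = [builder.add(tok) for tok in item.surface.split()]
        return (spans[0][0], spans[-1][1]), item.type_label
    rule = lexicon.rules[int(rng.integers(len(lexicon.rules)))]
    start = end = -1
    for k, slot in enumerate(rule.slots):
        if k > 0:
            for _ in range(int(rng.integers(0, rule.max_gap + 1))):
                builder.add(_filler(rng))
        item = _pick_item(rng, lexicon, slot)
        for tok in item.surface.split():
            s, e = builder.add(tok)
            if start < 0:
                start = s
            end = e
    return (start, end), rule.type_label


def _pick_item(
    rng: np.random.Generator, lexicon: EffectLexicon, slot: SlotConstraint
) -> EffectVocabItem:
    if slot.mode == "literal":
        for item in lexicon.vocab:
            if item.surface.casefold() == slot.value.casefold():
                return item
        raise RuntimeError(f"unresolved literal slot {slot.value!r}")
    if slot.mode == "pos":
        pool = [i for i in lexicon.vocab if i.pos == slot.value]
    else:
        pool = [i for i in lexicon.vocab if i.sem == slot.value]
    if not pool:
        raise RuntimeError(f"no vocabulary item satisfies slot {slot!r}")
    return pool[int(rng.integers(len(pool)))]


def _emit_product(
    builder: _Builder,
    rng: np.random.Generator,
    cfg: SimConfig,
    product_entries: Sequence[ProductEntry],
    brand_entries: Sequence[ProductEntry],
) -> Tuple[List[Tuple[str, Tuple[int, int]]], Optional[Tuple[str, str, str]]]:
    """Append a product mention, possibly inside a 'PRODUCT van BRAND'
    pattern context; return recorded mentions and the pattern occurrence."""
    entry = product_entries[int(rng.integers(len(product_entries)))]
    mentions: List[Tuple[str, Tuple[int, int]]] = []
    pattern = None
    if brand_entries and rng.random() < cfg.pattern_rate:
        span = builder.add(entry.canonical)
        mentions.append((entry.canonical, span))
        builder.add("van")
        brand = brand_entries[int(rng.integers(len(brand_entries)))]
        brand_span = builder.add(brand.canonical)
        mentions.append((brand.canonical, brand_span))
        pattern = ("PRODUCT van Y", entry.canonical, brand.canonical)
    else:
        variants = sorted(entry.variants)
        surface = (
            variants[int(rng.integers(len(variants)))]
            if rng.random() < 0.3
            else entry.canonical
        )
        span = builder.add(surface)
        mentions.append((entry.canonical, span))
    return mentions, pattern


def generate_corpus(
    cfg: SimConfig,
    lexicons: Tuple[Sequence[ProductEntry], EffectLexicon],
) -> Tuple[List[ForumPost], GroundTruth]:
    """Generate posts and the ground truth of every planting.

    Per paragraph one categorical draw decides its kind: planted (with
    probability ``plant_rate``), confound (``confound_rate``; negated or
    sentiment-only per ``confound_negated_fraction``), otherwise pure filler.
    """
    products, lexicon = lexicons
    rng = np.random.default_rng([cfg.seed, 1])
    product_entries = [e for e in products if e.kind in ("product", "product_type")]
    brand_entries = [e for e in products if e.kind == "brand"]
    standalone_items = [v for v in lexicon.vocab if v.standalone]
    sentiment_items = [v for v in lexicon.vocab if v.sem == "sentiment"]

    base_time = datetime(2016, 1, 1, 9, 0, 0)
    posts: List[ForumPost] = []
    truth = GroundTruth()
    lo, hi = cfg.paragraphs_per_post
    for p in range(cfg.n_posts):
        post_id = f"p{p:05d}"
        n_paragraphs = int(rng.integers(lo, hi + 1))
        paragraphs: List[Paragraph] = []
        for ordinal in range(n_paragraphs):
            pid = f"{post_id}#{ordinal}"
            builder = _Builder()
            for _ in range(3 + int(rng.integers(0, 5))):
                builder.add(_filler(rng))
            draw = rng.random()
            mentions: List[Tuple[str, Tuple[int, int]]] = []
            effects: List[Tuple[Tuple[int, int], str]] = []
            pattern = None
            negated = False
            if draw < cfg.plant_rate:
                kind = "planted"
                mentions, pattern = _emit_product(
                    builder, rng, cfg, product_entries, brand_entries
                )
                for _ in range(1 + int(rng.integers(0, 3))):
                    builder.add(_filler(rng))
                span, label = _emit_effect(builder, rng, lexicon, standalone_items)
                effects.append((span, label))
                for _ in range(int(rng.integers(0, 3))):
                    builder.add(_filler(rng))
                if len(product_entries) > 1 and rng.random() < cfg.multi_product_rate:
                    other = product_entries[int(rng.integers(len(product_entries)))]
                    span2 = builder.add(other.canonical)
                    mentions.append((other.canonical, span2))
            elif draw < cfg.plant_rate + cfg.confound_rate:
                entry = product_entries[int(rng.integers(len(product_entries)))]
                span = builder.add(entry.canonical)
                mentions.append((entry.canonical, span))
                builder.add(_filler(rng))
                if rng.random() < cfg.confound_negated_fraction:
                    kind = "confound_negated"
                    negated = True
                    builder.add(_choice(rng, NEGATIONS))
                    span, label = _emit_effect(
                        builder, rng, lexicon, standalone_items
                    )
                    effects.append((span, label))
                else:
                    kind = "confound_sentiment"
                    item = sentiment_items[int(rng.integers(len(sentiment_items)))]
                    builder.add(item.surface)
                for _ in range(int(rng.integers(0, 3))):
                    builder.add(_filler(rng))
            else:
                kind = "filler"
                for _ in range(int(rng.integers(2, 6))):
                    builder.add(_filler(rng))
            text = builder.text()
            paragraphs.append(Paragraph(pid, ordinal, text))
            truth.paragraphs[pid] = ParagraphTruth(
                paragraph_id=pid,
                kind=kind,
                text=text,
                products=tuple(mentions),
                effects=tuple(effects),
                negated=negated,
                pattern=pattern,
            )
        timestamp = (base_time + timedelta(hours=p)).isoformat()
        posts.append(
            ForumPost(
                forum_id="synthforum",
                thread_id=f"thread{p % 7}",
                title=" ".join(_filler(rng) for _ in range(3)),
                author_id=f"user{int(rng.integers(1, 200)):03d}",
                timestamp=timestamp,
                post_id=post_id,
                post_index=p,
                paragraphs=paragraphs,
            )
        )
    return posts, truth


# ---------------------------------------------------------------------------
# gold annotations
# ---------------------------------------------------------------------------

def gold_from_truth(
    truth: GroundTruth,
    annotator_noise: float,
    n_annotators: int,
    seed: int,
) -> List[GoldAnnotation]:
    """Simulate annotators marking effect spans.

    Each annotator marks each true (non-negated) effect span independently
    with probability ``1 - annotator_noise`` and, per paragraph, adds one
    spurious span with probability ``annotator_noise / 2``.
    """
    if not 0.0 <= annotator_noise <= 1.0:
        raise ValueError("annotator_noise must be in [0, 1]")
    if n_annotators < 1:
        raise ValueError("n_annotators must be >= 1")
    rng = np.random.default_rng([seed, 2])
    annotations: List[GoldAnnotation] = []
    for a in range(n_annotators):
        annotator = f"ann{a}"
        for pid in sorted(truth.paragraphs):
            pt = truth.paragraphs[pid]
            spans: List[Tuple[int, int]] = []
            if not pt.negated:
                for span, _ in pt.effects:
                    if rng.random() < 1.0 - annotator_noise:
                        spans.append(span)
            if rng.random() < annotator_noise / 2 and len(pt.text) >= 8:
                start = int(rng.integers(0, len(pt.text) - 5))
                spans.append((start, start + 5))
            if spans:
                annotations.append(GoldAnnotation(annotator, pid, tuple(spans)))
    return annotations


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def dump_truth(truth: GroundTruth) -> str:
    """TSV: paragraph_id, kind, negated, products ('canon:s:e' |-joined),
    effects ('s:e:label' ;-joined)."""
    lines = ["paragraph_id\tkind\tnegated\tproducts\teffects"]
    for pid in sorted(truth.paragraphs):
        pt = truth.paragraphs[pid]
        products = "|".join(f"{c}:{s}:{e}" for c, (s, e) in pt.products)
        effects = ";".join(f"{s}:{e}:{label}" for (s, e), label in pt.effects)
        lines.append(
            f"{pid}\t{pt.kind}\t{int(pt.negated)}\t{products}\t{effects}"
        )
    return "\n".join(lines) + "\n"


def write_fixtures(
    cfg: SimConfig,
    out_dir: Path,
    n_annotators: int = 3,
    annotator_noise: float = 0.2,
) -> Dict[str, Path]:
    """Generate and write a complete fixture set into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    products, lexicon = generate_lexicons(cfg)
    posts, truth = generate_corpus(cfg, (products, lexicon))
    gold = gold_from_truth(truth, annotator_noise, n_annotators, cfg.seed)
    vocab_tsv, rules_tsv = dump_effects(lexicon)

    paths = {
        "corpus": out_dir / "corpus.xml",
        "products": out_dir / "products.tsv",
        "effects_vocab": out_dir / "effects_vocab.tsv",
        "effects_rules": out_dir / "effects_rules.tsv",
        "truth": out_dir / "truth.tsv",
    }
    paths["corpus"].write_bytes(write_corpus(posts))
    paths["products"].write_text(dump_products(products), encoding="utf-8")
    paths["effects_vocab"].write_text(vocab_tsv, encoding="utf-8")
    paths["effects_rules"].write_text(rules_tsv, encoding="utf-8")
    paths["truth"].write_text(dump_truth(truth), encoding="utf-8")
    for a in range(n_annotators):
        path = out_dir / f"gold_{a}.tsv"
        subset = [g for g in gold if g.annotator_id == f"ann{a}"]
        path.write_text(dump_gold(subset), encoding="utf-8")
        paths[f"gold_{a}"] = path
    return paths
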