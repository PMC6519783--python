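"""Tokenization, lexicon matching, and the paragraph-level tuple filter.

A paragraph is retrieved iff it contains at least one products-list mention
AND at least one effects-list match (the *tuple filter*).  Every effect match
in a retrieved paragraph is attributed to every distinct product mentioned in
it — the method has no way of knowing which product an effect refers to when
several are discussed, and this over-attribution is kept on purpose (it is a
documented property of the approach, observable in evaluation).  Likewise no
negation handling is attempted: "geen last van diarree" still matches
"diarree".

One :class:`Hit` = (paragraph, unique product, effect span).  This unit makes
the per-product total equal the sum of its per-category counts, which is what
the reporting layer relies on.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

from .corpus_io import ForumPost, Paragraph, iter_paragraphs
from .lexicon import (
    CombinationRule,
    EffectLexicon,
    EffectVocabItem,
    ProductEntry,
    SlotConstraint,
)

__all__ = [
    "Token",
    "ProductMatch",
    "EffectMatch",
    "Hit",
    "tokenize",
    "match_products",
    "match_effects",
    "apply_tuple_filter",
    "search_paragraph",
    "search_corpus",
    "write_hits",
    "load_hits",
]


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # character offset, inclusive
    end: int  # character offset, exclusive


@dataclass(frozen=True)
class ProductMatch:
    paragraph_id: str
    entry: ProductEntry
    span: Tuple[int, int]
    matched_variant: str


@dataclass(frozen=True)
class EffectMatch:
    paragraph_id: str
    span: Tuple[int, int]  # first matched slot start .. last matched slot end
    source: str  # "vocab:<key>" or "rule:<rule_id>"
    type_label: str
    matched_text: str


@dataclass(frozen=True)
class Hit:
    paragraph_id: str
    product_canonical: str
    effect: EffectMatch


# tokens are word runs (internal hyphens/apostrophes kept, so "No-xplode" and
# "'s" stay single tokens) or single non-space punctuation characters
_TOKEN_RE = re.compile(r"['’]?\w+(?:['’\-]\w+)*|[^\w\s]")


def tokenize(text: str) -> List[Token]:
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# product matching
# ---------------------------------------------------------------------------

def match_products(
    tokens: Sequence[Token],
    paragraph_id: str,
    products: Sequence[ProductEntry],
) -> List[ProductMatch]:
    """Whole-token, case-insensitive matching of every product variant.

    At each position the longest matching variant wins and shorter overlapping
    matches are suppressed; scanning resumes after the match.
    """
    index: dict = {}
    max_len = 1
    for entry in products:
        for variant in entry.variants:
            key = tuple(variant.split())
            index.setdefault(key, (entry, variant))
            max_len = max(max_len, len(key))
    folded = [t.text.casefold() for t in tokens]
    matches: List[ProductMatch] = []
    i = 0
    while i < len(tokens):
        advanced = False
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(folded[i : i + length])
            if key in index:
                entry, variant = index[key]
                matches.append(
                    ProductMatch(
                        paragraph_id,
                        entry,
                        (tokens[i].start, tokens[i + length - 1].end),
                        variant,
                    )
                )
                i += length
                advanced = True
                break
        if not advanced:
            i += 1
    return matches


# ---------------------------------------------------------------------------
# effect matching
# ---------------------------------------------------------------------------

def _vocab_occurrences(
    folded: Sequence[str], vocab: Sequence[EffectVocabItem]
) -> List[List[Tuple[EffectVocabItem, int]]]:
    """occ[i] lists (item, n_tokens) for vocabulary items starting at token i.

    Bigram items require adjacent tokens — fixed collocations only.
    """
    occ: List[List[Tuple[EffectVocabItem, int]]] = [[] for _ in folded]
    for item in vocab:
        parts = item.tokens
        length = len(parts)
        for i in range(len(folded) - length + 1):
            if tuple(folded[i : i + length]) == parts:
                occ[i].append((item, length))
    return occ


def _slot_accepts(item: EffectVocabItem, slot: SlotConstraint) -> bool:
    if slot.mode == "literal":
        return item.surface.casefold() == slot.value.casefold()
    if slot.mode == "pos":
        return item.pos == slot.value
    return item.sem == slot.value


def _rule_spans(
    rule: CombinationRule,
    occ: Sequence[Sequence[Tuple[EffectVocabItem, int]]],
) -> Set[Tuple[int, int]]:
    """All (first_token, end_token_exclusive) index pairs where the rule fires.

    A rule fires at a span iff *some* assignment of vocabulary occurrences to
    its slots starts and ends there, with at most ``max_gap`` unmatched tokens
    between consecutive slots; distinct assignments yielding the same span
    collapse (matches are sets of spans, not derivations).
    """
    spans: Set[Tuple[int, int]] = set()

    def extend(slot_idx: int, min_pos: int, first: int, end: int) -> None:
        if slot_idx == len(rule.slots):
            spans.add((first, end))
            return
        slot = rule.slots[slot_idx]
        if slot_idx == 0:
            positions = range(len(occ))
        else:
            positions = range(min_pos, min(len(occ), min_pos + rule.max_gap + 1))
        for pos in positions:
            for item, length in occ[pos]:
                if _slot_accepts(item, slot):
                    extend(
                        slot_idx + 1,
                        pos + length,
                        pos if slot_idx == 0 else first,
                        pos + length,
                    )

    extend(0, 0, -1, -1)
    return spans


def match_effects(
    tokens: Sequence[Token],
    paragraph_id: str,
    lexicon: EffectLexicon,
    text: Optional[str] = None,
) -> List[EffectMatch]:
    """Find all standalone-item occurrences and all rule firings.

    Matches are deduplicated by (span, source); a token may participate in
    matches of different sources.  When ``text`` is given, ``matched_text`` is
    the exact character slice; otherwise tokens are joined with single spaces.
    """
    folded = [t.text.casefold() for t in tokens]
    occ = _vocab_occurrences(folded, lexicon.vocab)

    found: Set[Tuple[Tuple[int, int], str, str]] = set()
    for i, entries in enumerate(occ):
        for item, length in entries:
            if item.standalone:
                span = (tokens[i].start, tokens[i + length - 1].end)
                found.add((span, f"vocab:{item.key}", item.type_label))
    for rule in lexicon.rules:
        for first, end in _rule_spans(rule, occ):
            span = (tokens[first].start, tokens[end - 1].end)
            found.add((span, f"rule:{rule.rule_id}", rule.type_label))

    def slice_text(span: Tuple[int, int]) -> str:
        if text is not None:
            return text[span[0] : span[1]]
        covered = [t.text for t in tokens if t.start >= span[0] and t.end <= span[1]]
        return " ".join(covered)

    matches = [
        EffectMatch(paragraph_id, span, source, label, slice_text(span))
        for span, source, label in found
    ]
    matches.sort(key=lambda m: (m.span, m.source))
    return matches


# ---------------------------------------------------------------------------
# tuple filter and corpus-level search
# ---------------------------------------------------------------------------

def apply_tuple_filter(
    paragraph: Union[Paragraph, str],
    product_matches: Sequence[ProductMatch],
    effect_matches: Sequence[EffectMatch],
) -> List[Hit]:
    """Cross product of distinct canonical products x effect matches.

    Empty if either side is empty.  Duplicate mentions of the same product
    collapse to one canonical per paragraph.
    """
    if not product_matches or not effect_matches:
        return []
    pid = paragraph.paragraph_id if isinstance(paragraph, Paragraph) else paragraph
    canonicals = sorted({m.entry.canonical for m in product_matches})
    return [
        Hit(pid, canonical, effect)
        for canonical in canonicals
        for effect in effect_matches
    ]


def search_paragraph(
    paragraph: Paragraph,
    products: Sequence[ProductEntry],
    lexicon: EffectLexicon,
) -> List[Hit]:
    tokens = tokenize(paragraph.text)
    product_matches = match_products(tokens, paragraph.paragraph_id, products)
    effect_matches = match_effects(
        tokens, paragraph.paragraph_id, lexicon, text=paragraph.text
    )
    return apply_tuple_filter(paragraph, product_matches, effect_matches)


def search_corpus(
    posts: Iterable[ForumPost],
    products: Sequence[ProductEntry],
    lexicon: EffectLexicon,
) -> List[Hit]:
    hits: List[Hit] = []
    for paragraph in iter_paragraphs(posts):
        hits.extend(search_paragraph(paragraph, products, lexicon))
    return hits


# ---------------------------------------------------------------------------
# hits TSV round-trip
# ---------------------------------------------------------------------------

_HITS_HEADER = [
    "paragraph_id",
    "product",
    "effect_text",
    "effect_span",
    "type_label",
    "source_id",
]


def write_hits(hits: Iterable[Hit], destination: Union[str, Path, io.IOBase]) -> None:
    rows = [
        [
            h.paragraph_id,
            h.product_canonical,
            h.effect.matched_text,
            f"{h.effect.span[0]}:{h.effect.span[1]}",
            h.effect.type_label,
            h.effect.source,
        ]
        for h in hits
    ]
    buffer = io.StringIO()
    writer = csv.writer(buffer, delimiter="\t", lineterminator="\n")
    writer.writerow(_HITS_HEADER)
    writer.writerows(rows)
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(buffer.getvalue(), encoding="utf-8")
    else:
        destination.write(buffer.getvalue())


def load_hits(source: Union[str, Path, io.IOBase]) -> List[Hit]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        data = source.read()
        text = data.decode("utf-8") if isinstance(data, bytes) else data
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    header = next(reader, None)
    if header != _HITS_HEADER:
        raise ValueError(f"unexpected hits header: {header!r}")
    hits = []
    for row in reader:
        pid, product, effect_text, span_s, label, source_id = row
        start_s, _, end_s = span_s.partition(":")
        effect = EffectMatch(
            paragraph_id=pid,
            span=(int(start_s), int(end_s)),
            source=source_id,
            type_label=label,
            matched_text=effect_text,
        )
        hits.append(Hit(pid, product, effect))
    return hits
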