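"""Independent reference implementations used as oracles in tests.

Everything here is deliberately naive — exhaustive enumeration over all token
windows and all rule-slot assignments — and shares no matching code with the
package, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import html
import itertools
import re
import unicodedata

from suppsignal.lexicon import EffectLexicon, ProductEntry
from suppsignal.matcher import Token, tokenize


def reference_clean(raw: str) -> str:
    """Two-pass cleaner for texts whose entities decode in one step and whose
    decoded form contains no further entities or controls (the restricted
    inputs the property test generates)."""
    # pass 1: decode entities, drop control characters other than \n and \t
    decoded = html.unescape(raw)
    kept = []
    for ch in decoded:
        if ch in "\n\t" or unicodedata.category(ch) != "Cc":
            kept.append(ch)
    text = "".join(kept)
    # pass 2: NFC + collapse horizontal whitespace
    text = unicodedata.normalize("NFC", text)
    return re.sub(r"[ \t]+", " ", text)


def _slot_accepts(item, slot) -> bool:
    if slot.mode == "literal":
        return item.surface.casefold() == slot.value.casefold()
    if slot.mode == "pos":
        return item.pos == slot.value
    return item.sem == slot.value


def brute_force_effect_spans(tokens: list, lexicon: EffectLexicon) -> set:
    """All (char_span, source, type_label) triples, by full enumeration."""
    folded = [t.text.casefold() for t in tokens]
    occurrences = []  # (start_index, n_tokens, item)
    for item in lexicon.vocab:
        parts = list(item.tokens)
        for i in range(len(tokens) - len(parts) + 1):
            if folded[i : i + len(parts)] == parts:
                occurrences.append((i, len(parts), item))

    spans = set()
    for i, length, item in occurrences:
        if item.standalone:
            spans.add(
                (
                    (tokens[i].start, tokens[i + length - 1].end),
                    f"vocab:{item.key}",
                    item.type_label,
                )
            )
    for rule in lexicon.rules:
        for assignment in itertools.product(occurrences, repeat=len(rule.slots)):
            if not all(
                _slot_accepts(item, slot)
                for (_, _, item), slot in zip(assignment, rule.slots)
            ):
                continue
            chained = True
            for (i1, l1, _), (i2, _, _) in zip(assignment, assignment[1:]):
                gap = i2 - (i1 + l1)
                if gap < 0 or gap > rule.max_gap:
                    chained = False
                    break
            if not chained:
                continue
            first_i = assignment[0][0]
            last_i, last_l, _ = assignment[-1]
            spans.add(
                (
                    (tokens[first_i].start, tokens[last_i + last_l - 1].end),
                    f"rule:{rule.rule_id}",
                    rule.type_label,
                )
            )
    return spans


def brute_force_hits(
    paragraph_id: str,
    text: str,
    products: list[ProductEntry],
    lexicon: EffectLexicon,
) -> set:
    """Hit set as (paragraph_id, canonical, span, source) tuples.

    Product detection is a naive scan for any variant occurrence; valid as an
    oracle whenever no variant is a sub-sequence of another entry's variant
    (guaranteed for generated lexicons, whose variants are single distinct
    tokens).
    """
    tokens = tokenize(text)
    folded = [t.text.casefold() for t in tokens]
    canonicals = set()
    for entry in products:
        for variant in entry.variants:
            parts = variant.split()
            for i in range(len(tokens) - len(parts) + 1):
                if folded[i : i + len(parts)] == parts:
                    canonicals.add(entry.canonical)
    effect_spans = brute_force_effect_spans(tokens, lexicon)
    if not canonicals or not effect_spans:
        return set()
    return {
        (paragraph_id, canonical, span, source)
        for canonical in canonicals
        for span, source, _ in effect_spans
    }


def hit_key_set(hits) -> set:
    """Project package hits onto the oracle's tuple representation."""
    return {
        (h.paragraph_id, h.product_canonical, h.effect.span, h.effect.source)
        for h in hits
    }
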