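"""Gazetteer bootstrapping: growing the products list from corpus text.

Two harvesting mechanisms:

1. **Trademark extraction** — forum posts quoting product literature use
   accurate spelling plus the registered-trademark sign, so every token run
   immediately preceding a ``®`` or ``™`` is a high-precision product/brand
   candidate.

2. **Seed patterns** — contextual templates instantiated with already-known
   names: given the brand "Gaspari", ``'X van Gaspari'`` harvests product
   names; given the product "creatine", ``'creatine van Y'`` harvests brand
   names, and similarly for the bracketed and juxtaposed variants.

Candidates are meant to be reviewed by a human before promotion into the
products list; the CLI therefore writes them to a candidates file rather than
into the lexicon.  :func:`bootstrap_lexicon` nevertheless supports automatic
multi-round promotion (with a frequency threshold) so that chains such as
product -> new brand -> new product are reachable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .corpus_io import ForumPost, iter_paragraphs
from .lexicon import ProductEntry
from .matcher import Token, tokenize

__all__ = [
    "Candidate",
    "SeedPattern",
    "DEFAULT_PATTERNS",
    "DUTCH_STOPWORDS",
    "TRADEMARK_SYMBOLS",
    "extract_trademark_names",
    "expand_by_patterns",
    "bootstrap_lexicon",
    "dump_candidates",
]

TRADEMARK_SYMBOLS = ("®", "™")  # ® ™

# small closed-class list; slot captures must not be ordinary function words
DUTCH_STOPWORDS = frozenset(
    """de het een en van in op met voor naar bij uit aan over onder tussen door
    om tot als dan maar of want dus ook nog wel niet geen er hier daar dit dat
    deze die ik je jij u hij zij ze we wij jullie ze mij me jou hem haar ons
    hun is was zijn waren ben bent heb hebt heeft had hadden wordt word worden
    werd werden kan kun kunt kunnen kon moet moeten mag mogen zal zullen zou
    wil willen ga gaat gaan ging doe doet doen deed te al zo heel erg echt
    veel meer minder goed slecht beter best even weer toch nu dan straks toen
    iets niets alles iemand niemand wat wie waar hoe waarom welke mijn jouw
    uw""".split()
)


@dataclass(frozen=True)
class Candidate:
    """A harvested name with the evidence that produced it."""

    surface: str
    hypothesized_kind: str  # "product" or "brand"
    provenance: Tuple[Tuple[str, str], ...]  # (pattern_id, paragraph_id)

    @property
    def frequency(self) -> int:
        return len(self.provenance)

    @property
    def pattern_ids(self) -> Tuple[str, ...]:
        return tuple(sorted({p for p, _ in self.provenance}))


@dataclass(frozen=True)
class SeedPattern:
    """One contextual template with exactly one unknown slot."""

    pattern_id: str
    template: str  # documented template string, e.g. 'X van BRAND'
    slot_regex: str = r"^(?=.*[^\W\d_])[^\W_]+(?:-[^\W_]+)*$"

    def slot_matches(self, token_text: str) -> bool:
        if token_text.casefold() in DUTCH_STOPWORDS:
            return False
        return re.match(self.slot_regex, token_text) is not None


DEFAULT_PATTERNS: Tuple[SeedPattern, ...] = (
    SeedPattern("x_van_brand", "X van BRAND"),
    SeedPattern("x_paren_brand", "X (BRAND)"),
    SeedPattern("x_paren_van_brand", "X (van BRAND)"),
    SeedPattern("brand_x", "BRAND X"),
    SeedPattern("product_van_y", "PRODUCT van Y"),
)

_NAME_SHAPE_RE = re.compile(r"^[A-Z0-9][\w\-]*$")


def _name_like(token_text: str) -> bool:
    """Token shape for *extending* a capture: capitalized or containing a
    digit, alphanumeric with optional internal hyphen."""
    return _NAME_SHAPE_RE.match(token_text) is not None


def _capture_backward(
    tokens: Sequence[Token], anchor: int, pattern: SeedPattern, max_tokens: int = 4
) -> Optional[Tuple[int, int]]:
    """Capture the unknown slot ending just before token index ``anchor``."""
    last = anchor - 1
    if last < 0 or not pattern.slot_matches(tokens[last].text):
        return None
    first = last
    while first - 1 >= 0 and last - first + 1 < max_tokens and _name_like(
        tokens[first - 1].text
    ):
        first -= 1
    return first, last + 1


def _capture_forward(
    tokens: Sequence[Token], anchor: int, pattern: SeedPattern, max_tokens: int = 4
) -> Optional[Tuple[int, int]]:
    """Capture the unknown slot starting at token index ``anchor``."""
    if anchor >= len(tokens) or not pattern.slot_matches(tokens[anchor].text):
        return None
    last = anchor
    while last + 1 < len(tokens) and last - anchor + 1 < max_tokens and _name_like(
        tokens[last + 1].text
    ):
        last += 1
    return anchor, last + 1


class _CandidatePool:
    def __init__(self) -> None:
        self._pool: Dict[Tuple[str, str], Tuple[str, List[Tuple[str, str]]]] = {}

    def add(
        self, surface: str, kind: str, pattern_id: str, paragraph_id: str
    ) -> None:
        key = (surface.casefold(), kind)
        if key not in self._pool:
            self._pool[key] = (surface, [])
        self._pool[key][1].append((pattern_id, paragraph_id))

    def candidates(self) -> List[Candidate]:
        items = [
            Candidate(surface, kind, tuple(provenance))
            for (_, kind), (surface, provenance) in self._pool.items()
        ]
        items.sort(key=lambda c: (-c.frequency, c.surface.casefold(), c.surface))
        return items


def extract_trademark_names(posts: Iterable[ForumPost]) -> List[Candidate]:
    """Collect every maximal name-shaped token run immediately preceding a
    trademark symbol (no whitespace between name and symbol)."""
    pool = _CandidatePool()
    for paragraph in iter_paragraphs(posts):
        tokens = tokenize(paragraph.text)
        for i, token in enumerate(tokens):
            if token.text not in TRADEMARK_SYMBOLS:
                continue
            if i == 0 or tokens[i - 1].end != token.start:
                continue  # symbol must be glued to the name
            if not _name_like(tokens[i - 1].text):
                continue
            first = i - 1
            while first - 1 >= 0 and (i - first) < 4 and _name_like(
                tokens[first - 1].text
            ):
                first -= 1
            surface = paragraph.text[tokens[first].start : tokens[i - 1].end]
            pool.add(surface, "product", "trademark", paragraph.paragraph_id)
    return pool.candidates()


def _seed_surface_index(
    seeds: Sequence[ProductEntry], kinds: Set[str]
) -> Dict[Tuple[str, ...], str]:
    index: Dict[Tuple[str, ...], str] = {}
    for entry in seeds:
        if entry.kind not in kinds:
            continue
        for variant in entry.variants:
            index[tuple(variant.split())] = entry.canonical
    return index


def _find_seed_at(
    folded: Sequence[str], i: int, index: Dict[Tuple[str, ...], str]
) -> Optional[int]:
    """Return the token length of the longest seed variant starting at i."""
    best = None
    for key in index:
        length = len(key)
        if tuple(folded[i : i + length]) == key:
            if best is None or length > best:
                best = length
    return best


def expand_by_patterns(
    posts: Iterable[ForumPost],
    seeds: Sequence[ProductEntry],
    patterns: Sequence[SeedPattern] = DEFAULT_PATTERNS,
) -> List[Candidate]:
    """Instantiate every pattern with every known seed name and harvest the
    unknown slot.  Brand-anchored patterns yield product candidates; the
    product-anchored pattern yields brand candidates.  Candidates whose
    surface is already a seed variant are dropped.
    """
    brands = _seed_surface_index(seeds, {"brand"})
    products = _seed_surface_index(seeds, {"product", "product_type"})
    known: Set[str] = set()
    for entry in seeds:
        known |= set(entry.variants)
    by_id = {p.pattern_id: p for p in patterns}
    pool = _CandidatePool()

    for paragraph in iter_paragraphs(posts):
        tokens = tokenize(paragraph.text)
        folded = [t.text.casefold() for t in tokens]
        n = len(tokens)
        for i in range(n):
            # 'PRODUCT van Y' -> brand candidate Y
            pat = by_id.get("product_van_y")
            if pat is not None:
                length = _find_seed_at(folded, i, products)
                if length is not None and i + length < n and folded[i + length] == "van":
                    capture = _capture_forward(tokens, i + length + 1, pat)
                    if capture:
                        first, last = capture
                        surface = paragraph.text[tokens[first].start : tokens[last - 1].end]
                        pool.add(surface, "brand", pat.pattern_id, paragraph.paragraph_id)
            # brand-anchored patterns -> product candidate X
            blen = _find_seed_at(folded, i, brands)
            if blen is None:
                continue
            end = i + blen
            pat = by_id.get("x_van_brand")
            if pat is not None and i >= 2 and folded[i - 1] == "van":
                capture = _capture_backward(tokens, i - 1, pat)
                if capture:
                    first, last = capture
                    surface = paragraph.text[tokens[first].start : tokens[last - 1].end]
                    pool.add(surface, "product", pat.pattern_id, paragraph.paragraph_id)
            pat = by_id.get("x_paren_brand")
            if (
                pat is not None
                and i >= 2
                and folded[i - 1] == "("
                and end < n
                and folded[end] == ")"
            ):
                capture = _capture_backward(tokens, i - 1, pat)
                if capture:
                    first, last = capture
                    surface = paragraph.text[tokens[first].start : tokens[last - 1].end]
                    pool.add(surface, "product", pat.pattern_id, paragraph.paragraph_id)
            pat = by_id.get("x_paren_van_brand")
            if (
                pat is not None
                and i >= 3
                and folded[i - 1] == "van"
                and folded[i - 2] == "("
                and end < n
                and folded[end] == ")"
            ):
                capture = _capture_backward(tokens, i - 2, pat)
                if capture:
                    first, last = capture
                    surface = paragraph.text[tokens[first].start : tokens[last - 1].end]
                    pool.add(surface, "product", pat.pattern_id, paragraph.paragraph_id)
            pat = by_id.get("brand_x")
            if pat is not None:
                capture = _capture_forward(tokens, end, pat)
                if capture:
                    first, last = capture
                    surface = paragraph.text[tokens[first].start : tokens[last - 1].end]
                    pool.add(surface, "product", pat.pattern_id, paragraph.paragraph_id)

    return [c for c in pool.candidates() if c.surface.casefold() not in known]


def bootstrap_lexicon(
    posts: Iterable[ForumPost],
    seeds: Sequence[ProductEntry],
    patterns: Sequence[SeedPattern] = DEFAULT_PATTERNS,
    rounds: int = 1,
    min_freq: int = 1,
) -> List[Candidate]:
    """Iteratively expand the seed list.

    Each round runs :func:`expand_by_patterns` with the current seeds and
    promotes candidates reaching ``min_freq`` occurrences into the seed set.
    Returns every candidate promoted in any round, sorted by (frequency desc,
    surface asc).  Deterministic; the promoted set grows monotonically with
    the number of rounds.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    posts = list(posts)
    current: List[ProductEntry] = list(seeds)
    promoted: Dict[Tuple[str, str], Candidate] = {}
    for _ in range(rounds):
        new_promotions = []
        for candidate in expand_by_patterns(posts, current, patterns):
            key = (candidate.surface.casefold(), candidate.hypothesized_kind)
            if candidate.frequency >= min_freq and key not in promoted:
                promoted[key] = candidate
                new_promotions.append(candidate)
        if not new_promotions:
            break
        current = current + [
            ProductEntry(c.surface, c.hypothesized_kind) for c in new_promotions
        ]
    result = list(promoted.values())
    result.sort(key=lambda c: (-c.frequency, c.surface.casefold(), c.surface))
    return result


def dump_candidates(candidates: Iterable[Candidate]) -> str:
    """TSV: surface, kind, freq, comma-joined pattern ids."""
    lines = ["surface\tkind\tfreq\tpattern_ids"]
    for c in candidates:
        lines.append(
            f"{c.surface}\t{c.hypothesized_kind}\t{c.frequency}\t"
            + ",".join(c.pattern_ids)
        )
    return "\n".join(lines) + "\n"
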