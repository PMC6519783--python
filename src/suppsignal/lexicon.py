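"""Products gazetteer and effects lexicon.

The retrieval method is driven by two hand-curated term lists:

* a **products list** — supplement product and brand names together with
  spelling variants and short forms, and
* an **effects lexicon** — a vocabulary of word uni-/bigrams annotated with a
  part-of-speech tag and a coarse semantic class, plus **combination rules**
  describing which vocabulary items may combine into longer effect phrases
  (e.g. a sentiment adjective followed by a semantically vague noun).

Effect strings carry a *type label* (mostly organ-system based, e.g.
``'maag, lever en darmen'``) used to aggregate hits into report categories.
Strings that cannot be assigned a meaningful category carry the label
``'unspecified'``; because such vague strings dilute precision, a lexicon can
be narrowed with :func:`effective_lexicon` to drop everything labelled
``'unspecified'`` before searching.

File formats (UTF-8 TSV, ``#`` starts a comment line):

* ``products.tsv``: ``canonical <TAB> kind <TAB> variant|variant|...``
* ``effects_vocab.tsv``: ``surface <TAB> pos <TAB> sem <TAB> standalone(0/1)
  <TAB> type_label-or-'-'``
* ``effects_rules.tsv``: ``rule_id <TAB> slot+slot+... <TAB> max_gap <TAB>
  type_label`` where each slot is ``lit:<surface>``, ``pos:<TAG>`` or
  ``sem:<class>``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

from .errors import LexiconError

__all__ = [
    "POS_TAGS",
    "SEM_TAGS",
    "UNSPECIFIED",
    "PRODUCT_KINDS",
    "ProductEntry",
    "EffectVocabItem",
    "SlotConstraint",
    "CombinationRule",
    "EffectLexicon",
    "load_products",
    "dump_products",
    "load_effects",
    "dump_effects",
    "validate_lexicon",
    "effective_lexicon",
]

POS_TAGS = frozenset({"NOUN", "ADJ", "ADV", "VERB", "PREP", "QUANT"})
SEM_TAGS = frozenset(
    {"effect_noun", "vague_noun", "effect_adj", "sentiment", "body_part",
     "verb_effect", "other"}
)
PRODUCT_KINDS = frozenset({"product", "brand", "product_type"})

#: label for effect strings that could not be assigned a body-system category
UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class ProductEntry:
    """A gazetteer entry: canonical name plus case-folded variants."""

    canonical: str
    kind: str = "product"
    variants: frozenset = frozenset()

    def __post_init__(self):
        if not self.canonical:
            raise LexiconError("product entry with empty canonical name")
        if self.kind not in PRODUCT_KINDS:
            raise LexiconError(
                f"unknown product kind {self.kind!r} for {self.canonical!r}"
            )
        variants = {v.casefold() for v in self.variants}
        variants.add(self.canonical.casefold())
        object.__setattr__(self, "variants", frozenset(variants))


@dataclass(frozen=True)
class EffectVocabItem:
    """A 1- or 2-token vocabulary entry with POS and semantic class.

    ``standalone`` items denote an effect on their own (and then must carry a
    type label); non-standalone items (vague nouns, sentiment words, body
    parts, ...) only fire inside combination rules.  Keeping sentiment words
    non-standalone is deliberate: applied on their own they retrieve mostly
    irrelevant enthusiasm, while inside a rule ("dramatisch afgevallen") they
    mark a reported effect.
    """

    surface: str
    pos: str
    sem: str
    standalone: bool = False
    type_label: Optional[str] = None

    @property
    def tokens(self) -> Tuple[str, ...]:
        return tuple(self.surface.casefold().split())

    @property
    def key(self) -> str:
        return f"{self.surface.casefold()}|{self.pos}|{self.sem}"


@dataclass(frozen=True)
class SlotConstraint:
    """One slot of a combination rule: ``literal`` (a vocab surface),
    ``pos`` (a POS tag) or ``sem`` (a semantic class)."""

    mode: str
    value: str


@dataclass(frozen=True)
class CombinationRule:
    """Ordered slot sequence; between two consecutively matched slots at most
    ``max_gap`` unmatched tokens may intervene.  A firing rule labels the
    matched span with ``type_label``."""

    rule_id: str
    slots: Tuple[SlotConstraint, ...]
    max_gap: int
    type_label: str

    def __post_init__(self):
        object.__setattr__(self, "slots", tuple(self.slots))


@dataclass
class EffectLexicon:
    vocab: List[EffectVocabItem]
    rules: List[CombinationRule]
    labels: Set[str]
    include_unspecified: bool = True

    def surfaces(self) -> Set[str]:
        return {v.surface.casefold() for v in self.vocab}


# ---------------------------------------------------------------------------
# TSV reading helpers
# ---------------------------------------------------------------------------

TsvSource = Union[str, Path, io.IOBase]


def _read_rows(source: TsvSource) -> List[Tuple[int, List[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif isinstance(source, str):
        text = Path(source).read_text(encoding="utf-8")
    else:
        data = source.read()
        text = data.decode("utf-8") if isinstance(data, bytes) else data
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append((lineno, line.rstrip("\n").split("\t")))
    return rows


# ---------------------------------------------------------------------------
# products list
# ---------------------------------------------------------------------------

def load_products(source: TsvSource) -> List[ProductEntry]:
    """Load the products gazetteer.

    Duplicate canonicals (case-insensitively) are merged with a union of their
    variants; a variant mapped to two different canonicals is an error, since
    matching could then not attribute a mention unambiguously.
    """
    merged: dict = {}  # casefolded canonical -> (canonical, kind, set of variants)
    order: List[str] = []
    for lineno, fields in _read_rows(source):
        if len(fields) < 2:
            raise LexiconError(f"products line {lineno}: expected >=2 columns")
        canonical = fields[0].strip()
        kind = fields[1].strip()
        variants = set()
        if len(fields) > 2 and fields[2].strip():
            variants = {v.strip().casefold() for v in fields[2].split("|") if v.strip()}
        key = canonical.casefold()
        if key in merged:
            prev_canonical, prev_kind, prev_variants = merged[key]
            if prev_kind != kind:
                raise LexiconError(
                    f"products line {lineno}: {canonical!r} redeclared with kind "
                    f"{kind!r} (was {prev_kind!r})"
                )
            merged[key] = (prev_canonical, kind, prev_variants | variants)
        else:
            merged[key] = (canonical, kind, variants)
            order.append(key)
    entries = [
        ProductEntry(canonical, kind, frozenset(variants))
        for canonical, kind, variants in (merged[k] for k in order)
    ]
    owner: dict = {}
    for entry in entries:
        for variant in entry.variants:
            if variant in owner and owner[variant] != entry.canonical:
                raise LexiconError(
                    f"variant {variant!r} is claimed by both "
                    f"{owner[variant]!r} and {entry.canonical!r}"
                )
            owner[variant] = entry.canonical
    return entries


def dump_products(entries: Iterable[ProductEntry]) -> str:
    lines = []
    for entry in entries:
        variants = "|".join(sorted(entry.variants))
        lines.append(f"{entry.canonical}\t{entry.kind}\t{variants}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# effects lexicon
# ---------------------------------------------------------------------------

_SLOT_MODES = {"lit": "literal", "pos": "pos", "sem": "sem"}


def load_effects(vocab_source: TsvSource, rules_source: TsvSource) -> EffectLexicon:
    """Load the effects vocabulary and rules and cross-validate them."""
    vocab: List[EffectVocabItem] = []
    for lineno, fields in _read_rows(vocab_source):
        if len(fields) != 5:
            raise LexiconError(f"effects vocab line {lineno}: expected 5 columns")
        surface, pos, sem, standalone, label = (f.strip() for f in fields)
        if pos not in POS_TAGS:
            raise LexiconError(f"effects vocab line {lineno}: unknown pos {pos!r}")
        if sem not in SEM_TAGS:
            raise LexiconError(f"effects vocab line {lineno}: unknown sem {sem!r}")
        if standalone not in {"0", "1"}:
            raise LexiconError(
                f"effects vocab line {lineno}: standalone must be 0 or 1"
            )
        vocab.append(
            EffectVocabItem(
                surface=surface,
                pos=pos,
                sem=sem,
                standalone=standalone == "1",
                type_label=None if label == "-" else label,
            )
        )

    rules: List[CombinationRule] = []
    for lineno, fields in _read_rows(rules_source):
        if len(fields) != 4:
            raise LexiconError(f"effects rules line {lineno}: expected 4 columns")
        rule_id, slot_spec, max_gap_s, label = (f.strip() for f in fields)
        slots = []
        for part in slot_spec.split("+"):
            part = part.strip()
            mode, _, value = part.partition(":")
            if mode not in _SLOT_MODES or not value:
                raise LexiconError(
                    f"effects rules line {lineno}: bad slot spec {part!r}"
                )
            slots.append(SlotConstraint(_SLOT_MODES[mode], value))
        try:
            max_gap = int(max_gap_s)
        except ValueError:
            raise LexiconError(
                f"effects rules line {lineno}: max_gap must be an integer"
            ) from None
        rules.append(CombinationRule(rule_id, tuple(slots), max_gap, label))

    labels = {v.type_label for v in vocab if v.type_label is not None}
    labels |= {r.type_label for r in rules}
    labels.add(UNSPECIFIED)
    lexicon = EffectLexicon(vocab=vocab, rules=rules, labels=labels)
    diagnostics = validate_lexicon(lexicon)
    if diagnostics:
        raise LexiconError("invalid effects lexicon: " + "; ".join(diagnostics))
    return lexicon


def dump_effects(lexicon: EffectLexicon) -> Tuple[str, str]:
    """Serialize a lexicon back to (vocab_tsv, rules_tsv) text."""
    vocab_lines = [
        "\t".join(
            [
                item.surface,
                item.pos,
                item.sem,
                "1" if item.standalone else "0",
                item.type_label if item.type_label is not None else "-",
            ]
        )
        for item in lexicon.vocab
    ]
    mode_back = {v: k for k, v in _SLOT_MODES.items()}
    rule_lines = []
    for rule in lexicon.rules:
        spec = "+".join(f"{mode_back[s.mode]}:{s.value}" for s in rule.slots)
        rule_lines.append(
            f"{rule.rule_id}\t{spec}\t{rule.max_gap}\t{rule.type_label}"
        )
    return "\n".join(vocab_lines) + "\n", "\n".join(rule_lines) + "\n"


def validate_lexicon(lexicon: EffectLexicon) -> List[str]:
    """Return one diagnostic string per invariant violation (empty if valid)."""
    diags: List[str] = []
    if UNSPECIFIED not in lexicon.labels:
        diags.append(f"label set must define {UNSPECIFIED!r}")
    surfaces = lexicon.surfaces()
    for i, item in enumerate(lexicon.vocab):
        where = f"vocab[{i}] {item.surface!r}"
        if not item.surface.strip():
            diags.append(f"{where}: empty surface")
        if len(item.tokens) > 2:
            diags.append(f"{where}: more than 2 tokens")
        if item.pos not in POS_TAGS:
            diags.append(f"{where}: unknown pos {item.pos!r}")
        if item.sem not in SEM_TAGS:
            diags.append(f"{where}: unknown sem {item.sem!r}")
        if item.standalone and item.type_label is None:
            diags.append(f"{where}: standalone item without type label")
        if item.type_label is not None and item.type_label not in lexicon.labels:
            diags.append(f"{where}: undefined type label {item.type_label!r}")
    seen_rule_ids = set()
    for i, rule in enumerate(lexicon.rules):
        where = f"rule[{i}] {rule.rule_id!r}"
        if rule.rule_id in seen_rule_ids:
            diags.append(f"{where}: duplicate rule id")
        seen_rule_ids.add(rule.rule_id)
        if len(rule.slots) < 2:
            diags.append(f"{where}: fewer than 2 slots")
        if not 0 <= rule.max_gap <= 5:
            diags.append(f"{where}: max_gap {rule.max_gap} outside 0..5")
        if rule.type_label not in lexicon.labels:
            diags.append(f"{where}: undefined type label {rule.type_label!r}")
        for j, slot in enumerate(rule.slots):
            if slot.mode == "literal":
                if slot.value.casefold() not in surfaces:
                    diags.append(
                        f"{where} slot[{j}]: literal {slot.value!r} not in vocabulary"
                    )
            elif slot.mode == "pos":
                if slot.value not in POS_TAGS:
                    diags.append(f"{where} slot[{j}]: unknown pos {slot.value!r}")
            elif slot.mode == "sem":
                if slot.value not in SEM_TAGS:
                    diags.append(f"{where} slot[{j}]: unknown sem {slot.value!r}")
            else:
                diags.append(f"{where} slot[{j}]: unknown mode {slot.mode!r}")
    return diags


def effective_lexicon(
    lexicon: EffectLexicon, include_unspecified: bool
) -> EffectLexicon:
    """Return the lexicon actually used for searching.

    With ``include_unspecified=False`` every vocabulary item and rule labelled
    ``'unspecified'`` is dropped — the narrowing used when screening for
    suspect products, where vague effect strings only add noise.
    """
    if include_unspecified:
        return lexicon
    return EffectLexicon(
        vocab=[v for v in lexicon.vocab if v.type_label != UNSPECIFIED],
        rules=[r for r in lexicon.rules if r.type_label != UNSPECIFIED],
        labels=set(lexicon.labels),
        include_unspecified=False,
    )
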