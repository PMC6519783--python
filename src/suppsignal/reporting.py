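"""Aggregation of hits into the three report levels, and product ranking.

Level 1 (*effect type report*): hit counts per (product, effect category).
Level 2 (*effect details report*): one row per hit, with the paragraph id.
Level 3 (*paragraph report*): the full paragraphs with product and effect
spans marked up (HTML; products and effects carry distinct CSS classes).

The per-product total over level-1 categories equals the number of level-2
rows for that product equals the product's total hit count — a conservation
law that holds for any input because all three views are derived from the
same hit list.  Ranking products by total hit count is the package's risk
signal: products repeatedly co-mentioned with effects float to the top.
"""

from __future__ import annotations

import csv
import html as _html
import io
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .corpus_io import ForumPost, iter_paragraphs
from .errors import ReportError
from .lexicon import ProductEntry
from .matcher import Hit, match_products, tokenize

__all__ = [
    "TypeReportRow",
    "DetailReportRow",
    "AnnotatedParagraph",
    "effect_type_report",
    "effect_details_report",
    "paragraph_report",
    "rank_products",
    "filter_by_category",
    "render_html",
    "write_type_report",
    "write_details_report",
    "write_ranking",
]


@dataclass(frozen=True)
class TypeReportRow:
    product_canonical: str
    type_label: str
    n_hits: int


@dataclass(frozen=True)
class DetailReportRow:
    product_canonical: str
    type_label: str
    effect_text: str
    paragraph_id: str


@dataclass(frozen=True)
class AnnotatedParagraph:
    paragraph_id: str
    text: str
    product_spans: Tuple[Tuple[int, int, str], ...]  # (start, end, canonical)
    effect_spans: Tuple[Tuple[int, int, str], ...]  # (start, end, type_label)


def effect_type_report(hits: Sequence[Hit]) -> List[TypeReportRow]:
    """Group hits by (product, type label); sort by product, then count
    descending (label ascending on ties, for determinism)."""
    counts: Counter = Counter(
        (h.product_canonical, h.effect.type_label) for h in hits
    )
    rows = [
        TypeReportRow(product, label, n) for (product, label), n in counts.items()
    ]
    rows.sort(key=lambda r: (r.product_canonical, -r.n_hits, r.type_label))
    return rows


def effect_details_report(hits: Sequence[Hit]) -> List[DetailReportRow]:
    """One row per hit (a bijection), in hit order."""
    return [
        DetailReportRow(
            h.product_canonical, h.effect.type_label, h.effect.matched_text,
            h.paragraph_id,
        )
        for h in hits
    ]


def paragraph_report(
    hits: Sequence[Hit],
    posts: Iterable[ForumPost],
    products: Sequence[ProductEntry],
) -> List[AnnotatedParagraph]:
    """One annotated paragraph per distinct paragraph id in the hits.

    Effect spans come from the hits themselves; product spans are recomputed
    from the products list (hits carry only the canonical name), restricted to
    the products actually hit in that paragraph.
    """
    text_by_id = {p.paragraph_id: p.text for p in iter_paragraphs(posts)}
    by_paragraph: Dict[str, List[Hit]] = defaultdict(list)
    for hit in hits:
        by_paragraph[hit.paragraph_id].append(hit)
    report = []
    for pid in sorted(by_paragraph):
        if pid not in text_by_id:
            raise ReportError(f"hit references unknown paragraph {pid!r}")
        text = text_by_id[pid]
        hit_products = {h.product_canonical for h in by_paragraph[pid]}
        tokens = tokenize(text)
        product_spans = tuple(
            sorted(
                (m.span[0], m.span[1], m.entry.canonical)
                for m in match_products(tokens, pid, products)
                if m.entry.canonical in hit_products
            )
        )
        effect_spans = tuple(
            sorted(
                {
                    (h.effect.span[0], h.effect.span[1], h.effect.type_label)
                    for h in by_paragraph[pid]
                }
            )
        )
        report.append(AnnotatedParagraph(pid, text, product_spans, effect_spans))
    return report


def rank_products(
    type_rows: Sequence[TypeReportRow], min_hits: int = 0
) -> List[Tuple[str, int]]:
    """Total hits per product, descending (alphabetical on ties); products
    below ``min_hits`` are dropped."""
    totals: Counter = Counter()
    for row in type_rows:
        totals[row.product_canonical] += row.n_hits
    ranked = [(p, n) for p, n in totals.items() if n >= min_hits]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


def filter_by_category(
    hits: Sequence[Hit],
    labels: Set[str],
    known_labels: Optional[Set[str]] = None,
) -> List[Hit]:
    """Keep hits whose type label is in ``labels``.

    When the lexicon's label inventory is supplied via ``known_labels``,
    requesting an undefined label raises (it would silently match nothing).
    """
    if known_labels is not None:
        unknown = set(labels) - set(known_labels)
        if unknown:
            raise ReportError(f"unknown type label(s): {sorted(unknown)}")
    return [h for h in hits if h.effect.type_label in labels]


# ---------------------------------------------------------------------------
# HTML rendering (level 3)
# ---------------------------------------------------------------------------

_HTML_HEAD = (
    "<!DOCTYPE html>\n<html>\n<head>\n<meta charset=\"utf-8\"/>\n"
    "<title>paragraph report</title>\n<style>\n"
    ".product{color:#c00;font-weight:bold}\n"
    ".effect{color:#00c}\n"
    "div.paragraph{margin:1em 0;border-bottom:1px solid #ddd;padding:0.5em}\n"
    "</style>\n</head>\n<body>\n"
)


def _markup_paragraph(par: AnnotatedParagraph) -> str:
    """Wrap product/effect spans in <span> elements.

    Spans may overlap (two rules can cover intersecting stretches), so the
    text is first partitioned into maximal runs with a constant set of
    classes; each run becomes at most one span.  Stripping the markup
    therefore reproduces the original text exactly.
    """
    classes: List[Set[str]] = [set() for _ in par.text]
    for start, end, _ in par.product_spans:
        for i in range(start, end):
            classes[i].add("product")
    for start, end, _ in par.effect_spans:
        for i in range(start, end):
            classes[i].add("effect")
    pieces: List[str] = []
    i = 0
    n = len(par.text)
    while i < n:
        j = i
        while j < n and classes[j] == classes[i]:
            j += 1
        chunk = _html.escape(par.text[i:j])
        if classes[i]:
            cls = " ".join(sorted(classes[i]))
            pieces.append(f'<span class="{cls}">{chunk}</span>')
        else:
            pieces.append(chunk)
        i = j
    return "".join(pieces)


def render_html(report: Sequence[AnnotatedParagraph]) -> str:
    """Standalone HTML page for the paragraph report."""
    parts = [_HTML_HEAD]
    for par in report:
        parts.append(
            f'<div class="paragraph" id="{_html.escape(par.paragraph_id)}">\n'
            f"<h4>{_html.escape(par.paragraph_id)}</h4>\n"
            f"<p>{_markup_paragraph(par)}</p>\n</div>\n"
        )
    parts.append("</body>\n</html>\n")
    return "".join(parts)


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def _write_tsv(
    destination: Union[str, Path, io.IOBase],
    header: List[str],
    rows: Iterable[Sequence],
) -> None:
    buffer = io.StringIO()
    writer = csv.writer(buffer, delimiter="\t", lineterminator="\n")
    writer.writerow(header)
    writer.writerows(rows)
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(buffer.getvalue(), encoding="utf-8")
    else:
        destination.write(buffer.getvalue())


def write_type_report(rows, destination) -> None:
    _write_tsv(
        destination,
        ["product", "type_label", "n_hits"],
        ([r.product_canonical, r.type_label, r.n_hits] for r in rows),
    )


def write_details_report(rows, destination) -> None:
    _write_tsv(
        destination,
        ["product", "type_label", "effect_text", "paragraph_id"],
        (
            [r.product_canonical, r.type_label, r.effect_text, r.paragraph_id]
            for r in rows
        ),
    )


def write_ranking(ranking, destination) -> None:
    _write_tsv(destination, ["product", "total_hits"], ranking)
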