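"""Forum-post corpus I/O.

Forum posts are stored in a small XML dialect: a ``<corpus>`` root holding
``<post>`` elements with the post metadata as attributes, a ``<title>`` child
and one ``<p n="...">`` child per paragraph.  The paragraph — not the post —
is the retrieval unit everywhere else in the package, because paragraphs are
short and relatively self-contained, which makes retrieved text inspectable.

This module covers the preparation steps applied to scraped forum text:
character-level clean-up (entity decoding, control stripping, whitespace
normalisation) and segmentation of post bodies into paragraphs at blank
lines.
"""

from __future__ import annotations

import html
import io
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Union

from lxml import etree

from .errors import CorpusFormatError, CorpusSchemaError

__all__ = [
    "Paragraph",
    "ForumPost",
    "clean_text",
    "segment_paragraphs",
    "parse_corpus",
    "write_corpus",
    "ingest_raw",
    "make_post",
    "iter_paragraphs",
]


@dataclass(frozen=True)
class Paragraph:
    """One paragraph of a post; ``paragraph_id`` is ``<post_id>#<ordinal>``."""

    paragraph_id: str
    ordinal: int
    text: str


@dataclass
class ForumPost:
    forum_id: str
    thread_id: str
    title: str
    author_id: str  # pseudonymized upstream; never a real name in synthetic data
    timestamp: str  # ISO-8601
    post_id: str
    post_index: int
    paragraphs: List[Paragraph] = field(default_factory=list)


# ---------------------------------------------------------------------------
# cleaning and segmentation
# ---------------------------------------------------------------------------

def _strip_controls(text: str) -> str:
    # keep newline and tab; tabs are collapsed together with spaces later
    return "".join(
        ch for ch in text if ch in "\n\t" or unicodedata.category(ch) != "Cc"
    )


def clean_text(raw: str) -> str:
    """Normalize scraped text: decode HTML entities, drop control characters,
    collapse runs of spaces/tabs, NFC-normalize.  Newline structure (and hence
    paragraph boundaries) is preserved.  Total and idempotent.
    """
    text = raw
    # entity decoding and control stripping interact (entities can encode
    # controls, controls can split entities), so iterate to a fixpoint
    for _ in range(1000):
        nxt = html.unescape(_strip_controls(text))
        if nxt == text:
            break
        text = nxt
    text = _strip_controls(text)
    text = unicodedata.normalize("NFC", text)
    text = re.sub(r"[ \t]+", " ", text)
    return text


_BLANK_RUN_RE = re.compile(r"\n\s*\n")


def segment_paragraphs(body: str, post_id: str = "") -> List[Paragraph]:
    """Split a cleaned post body on runs of blank lines.

    Each segment is stripped; empty segments are dropped; ordinals run from 0.
    """
    segments = [s.strip() for s in _BLANK_RUN_RE.split(body)]
    return [
        Paragraph(f"{post_id}#{i}", i, text)
        for i, text in enumerate(s for s in segments if s)
    ]


def make_post(
    *,
    forum_id: str = "",
    thread_id: str = "",
    title: str = "",
    author_id: str = "",
    timestamp: str = "",
    post_id: str,
    post_index: int = 0,
    body: str = "",
) -> ForumPost:
    """Build a post from a raw body: clean, then segment into paragraphs."""
    cleaned = clean_text(body)
    return ForumPost(
        forum_id=forum_id,
        thread_id=thread_id,
        title=clean_text(title),
        author_id=author_id,
        timestamp=timestamp,
        post_id=post_id,
        post_index=post_index,
        paragraphs=segment_paragraphs(cleaned, post_id),
    )


def iter_paragraphs(posts: Iterable[ForumPost]) -> Iterator[Paragraph]:
    for post in posts:
        yield from post.paragraphs


# ---------------------------------------------------------------------------
# XML parsing / serialization
# ---------------------------------------------------------------------------

XmlSource = Union[str, Path, bytes, io.IOBase]


def _as_parse_source(source: XmlSource):
    if isinstance(source, bytes):
        return io.BytesIO(source)
    return source if not isinstance(source, Path) else str(source)


def _post_from_element(el: etree._Element, position: int) -> ForumPost:
    post_id = el.get("id")
    if post_id is None:
        raise CorpusSchemaError(
            f"<post> element #{position} (line {el.sourceline}) is missing the "
            "mandatory 'id' attribute"
        )
    title_el = el.find("title")
    title = (title_el.text or "") if title_el is not None else ""
    paragraphs = [
        Paragraph(f"{post_id}#{i}", i, p.text or "")
        for i, p in enumerate(el.findall("p"))
    ]
    index_attr = el.get("index", "")
    try:
        post_index = int(index_attr) if index_attr else 0
    except ValueError:
        raise CorpusSchemaError(
            f"<post id={post_id!r}> has non-integer index {index_attr!r}"
        ) from None
    return ForumPost(
        forum_id=el.get("forum", ""),
        thread_id=el.get("thread", ""),
        title=title,
        author_id=el.get("author", ""),
        timestamp=el.get("timestamp", ""),
        post_id=post_id,
        post_index=post_index,
        paragraphs=paragraphs,
    )


def parse_corpus(xml_source: XmlSource) -> List[ForumPost]:
    """Parse a corpus XML file into posts, preserving document order."""
    try:
        tree = etree.parse(_as_parse_source(xml_source))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise CorpusFormatError(f"cannot parse corpus XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "corpus":
        raise CorpusSchemaError(f"expected root element <corpus>, found <{root.tag}>")
    return [_post_from_element(el, i) for i, el in enumerate(root.findall("post"))]


def write_corpus(posts: Iterable[ForumPost]) -> bytes:
    """Serialize posts to the corpus XML dialect, deterministically (UTF-8,
    fixed attribute order)."""
    root = etree.Element("corpus")
    for post in posts:
        el = etree.SubElement(root, "post")
        el.set("forum", post.forum_id)
        el.set("thread", post.thread_id)
        el.set("id", post.post_id)
        el.set("index", str(post.post_index))
        el.set("author", post.author_id)
        el.set("timestamp", post.timestamp)
        title = etree.SubElement(el, "title")
        title.text = post.title
        for par in post.paragraphs:
            p = etree.SubElement(el, "p")
            p.set("n", str(par.ordinal))
            p.text = par.text
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def ingest_raw(xml_source: XmlSource) -> List[ForumPost]:
    """Read a raw (pre-clean-up) corpus and return cleaned, segmented posts.

    Raw posts may carry their text either in a single ``<body>`` child (blank
    lines marking paragraph breaks) or in already-split ``<p>`` children; in
    both cases every text field is passed through :func:`clean_text`.
    """
    try:
        tree = etree.parse(_as_parse_source(xml_source))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise CorpusFormatError(f"cannot parse raw corpus XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "corpus":
        raise CorpusSchemaError(f"expected root element <corpus>, found <{root.tag}>")
    posts: List[ForumPost] = []
    for i, el in enumerate(root.findall("post")):
        post = _post_from_element(el, i)
        body_el = el.find("body")
        if body_el is not None:
            body = clean_text(body_el.text or "")
        else:
            body = "\n\n".join(clean_text(p.text) for p in post.paragraphs)
        post.title = clean_text(post.title)
        post.paragraphs = segment_paragraphs(body, post.post_id)
        posts.append(post)
    return posts
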