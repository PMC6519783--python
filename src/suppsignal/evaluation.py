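"""Evaluation of retrieval output against human judgements.

Two protocols are supported, mirroring how such systems are validated:

* **Expert comparison, paragraph level** — the set of paragraphs the system
  retrieved is compared against the set an expert marked as containing
  effects, over a fixed paragraph universe, yielding precision, recall and
  accuracy from the 2x2 confusion table.

* **Multi-annotator study, match level** — several annotators independently
  mark effect spans; a system match counts as *supported* by an annotator if
  its span overlaps one of that annotator's spans (>= 1 character by default)
  in the same paragraph.  Reported are the fractions of system matches
  supported by at least k annotators, and Cohen's kappa between annotator
  pairs (paragraph-level binary judgements).

Undefined ratios (e.g. precision with no retrieved items) are reported as
NaN, never as 0 — a 0 would claim the system was measurably wrong.
"""

from __future__ import annotations

import csv
import io
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple, Union

from .matcher import EffectMatch

__all__ = [
    "GoldAnnotation",
    "ConfusionCounts",
    "EvalMetrics",
    "confusion",
    "prf_accuracy",
    "cohen_kappa",
    "annotator_support",
    "spans_overlap",
    "load_gold",
    "dump_gold",
]


def _merge_spans(spans: Iterable[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    """Sort and merge overlapping/adjacent-overlapping spans."""
    merged: List[List[int]] = []
    for start, end in sorted(spans):
        if merged and start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GoldAnnotation:
    """Effect spans one annotator marked in one paragraph (merged,
    non-overlapping)."""

    annotator_id: str
    paragraph_id: str
    spans: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "spans", _merge_spans(self.spans))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalMetrics:
    precision: float
    recall: float
    accuracy: float
    kappa: float = math.nan


def confusion(
    retrieved: Set[str], gold_positive: Set[str], universe: Set[str]
) -> ConfusionCounts:
    """Standard 2x2 counts over a fixed universe of paragraph ids."""
    retrieved = set(retrieved)
    gold_positive = set(gold_positive)
    universe = set(universe)
    if not retrieved <= universe:
        raise ValueError("retrieved set is not a subset of the universe")
    if not gold_positive <= universe:
        raise ValueError("gold set is not a subset of the universe")
    tp = len(retrieved & gold_positive)
    fp = len(retrieved - gold_positive)
    fn = len(gold_positive - retrieved)
    tn = len(universe - retrieved - gold_positive)
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def prf_accuracy(c: ConfusionCounts) -> EvalMetrics:
    return EvalMetrics(
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        accuracy=_ratio(c.tp + c.tn, c.total),
    )


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    p_e is the expected agreement from the marginal label distributions.  If
    p_e == 1 (both raters constant with the same label set), agreement is
    already saturated: returns 1.0 when observed agreement is also perfect,
    NaN otherwise.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    if n == 0:
        raise ValueError("empty label vectors")
    p_o = sum(x == y for x, y in zip(a, b)) / n
    labels = set(a) | set(b)
    p_e = sum((a.count(l) / n) * (b.count(l) / n) for l in labels)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else math.nan
    return (p_o - p_e) / (1.0 - p_e)


def spans_overlap(a: Tuple[int, int], b: Tuple[int, int], min_overlap: int = 1) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) >= min_overlap


def annotator_support(
    system_matches: Sequence[EffectMatch],
    gold: Sequence[GoldAnnotation],
    n_annotators: int,
    min_overlap: int = 1,
) -> Dict[int, float]:
    """Fraction of system matches supported by >= k annotators, for k = n..1.

    Support = span overlap of at least ``min_overlap`` characters with any of
    the annotator's spans in the same paragraph.  The fractions are monotone
    non-decreasing as k decreases.
    """
    if n_annotators < 1:
        raise ValueError("n_annotators must be >= 1")
    if not system_matches:
        raise ValueError("no system matches to evaluate")
    spans_by: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    annotators: Set[str] = set()
    for g in gold:
        annotators.add(g.annotator_id)
        spans_by[(g.annotator_id, g.paragraph_id)].extend(g.spans)
    if len(annotators) > n_annotators:
        raise ValueError(
            f"gold names {len(annotators)} annotators, more than n_annotators="
            f"{n_annotators}"
        )
    support_counts = []
    for match in system_matches:
        supporters = 0
        for annotator in annotators:
            spans = spans_by.get((annotator, match.paragraph_id), ())
            if any(spans_overlap(match.span, s, min_overlap) for s in spans):
                supporters += 1
        support_counts.append(supporters)
    total = len(system_matches)
    return {
        k: sum(c >= k for c in support_counts) / total
        for k in range(n_annotators, 0, -1)
    }


# ---------------------------------------------------------------------------
# gold annotation TSV: annotator_id \t paragraph_id \t start \t end
# ---------------------------------------------------------------------------

def load_gold(source: Union[str, Path, io.IOBase]) -> List[GoldAnnotation]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        data = source.read()
        text = data.decode("utf-8") if isinstance(data, bytes) else data
    spans: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    order: List[Tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"gold line {lineno}: expected 4 columns")
        annotator, pid, start_s, end_s = fields
        key = (annotator, pid)
        if key not in spans:
            order.append(key)
        spans[key].append((int(start_s), int(end_s)))
    return [
        GoldAnnotation(annotator, pid, tuple(spans[(annotator, pid)]))
        for annotator, pid in order
    ]


def dump_gold(annotations: Iterable[GoldAnnotation]) -> str:
    lines = []
    for g in annotations:
        for start, end in g.spans:
            lines.append(f"{g.annotator_id}\t{g.paragraph_id}\t{start}\t{end}")
    return "\n".join(lines) + ("\n" if lines else "")
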