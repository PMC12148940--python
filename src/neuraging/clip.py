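"""CLIP binding-window annotation and cross-condition sharing.

Enriched CLIP windows are assigned to transcript elements (5'UTR, CDS,
3'UTR, intron, noncoding exon, or intergenic) by maximal strand-matched
base-pair overlap, the element-fraction profile summarizes where a
binding protein sits on the transcriptome, and window sharing between
two conditions quantifies how much of the binding landscape is
condition-specific.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .intervals import (
    ELEMENT_LABELS,
    ELEMENT_PRIORITY,
    BindingWindow,
    GenomicInterval,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ElementIndex",
    "assign_region",
    "assign_regions",
    "element_fractions",
    "window_overlap_sets",
]

_PRIORITY_RANK = {lab: i for i, lab in enumerate(ELEMENT_PRIORITY)}


class ElementIndex:
    """Interval index over the element geometry of a model collection.

    Keyed by (chrom, strand); payloads are element labels.  Built once,
    reused for every window — assignment is independent of how the models
    were batched when the index was built.
    """

    def __init__(self, models: Iterable[TranscriptModel]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        n_models = 0
        for m in models:
            n_models += 1
            tree = self._trees.setdefault((m.chrom, m.strand), IntervalTree())
            for label, iv in m.elements():
                tree.addi(iv.start, iv.end, label)
        if n_models == 0:
            raise ValueError("no transcript models supplied")

    def element_overlaps(self, iv: GenomicInterval) -> dict[str, int]:
        """Max per-label overlap (bp) of ``iv`` with any indexed element."""
        tree = self._trees.get((iv.chrom, iv.strand))
        if tree is None:
            return {}
        best: dict[str, int] = {}
        for hit in tree.overlap(iv.start, iv.end):
            bp = min(hit.end, iv.end) - max(hit.begin, iv.start)
            if bp > best.get(hit.data, 0):
                best[hit.data] = bp
        return best


def assign_region(
    window: BindingWindow, index: ElementIndex | Iterable[TranscriptModel]
) -> str:
    """Element label for one window.

    The label is the element with maximal base-pair overlap across all
    same-strand transcripts; ties break by the fixed priority
    CDS > 3'UTR > 5'UTR > noncoding_exon > intron; zero overlap yields
    ``intergenic``.
    """
    if not isinstance(index, ElementIndex):
        index = ElementIndex(index)
    overlaps = index.element_overlaps(window.interval)
    if not overlaps:
        return "intergenic"
    return min(overlaps.items(), key=lambda kv: (-kv[1], _PRIORITY_RANK[kv[0]]))[0]


def assign_regions(
    windows: Sequence[BindingWindow],
    models: Iterable[TranscriptModel] | ElementIndex,
) -> list[str]:
    index = models if isinstance(models, ElementIndex) else ElementIndex(models)
    return [assign_region(w, index) for w in windows]


def element_fractions(
    windows: Sequence[BindingWindow],
    models: Iterable[TranscriptModel] | ElementIndex,
) -> dict[str, Fraction]:
    """Fraction of windows per element label.

    Returned as exact rationals over the six labels so the fractions sum
    to 1 identically; callers wanting floats can map ``float`` over the
    values.
    """
    if len(windows) == 0:
        raise ValueError("element_fractions needs at least one window")
    labels = assign_regions(windows, models)
    total = len(labels)
    return {
        lab: Fraction(sum(1 for x in labels if x == lab), total)
        for lab in ELEMENT_LABELS
    }


def _window_trees(
    windows: Sequence[BindingWindow],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for w in windows:
        iv = w.interval
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
            iv.start, iv.end
        )
    return trees


def window_overlap_sets(
    windows_a: Sequence[BindingWindow],
    windows_b: Sequence[BindingWindow],
    min_overlap_frac: float = 0.5,
) -> dict[str, int]:
    """Shared/unique window counts between two conditions.

    A window is *shared* when some same-strand window on the other side
    overlaps it by at least ``min_overlap_frac`` of the shorter of the
    two windows' lengths.
    """
    if not (0.0 < min_overlap_frac <= 1.0):
        raise ValueError("min_overlap_frac must be in (0, 1]")

    def count_shared(
        src: Sequence[BindingWindow], trees: dict[tuple[str, str], IntervalTree]
    ) -> int:
        shared = 0
        for w in src:
            iv = w.interval
            tree = trees.get((iv.chrom, iv.strand))
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                bp = min(hit.end, iv.end) - max(hit.begin, iv.start)
                shorter = min(len(iv), hit.end - hit.begin)
                if bp >= min_overlap_frac * shorter:
                    shared += 1
                    break
        return shared

    trees_a = _window_trees(windows_a)
    trees_b = _window_trees(windows_b)
    shared_a = count_shared(windows_a, trees_b)
    shared_b = count_shared(windows_b, trees_a)
    return {
        "shared_A": shared_a,
        "unique_A": len(windows_a) - shared_a,
        "shared_B": shared_b,
        "unique_B": len(windows_b) - shared_b,
    }
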