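"""Readers and writers for the pipeline's on-disk formats.

Formats handled here: BED6 (binding windows), minimal GTF (exon and CDS
features with gene_id/transcript_id attributes), TSV tables (pandas),
multi-page 16-bit TIFF (tifffile) and YAML parameter manifests.  GTF is
1-based inclusive on disk and converted to the internal 0-based
half-open convention on ingestion; BED is already 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

from .intervals import BindingWindow, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed6",
    "write_bed6",
    "read_gtf_minimal",
    "write_gtf_minimal",
    "read_image",
    "write_image",
    "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed6(path: str | Path, condition: str = "") -> list[BindingWindow]:
    """Read binding windows from a BED6 file.

    Column 5 is kept as an enrichment score when numeric; strand is
    required.  Raises :class:`ParseError` naming the offending line.
    """
    windows: list[BindingWindow] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                score = float(score_s)
            except ValueError:
                score = None
            windows.append(
                BindingWindow(
                    interval=GenomicInterval(chrom, start, end, strand),
                    window_id=name,
                    condition=condition,
                    score=score,
                )
            )
    if not windows:
        logger.warning("no windows parsed from %s", path)
    return windows


def write_bed6(windows: Iterable[BindingWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            iv = w.interval
            score = 0 if w.score is None else w.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{w.window_id}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Minimal GTF (exon + CDS)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_minimal(path: str | Path) -> list[TranscriptModel]:
    """Assemble transcript models from a minimal GTF.

    Only ``exon`` and ``CDS`` features are consumed; each must carry
    ``gene_id`` and ``transcript_id`` attributes.  Coordinates are
    converted from GTF's 1-based inclusive to 0-based half-open.
    Model-level invariant violations (e.g. CDS outside the exon union)
    raise ``ValueError`` naming the transcript.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ParseError(
                    f"{path}:{lineno}: missing gene_id/transcript_id attribute"
                )
            tid = attr["transcript_id"]
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end after conversion")
            meta.setdefault(tid, (attr["gene_id"], chrom, strand))
            if feature == "exon":
                exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
            else:
                cds.setdefault(tid, []).append((start, end))

    models = []
    for tid, (gene_id, chrom, strand) in meta.items():
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons.get(tid, []),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def write_gtf_minimal(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Serialize models as minimal GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id)):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\tneuraging\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            if m.is_coding:
                # CDS emitted per exon segment inside the CDS span
                for e in m.exons:
                    s = max(e.start, m.cds_start)
                    t = min(e.end, m.cds_end)
                    if t > s:
                        fh.write(
                            f"{m.chrom}\tneuraging\tCDS\t{s + 1}\t{t}\t.\t"
                            f"{m.strand}\t0\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# Images and manifests
# ---------------------------------------------------------------------------

def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a (channels, H, W) stack as multi-page 16-bit grayscale TIFF."""
    arr = np.asarray(image)
    if arr.ndim != 3:
        raise ValueError("expected a (channels, height, width) array")
    tifffile.imwrite(path, arr.astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (channels, H, W) array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return arr


def write_manifest(params: dict, path: str | Path) -> None:
    """Write a YAML manifest of generator/analysis parameters."""
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
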