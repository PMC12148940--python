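"""Synthetic gene models and element-targeted binding windows."""

from __future__ import annotations

import numpy as np

from ..intervals import BindingWindow, GenomicInterval, TranscriptModel

__all__ = ["simulate_gene_models", "simulate_binding_windows"]

_GENE_GAP = 5_000  # bp between consecutive genes


def simulate_gene_models(
    n_genes: int,
    exons_per_gene: int = 5,
    seed: int = 0,
    chrom: str = "chrSim",
) -> list[TranscriptModel]:
    """Non-overlapping coding transcripts on one synthetic chromosome.

    Each transcript has a 5'UTR (inside the first exon), a CDS spanning
    every exon boundary, a 3'UTR (inside the last exon) and
    ``exons_per_gene - 1`` introns; strands alternate.  Exon and intron
    lengths are drawn per gene from its own substream, so adding genes
    never changes earlier ones.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if exons_per_gene < 3:
        raise ValueError(
            "exons_per_gene must be >= 3 to host a skipped internal exon"
        )
    streams = np.random.SeedSequence(seed).spawn(n_genes)
    models = []
    cursor = 1_000
    for g in range(n_genes):
        rng = np.random.default_rng(streams[g])
        strand = "+" if g % 2 == 0 else "-"
        exon_lens = rng.integers(150, 401, size=exons_per_gene)
        intron_lens = rng.integers(600, 2001, size=exons_per_gene - 1)
        exons = []
        pos = cursor
        for i in range(exons_per_gene):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
            pos += int(exon_lens[i])
            if i < exons_per_gene - 1:
                pos += int(intron_lens[i])
        # UTRs live inside the terminal exons; the CDS crosses every
        # exon-exon boundary.  Genomic left/right UTR lengths; labels
        # flip automatically with strand in TranscriptModel.elements().
        left_utr = int(rng.integers(40, min(120, exon_lens[0] - 20)))
        right_utr = int(rng.integers(40, min(120, exon_lens[-1] - 20)))
        models.append(
            TranscriptModel(
                transcript_id=f"tx{g}",
                gene_id=f"gene{g}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=exons[0].start + left_utr,
                cds_end=exons[-1].end - right_utr,
            )
        )
        cursor = pos + _GENE_GAP
    return models


def simulate_binding_windows(
    models: list[TranscriptModel],
    region_weights: dict[str, float],
    n_windows: int,
    window_len: int = 50,
    seed: int = 0,
) -> tuple[list[BindingWindow], list[str]]:
    """Windows placed entirely inside elements drawn by weight.

    Each window's element class is drawn with probability proportional to
    ``region_weights``; within the class, a host element interval long
    enough for the window is chosen uniformly and the window start is
    uniform inside it.  Returns the windows and their truth labels.
    """
    if n_windows < 0:
        raise ValueError("n_windows must be >= 0")
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    weights = {k: float(v) for k, v in region_weights.items() if v != 0}
    if any(v < 0 for v in weights.values()) or not weights:
        raise ValueError("region_weights must be non-negative and not all zero")

    by_label: dict[str, list[GenomicInterval]] = {}
    for m in models:
        for label, iv in m.elements():
            if len(iv) >= window_len:
                by_label.setdefault(label, []).append(iv)
    for label in weights:
        if label not in by_label:
            raise ValueError(
                f"element {label!r} absent from all models (or every instance "
                f"is shorter than window_len={window_len})"
            )

    labels = sorted(weights)
    probs = np.array([weights[l] for l in labels])
    probs = probs / probs.sum()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    windows: list[BindingWindow] = []
    truth: list[str] = []
    for i in range(n_windows):
        label = labels[int(rng.choice(len(labels), p=probs))]
        hosts = by_label[label]
        iv = hosts[int(rng.integers(len(hosts)))]
        start = int(rng.integers(iv.start, iv.end - window_len + 1))
        windows.append(
            BindingWindow(
                interval=GenomicInterval(iv.chrom, start, start + window_len, iv.strand),
                window_id=f"w{i}",
            )
        )
        truth.append(label)
    return windows, truth
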