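"""Ribosome footprints with length-dependent P-site structure.

Each footprint is emitted in transcript coordinates: a true P-site is
drawn uniformly inside the gene's CDS and the 5' end is placed at
P-site minus the length-appropriate offset (+12 nt for 28-29 nt reads,
+13 nt for 30-33 nt).  Lengths without a defined offset (34 nt appears
in real libraries but carries no offset rule) use the 30-33 convention
for placement only; the analysis side discards them, which is part of
what the generator lets tests exercise.

Per-gene footprint depth is proportional to abundance x translation
efficiency; matched RNA counts are proportional to abundance alone.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from ..intervals import TranscriptModel
from ..ribo import P_SITE_OFFSETS

logger = logging.getLogger(__name__)

__all__ = ["simulate_ribo_reads", "simulate_te_counts"]

_FALLBACK_OFFSET = 13  # placement-only offset for lengths without a rule


def simulate_ribo_reads(
    models: list[TranscriptModel],
    te_per_gene: Mapping[str, float],
    reads_per_gene: int = 2000,
    length_distribution: Mapping[int, float] | None = None,
    abundance_per_gene: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (footprint read table, RNA count table, truth).

    The read table has columns transcript_id / five_prime_pos / length_nt;
    the RNA table is a one-column gene x count frame.  Expected footprint
    depth for gene g is ``reads_per_gene * abundance[g] * te[g]`` and
    expected RNA count ``reads_per_gene * abundance[g]`` (both Poisson).
    Genes whose CDS cannot host any P-site are skipped with a warning.
    """
    if length_distribution is None:
        length_distribution = {28: 0.2, 29: 0.2, 30: 0.2, 31: 0.2, 32: 0.1, 33: 0.1}
    lengths = np.array(sorted(length_distribution))
    if not np.all((lengths >= 28) & (lengths <= 34)):
        raise ValueError("length_distribution support must lie in 28..34")
    probs = np.array([length_distribution[l] for l in lengths], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("length_distribution must sum to 1")
    if reads_per_gene < 0:
        raise ValueError("reads_per_gene must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tx_col: list[str] = []
    pos_col: list[np.ndarray] = []
    len_col: list[np.ndarray] = []
    rna_rows = {}
    true_te = {}

    offsets = np.array(
        [P_SITE_OFFSETS.get(int(l), _FALLBACK_OFFSET) for l in lengths]
    )
    max_offset = int(offsets.max())

    for m in models:
        span = m.cds_in_transcript_coords()
        if span is None:
            continue
        gene = m.gene_id
        te = float(te_per_gene.get(gene, 1.0))
        abundance = float(
            abundance_per_gene.get(gene, 1.0) if abundance_per_gene else 1.0
        )
        lo, hi = span
        if hi - lo < 1 or lo < max_offset:
            logger.warning(
                "gene %s skipped: CDS cannot host a P-site for all read lengths",
                gene,
            )
            continue
        n_rpf = int(rng.poisson(reads_per_gene * abundance * te))
        if n_rpf > 0:
            li = rng.choice(len(lengths), size=n_rpf, p=probs)
            p_sites = rng.integers(lo, hi, size=n_rpf)
            tx_col.extend([m.transcript_id] * n_rpf)
            pos_col.append(p_sites - offsets[li])
            len_col.append(lengths[li])
        rna_rows[gene] = int(rng.poisson(reads_per_gene * abundance))
        true_te[gene] = te

    reads = pd.DataFrame(
        {
            "transcript_id": tx_col,
            "five_prime_pos": (
                np.concatenate(pos_col) if pos_col else np.array([], dtype=int)
            ),
            "length_nt": (
                np.concatenate(len_col) if len_col else np.array([], dtype=int)
            ),
        }
    )
    rna = pd.DataFrame(
        {"count": pd.Series(rna_rows, name="count")}
    ).rename_axis("gene_id")
    truth = {"te_per_gene": true_te, "reads_per_gene": reads_per_gene}
    return reads, rna, truth


def simulate_te_counts(
    n_genes: int,
    te_b_over_a: Mapping[str, float] | float = 1.0,
    n_replicates: int = 3,
    mean_rpf: float = 500.0,
    mean_rna: float = 500.0,
    seed: int = 0,
) -> dict:
    """Poisson count tables for TE calibration/power studies.

    A lighter companion to :func:`simulate_ribo_reads`: per-gene counts
    are drawn directly at the count level (no read placement), which is
    what the differential-TE statistic consumes.  ``te_b_over_a`` is the
    true per-gene TE ratio between conditions (scalar or per-gene map).
    Returns dict of gene x replicate DataFrames rpf_a/rna_a/rpf_b/rna_b
    and the true log2 TE ratio per gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    if isinstance(te_b_over_a, Mapping):
        ratio = np.array([float(te_b_over_a.get(g, 1.0)) for g in genes])
    else:
        ratio = np.full(n_genes, float(te_b_over_a))

    def table(mean: np.ndarray, tag: str) -> pd.DataFrame:
        lam = np.broadcast_to(mean[:, None], (n_genes, n_replicates))
        return pd.DataFrame(
            rng.poisson(lam), index=genes,
            columns=[f"{tag}{r + 1}" for r in range(n_replicates)],
        )

    out = {
        "rpf_a": table(np.full(n_genes, mean_rpf), "A"),
        "rna_a": table(np.full(n_genes, mean_rna), "A"),
        "rpf_b": table(mean_rpf * ratio, "B"),
        "rna_b": table(np.full(n_genes, mean_rna), "B"),
        "true_log2_te_ratio": pd.Series(np.log2(ratio), index=genes),
    }
    return out
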