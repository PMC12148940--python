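"""Ribosome-profiling P-site assignment and translation efficiency.

Footprint reads carry a 5' position and a length; the ribosome P-site is
the 5' end plus a length-dependent offset (+12 nt for 28-29 nt reads,
+13 nt for 30-33 nt reads; other lengths carry no defined offset and are
discarded).  P-sites falling inside a gene's CDS are counted, and
translation efficiency is the library-normalized footprint density over
the library-normalized mRNA abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import TranscriptModel
from .stats import bh_fdr, welch_t_test_rows

logger = logging.getLogger(__name__)

__all__ = [
    "P_SITE_OFFSETS",
    "FootprintRead",
    "assign_p_sites",
    "cds_counts",
    "translation_efficiency",
    "differential_te",
]

# 5'-end offset to the ribosome P-site, by footprint length (nt).
P_SITE_OFFSETS: dict[int, int] = {28: 12, 29: 12, 30: 13, 31: 13, 32: 13, 33: 13}


@dataclass(frozen=True)
class FootprintRead:
    """One ribosome footprint in transcript coordinates.

    ``five_prime_pos`` is 0-based on the transcript's 5'->3' axis, so the
    P-site offset is always additive regardless of genomic strand.
    """

    transcript_id: str
    five_prime_pos: int
    length_nt: int

    def __post_init__(self) -> None:
        if not (20 <= self.length_nt <= 50):
            raise ValueError(
                f"footprint length {self.length_nt} outside plausible 20-50 nt"
            )
        if self.five_prime_pos < 0:
            raise ValueError("negative 5' position")


def assign_p_sites(
    reads: "Sequence[FootprintRead] | pd.DataFrame",
) -> tuple[pd.DataFrame, int]:
    """P-site per read with a defined offset.

    Accepts a sequence of :class:`FootprintRead` or a DataFrame with
    columns transcript_id / five_prime_pos / length_nt.  Reads whose
    length has no offset rule (anything outside 28-33 nt) are discarded;
    the discard count is returned alongside a transcript_id / p_site
    frame.  Pure per-read mapping: order-independent.
    """
    if not isinstance(reads, pd.DataFrame):
        reads = reads_to_frame(list(reads))
    lengths = reads["length_nt"].to_numpy()
    offsets = np.full(len(reads), -1)
    for length, off in P_SITE_OFFSETS.items():
        offsets[lengths == length] = off
    keep = offsets >= 0
    n_discarded = int((~keep).sum())
    sites = pd.DataFrame(
        {
            "transcript_id": reads["transcript_id"].to_numpy()[keep],
            "p_site": reads["five_prime_pos"].to_numpy()[keep] + offsets[keep],
        }
    )
    return sites, n_discarded


def cds_counts(
    p_sites: "pd.DataFrame | Sequence[tuple[str, int]]",
    models: Iterable[TranscriptModel],
) -> tuple[dict[str, int], int]:
    """Per-gene count of P-sites landing inside the CDS.

    ``p_sites`` is the frame from :func:`assign_p_sites` (or (transcript,
    position) pairs).  P-sites in noncoding transcripts, outside every
    CDS, or on unknown transcripts are tallied as ``n_outside``.  Genes
    of coding models are reported even at zero counts.
    """
    cds_by_tx: dict[str, tuple[str, tuple[int, int]]] = {}
    counts: dict[str, int] = {}
    n_models = 0
    for m in models:
        n_models += 1
        span = m.cds_in_transcript_coords()
        if span is not None:
            cds_by_tx[m.transcript_id] = (m.gene_id, span)
            counts.setdefault(m.gene_id, 0)
    if n_models == 0:
        raise ValueError("empty transcript model set")
    if isinstance(p_sites, pd.DataFrame):
        pairs = zip(p_sites["transcript_id"].to_numpy(), p_sites["p_site"].to_numpy())
    else:
        pairs = iter(p_sites)
    n_outside = 0
    for tx, pos in pairs:
        entry = cds_by_tx.get(tx)
        if entry is None:
            n_outside += 1
            continue
        gene, (lo, hi) = entry
        if lo <= pos < hi:
            counts[gene] += 1
        else:
            n_outside += 1
    return counts, n_outside


def translation_efficiency(
    rpf_counts: pd.DataFrame,
    rna_counts: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene, per-replicate TE.

    te = ((rpf + pc) / rpf_library_size) / ((rna + pc) / rna_library_size)
    with library size the column sum of raw counts.  Inputs are gene x
    replicate count tables indexed by gene id; genes absent from either
    assay are dropped (count logged).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    common = rpf_counts.index.intersection(rna_counts.index)
    n_dropped = (len(rpf_counts) - len(common)) + (len(rna_counts) - len(common))
    if n_dropped:
        logger.warning("dropped %d gene rows absent from one assay", n_dropped)
    if len(common) == 0:
        raise ValueError("no genes shared between RPF and RNA tables")
    rpf = rpf_counts.loc[common].astype(float)
    rna = rna_counts.loc[common].astype(float)
    rpf_lib = rpf.sum(axis=0)
    rna_lib = rna.sum(axis=0)
    if (rpf_lib <= 0).any() or (rna_lib <= 0).any():
        raise ValueError("library size must be positive in every replicate")
    if rpf.shape[1] != rna.shape[1]:
        raise ValueError("RPF and RNA tables must have matching replicates")
    rpf_rate = (rpf + pseudocount).div(rpf_lib, axis=1)
    rna_rate = (rna + pseudocount).div(rna_lib.to_numpy(), axis=1)
    te = rpf_rate.to_numpy() / rna_rate.to_numpy()
    return pd.DataFrame(te, index=common, columns=rpf.columns)


def differential_te(te_a: pd.DataFrame, te_b: pd.DataFrame) -> pd.DataFrame:
    """Welch test on log2 TE replicates per gene, BH across genes.

    log2_delta_te = mean(log2 te_B) - mean(log2 te_A).
    """
    if te_a.shape[1] < 2 or te_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    common = te_a.index.intersection(te_b.index)
    if len(common) == 0:
        raise ValueError("no genes shared between conditions")
    la = np.log2(te_a.loc[common].to_numpy())
    lb = np.log2(te_b.loc[common].to_numpy())
    _, _, pvals = welch_t_test_rows(lb, la)
    df = pd.DataFrame(
        {
            "gene_id": common,
            "log2_delta_te": lb.mean(axis=1) - la.mean(axis=1),
            "p_value": pvals,
        }
    )
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df


def reads_to_frame(reads: Sequence[FootprintRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in reads],
            "five_prime_pos": [r.five_prime_pos for r in reads],
            "length_nt": [r.length_nt for r in reads],
        }
    )


def reads_from_frame(df: pd.DataFrame) -> list[FootprintRead]:
    return [
        FootprintRead(str(t), int(p), int(n))
        for t, p, n in zip(df["transcript_id"], df["five_prime_pos"], df["length_nt"])
    ]
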