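"""Positional binding-splicing association map for skipped exons.

For each positional locus around a cassette exon (distal/proximal
upstream intron, exon body, proximal/distal downstream intron) this
module asks: are exons with a binding window at that locus more likely
to be differentially included (or excluded) between two conditions?
Association per locus is a 2x2 odds ratio tested with the
likelihood-ratio (G) test, FDR-corrected across loci.

Differential inclusion calls are made from per-replicate PSI (percent
spliced in) with a Welch test and BH correction, thresholded on |dPSI|
and q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import BindingWindow, GenomicInterval
from .stats import bh_fdr, g_test_2x2, welch_t_test, welch_t_test_rows

logger = logging.getLogger(__name__)

__all__ = [
    "BIN_ORDER",
    "SplicingEvent",
    "LocusBinModel",
    "call_differential_events",
    "bin_loci",
    "binding_matrix",
    "locus_odds_ratios",
    "events_to_frame",
    "events_from_frame",
]

# Transcription-ordered loci around a skipped exon.
BIN_ORDER = (
    "distal_upstream_intron",
    "proximal_upstream_intron_3ss",
    "exon_body",
    "proximal_downstream_intron_5ss",
    "distal_downstream_intron",
)

CALLS = ("included_up", "excluded_up", "unchanged")


@dataclass
class SplicingEvent:
    """One skipped-exon event with per-replicate PSI in two conditions.

    ``upstream_intron``/``downstream_intron`` are transcription-aware: the
    upstream intron is 5' of the exon in the direction of transcription
    (genomically right of the exon on the minus strand).
    """

    event_id: str
    gene_id: str
    exon: GenomicInterval
    upstream_intron: GenomicInterval
    downstream_intron: GenomicInterval
    psi_a: np.ndarray = field(default_factory=lambda: np.array([]))
    psi_b: np.ndarray = field(default_factory=lambda: np.array([]))
    call: str = "unchanged"
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        self.psi_a = np.asarray(self.psi_a, dtype=float)
        self.psi_b = np.asarray(self.psi_b, dtype=float)
        for name, arr in (("psi_a", self.psi_a), ("psi_b", self.psi_b)):
            if arr.size and (np.any(arr < 0) or np.any(arr > 1)):
                raise ValueError(f"{self.event_id}: {name} outside [0,1]")
        ex, up, dn = self.exon, self.upstream_intron, self.downstream_intron
        if ex.strand == "+":
            ok = up.end == ex.start and dn.start == ex.end
        else:
            ok = up.start == ex.end and dn.end == ex.start
        if not ok:
            raise ValueError(
                f"{self.event_id}: flanking introns not adjacent to exon "
                "on the strand-appropriate sides"
            )

    @property
    def delta_psi(self) -> float:
        return float(self.psi_b.mean() - self.psi_a.mean())


@dataclass(frozen=True)
class LocusBinModel:
    """Width of the splice-site-proximal intron bins, in nt."""

    proximal_width_nt: int = 250

    def __post_init__(self) -> None:
        if self.proximal_width_nt < 1:
            raise ValueError("proximal_width_nt must be >= 1")


def call_differential_events(
    events: Sequence[SplicingEvent],
    dpsi_min: float = 0.1,
    fdr_max: float = 0.05,
) -> list[SplicingEvent]:
    """Welch test on PSI replicates per event, BH across events, call by
    q <= ``fdr_max`` and |dPSI| >= ``dpsi_min`` with the dPSI sign giving
    the direction.  Events with < 2 replicates in either condition are
    dropped (count logged)."""
    usable = [e for e in events if e.psi_a.size >= 2 and e.psi_b.size >= 2]
    dropped = len(events) - len(usable)
    if dropped:
        logger.warning("dropped %d events with missing replicates", dropped)
    if not usable:
        raise ValueError("no events with enough replicates")
    na = min(e.psi_a.size for e in usable)
    nb = min(e.psi_b.size for e in usable)
    if all(e.psi_a.size == na and e.psi_b.size == nb for e in usable):
        # uniform replicate counts: test all events in one vectorized pass
        _, _, pvals = welch_t_test_rows(
            np.stack([e.psi_b for e in usable]),
            np.stack([e.psi_a for e in usable]),
        )
    else:
        pvals = np.empty(len(usable))
        for i, e in enumerate(usable):
            try:
                pvals[i] = welch_t_test(e.psi_b, e.psi_a).p_value
            except ValueError:
                # both samples constant and equal: identical PSI, no evidence
                pvals[i] = 1.0
    qvals = bh_fdr(pvals)
    out = []
    for e, q in zip(usable, qvals):
        d = e.delta_psi
        # an exact-zero dPSI is "unchanged" at any threshold; the 1e-9
        # floor keeps float round-off in the replicate means from
        # manufacturing a direction when dpsi_min is 0
        floor = max(dpsi_min, 1e-9)
        if q <= fdr_max and d >= floor:
            call = "included_up"
        elif q <= fdr_max and d <= -floor:
            call = "excluded_up"
        else:
            call = "unchanged"
        out.append(replace(e, call=call, q_value=float(q)))
    return out


def bin_loci(
    event: SplicingEvent, model: LocusBinModel = LocusBinModel()
) -> dict[str, Optional[GenomicInterval]]:
    """Positional bins around the event's exon as genomic intervals.

    Proximal bins are the ``proximal_width_nt`` of each intron adjacent
    to the exon (truncated to the intron length); distal bins are the
    remainder and may be ``None`` when the intron is short.  On the minus
    strand the genomically left intron is the downstream one, so bins
    mirror exactly under coordinate reflection.
    """
    w = model.proximal_width_nt
    ex = event.exon
    up, dn = event.upstream_intron, event.downstream_intron

    def split(intron: GenomicInterval, exon_side: str):
        # exon_side: which genomic end of the intron touches the exon
        if exon_side == "right":  # intron | exon : proximal at intron end
            cut = max(intron.start, intron.end - w)
            prox = GenomicInterval(intron.chrom, cut, intron.end, intron.strand)
            dist = (
                GenomicInterval(intron.chrom, intron.start, cut, intron.strand)
                if cut > intron.start
                else None
            )
        else:  # exon | intron : proximal at intron start
            cut = min(intron.end, intron.start + w)
            prox = GenomicInterval(intron.chrom, intron.start, cut, intron.strand)
            dist = (
                GenomicInterval(intron.chrom, cut, intron.end, intron.strand)
                if cut < intron.end
                else None
            )
        return prox, dist

    if ex.strand == "+":
        up_prox, up_dist = split(up, "right")
        dn_prox, dn_dist = split(dn, "left")
    else:
        up_prox, up_dist = split(up, "left")
        dn_prox, dn_dist = split(dn, "right")

    return {
        "distal_upstream_intron": up_dist,
        "proximal_upstream_intron_3ss": up_prox,
        "exon_body": ex,
        "proximal_downstream_intron_5ss": dn_prox,
        "distal_downstream_intron": dn_dist,
    }


def binding_matrix(
    events: Sequence[SplicingEvent],
    windows: Iterable[BindingWindow],
    model: LocusBinModel = LocusBinModel(),
) -> np.ndarray:
    """Boolean events x bins matrix: True iff >= 1 nt of a same-strand
    window overlaps the bin interval."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for wdw in windows:
        iv = wdw.interval
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
            iv.start, iv.end
        )
    mat = np.zeros((len(events), len(BIN_ORDER)), dtype=bool)
    for i, e in enumerate(events):
        bins = bin_loci(e, model)
        for j, name in enumerate(BIN_ORDER):
            iv = bins[name]
            if iv is None:
                continue
            tree = trees.get((iv.chrom, iv.strand))
            if tree is not None and tree.overlaps(iv.start, iv.end):
                mat[i, j] = True
    return mat


def locus_odds_ratios(
    events: Sequence[SplicingEvent],
    matrix: np.ndarray,
    direction: str = "inclusion",
) -> pd.DataFrame:
    """Per-locus odds ratio of a differential call given binding.

    For each bin the 2x2 table is {bound, unbound} x {called in
    ``direction``, not}; OR/G/p come from the likelihood-ratio test and q
    from BH across the bins.  ``direction='both'`` stacks both maps.
    """
    if direction == "both":
        return pd.concat(
            [
                locus_odds_ratios(events, matrix, "inclusion"),
                locus_odds_ratios(events, matrix, "exclusion"),
            ],
            ignore_index=True,
        )
    if direction not in ("inclusion", "exclusion"):
        raise ValueError(f"unknown direction {direction!r}")
    if len(events) == 0:
        raise ValueError("no events to test")
    if matrix.shape != (len(events), len(BIN_ORDER)):
        raise ValueError("matrix shape does not match events x bins")

    target = "included_up" if direction == "inclusion" else "excluded_up"
    called = np.array([e.call == target for e in events])
    rows = []
    for j, name in enumerate(BIN_ORDER):
        bound = matrix[:, j]
        a = int(np.sum(bound & called))
        b = int(np.sum(bound & ~called))
        c = int(np.sum(~bound & called))
        d = int(np.sum(~bound & ~called))
        res = g_test_2x2([[a, b], [c, d]])
        rows.append(
            {
                "locus_bin": name,
                "direction": direction,
                "n_bound_called": a,
                "n_bound_other": b,
                "n_unbound_called": c,
                "n_unbound_other": d,
                "odds_ratio": res.estimate,
                "g_statistic": res.statistic,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# TSV round-trip helpers
# ---------------------------------------------------------------------------

def events_to_frame(events: Sequence[SplicingEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "gene_id": e.gene_id,
                "chrom": e.exon.chrom,
                "strand": e.exon.strand,
                "exon_start": e.exon.start,
                "exon_end": e.exon.end,
                "upstream_intron_start": e.upstream_intron.start,
                "upstream_intron_end": e.upstream_intron.end,
                "downstream_intron_start": e.downstream_intron.start,
                "downstream_intron_end": e.downstream_intron.end,
                "psi_A": ",".join(f"{v:.6g}" for v in e.psi_a),
                "psi_B": ",".join(f"{v:.6g}" for v in e.psi_b),
                "call": e.call,
            }
        )
    return pd.DataFrame(rows)


def events_from_frame(df: pd.DataFrame) -> list[SplicingEvent]:
    events = []
    for row in df.itertuples(index=False):
        chrom, strand = row.chrom, row.strand
        events.append(
            SplicingEvent(
                event_id=row.event_id,
                gene_id=row.gene_id,
                exon=GenomicInterval(chrom, row.exon_start, row.exon_end, strand),
                upstream_intron=GenomicInterval(
                    chrom, row.upstream_intron_start, row.upstream_intron_end, strand
                ),
                downstream_intron=GenomicInterval(
                    chrom,
                    row.downstream_intron_start,
                    row.downstream_intron_end,
                    strand,
                ),
                psi_a=np.array(
                    [float(v) for v in str(row.psi_A).split(",") if v != ""]
                ),
                psi_b=np.array(
                    [float(v) for v in str(row.psi_B).split(",") if v != ""]
                ),
                call=getattr(row, "call", "unchanged"),
            )
        )
    return events
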