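"""Skipped-exon datasets with planted positional binding-inclusion odds.

The generative model: each event is anchored on its own internal exon
(events never share flanking introns).  Binding at each of the five
positional loci is an independent Bernoulli draw; the event's probability
of being differentially included is set on the odds scale,

    odds(diff | binding vector b) = odds_0 * prod_bins locus_odds[bin]^b,

so with a single non-null locus the marginal odds ratio at that locus
equals the planted value exactly.  Differential events get a fixed PSI
shift; replicate PSI values are condition means plus Gaussian noise
truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..intervals import BindingWindow, GenomicInterval, TranscriptModel
from ..splicemap import BIN_ORDER, LocusBinModel, SplicingEvent, bin_loci

__all__ = ["SpliceSimParams", "simulate_splicing_dataset"]


@dataclass(frozen=True)
class SpliceSimParams:
    """Generative parameters for one skipped-exon dataset.

    ``locus_odds`` maps locus-bin name (see
    :data:`neuraging.splicemap.BIN_ORDER`) to the true odds ratio of
    differential inclusion given binding there; unlisted bins are null
    (odds 1).  ``effect_dpsi`` is the PSI shift given to differential
    events (sign = inclusion up in condition B).
    """

    n_events: int = 1000
    locus_odds: dict[str, float] = field(default_factory=dict)
    baseline_diff_rate: float = 0.2
    binding_rate_per_locus: float = 0.3
    n_replicates_per_condition: int = 3
    psi_noise_sd: float = 0.05
    effect_dpsi: float = 0.4
    window_len: int = 50
    proximal_width_nt: int = 250
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        for k, v in self.locus_odds.items():
            if k not in BIN_ORDER:
                raise ValueError(f"unknown locus bin {k!r}")
            if not v > 0:
                raise ValueError(f"locus odds must be > 0 (bin {k})")
        if not (0.0 < self.baseline_diff_rate < 1.0):
            raise ValueError("baseline_diff_rate must be in (0,1)")
        if not (0.0 < self.binding_rate_per_locus < 1.0):
            raise ValueError("binding_rate_per_locus must be in (0,1)")
        if self.n_replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.psi_noise_sd < 0:
            raise ValueError("psi_noise_sd must be >= 0")
        if not (0.0 < self.effect_dpsi <= 0.5):
            raise ValueError("effect_dpsi must be in (0, 0.5]")
        # guard against a numerically degenerate implied probability
        odds0 = self.baseline_diff_rate / (1.0 - self.baseline_diff_rate)
        max_odds = odds0 * float(
            np.prod([max(v, 1.0) for v in self.locus_odds.values()] or [1.0])
        )
        p_max = max_odds / (1.0 + max_odds)
        if not (0.0 < p_max < 1.0):
            raise ValueError("implied differential probability outside (0,1)")


def _event_anchors(models: list[TranscriptModel], n_events: int):
    """Distinct internal exons, strided so no two events share an intron."""
    anchors = []
    for m in models:
        if len(m.exons) < 3:
            continue
        # internal exon indices 1..n-2, every other one
        for i in range(1, len(m.exons) - 1, 2):
            anchors.append((m, i))
    if len(anchors) < n_events:
        raise ValueError(
            f"models host only {len(anchors)} independent internal exons; "
            f"{n_events} events requested — supply more/longer gene models"
        )
    return anchors[:n_events]


def simulate_splicing_dataset(
    models: list[TranscriptModel],
    params: SpliceSimParams,
) -> tuple[list[SplicingEvent], list[BindingWindow], pd.DataFrame]:
    """Generate (events, binding windows, truth table).

    Truth columns: event_id, bound_<bin> per locus, is_differential.
    Windows are placed wholly inside the bound locus bins, so the
    analysis-side binding matrix recovers the truth vectors exactly.
    """
    params.validate()
    anchors = _event_anchors(models, params.n_events)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    bin_model = LocusBinModel(proximal_width_nt=params.proximal_width_nt)
    odds0 = params.baseline_diff_rate / (1.0 - params.baseline_diff_rate)
    odds_vec = np.array([params.locus_odds.get(b, 1.0) for b in BIN_ORDER])

    events: list[SplicingEvent] = []
    windows: list[BindingWindow] = []
    truth_rows = []
    nrep = params.n_replicates_per_condition

    for idx, (m, i) in enumerate(anchors):
        exon = m.exons[i]
        left = GenomicInterval(m.chrom, m.exons[i - 1].end, exon.start, m.strand)
        right = GenomicInterval(m.chrom, exon.end, m.exons[i + 1].start, m.strand)
        up, dn = (left, right) if m.strand == "+" else (right, left)
        event = SplicingEvent(
            event_id=f"ev{idx}",
            gene_id=m.gene_id,
            exon=exon,
            upstream_intron=up,
            downstream_intron=dn,
        )

        bins = bin_loci(event, bin_model)
        bound = rng.random(len(BIN_ORDER)) < params.binding_rate_per_locus
        for j, name in enumerate(BIN_ORDER):
            if bins[name] is None:  # zero-length distal bin cannot be bound
                bound[j] = False
        odds = odds0 * float(np.prod(odds_vec[bound]))
        p_diff = odds / (1.0 + odds)
        is_diff = bool(rng.random() < p_diff)

        base = float(rng.uniform(0.2, 0.5))
        mean_a = base
        mean_b = base + (params.effect_dpsi if is_diff else 0.0)
        psi_a = np.clip(rng.normal(mean_a, params.psi_noise_sd, nrep), 0.0, 1.0)
        psi_b = np.clip(rng.normal(mean_b, params.psi_noise_sd, nrep), 0.0, 1.0)
        event.psi_a, event.psi_b = psi_a, psi_b
        events.append(event)

        for j, name in enumerate(BIN_ORDER):
            if not bound[j]:
                continue
            iv = bins[name]
            wl = min(params.window_len, len(iv))
            start = int(rng.integers(iv.start, iv.end - wl + 1))
            windows.append(
                BindingWindow(
                    interval=GenomicInterval(iv.chrom, start, start + wl, iv.strand),
                    window_id=f"ev{idx}_{name}",
                )
            )
        truth_rows.append(
            {
                "event_id": event.event_id,
                **{f"bound_{name}": bool(bound[j]) for j, name in enumerate(BIN_ORDER)},
                "is_differential": is_diff,
            }
        )

    return events, windows, pd.DataFrame(truth_rows)
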