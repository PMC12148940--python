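import numpy as np
import pytest
from dataclasses import replace

from neuraging.intervals import BindingWindow, GenomicInterval
from neuraging.simulate import (
    SpliceSimParams,
    simulate_gene_models,
    simulate_splicing_dataset,
)
from neuraging.splicemap import (
    BIN_ORDER,
    LocusBinModel,
    SplicingEvent,
    bin_loci,
    binding_matrix,
    call_differential_events,
    events_from_frame,
    events_to_frame,
    locus_odds_ratios,
)


def _event(strand="+", psi_a=(0.3, 0.3, 0.3), psi_b=(0.3, 0.3, 0.3), eid="e"):
    if strand == "+":
        up = GenomicInterval("c", 500, 1000, "+")
        exon = GenomicInterval("c", 1000, 1100, "+")
        down = GenomicInterval("c", 1100, 1600, "+")
    else:
        exon = GenomicInterval("c", 1000, 1100, "-")
        up = GenomicInterval("c", 1100, 1600, "-")
        down = GenomicInterval("c", 500, 1000, "-")
    return SplicingEvent(eid, "g", exon, up, down,
                         psi_a=np.array(psi_a), psi_b=np.array(psi_b))


class TestBinLoci:
    def test_plus_strand_arithmetic(self):
        bins = bin_loci(_event("+"), LocusBinModel(proximal_width_nt=250))
        assert (bins["proximal_upstream_intron_3ss"].start,
                bins["proximal_upstream_intron_3ss"].end) == (750, 1000)
        assert (bins["distal_upstream_intron"].start,
                bins["distal_upstream_intron"].end) == (500, 750)
        assert (bins["exon_body"].start, bins["exon_body"].end) == (1000, 1100)
        assert (bins["proximal_downstream_intron_5ss"].start,
                bins["proximal_downstream_intron_5ss"].end) == (1100, 1350)
        assert (bins["distal_downstream_intron"].start,
                bins["distal_downstream_intron"].end) == (1350, 1600)

    def test_short_intron_truncates_proximal_and_empties_distal(self):
        ev = SplicingEvent(
            "e", "g",
            exon=GenomicInterval("c", 1000, 1100, "+"),
            upstream_intron=GenomicInterval("c", 900, 1000, "+"),
            downstream_intron=GenomicInterval("c", 1100, 1600, "+"),
            psi_a=np.array([0.5, 0.5]), psi_b=np.array([0.5, 0.5]),
        )
        bins = bin_loci(ev, LocusBinModel(250))
        prox = bins["proximal_upstream_intron_3ss"]
        assert (prox.start, prox.end) == (900, 1000)
        assert bins["distal_upstream_intron"] is None

    def test_minus_strand_mirrors_reflected_plus_strand(self):
        # reflection oracle: reflect every coordinate around L and flip
        # strand; bins must map onto each other exactly
        L = 2100
        plus_bins = bin_loci(_event("+"), LocusBinModel(250))
        minus_bins = bin_loci(_event("-"), LocusBinModel(250))
        for name in BIN_ORDER:
            p, m = plus_bins[name], minus_bins[name]
            assert (p is None) == (m is None)
            if p is not None:
                assert (L - p.end, L - p.start) == (m.start, m.end)

    def test_flank_adjacency_is_validated(self):
        with pytest.raises(ValueError, match="adjacent"):
            SplicingEvent(
                "bad", "g",
                exon=GenomicInterval("c", 1000, 1100, "+"),
                upstream_intron=GenomicInterval("c", 500, 990, "+"),
                downstream_intron=GenomicInterval("c", 1100, 1600, "+"),
            )


class TestCalls:
    def test_clean_shift_called_included_up(self):
        events = [
            _event(psi_a=(0.3, 0.3, 0.3), psi_b=(0.7, 0.7, 0.7), eid="shift"),
            _event(psi_a=(0.5, 0.5, 0.5), psi_b=(0.5, 0.5, 0.5), eid="flat"),
        ]
        called = {e.event_id: e.call for e in call_differential_events(events)}
        assert called["shift"] == "included_up"
        assert called["flat"] == "unchanged"

    def test_zero_delta_is_unchanged_at_any_threshold(self):
        events = [_event(psi_a=(0.2, 0.4, 0.3), psi_b=(0.3, 0.2, 0.4))]
        (out,) = call_differential_events(events, dpsi_min=0.0, fdr_max=1.0)
        assert out.delta_psi == pytest.approx(0.0)
        assert out.call == "unchanged"

    def test_sensitivity_and_fdr_on_generated_truth(self):
        models = simulate_gene_models(270, exons_per_gene=7, seed=50)
        sens, fdr = [], []
        for seed in range(10):
            params = SpliceSimParams(n_events=800, seed=seed)
            events, _, truth = simulate_splicing_dataset(models, params)
            called = call_differential_events(events)
            is_diff = dict(zip(truth.event_id, truth.is_differential))
            pred = np.array([e.call == "included_up" for e in called])
            true = np.array([is_diff[e.event_id] for e in called])
            sens.append((pred & true).sum() / max(true.sum(), 1))
            fdr.append((pred & ~true).sum() / max(pred.sum(), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.1


class TestBindingMatrix:
    def test_window_on_exon_sets_only_exon_bin(self):
        ev = _event()
        window = BindingWindow(GenomicInterval("c", 1000, 1100, "+"), "w")
        mat = binding_matrix([ev], [window])
        row = dict(zip(BIN_ORDER, mat[0]))
        assert row["exon_body"] and sum(mat[0]) == 1

    def test_no_windows_gives_all_false(self):
        assert not binding_matrix([_event()], []).any()

    def test_recovers_generated_truth_vectors(self, ):
        models = simulate_gene_models(100, exons_per_gene=7, seed=51)
        params = SpliceSimParams(n_events=300, seed=3)
        events, windows, truth = simulate_splicing_dataset(models, params)
        mat = binding_matrix(events, windows)
        want = truth[[f"bound_{b}" for b in BIN_ORDER]].to_numpy()
        assert np.array_equal(mat, want)


class TestLocusOddsRatios:
    @staticmethod
    def _toy(n_bound_called=30, n_bound_other=10, n_unbound_called=10,
             n_unbound_other=30):
        events, flags = [], []
        spec = [
            (n_bound_called, True, "included_up"),
            (n_bound_other, True, "unchanged"),
            (n_unbound_called, False, "included_up"),
            (n_unbound_other, False, "unchanged"),
        ]
        i = 0
        for count, bound, call in spec:
            for _ in range(count):
                e = _event(eid=f"t{i}")
                e.call = call
                events.append(e)
                flags.append(bound)
                i += 1
        matrix = np.zeros((len(events), len(BIN_ORDER)), dtype=bool)
        matrix[:, BIN_ORDER.index("exon_body")] = flags
        return events, matrix

    def test_hand_computed_table(self):
        events, matrix = self._toy()
        out = locus_odds_ratios(events, matrix, "inclusion").set_index("locus_bin")
        row = out.loc["exon_body"]
        assert row["odds_ratio"] == pytest.approx(9.0)
        assert row["g_statistic"] == pytest.approx(20.93, abs=0.01)

    def test_contingency_cells_conserve_event_count(self):
        events, matrix = self._toy(17, 23, 31, 29)
        out = locus_odds_ratios(events, matrix, "inclusion")
        cells = out[["n_bound_called", "n_bound_other",
                     "n_unbound_called", "n_unbound_other"]].sum(axis=1)
        assert (cells == len(events)).all()

    def test_condition_swap_maps_inclusion_onto_exclusion(self):
        models = simulate_gene_models(80, exons_per_gene=7, seed=52)
        params = SpliceSimParams(n_events=200, seed=5)
        events, windows, _ = simulate_splicing_dataset(models, params)
        called = call_differential_events(events)
        swapped = call_differential_events(
            [replace(e, psi_a=e.psi_b, psi_b=e.psi_a) for e in events]
        )
        mat = binding_matrix(called, windows)
        inc = locus_odds_ratios(called, mat, "inclusion")
        exc = locus_odds_ratios(swapped, mat, "exclusion")
        assert np.allclose(inc["odds_ratio"], exc["odds_ratio"])
        assert np.allclose(inc["p_value"], exc["p_value"])

    def test_strand_reflection_leaves_map_unchanged(self):
        models = simulate_gene_models(80, exons_per_gene=7, seed=53)
        params = SpliceSimParams(n_events=200, seed=6)
        events, windows, _ = simulate_splicing_dataset(models, params)
        L = max(w.interval.end for w in windows) + max(e.exon.end for e in events)

        def refl_iv(iv):
            return GenomicInterval(
                iv.chrom, L - iv.end, L - iv.start, "-" if iv.strand == "+" else "+"
            )

        r_events = [
            SplicingEvent(e.event_id, e.gene_id, refl_iv(e.exon),
                          refl_iv(e.upstream_intron), refl_iv(e.downstream_intron),
                          psi_a=e.psi_a, psi_b=e.psi_b)
            for e in events
        ]
        r_windows = [BindingWindow(refl_iv(w.interval), w.window_id) for w in windows]
        a = locus_odds_ratios(
            call_differential_events(events), binding_matrix(events, windows),
            "inclusion",
        )
        b = locus_odds_ratios(
            call_differential_events(r_events),
            binding_matrix(r_events, r_windows),
            "inclusion",
        )
        assert np.allclose(a["odds_ratio"], b["odds_ratio"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_direction_both_stacks_maps(self):
        events, matrix = self._toy()
        out = locus_odds_ratios(events, matrix, "both")
        assert set(out["direction"]) == {"inclusion", "exclusion"}
        assert len(out) == 2 * len(BIN_ORDER)


def test_events_roundtrip_through_frame():
    events = [
        _event(psi_a=(0.2, 0.25, 0.3), psi_b=(0.6, 0.62, 0.64), eid="rt1"),
        _event(strand="-", eid="rt2"),
    ]
    back = events_from_frame(events_to_frame(events))
    for a, b in zip(events, back):
        assert a.event_id == b.event_id
        assert a.exon == b.exon
        assert a.upstream_intron == b.upstream_intron
        assert np.allclose(a.psi_a, b.psi_a) and np.allclose(a.psi_b, b.psi_b)
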