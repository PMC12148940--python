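import numpy as np
import pytest

from neuraging.imaging import segment_nuclei
from neuraging.io import write_gtf_minimal
from neuraging.ribo import P_SITE_OFFSETS
from neuraging.simulate import (
    ImageSimParams,
    SpliceSimParams,
    simulate_binding_windows,
    simulate_cell_image,
    simulate_expression_pairs,
    simulate_gene_models,
    simulate_ribo_reads,
    simulate_splicing_dataset,
)
from neuraging.splicemap import events_to_frame


class TestImageGenerator:
    def test_bit_identical_under_fixed_seed(self):
        params = ImageSimParams(n_cells=4, n_foci_per_cell=3, seed=7)
        img1, truth1 = simulate_cell_image(params)
        img2, truth2 = simulate_cell_image(params)
        assert np.array_equal(img1, img2)
        assert truth1.foci == truth2.foci
        assert np.array_equal(truth1.nuclear_labels, truth2.nuclear_labels)

    def test_truth_records_every_planted_focus(self, default_image):
        _, truth = default_image
        params = ImageSimParams(seed=3)
        assert len(truth.foci) == params.n_cells * params.n_foci_per_cell
        h, w = params.height_px, params.width_px
        for f in truth.foci:
            assert 0 <= f.row < h and 0 <= f.col < w
            r, c = int(f.row), int(f.col)
            # foci live in the cytoplasm of their own cell
            assert truth.cell_labels[r, c] == f.cell
            assert truth.nuclear_labels[r, c] == 0

    def test_no_signal_outside_cells_without_noise(self):
        params = ImageSimParams(
            seed=1, n_foci_per_cell=0, background_level=0.0, read_noise_sd=0.0
        )
        image, truth = simulate_cell_image(params)
        outside = truth.cell_labels == 0
        assert image[1][outside].max() == 0

    def test_fully_nuclear_partition_without_noise(self):
        params = ImageSimParams(
            seed=2, nuclear_fraction_true=1.0, n_foci_per_cell=0,
            background_level=0.0, read_noise_sd=0.0,
        )
        image, truth = simulate_cell_image(params)
        assert image[1][truth.nuclear_labels == 0].max() == 0

    def test_foci_incompatible_with_full_nuclear_budget(self):
        params = ImageSimParams(seed=2, nuclear_fraction_true=1.0, n_foci_per_cell=2)
        with pytest.raises(ValueError, match="budget"):
            simulate_cell_image(params)

    def test_impossible_placement_names_the_cell(self):
        params = ImageSimParams(width_px=96, height_px=96, n_cells=6, seed=0)
        with pytest.raises(RuntimeError, match="cell"):
            simulate_cell_image(params)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ImageSimParams(nuclear_fraction_true=1.2).validate()
        with pytest.raises(ValueError):
            ImageSimParams(focus_elongation=0.5).validate()


class TestGeneModels:
    def test_minimal_gene_has_two_introns(self):
        (model,) = simulate_gene_models(1, exons_per_gene=3, seed=0)
        assert len(model.introns()) == 2
        labels = {lab for lab, _ in model.elements()}
        assert {"5'UTR", "CDS", "3'UTR", "intron"} <= labels

    def test_exon_minimum_enforced(self):
        with pytest.raises(ValueError):
            simulate_gene_models(1, exons_per_gene=2, seed=0)

    def test_both_strands_and_no_gene_overlap(self, gene_models):
        assert {m.strand for m in gene_models} == {"+", "-"}
        spans = sorted((m.start, m.end) for m in gene_models)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 > e1

    def test_gtf_serialization_deterministic(self, tmp_path):
        buf = []
        for _ in range(2):
            models = simulate_gene_models(5, exons_per_gene=4, seed=9)
            path = tmp_path / "m.gtf"
            write_gtf_minimal(models, path)
            buf.append(path.read_text())
        assert buf[0] == buf[1]


class TestBindingWindows:
    def test_degenerate_weights(self, gene_models):
        windows, truth = simulate_binding_windows(gene_models, {"intron": 1}, 100, seed=0)
        assert set(truth) == {"intron"}

    def test_empty_request(self, gene_models):
        windows, truth = simulate_binding_windows(gene_models, {"CDS": 1}, 0, seed=0)
        assert windows == [] and truth == []

    def test_absent_element_is_configuration_error(self, gene_models):
        with pytest.raises(ValueError, match="noncoding_exon"):
            simulate_binding_windows(gene_models, {"noncoding_exon": 1}, 10, seed=0)

    def test_balanced_weights_converge(self, gene_models):
        _, truth = simulate_binding_windows(
            gene_models, {"CDS": 1, "3'UTR": 1}, 10_000, window_len=20, seed=3
        )
        frac_cds = truth.count("CDS") / len(truth)
        assert frac_cds == pytest.approx(0.5, abs=0.03)  # binomial 3 SE ~ 0.015

    def test_windows_fully_inside_declared_element(self, gene_models):
        windows, truth = simulate_binding_windows(
            gene_models, {"intron": 1, "CDS": 1}, 200, seed=4
        )
        by_tx = {m.transcript_id: m for m in gene_models}
        for w, label in zip(windows, truth):
            hosts = [
                iv
                for m in gene_models
                for lab, iv in m.elements()
                if lab == label and iv.contains(w.interval)
            ]
            assert hosts, f"window {w.window_id} not inside any {label}"


class TestSplicingGenerator:
    def test_zero_noise_gives_identical_replicates(self):
        models = simulate_gene_models(30, exons_per_gene=5, seed=1)
        params = SpliceSimParams(n_events=30, psi_noise_sd=0.0, seed=2)
        events, _, _ = simulate_splicing_dataset(models, params)
        for e in events:
            assert np.ptp(e.psi_a) == 0.0 and np.ptp(e.psi_b) == 0.0

    def test_deterministic(self):
        models = simulate_gene_models(30, exons_per_gene=5, seed=1)
        params = SpliceSimParams(n_events=30, seed=5)
        a = simulate_splicing_dataset(models, params)
        b = simulate_splicing_dataset(models, params)
        assert events_to_frame(a[0]).equals(events_to_frame(b[0]))
        assert a[2].equals(b[2])

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="locus"):
            SpliceSimParams(locus_odds={"nowhere": 2.0}).validate()
        with pytest.raises(ValueError):
            SpliceSimParams(baseline_diff_rate=1.5).validate()
        with pytest.raises(ValueError):
            SpliceSimParams(locus_odds={"exon_body": -1.0}).validate()

    def test_capacity_error_mentions_models(self):
        models = simulate_gene_models(2, exons_per_gene=5, seed=1)
        with pytest.raises(ValueError, match="internal exons"):
            simulate_splicing_dataset(models, SpliceSimParams(n_events=100))


class TestExpressionGenerator:
    def test_designed_subsets_disjoint_and_sized(self):
        sim = simulate_expression_pairs(
            n_genes=1000, frac_high_protein_normal_rna=0.1, rbp_fraction=0.2, seed=0
        )
        truth = sim["truth"]
        assert truth["is_high_protein"].sum() == 100
        assert truth["is_rbp"].sum() == 200
        assert not (truth["is_high_protein"] & truth["is_rbp"]).any()

    def test_deterministic(self):
        a = simulate_expression_pairs(n_genes=50, seed=3)
        b = simulate_expression_pairs(n_genes=50, seed=3)
        assert a["protein_a"].equals(b["protein_a"])
        assert a["truth"].equals(b["truth"])

    def test_subset_budget_validated(self):
        with pytest.raises(ValueError):
            simulate_expression_pairs(
                n_genes=100, frac_high_protein_normal_rna=0.6, rbp_fraction=0.6
            )


class TestRiboGenerator:
    def test_true_p_sites_inside_cds(self):
        models = simulate_gene_models(5, exons_per_gene=4, seed=4)
        cds = {m.transcript_id: m.cds_in_transcript_coords() for m in models}
        reads, _, _ = simulate_ribo_reads(models, {}, reads_per_gene=200, seed=5)
        ruled = reads[reads["length_nt"] <= 33]
        for tx, pos, ln in ruled.itertuples(index=False):
            lo, hi = cds[tx]
            assert lo <= pos + P_SITE_OFFSETS[ln] < hi

    def test_length_distribution_must_normalize(self):
        models = simulate_gene_models(2, exons_per_gene=3, seed=0)
        with pytest.raises(ValueError):
            simulate_ribo_reads(models, {}, length_distribution={28: 0.4}, seed=0)

    def test_deterministic(self):
        models = simulate_gene_models(5, exons_per_gene=4, seed=4)
        a = simulate_ribo_reads(models, {}, reads_per_gene=100, seed=9)
        b = simulate_ribo_reads(models, {}, reads_per_gene=100, seed=9)
        assert a[0].equals(b[0]) and a[1].equals(b[1])


def test_generated_nuclei_segmentable(default_image):
    # the generator's default contrast supports the analysis defaults
    image, truth = default_image
    assert segment_nuclei(image[0]).n_nuclei == truth.nuclear_labels.max()
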