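import math

import numpy as np
import pandas as pd
import pytest

from neuraging.imaging import (
    NuclearMask,
    compare_conditions,
    detect_granules,
    granules_per_cell,
    measure_mask,
    nuclear_fraction,
    quantify_image,
    segment_nuclei,
)
from neuraging.simulate import ImageSimParams, simulate_cell_image


def _match_labels(found: NuclearMask, truth_labels: np.ndarray) -> list[float]:
    """Best Jaccard of each truth nucleus against any found label."""
    scores = []
    for k in range(1, truth_labels.max() + 1):
        t = truth_labels == k
        best = 0.0
        for j in range(1, found.n_nuclei + 1):
            f = found.labels == j
            inter = (t & f).sum()
            union = (t | f).sum()
            best = max(best, inter / union)
        scores.append(best)
    return scores


class TestSegmentation:
    def test_recovers_planted_nuclei(self, default_image):
        image, truth = default_image
        found = segment_nuclei(image[0])
        assert found.n_nuclei == truth.nuclear_labels.max()
        assert min(_match_labels(found, truth.nuclear_labels)) >= 0.9

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment_nuclei(np.zeros((64, 64)))

    def test_additive_offset_leaves_mask_unchanged(self, default_image):
        image, _ = default_image
        a = segment_nuclei(image[0].astype(float))
        b = segment_nuclei(image[0].astype(float) + 500.0)
        assert np.array_equal(a.labels, b.labels)


class TestNuclearFraction:
    def test_fully_nuclear_signal_gives_one(self):
        params = ImageSimParams(
            seed=5, nuclear_fraction_true=1.0, n_foci_per_cell=0,
            background_level=0.0, read_noise_sd=0.0,
        )
        image, truth = simulate_cell_image(params)
        nuclei = segment_nuclei(image[0])
        frac, per_cell, flag = nuclear_fraction(image[1].astype(float), nuclei)
        assert not flag
        assert frac == pytest.approx(1.0, abs=1e-6)
        assert per_cell == pytest.approx(np.ones_like(per_cell), abs=1e-6)

    def test_zero_signal_convention(self, default_image):
        image, _ = default_image
        nuclei = segment_nuclei(image[0])
        frac, per_cell, flag = nuclear_fraction(
            np.zeros_like(image[1], dtype=float), nuclei
        )
        assert flag and frac == 0.0

    def test_invariant_under_intensity_scaling(self, default_image):
        image, _ = default_image
        nuclei = segment_nuclei(image[0])
        protein = image[1].astype(float)
        f1, _, _ = nuclear_fraction(protein, nuclei)
        f2, _, _ = nuclear_fraction(protein * 3.0, nuclei)
        assert f2 == pytest.approx(f1, rel=1e-9)
        assert 0.0 <= f1 <= 1.0

    def test_refuses_empty_mask(self, default_image):
        image, _ = default_image
        empty = NuclearMask(labels=np.zeros_like(image[0], dtype=np.int32), n_nuclei=0)
        with pytest.raises(ValueError):
            nuclear_fraction(image[1].astype(float), empty)


class TestGranuleDetection:
    def test_analytic_shape_scores(self):
        canvas = np.zeros((120, 120), dtype=bool)
        rr, cc = np.mgrid[0:120, 0:120]
        canvas[(rr - 30) ** 2 + (cc - 30) ** 2 <= 14**2] = True  # disk d=28
        canvas[70:94, 70:94] = True  # square side 24
        disk, square = sorted(measure_mask(canvas), key=lambda g: g.centroid)
        assert disk.circularity == pytest.approx(1.0, abs=0.05)
        assert disk.roundness == pytest.approx(1.0, abs=0.05)
        assert square.circularity == pytest.approx(math.pi / 4, abs=0.05)

    def test_translation_equivariance(self, default_image):
        image, _ = default_image
        protein = image[1].astype(float)
        base = detect_granules(protein)
        shifted = detect_granules(np.roll(protein, (7, 11), axis=(0, 1)))
        assert len(base) == len(shifted)
        got = sorted((g.centroid[0] + 7, g.centroid[1] + 11) for g in base)
        want = sorted(g.centroid for g in shifted)
        assert np.allclose(got, want, atol=0.5)

    def test_sigma_ordering_enforced(self, default_image):
        image, _ = default_image
        with pytest.raises(ValueError):
            detect_granules(image[1].astype(float), 5.0, 2.5)

    def test_elongated_foci_score_lower_circularity(self):
        scores = {}
        for elong in (1.0, 3.0):
            image, _ = simulate_cell_image(
                ImageSimParams(seed=9, focus_elongation=elong)
            )
            granules = detect_granules(image[1].astype(float))
            scores[elong] = np.mean([g.circularity for g in granules])
        assert scores[1.0] > scores[3.0]

    def test_more_planted_foci_never_fewer_detections(self):
        detections = []
        for n in (0, 2, 4):
            image, _ = simulate_cell_image(
                ImageSimParams(seed=13, n_foci_per_cell=n)
            )
            detections.append(len(detect_granules(image[1].astype(float))))
        assert detections == sorted(detections)


class TestPerCellSummaries:
    def test_granules_per_cell_arithmetic(self, default_image):
        image, _ = default_image
        nuclei = segment_nuclei(image[0])
        granules = detect_granules(image[1].astype(float))
        assert granules_per_cell(granules, nuclei) == len(granules) / nuclei.n_nuclei
        assert granules_per_cell([], nuclei) == 0.0
        with pytest.raises(ValueError):
            granules_per_cell(granules, NuclearMask(np.zeros((4, 4), int), 0))

    def test_quantify_image_assigns_foci_to_cells(self, default_image):
        image, truth = default_image
        cells, granules = quantify_image(image, image_id="f0")
        assert len(cells) == truth.nuclear_labels.max()
        assert cells["n_granules"].sum() == len(granules)
        assert cells["nuclear_fraction"].between(0, 1).all()


class TestCompareConditions:
    def test_identical_tables_are_null(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame({"nuclear_fraction": rng.uniform(0.4, 0.6, 12)})
        out = compare_conditions(rows, rows.copy(), metrics=("nuclear_fraction",))
        res = out["nuclear_fraction"]["result"]
        assert res.statistic == pytest.approx(0.0) and res.p_value == 1.0

    def test_planted_outlier_is_removed_before_testing(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame({"nuclear_fraction": np.r_[rng.normal(0.5, 0.01, 11), 5.0]})
        b = pd.DataFrame({"nuclear_fraction": rng.normal(0.5, 0.01, 12)})
        out = compare_conditions(a, b, metrics=("nuclear_fraction",))
        assert 11 in out["nuclear_fraction"]["removed_A"]
        assert out["nuclear_fraction"]["removed_B"] == []

    def test_null_calibration_of_pvalues(self):
        # same synthetic distribution on both sides: p should not be
        # systematically small
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(300):
            a = pd.DataFrame({"m": rng.normal(0, 1, 10)})
            b = pd.DataFrame({"m": rng.normal(0, 1, 10)})
            pvals.append(compare_conditions(a, b, metrics=("m",))["m"]["result"].p_value)
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01
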