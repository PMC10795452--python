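"""Evaluation metrics against brute-force oracles and worked examples."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from st4dseg.core import PhaseMaskSet, merge_igtv
from st4dseg.metrics import (
    EmptyMaskError,
    aggregate_reports,
    dsc,
    evaluate_subject,
    hd95,
    surface_voxels,
    vd,
)

# ---------------------------------------------------------------------------
# brute-force oracles (pairwise distances over explicit surface coordinates)
# ---------------------------------------------------------------------------

def brute_surface(mask):
    """Surface voxels by explicit 6-neighbor scan."""
    mask = np.asarray(mask) > 0
    out = np.zeros_like(mask)
    idx = np.argwhere(mask)
    for i, j, k in idx:
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1] and 0 <= nk < mask.shape[2]):
                out[i, j, k] = True
                break
            if not mask[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def brute_hd(a, b, spacing, percentile):
    pa = np.argwhere(brute_surface(a)) * np.asarray(spacing)
    pb = np.argwhere(brute_surface(b)) * np.asarray(spacing)
    d = cdist(pa, pb)
    return max(
        np.percentile(d.min(axis=1), percentile),
        np.percentile(d.min(axis=0), percentile),
    )


def random_mask_pair(rng, max_side=12):
    shape = tuple(rng.integers(4, max_side + 1, size=3))
    a = np.zeros(shape, dtype=np.uint8)
    b = np.zeros(shape, dtype=np.uint8)
    # random blobs: a few boxes each, guaranteed nonempty
    for m in (a, b):
        for _ in range(rng.integers(1, 4)):
            lo = [rng.integers(0, s - 1) for s in shape]
            hi = [rng.integers(l + 1, s + 1) for l, s in zip(lo, shape)]
            m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
    return a, b


class TestDsc:
    def test_identical_nonempty(self, rng):
        a = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
        assert dsc(a, a) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert dsc(a, b) == 0.0

    def test_half_overlap_worked_example(self):
        # |A| = |B| = 4, |A∩B| = 2 -> 2*2/8 = 0.5
        a = np.zeros((4, 4, 1), dtype=np.uint8)
        b = np.zeros((4, 4, 1), dtype=np.uint8)
        a[0, 0:4, 0] = 1
        b[0, 2:4, 0] = 1
        b[1, 0:2, 0] = 1
        assert (a.sum(), b.sum(), (a & b).sum()) == (4, 4, 2)
        assert dsc(a, b) == 0.5

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((3, 3, 3), dtype=np.uint8)
        assert dsc(z, z) == 1.0

    def test_one_empty_is_zero(self):
        z = np.zeros((3, 3, 3), dtype=np.uint8)
        a = z.copy()
        a[1, 1, 1] = 1
        assert dsc(a, z) == 0.0

    def test_symmetric(self, rng):
        a, b = random_mask_pair(rng)
        assert dsc(a, b) == dsc(b, a)

    def test_extent_mismatch(self):
        with pytest.raises(ValueError, match="extents"):
            dsc(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))


class TestHd95:
    def test_identical_masks_zero_distance(self, rng):
        a, _ = random_mask_pair(rng)
        assert hd95(a, a, (1, 1, 1)) == 0.0

    def test_single_voxels_one_slice_apart(self):
        a = np.zeros((3, 3, 3), dtype=np.uint8)
        b = np.zeros((3, 3, 3), dtype=np.uint8)
        a[1, 1, 0] = 1
        b[1, 1, 1] = 1
        assert hd95(a, b, (0.977, 0.977, 3.0)) == pytest.approx(3.0, abs=1e-9)

    def test_empty_mask_undefined(self):
        a = np.zeros((3, 3, 3), dtype=np.uint8)
        b = a.copy()
        b[0, 0, 0] = 1
        with pytest.raises(EmptyMaskError):
            hd95(a, b, (1, 1, 1))

    def test_symmetric(self, rng):
        a, b = random_mask_pair(rng)
        sp = (0.9, 1.1, 2.5)
        assert hd95(a, b, sp) == pytest.approx(hd95(b, a, sp))

    def test_surface_extraction_matches_brute_force(self, rng):
        for _ in range(10):
            a, _ = random_mask_pair(rng)
            assert np.array_equal(surface_voxels(a), brute_surface(a))

    def test_oracle_equivalence_50_random_pairs(self):
        """Distance-transform HD95 equals all-pairs-distance HD95."""
        rng = np.random.default_rng(2024)
        for trial in range(50):
            a, b = random_mask_pair(rng)
            spacing = tuple(rng.uniform(0.5, 3.0, size=3))
            ours = hd95(a, b, spacing)
            brute = brute_hd(a, b, spacing, 95)
            assert ours == pytest.approx(brute, abs=1e-9), f"trial {trial}"

    def test_hd95_bounded_by_exact_hausdorff(self, rng):
        for _ in range(10):
            a, b = random_mask_pair(rng)
            spacing = (1.0, 1.0, 2.0)
            assert hd95(a, b, spacing) <= brute_hd(a, b, spacing, 100) + 1e-9


class TestVd:
    def test_identical_masks(self, rng):
        a, _ = random_mask_pair(rng)
        assert vd(a, a, (1, 1, 1)) == 0.0

    def test_worked_example_clinical_spacing(self):
        # truth 100 voxels, prediction 90, voxel = 0.977*0.977*3.0 mm^3
        b = np.zeros((10, 10, 2), dtype=np.uint8)
        b[:10, :10, 0] = 1
        a = b.copy()
        a[9, :10, 0] = 0
        assert (int(a.sum()), int(b.sum())) == (90, 100)
        out = vd(a, b, (0.977, 0.977, 3.0))
        assert out == pytest.approx(10 * 2.8635870 / 1000.0, abs=1e-6)
        assert out == pytest.approx(0.0286, abs=1e-4)

    def test_antisymmetric(self, rng):
        a, b = random_mask_pair(rng)
        sp = (1.5, 1.5, 3.0)
        assert vd(a, b, sp) == pytest.approx(-vd(b, a, sp))

    def test_sign_convention_under_segmentation_positive(self):
        b = np.ones((3, 3, 3), dtype=np.uint8)
        a = np.zeros_like(b)
        a[0, 0, 0] = 1
        assert vd(a, b, (1, 1, 1)) > 0


class TestEvaluateSubject:
    @pytest.fixture()
    def mask_sets(self, rng):
        truth = (rng.random((8, 8, 4, 5)) > 0.7).astype(np.uint8)
        spacing = (1.0, 1.0, 2.0)
        return PhaseMaskSet(truth.copy(), spacing), PhaseMaskSet(truth, spacing)

    def test_perfect_prediction(self, mask_sets):
        pred, truth = mask_sets
        report = evaluate_subject(pred, truth)
        for row in report.rows:
            assert row["dsc"] == 1.0
            assert row["hd95_mm"] == 0.0
            assert row["vd_cc"] == 0.0

    def test_row_count_is_phases_plus_igtv(self, mask_sets):
        pred, truth = mask_sets
        report = evaluate_subject(pred, truth)
        assert len(report.rows) == truth.P + 1
        assert report.rows[-1]["phase"] == "IGTV"

    def test_single_phase_perturbation_localized(self, mask_sets):
        pred, truth = mask_sets
        perturbed = pred.masks.copy()
        perturbed[..., 2] = 0
        perturbed[2:5, 2:5, 1:3, 2] = 1
        report = evaluate_subject(PhaseMaskSet(perturbed, pred.spacing), truth)
        clean = evaluate_subject(truth, truth)
        for i, (got, ref) in enumerate(zip(report.rows, clean.rows)):
            if report.rows[i]["phase"] in (report.rows[2]["phase"], "IGTV"):
                assert got["dsc"] < 1.0 or got["phase"] == "IGTV"
            else:
                assert got == ref

    def test_phase_count_mismatch(self, mask_sets):
        pred, truth = mask_sets
        bad = PhaseMaskSet(truth.masks[..., :3], truth.spacing)
        with pytest.raises(ValueError):
            evaluate_subject(bad, truth)

    def test_igtv_row_uses_union(self, rng):
        masks = np.zeros((6, 6, 3, 3), dtype=np.uint8)
        masks[1, 1, 1, 0] = 1
        masks[4, 4, 1, 1] = 1
        truth = PhaseMaskSet(masks, (1, 1, 1))
        pred = merge_igtv(truth)
        report = evaluate_subject(pred, truth)
        assert report.row("IGTV")["dsc"] == 1.0

    def test_csv_round_trip(self, mask_sets, tmp_path):
        import csv

        pred, truth = mask_sets
        report = evaluate_subject(pred, truth)
        report.to_csv(tmp_path / "r.csv")
        with open(tmp_path / "r.csv") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == truth.P + 1
        assert float(rows[0]["dsc"]) == 1.0


class TestAggregate:
    def test_mean_and_sd_across_subjects(self, rng):
        reports = []
        for _ in range(3):
            truth = (rng.random((6, 6, 3, 4)) > 0.6).astype(np.uint8)
            ms = PhaseMaskSet(truth, (1, 1, 1))
            reports.append(evaluate_subject(ms, ms))
        agg = aggregate_reports(reports)
        assert len(agg.rows) == 5
        assert agg.rows[0]["dsc"] == 1.0 and agg.rows[0]["dsc_sd"] == 0.0
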