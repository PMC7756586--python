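from fractions import Fraction

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cascadeseg.errors import ContractError, EmptyMaskError, UndefinedMetricError
from cascadeseg.metrics import (EvalConfig, MetricsReport, dice, evaluate_cohort,
                                evaluate_pair, extract_surface,
                                hausdorff_distance, mean_surface_distance,
                                trim_to_reference_extent)
from cascadeseg.volume_io import StructureSet

SPACING = (2.5, 1.17, 1.17)


def brute_surface(mask):
    """Independent surface oracle: explicit 6-neighbour check with border=bg."""
    mask = mask.astype(bool)
    pts = []
    nz, ny, nx = mask.shape
    for z, y, x in zip(*np.nonzero(mask)):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx) or not mask[zz, yy, xx]:
                pts.append((z, y, x))
                break
    return np.array(pts, dtype=float)


def brute_msd_hd(pred, ref, spacing):
    """O(n^2) all-pairs oracle for MSD and HD, in cm."""
    sp = brute_surface(pred) * np.array(spacing)
    sr = brute_surface(ref) * np.array(spacing)
    d = cdist(sp, sr)
    d_pr = d.min(axis=1)
    d_rp = d.min(axis=0)
    msd = 0.5 * (d_pr.mean() + d_rp.mean()) / 10.0
    hd = max(d_pr.max(), d_rp.max()) / 10.0
    return msd, hd


def random_mask(rng, shape, p=0.25):
    m = (rng.random(shape) < p).astype(np.uint8)
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = 1
    return m


class TestDice:
    def test_identical(self):
        m = np.ones((3, 3, 3), dtype=np.uint8)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0], b[3] = 1, 1
        assert dice(a, b) == 0.0

    def test_shifted_cubes(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0:2, 0:2, 0:2] = 1
        b[0:2, 0:2, 1:3] = 1  # overlap of 4 voxels
        assert dice(a, b) == pytest.approx(2 * 4 / 16)

    def test_empty_policies(self):
        e = np.zeros((2, 2, 2), dtype=np.uint8)
        f = np.ones((2, 2, 2), dtype=np.uint8)
        assert dice(e, e) == 1.0
        assert dice(e, f) == 0.0 and dice(f, e) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = random_mask(rng, (5, 5, 5)), random_mask(rng, (5, 5, 5))
        assert dice(a, b) == dice(b, a)

    def test_grid_mismatch(self):
        with pytest.raises(ContractError):
            dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))

    def test_exact_rational(self):
        rng = np.random.default_rng(1)
        a, b = random_mask(rng, (6, 6, 6)), random_mask(rng, (6, 6, 6))
        inter = int((a & b).sum())
        frac = Fraction(2 * inter, int(a.sum()) + int(b.sum()))
        assert dice(a, b) == float(frac)


class TestSurface:
    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        m[1, 1, 1] = 1
        np.testing.assert_array_equal(extract_surface(m), [[1, 1, 1]])

    def test_cube_surface_count(self):
        m = np.zeros((5, 5, 5), dtype=np.uint8)
        m[1:4, 1:4, 1:4] = 1
        assert len(extract_surface(m)) == 26

    def test_thin_slab_all_surface(self):
        m = np.zeros((3, 4, 4), dtype=np.uint8)
        m[1] = 1
        assert len(extract_surface(m)) == 16

    def test_volume_border_counts_as_background(self):
        m = np.ones((2, 2, 2), dtype=np.uint8)
        assert len(extract_surface(m)) == 8

    def test_physical_units(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        m[2, 1, 0] = 1
        np.testing.assert_allclose(extract_surface(m, SPACING), [[5.0, 1.17, 0.0]])

    def test_empty(self):
        with pytest.raises(EmptyMaskError):
            extract_surface(np.zeros((2, 2, 2)))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        m = random_mask(rng, (7, 7, 7))
        got = {tuple(p) for p in extract_surface(m)}
        want = {tuple(p) for p in brute_surface(m)}
        assert got == want


class TestSurfaceDistances:
    def test_identical_zero(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[1:3, 1:3, 1:3] = 1
        assert mean_surface_distance(m, m, SPACING) == 0.0
        assert hausdorff_distance(m, m, SPACING) == 0.0

    def test_point_pair_10mm(self):
        a = np.zeros((8, 4, 4), dtype=np.uint8)
        b = np.zeros((8, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[4, 0, 0] = 1  # 4 slices * 2.5 mm = 10 mm
        assert mean_surface_distance(a, b, SPACING) == pytest.approx(1.0)
        assert hausdorff_distance(a, b, SPACING) == pytest.approx(1.0)

    def test_empty_mask_undefined(self):
        a = np.zeros((3, 3, 3), dtype=np.uint8)
        b = np.ones((3, 3, 3), dtype=np.uint8)
        with pytest.raises(UndefinedMetricError):
            mean_surface_distance(a, b, SPACING)
        with pytest.raises(UndefinedMetricError):
            hausdorff_distance(b, a, SPACING)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 13, 3))
        a, b = random_mask(rng, shape), random_mask(rng, shape)
        msd_o, hd_o = brute_msd_hd(a, b, SPACING)
        assert mean_surface_distance(a, b, SPACING) == pytest.approx(msd_o, abs=1e-9)
        assert hausdorff_distance(a, b, SPACING) == pytest.approx(hd_o, abs=1e-9)

    def test_hd_at_least_msd(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a, b = random_mask(rng, (6, 6, 6)), random_mask(rng, (6, 6, 6))
            assert hausdorff_distance(a, b, SPACING) >= \
                mean_surface_distance(a, b, SPACING) - 1e-12

    def test_translation_invariance(self):
        rng = np.random.default_rng(10)
        a = np.zeros((10, 10, 10), dtype=np.uint8)
        b = np.zeros((10, 10, 10), dtype=np.uint8)
        a[2:5, 2:5, 2:5] = 1
        b[3:6, 2:5, 2:5] = 1
        a2, b2 = np.roll(a, 3, axis=2), np.roll(b, 3, axis=2)
        assert mean_surface_distance(a, b, SPACING) == \
            pytest.approx(mean_surface_distance(a2, b2, SPACING))
        assert hausdorff_distance(a, b, SPACING) == \
            pytest.approx(hausdorff_distance(a2, b2, SPACING))


class TestTrim:
    def test_superior_trim(self):
        pred = np.zeros((40, 4, 4), dtype=np.uint8)
        ref = np.zeros((40, 4, 4), dtype=np.uint8)
        pred[5:31] = 1
        ref[5:26] = 1
        out = trim_to_reference_extent(pred, ref, "superior")
        occ = np.flatnonzero(out.any(axis=(1, 2)))
        assert (occ.min(), occ.max()) == (5, 25)

    def test_already_within(self):
        pred = np.zeros((20, 4, 4), dtype=np.uint8)
        ref = np.zeros((20, 4, 4), dtype=np.uint8)
        pred[8:12] = 1
        ref[5:15] = 1
        for end in ("superior", "inferior"):
            np.testing.assert_array_equal(
                trim_to_reference_extent(pred, ref, end), pred)

    def test_random_voxelwise_oracle(self):
        rng = np.random.default_rng(11)
        pred = random_mask(rng, (16, 5, 5))
        ref = random_mask(rng, (16, 5, 5))
        zs = np.flatnonzero(ref.any(axis=(1, 2)))
        z = np.arange(16)[:, None, None]
        np.testing.assert_array_equal(
            trim_to_reference_extent(pred, ref, "superior"),
            pred * (z <= zs.max()))
        np.testing.assert_array_equal(
            trim_to_reference_extent(pred, ref, "inferior"),
            pred * (z >= zs.min()))

    def test_empty_reference_rejected(self):
        with pytest.raises(ContractError):
            trim_to_reference_extent(np.ones((4, 4, 4)), np.zeros((4, 4, 4)),
                                     "superior")


def _sset(scan_id, shape, **masks):
    s = StructureSet(volume_id=scan_id, grid_shape=shape)
    for name, m in masks.items():
        s.add_mask(name, m, "predicted")
    return s


class TestEvaluateCohort:
    def test_perfect_predictions(self, small_phantom):
        _, gt = small_phantom
        preds = {"scan0": gt}
        refs = {"scan0": gt}
        table, summary, outliers = evaluate_cohort(preds, refs, SPACING)
        assert (table["dsc"] == 1.0).all()
        assert (table["msd_cm"] == 0.0).all()
        assert (table["hd_cm"] == 0.0).all()
        assert not outliers

    def test_empty_prediction_missing_metric(self):
        shape = (6, 6, 6)
        ref_mask = np.zeros(shape, dtype=np.uint8)
        ref_mask[2:4, 2:4, 2:4] = 1
        preds = {"a": _sset("a", shape, bladder=np.zeros(shape, dtype=np.uint8)),
                 "b": _sset("b", shape, bladder=ref_mask)}
        refs = {"a": _sset("a", shape, bladder=ref_mask),
                "b": _sset("b", shape, bladder=ref_mask)}
        table, summary, _ = evaluate_cohort(preds, refs, SPACING)
        row_a = table[table["scan"] == "a"].iloc[0]
        assert row_a["status"] == "missing_metric" and row_a["dsc"] == 0.0
        assert np.isnan(row_a["msd_cm"])
        assert summary.iloc[0]["n"] == 2

    def test_missing_reference_skipped(self):
        shape = (4, 4, 4)
        m = np.ones(shape, dtype=np.uint8)
        preds = {"a": _sset("a", shape, bladder=m)}
        table, _, _ = evaluate_cohort(preds, {}, SPACING)
        assert (table["status"] == "skipped").all()

    def test_trim_rules_applied_for_registered_structures(self):
        shape = (30, 5, 5)
        pred = np.zeros(shape, dtype=np.uint8)
        ref = np.zeros(shape, dtype=np.uint8)
        pred[5:26] = 1
        ref[5:20] = 1
        rep = evaluate_pair(pred, ref, "pan", SPACING)  # superior trim
        assert rep.dsc == 1.0
        rep2 = evaluate_pair(pred, ref, "bladder", SPACING)  # no trim
        assert rep2.dsc < 1.0

    def test_dilated_predictions_match_per_scan_oracle(self):
        from scipy.ndimage import binary_dilation
        rng = np.random.default_rng(12)
        preds, refs = {}, {}
        expected = {}
        for i in range(6):
            sid = f"s{i}"
            shape = (10, 10, 10)
            gt = np.zeros(shape, dtype=np.uint8)
            c = rng.integers(3, 7, 3)
            gt[c[0] - 2: c[0] + 2, c[1] - 2: c[1] + 2, c[2] - 2: c[2] + 2] = 1
            pm = binary_dilation(gt).astype(np.uint8)
            preds[sid] = _sset(sid, shape, organ=pm)
            refs[sid] = _sset(sid, shape, organ=gt)
            inter = int((pm & gt).sum())
            expected[sid] = 2 * inter / (int(pm.sum()) + int(gt.sum()))
        table, summary, _ = evaluate_cohort(preds, refs, SPACING)
        for sid, dsc in expected.items():
            assert table[table["scan"] == sid].iloc[0]["dsc"] == pytest.approx(dsc)
        assert summary.iloc[0]["dsc_mean"] == pytest.approx(np.mean(list(expected.values())))

    def test_report_invariants(self):
        with pytest.raises(ContractError):
            MetricsReport("s", dsc=1.2, msd_cm=0.0, hd_cm=0.0,
                          n_pred_voxels=1, n_ref_voxels=1)
        with pytest.raises(ContractError):
            MetricsReport("s", dsc=0.5, msd_cm=2.0, hd_cm=1.0,
                          n_pred_voxels=1, n_ref_voxels=1)
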