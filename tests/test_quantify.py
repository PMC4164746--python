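import numpy as np
import pytest
from hypothesis import given, strategies as st

from dorsalhorn.geometry import Rect
from dorsalhorn.quantify import (
    Blob,
    DetectionParams,
    accentuate,
    count_channel,
    overlap_correct,
    segment,
)
from dorsalhorn.synth import NoiseModel, _paint_puncta, sample_puncta
from scipy.ndimage import gaussian_filter

PX = 0.1


def _disc_image(centers_um, area_um2, amp=900.0, shape=(600, 600), background=0.0):
    """Paint discs of a given area; background optional."""
    img = np.zeros(shape, dtype=np.float32)
    n = max(1, round(area_um2 / PX**2))
    r = int(np.ceil(np.sqrt(n / np.pi))) + 2
    for cx, cy in centers_um:
        ix, iy = int(round(cx / PX)), int(round(cy / PX))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        d2 = (xx + ix - cx / PX + 0.5) ** 2 + (yy + iy - cy / PX + 0.5) ** 2
        sel = np.argsort(d2.ravel())[:n]
        img[iy + yy.ravel()[sel], ix + xx.ravel()[sel]] += amp
    return img + background


def _flood_fill_count(mask):
    """Independent 4-connected component count by explicit BFS."""
    seen = np.zeros_like(mask, dtype=bool)
    H, W = mask.shape
    count = 0
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


class TestAccentuate:
    def test_constant_image_maps_to_zero(self):
        img = np.full((200, 200), 500, dtype=np.uint16)
        out = accentuate(img, PX, 0.5)
        assert np.all(out == 0)

    def test_bouton_scale_spot_is_preserved(self):
        img = _disc_image([(10.0, 10.0)], 0.25, amp=800.0, shape=(200, 200), background=100.0)
        out = accentuate(img.astype(np.uint16), PX, 0.56)
        assert out.max() >= 0.9 * 800.0

    def test_wide_band_is_suppressed(self):
        img = np.full((400, 400), 100, dtype=np.uint16)
        img[100:300, :] = 1000  # a 20 um-wide bright band
        out = accentuate(img, PX, 0.56)
        assert out[150:250].max() < 420  # far below the detection threshold

    def test_subpixel_scale_raises(self):
        with pytest.raises(ValueError):
            accentuate(np.zeros((10, 10), dtype=np.uint16), PX, 0.05)


class TestSegment:
    def test_blank_image_gives_no_blobs(self):
        assert segment(np.zeros((100, 100)), 10.0, PX) == []

    def test_threshold_at_max_gives_empty_list(self):
        img = _disc_image([(5.0, 5.0)], 0.3, amp=700.0, shape=(100, 100))
        assert segment(img, img.max(), PX) == []

    def test_min_area_filter_removes_sub_005_um2_objects(self):
        # a 3-pixel object at 0.1 um/px is 0.03 um^2 < 0.05 um^2
        img = np.zeros((50, 50))
        img[10, 10:13] = 900.0
        assert segment(img, 100.0, PX, min_area_um2=0.05) == []
        assert len(segment(img, 100.0, PX, min_area_um2=0.02)) == 1

    def test_ten_disjoint_discs_give_ten_blobs(self):
        centers = [(5.0 + 5.0 * i, 5.0 + 4.0 * (i % 3)) for i in range(10)]
        img = _disc_image(centers, 0.2, shape=(600, 600))
        blobs = segment(img, 100.0, PX)
        assert len(blobs) == 10
        for b in blobs:
            assert b.area_um2 == pytest.approx(0.2, abs=0.01)

    def test_matches_flood_fill_oracle_on_random_rasters(self, rng):
        for _ in range(5):
            img = (rng.random((60, 60)) < 0.25).astype(float) * 500.0
            blobs = segment(img, 100.0, PX, min_area_um2=0.0)
            assert len(blobs) == _flood_fill_count(img > 100.0)

    def test_four_connectivity_splits_diagonal_touch(self):
        img = np.zeros((10, 10))
        img[2, 2] = img[3, 3] = 900.0  # diagonal neighbours
        blobs = segment(img, 100.0, PX, min_area_um2=0.0)
        assert len(blobs) == 2


class TestOverlapCorrect:
    def test_identity_for_mean_sized_blob(self):
        b = [Blob(0.2, 0, 0, 0, 0, 20)]
        assert overlap_correct(b, 0.2).corrected_count == 1

    def test_double_area_blob_counts_twice(self):
        b = [Blob(0.6, 0, 0, 0, 0, 60)]
        assert overlap_correct(b, 0.3).corrected_count == 2

    def test_round_half_to_even_keeps_small_blobs_single(self):
        blobs = [Blob(0.25, 0, 0, 0, 0, 25), Blob(0.1, 0, 0, 0, 0, 10)]
        # max(1, round(1.25)) + max(1, round(0.5)) = 1 + 1
        assert overlap_correct(blobs, 0.2).corrected_count == 2

    def test_nonpositive_mean_area_raises(self):
        with pytest.raises(ValueError):
            overlap_correct([], 0.0)

    def test_total_area_mode_pools_blob_area(self):
        blobs = [Blob(0.1, 0, 0, 0, 0, 10) for _ in range(5)]
        res = overlap_correct(blobs, 0.3, mode="total_area")
        assert res.corrected_count == 2  # round(0.5 / 0.3), no raw-count floor

    def test_boolean_mode_matches_total_area_at_low_coverage(self):
        blobs = [Blob(0.3, 0, 0, 0, 0, 30) for _ in range(4)]
        lo = overlap_correct(blobs, 0.3, mode="boolean", region_area_um2=1e6)
        assert lo.corrected_count == 4
        with pytest.raises(ValueError, match="region_area"):
            overlap_correct(blobs, 0.3, mode="boolean")

    def test_boolean_mode_recovers_clumped_counts(self):
        # 30% coverage of a 100 um^2 region: -100*ln(0.7)/0.2 ≈ 178 counts
        blobs = [Blob(30.0, 0, 0, 0, 0, 3000)]
        res = overlap_correct(blobs, 0.2, mode="boolean", region_area_um2=100.0)
        assert res.corrected_count == pytest.approx(-100.0 * np.log(0.7) / 0.2, abs=0.5)

    @given(
        areas=st.lists(st.floats(min_value=0.05, max_value=1.2), min_size=0, max_size=30),
        mean=st.floats(min_value=0.1, max_value=0.5),
    )
    def test_corrected_never_below_raw_and_equality_when_small(self, areas, mean):
        blobs = [Blob(a, 0, 0, 0, 0, int(a / PX**2)) for a in areas]
        res = overlap_correct(blobs, mean)
        assert res.corrected_count >= res.raw_blob_count
        if all(a <= 1.45 * mean for a in areas):
            assert res.corrected_count == res.raw_blob_count


class TestCountChannel:
    def test_blank_image_counts_zero(self):
        res = count_channel(np.zeros((300, 300), dtype=np.uint16), PX, DetectionParams())
        assert res.corrected_count == 0

    def test_fifty_well_separated_puncta_count_exactly(self):
        centers = [(6.0 + 5.5 * (i % 10), 6.0 + 5.5 * (i // 10)) for i in range(50)]
        img = _disc_image(centers, 0.2, amp=900.0, shape=(620, 620), background=200.0)
        res = count_channel(img.astype(np.uint16), PX, DetectionParams(mean_area_um2=0.2))
        assert res.raw_blob_count == 50
        assert res.corrected_count == 50

    def test_adding_a_disjoint_punctum_never_decreases_count(self):
        centers = [(10.0, 10.0), (20.0, 20.0), (30.0, 10.0)]
        p = DetectionParams(mean_area_um2=0.2)
        base = count_channel(
            _disc_image(centers, 0.2, background=200.0, shape=(400, 400)).astype(np.uint16), PX, p
        )
        more = count_channel(
            _disc_image(centers + [(30.0, 30.0)], 0.2, background=200.0, shape=(400, 400)).astype(
                np.uint16
            ),
            PX,
            p,
        )
        assert more.corrected_count >= base.corrected_count + 1

    def test_saturated_image_warns_and_returns_empty(self):
        img = np.full((100, 100), 4095, dtype=np.uint16)
        with pytest.warns(UserWarning, match="saturated"):
            res = count_channel(img, PX, DetectionParams())
        assert res.corrected_count == 0


def _rendered_region(density, mean_area, seed, size_um=100.0, margin=10.0):
    noise = NoiseModel()
    rng = np.random.default_rng((seed, int(density * 10)))
    reg = Rect(margin, margin, size_um - 2 * margin, size_um - 2 * margin)
    fld = sample_puncta(reg, density, mean_area, 0.5, rng, "IB4")
    shape = (int(size_um / PX), int(size_um / PX))
    img = np.zeros(shape, dtype=np.float32)
    _paint_puncta(img, fld, PX)
    img = gaussian_filter(img, noise.psf_sigma_um / PX, truncate=3.0)
    img += noise.background_level + rng.normal(0, noise.background_sd, shape).astype(np.float32)
    return np.clip(img, 0, 4095).astype(np.uint16), fld, reg


@pytest.mark.parametrize("marker,mean_area", [("IB4", 0.3), ("GAD65", 0.2)])
def test_density_recovery_bias_within_ten_percent(marker, mean_area):
    """Corrected-count density tracks ground truth across 1-40 per 100 um^2."""
    from dorsalhorn.quantify import DEFAULT_PARAMS, accentuate, overlap_correct, segment

    p = DEFAULT_PARAMS[marker]
    for density in (1.0, 10.0, 25.0, 40.0):
        tot_est, tot_true = 0.0, 0
        for seed in range(6):
            img, fld, reg = _rendered_region(density, mean_area, seed)
            acc = accentuate(img, PX, p.bouton_diameter_um)
            blobs = [
                b
                for b in segment(acc, p.threshold_dn, PX, p.min_area_um2)
                if reg.contains_point(b.centroid_x_um, b.centroid_y_um)
            ]
            tot_est += overlap_correct(
                blobs, mean_area, p.correction, region_area_um2=reg.area_um2
            ).corrected_count
            tot_true += fld.count
        assert tot_true > 0
        bias = tot_est / tot_true - 1.0
        assert abs(bias) <= 0.10, f"{marker} density {density}: bias {bias:+.3f}"
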