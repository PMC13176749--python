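"""Unit and property tests for VOI statistics and the SNR/CNR/DIN metrics."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cbctqa.image_quality import (
    EntityAggregate,
    VoiSpec,
    VoiStats,
    aggregate_entity,
    cnr,
    compute_quality,
    din,
    ellipse_mask,
    extract_voi,
    quality_ratio,
    snr,
    uniformity_profile,
)


def _spec(cx, cy, d, entity="bone", voi_id="v", region="reg", protocol="p"):
    return VoiSpec(
        voi_id=voi_id, slice_region=region, protocol=protocol,
        entity=entity, center=(cx, cy), diameter=d,
    )


def _brute_force_stats(image, cx, cy, diameter):
    """Independent per-pixel oracle: loop, test centre-in-ellipse, summarise."""
    r = diameter / 2.0
    picked = []
    rows, cols = image.shape
    for y in range(rows):
        for x in range(cols):
            if (x - cx) ** 2 + (y - cy) ** 2 <= r * r:
                picked.append(image[y, x])
    arr = np.array(picked, dtype=float)
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return arr.size, arr.min(), arr.max(), arr.mean(), sd


class TestVoiExtraction:
    def test_diameter6_pixel_counts(self):
        # half-integer centre: the inscribed circle covers 32 pixel centres
        assert ellipse_mask((10, 10), (4.5, 4.5), 6).sum() == 32
        # integer centre: 29
        assert ellipse_mask((11, 11), (5.0, 5.0), 6).sum() == 29

    def test_constant_region(self):
        image = np.full((12, 12), 7.25)
        stats = extract_voi(image, _spec(5.5, 5.5, 6))
        assert stats.mean == 7.25
        assert stats.sd == 0.0
        assert stats.minimum == stats.maximum == 7.25
        assert stats.n_pixels == 32

    @given(st.integers(0, 200))
    def test_matches_bruteforce_oracle(self, case):
        rng = np.random.default_rng(case)
        image = rng.normal(0, 300, size=(32, 32))
        d = float(rng.integers(2, 13))
        half = d / 2.0
        cx = float(rng.uniform(half, 31.5 - half))
        cy = float(rng.uniform(half, 31.5 - half))
        if rng.integers(2):  # exercise half-integer centres too
            cx, cy = round(cx) - 0.5, round(cy) - 0.5
        stats = extract_voi(image, _spec(cx, cy, d))
        n, mn, mx, mean, sd = _brute_force_stats(image, cx, cy, d)
        assert stats.n_pixels == n
        assert stats.mean == pytest.approx(mean, rel=1e-12, abs=1e-12)
        assert stats.sd == pytest.approx(sd, rel=1e-12, abs=1e-12)
        assert stats.minimum == mn and stats.maximum == mx

    def test_pixel_spacing_gives_mm2_area(self):
        image = np.zeros((12, 12))
        stats = extract_voi(image, _spec(5.5, 5.5, 6), pixel_spacing=(0.127, 0.127))
        assert stats.area_mm2 == pytest.approx(32 * 0.127**2)

    def test_out_of_bounds_rejected(self):
        image = np.zeros((10, 10))
        with pytest.raises(ValueError, match="exceeds image bounds"):
            extract_voi(image, _spec(1.0, 5.0, 6))
        with pytest.raises(ValueError, match="diameter"):
            _spec(5.0, 5.0, 1.0)


class TestAggregation:
    def test_three_voi_aggregate_full_rotation_bone(self):
        stats = [
            VoiStats(voi_id=str(i), area_px2=28.44, minimum=m, maximum=m,
                     mean=m, sd=0.0, slice_region="paranasal_sinus",
                     protocol="regular", entity="bone")
            for i, m in enumerate((2011.5, 1940.9, 2087.0))
        ]
        agg = aggregate_entity(stats)
        assert agg.mean == pytest.approx(2013.1, abs=0.05)
        assert agg.sd == pytest.approx(73.1, abs=0.05)

    def test_aggregate_with_negative_means(self):
        means = (84.4, 24.7, -122.2)  # maxilla soft tissue, full rotation
        stats = [
            VoiStats(voi_id=str(i), area_px2=28.44, minimum=m, maximum=m,
                     mean=m, sd=0.0, entity="soft_tissue")
            for i, m in enumerate(means)
        ]
        agg = aggregate_entity(stats)
        assert agg.mean == pytest.approx(-4.4, abs=0.05)
        assert agg.sd == pytest.approx(106.3, abs=0.05)
        assert agg.dmax == pytest.approx(117.8, abs=0.05)

    def test_identical_means_degenerate(self):
        stats = [
            VoiStats(voi_id=str(i), area_px2=1, minimum=5, maximum=5, mean=5, sd=0)
            for i in range(3)
        ]
        agg = aggregate_entity(stats)
        assert agg.sd == 0.0 and agg.dmax == 0.0

    def test_single_voi_warns(self, caplog):
        s = VoiStats(voi_id="1", area_px2=1, minimum=1, maximum=1, mean=1, sd=0)
        with caplog.at_level("WARNING"):
            agg = aggregate_entity([s])
        assert agg.sd == 0.0
        assert any("single VOI" in r.message for r in caplog.records)

    def test_mixed_or_empty_groups_rejected(self):
        a = VoiStats(voi_id="1", area_px2=1, minimum=1, maximum=1, mean=1, sd=0,
                     entity="bone")
        b = VoiStats(voi_id="2", area_px2=1, minimum=1, maximum=1, mean=1, sd=0,
                     entity="air")
        with pytest.raises(ValueError, match="mixes"):
            aggregate_entity([a, b])
        with pytest.raises(ValueError, match="empty"):
            aggregate_entity([])

    @given(st.lists(st.floats(-1000, 2500), min_size=2, max_size=6))
    def test_dmax_identity(self, means):
        stats = [
            VoiStats(voi_id=str(i), area_px2=1, minimum=m, maximum=m, mean=m, sd=0)
            for i, m in enumerate(means)
        ]
        agg = aggregate_entity(stats)
        assert agg.dmax == pytest.approx(
            max(abs(agg.maximum - agg.mean), abs(agg.mean - agg.minimum)),
            rel=1e-12, abs=1e-12,
        )


def _agg_from_means(means, entity, region="reg", protocol="p"):
    return aggregate_entity([
        VoiStats(voi_id=str(i), area_px2=28.44, minimum=m, maximum=m, mean=m,
                 sd=0.0, slice_region=region, protocol=protocol, entity=entity)
        for i, m in enumerate(means)
    ])


class TestMetrics:
    def test_metric_values_from_published_aggregates(self):
        bone = _agg_from_means((1566.7, 1952.1, 1725.8), "bone")   # mandible, 360
        soft = _agg_from_means((-106.0, 15.6, -67.4), "soft_tissue")
        assert snr(bone, soft) == pytest.approx(28.14, abs=0.05)
        assert cnr(bone, soft) == pytest.approx(28.99, abs=0.05)
        assert din(bone, soft) == pytest.approx(26.41, abs=0.05)

    def test_zero_noise_guards(self):
        bone = _agg_from_means((100.0, 100.0, 100.0), "bone")
        soft = _agg_from_means((5.0, 5.0, 5.0), "soft_tissue")
        with pytest.raises(ValueError, match="zero noise"):
            snr(bone, soft)
        with pytest.raises(ValueError, match="zero noise"):
            cnr(bone, soft)
        with pytest.raises(ValueError, match="Dmax"):
            din(bone, soft)

    def test_cnr_zero_when_no_contrast(self):
        soft = _agg_from_means((10.0, 20.0, 30.0), "soft_tissue")
        bone = _agg_from_means((20.0, 20.0, 20.0), "bone")
        assert cnr(bone, soft) == 0.0

    @given(
        st.lists(st.integers(500, 2500), min_size=3, max_size=3),
        st.lists(st.integers(-200, 200), min_size=3, max_size=3, unique=True),
        st.floats(0.1, 10.0),
        st.floats(-500, 500),
    )
    def test_scale_and_shift_invariances(self, bone_means, soft_means, k, c):
        bone_means = [float(m) for m in bone_means]
        soft_means = [float(m) for m in soft_means]
        bone = _agg_from_means(bone_means, "bone")
        soft = _agg_from_means(soft_means, "soft_tissue")
        bone_k = _agg_from_means([k * m for m in bone_means], "bone")
        soft_k = _agg_from_means([k * m for m in soft_means], "soft_tissue")
        bone_c = _agg_from_means([m + c for m in bone_means], "bone")
        soft_c = _agg_from_means([m + c for m in soft_means], "soft_tissue")
        # positive rescaling leaves all three metrics unchanged
        assert snr(bone_k, soft_k) == pytest.approx(abs(snr(bone, soft)), rel=1e-6)
        assert cnr(bone_k, soft_k) == pytest.approx(cnr(bone, soft), rel=1e-6, abs=1e-9)
        assert din(bone_k, soft_k) == pytest.approx(din(bone, soft), rel=1e-6, abs=1e-9)
        # a constant offset cancels in CNR and DIN but shifts SNR by c/sd_soft
        assert cnr(bone_c, soft_c) == pytest.approx(cnr(bone, soft), rel=1e-6, abs=1e-6)
        assert din(bone_c, soft_c) == pytest.approx(din(bone, soft), rel=1e-6, abs=1e-6)
        assert snr(bone_c, soft_c) - snr(bone, soft) == pytest.approx(
            c / soft.sd, rel=1e-6, abs=1e-6
        )

    def test_quality_ratio_rounding_and_guards(self):
        from cbctqa.image_quality import QualityMetrics

        regular = QualityMetrics("mandible", "regular", snr=28.14, cnr=28.99, din=26.41)
        quick = QualityMetrics("mandible", "quick", snr=23.31, cnr=24.62, din=21.46)
        ratios = quality_ratio(quick, regular)
        assert ratios.rounded == {"snr": 0.83, "cnr": 0.85, "din": 0.81}
        same = quality_ratio(regular, regular)
        assert all(v == 1.0 for v in same.ratios.values())
        zero = QualityMetrics("mandible", "quick", snr=0.0, cnr=0.0, din=0.0)
        with pytest.raises(ValueError, match="> 0"):
            quality_ratio(regular, zero)


class TestUniformityProfile:
    def test_profile_reorganises_aggregates(self, iq_result):
        profile = uniformity_profile(iq_result.aggregates)
        assert len(profile) == 18
        assert list(profile.columns) == ["slice_region", "protocol", "entity", "mean", "sd"]
        # ordered by slice region first, then protocol, entities bone/soft/air
        assert list(profile["slice_region"].unique()) == [
            "paranasal_sinus", "maxilla", "mandible"
        ]
        first = profile.iloc[0]
        assert first["entity"] == "bone"
        assert first["mean"] == pytest.approx(2013.1, abs=0.05)
        # numbers are identical to the aggregates, just reorganised
        by_key = {
            (a.slice_region, a.protocol, a.entity): a for a in iq_result.aggregates
        }
        for _, row in profile.iterrows():
            agg = by_key[(row["slice_region"], row["protocol"], row["entity"])]
            assert row["mean"] == agg.mean and row["sd"] == agg.sd

    def test_single_aggregate_profile(self):
        agg = _agg_from_means((1.0, 2.0, 3.0), "bone")
        profile = uniformity_profile([agg])
        assert len(profile) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            uniformity_profile([])
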