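"""Tests for the synthetic TLD-study and slice generators."""
import math

import numpy as np
import pytest

from cbctqa import reference
from cbctqa.dosimetry import RegionDose, effective_dose
from cbctqa.image_quality import aggregate_entity, cnr, extract_voi
from cbctqa.phantom import (
    Annulus,
    Disc,
    Rect,
    SynthSliceConfig,
    SynthTldConfig,
    default_slice_config,
    make_slice,
    make_tld_study,
)
from cbctqa.pipeline import run_dose_stage


TRUE_DOSES = {"hypophysis": 1.042, "oral_mucosa": 1.566, "thyroid_right": 0.134}


class TestTldStudy:
    def test_same_seed_reproduces_readouts(self):
        config = SynthTldConfig(true_doses=TRUE_DOSES, seed=42)
        first, _ = make_tld_study(config)
        second, _ = make_tld_study(config)
        assert [(r.dosimeter_id, r.value) for r in first] == [
            (r.dosimeter_id, r.value) for r in second
        ]

    def test_zero_noise_recovers_truth_exactly(self, ref_weighting):
        true_doses = {
            region: (lo + hi) / 2
            for (region, proto), (lo, hi) in reference.DOSE_CONSTITUENTS.items()
            if proto == reference.REGULAR
        }
        config = SynthTldConfig(true_doses=true_doses, noise_cv=0.0, seed=1)
        readouts, truth = make_tld_study(config)
        result = run_dose_stage(readouts, ref_weighting)
        report = result.reports["synthetic"]
        for rd in report.region_doses:
            assert rd.mean == pytest.approx(true_doses[rd.region], abs=1e-12)
            assert rd.sd == pytest.approx(0.0, abs=1e-12)
        expected_ed = effective_dose(
            [RegionDose.from_values(r, "synthetic", [d]) for r, d in true_doses.items()],
            ref_weighting,
        )
        assert report.effective_dose == pytest.approx(expected_ed, abs=1e-12)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SynthTldConfig(true_doses={})
        with pytest.raises(ValueError, match="> 0"):
            SynthTldConfig(true_doses={"a": -1.0})
        with pytest.raises(ValueError, match="noise_cv"):
            SynthTldConfig(true_doses=TRUE_DOSES, noise_cv=-0.1)
        with pytest.raises(ValueError, match="counts"):
            SynthTldConfig(true_doses=TRUE_DOSES, n_per_region=0)


class TestSliceGeometry:
    def test_same_seed_bit_identical_image(self):
        config = default_slice_config(image_size=(96, 96), seed=5)
        a = make_slice(config)
        b = make_slice(config)
        assert np.array_equal(a.image, b.image)
        assert np.isfinite(a.image).all()

    def test_masks_partition_image(self):
        result = make_slice(default_slice_config(image_size=(96, 96), seed=5))
        total = np.zeros(result.image.shape, dtype=int)
        for mask in result.masks.values():
            total += mask.astype(int)
        assert (total == 1).all()

    def test_zero_noise_slice_reproduces_entity_means(self):
        config = default_slice_config(
            image_size=(96, 96),
            within_voi_sd={"bone": 0.0, "soft_tissue": 0.0, "air": 0.0},
            between_voi_sd={"bone": 0.0, "soft_tissue": 0.0, "air": 0.0},
            seed=3,
        )
        result = make_slice(config)
        stats = [extract_voi(result.image, spec) for spec in result.voi_specs]
        for s in stats:
            assert s.mean == config.entity_means[s.entity]
            assert s.sd == 0.0
        bone = aggregate_entity([s for s in stats if s.entity == "bone"])
        soft = aggregate_entity([s for s in stats if s.entity == "soft_tissue"])
        with pytest.raises(ValueError, match="zero noise"):
            cnr(bone, soft)

    def test_quick_mode_noise_scales_with_sqrt_mas(self):
        kwargs = dict(image_size=(128, 128), seed=11)
        regular = make_slice(default_slice_config(protocol_mas=21.6, **kwargs))
        quick = make_slice(default_slice_config(protocol_mas=14.4, **kwargs))
        sd_reg = regular.image[regular.masks["soft_tissue"]].std()
        sd_quick = quick.image[quick.masks["soft_tissue"]].std()
        assert sd_quick / sd_reg == pytest.approx(math.sqrt(21.6 / 14.4), rel=0.05)

    def test_out_of_bounds_shapes_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            make_slice(SynthSliceConfig(
                image_size=(64, 64),
                shapes=(Disc("bone", (32.0, 32.0), 40.0),),
            ))
        with pytest.raises(ValueError, match="out of bounds"):
            make_slice(SynthSliceConfig(
                image_size=(64, 64),
                shapes=(Rect("bone", 60, 0, 10, 10),),
            ))

    def test_overlapping_shapes_later_wins(self):
        config = SynthSliceConfig(
            image_size=(64, 64),
            shapes=(
                Disc("soft_tissue", (31.5, 31.5), 20.0),
                Rect("bone", 28, 28, 8, 8),
            ),
            within_voi_sd={"bone": 0.0, "soft_tissue": 0.0, "air": 0.0},
        )
        result = make_slice(config)
        assert result.masks["bone"][30, 30]
        assert not result.masks["soft_tissue"][30, 30]
        assert result.image[30, 30] == config.entity_means["bone"]

    def test_voi_leaving_entity_rejected(self):
        base = default_slice_config(image_size=(96, 96))
        from dataclasses import replace
        from cbctqa.image_quality import VoiSpec

        bad_voi = VoiSpec(voi_id="bad", slice_region="synthetic_head",
                          protocol="synthetic", entity="bone",
                          center=(47.5, 47.5), diameter=6)  # image centre = soft
        config = replace(base, voi_specs=base.voi_specs + (bad_voi,))
        with pytest.raises(ValueError, match="leaves its entity region"):
            make_slice(config)


class TestCnrRecovery:
    def test_cnr_median_matches_statistical_oracle(self):
        """The image-pipeline CNR estimate follows the analytic noise model.

        Oracle: draw the three VOI means directly from the generative model
        (entity mean + between-VOI offset + averaged pixel noise) and form the
        same |bone - soft| / sd(soft) statistic, bypassing images entirely.
        With n=3 the sample-SD denominator makes the median sit well above the
        asymptotic contrast/dispersion value, and the pipeline must reproduce
        that distribution, not the naive ratio.
        """
        between = {"bone": 150.0, "soft_tissue": 60.0, "air": 40.0}
        estimates = []
        n_pixels = None
        within_eff = None
        for seed in range(300):
            config = default_slice_config(
                image_size=(96, 96), between_voi_sd=between, seed=seed,
            )
            result = make_slice(config)
            stats = [extract_voi(result.image, s) for s in result.voi_specs]
            bone = aggregate_entity([s for s in stats if s.entity == "bone"])
            soft = aggregate_entity([s for s in stats if s.entity == "soft_tissue"])
            estimates.append(cnr(bone, soft))
            if n_pixels is None:
                truth = result.ground_truth
                n_pixels = {
                    spec.entity: [
                        truth.voi_n_pixels[s.voi_id]
                        for s in result.voi_specs if s.entity == spec.entity
                    ]
                    for spec in result.voi_specs
                }
                within_eff = truth.within_sd_effective
        pipeline_median = float(np.median(estimates))

        rng = np.random.default_rng(424242)
        oracle = []
        for _ in range(20_000):
            bone_means = np.array([
                1800.0 + rng.normal(0, between["bone"])
                + rng.normal(0, within_eff["bone"] / math.sqrt(n))
                for n in n_pixels["bone"]
            ])
            soft_means = np.array([
                rng.normal(0, between["soft_tissue"])
                + rng.normal(0, within_eff["soft_tissue"] / math.sqrt(n))
                for n in n_pixels["soft_tissue"]
            ])
            oracle.append(
                abs(bone_means.mean() - soft_means.mean()) / soft_means.std(ddof=1)
            )
        oracle_median = float(np.median(oracle))
        assert pipeline_median == pytest.approx(oracle_median, rel=0.06)

    def test_cnr_approaches_contrast_over_dispersion_with_more_vois(self):
        """With pixel noise off, the CNR estimate converges to the true
        contrast / between-VOI dispersion (1800/60 = 30) as the soft-tissue
        VOI count grows; at n=3 the sample-SD bias keeps it far away."""
        from cbctqa.image_quality import VoiSpec

        no_within = {"bone": 0.0, "soft_tissue": 0.0, "air": 0.0}
        between = {"bone": 150.0, "soft_tissue": 60.0, "air": 0.0}
        m = 96
        cy = cx = (m - 1) / 2.0
        shapes = (
            Disc("soft_tissue", (cy, cx), 0.45 * m),
            Annulus("bone", (cy, cx), 0.30 * m, 0.40 * m),
        )
        rb = 0.35 * m
        bone_sites = [
            (cx, cy - rb),
            (cx - rb * math.cos(math.pi / 6), cy + rb / 2),
            (cx + rb * math.cos(math.pi / 6), cy + rb / 2),
        ]
        grid = [cx + 7.0 * k for k in (-2, -1, 0, 1, 2)]
        soft_sites = [(x, y) for y in grid for x in grid]  # 25 interior sites

        def run(n_soft, seed):
            vois = [
                VoiSpec(voi_id=f"b{i}", slice_region="s", protocol="p",
                        entity="bone", center=site, diameter=6)
                for i, site in enumerate(bone_sites)
            ] + [
                VoiSpec(voi_id=f"s{i}", slice_region="s", protocol="p",
                        entity="soft_tissue", center=site, diameter=6)
                for i, site in enumerate(soft_sites[:n_soft])
            ]
            config = SynthSliceConfig(
                image_size=(m, m), shapes=shapes, voi_specs=tuple(vois),
                within_voi_sd=no_within, between_voi_sd=between, seed=seed,
            )
            result = make_slice(config)
            stats = [extract_voi(result.image, s) for s in result.voi_specs]
            bone = aggregate_entity([s for s in stats if s.entity == "bone"])
            soft = aggregate_entity([s for s in stats if s.entity == "soft_tissue"])
            return cnr(bone, soft)

        few = np.median([run(3, seed) for seed in range(150)])
        many = np.median([run(25, seed) for seed in range(150)])
        true_cnr = 1800.0 / 60.0
        assert abs(many - true_cnr) / true_cnr <= 0.05
        assert abs(many - true_cnr) < abs(few - true_cnr)
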