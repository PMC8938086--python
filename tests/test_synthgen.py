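import numpy as np
import pandas as pd
import pytest

from sonohcc.segeval import select_gold_standard, voe
from sonohcc.synthgen import (
    DEFAULT_FEATURE_PROBABILITIES,
    AnnotatorConfig,
    CohortConfig,
    IHCCohortConfig,
    PhantomConfig,
    cohort_to_frame,
    generate_cohort,
    generate_ihc_cohort,
    generate_phantom,
    simulate_annotators,
)


class TestPhantom:
    def test_zero_noise_is_exact_two_level_image(self):
        cfg = PhantomConfig(impulse_density=0.0, speckle_scale=0.0, seed=1)
        image, mask = generate_phantom(cfg)
        expected = np.where(mask > 0, cfg.lesion_level, cfg.background_level)
        assert np.array_equal(image, expected)

    def test_impulse_density_realised(self):
        cfg = PhantomConfig(
            height=64, width=64, impulse_density=0.1, speckle_scale=0.0,
            background_level=100, lesion_level=150, seed=2,
        )
        image, _ = generate_phantom(cfg)
        extreme_fraction = np.mean((image == 0) | (image == 255))
        assert extreme_fraction == pytest.approx(0.1, abs=0.03)

    def test_determinism(self):
        cfg = PhantomConfig(speckle_scale=0.3, impulse_density=0.05, seed=7)
        img1, mask1 = generate_phantom(cfg)
        img2, mask2 = generate_phantom(cfg)
        assert np.array_equal(img1, img2)
        assert np.array_equal(mask1, mask2)

    def test_output_closure(self):
        cfg = PhantomConfig(
            lesion_shape="irregular-blob", boundary_perturbation=3.0,
            speckle_scale=0.5, impulse_density=0.2, seed=3,
        )
        image, mask = generate_phantom(cfg)
        assert image.dtype == np.uint8
        assert set(np.unique(mask)) <= {0, 1}

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomConfig(center=(-50.0, -50.0), axes=(2.0, 2.0)))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(height=4)
        with pytest.raises(ValueError):
            PhantomConfig(impulse_density=1.5)
        with pytest.raises(ValueError):
            PhantomConfig(lesion_level=300)


class TestAnnotators:
    def test_zero_perturbation_copies_input(self, disk_mask):
        masks = simulate_annotators(
            disk_mask, AnnotatorConfig(k=3, boundary_jitter=0.0, outlier_rate=0.0, seed=1)
        )
        assert len(masks) == 3
        assert all(voe(m, disk_mask) == 0.0 for m in masks)

    def test_jitter_produces_positive_mean_voe(self, disk_mask):
        masks = simulate_annotators(
            disk_mask, AnnotatorConfig(k=4, boundary_jitter=2.0, seed=5)
        )
        pairwise = [
            voe(masks[i], masks[j])
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        assert np.mean(pairwise) > 0.0

    def test_all_outliers_still_yield_a_member_gold(self, disk_mask):
        masks = simulate_annotators(
            disk_mask, AnnotatorConfig(k=3, boundary_jitter=1.0, outlier_rate=1.0, seed=2)
        )
        idx, gold = select_gold_standard(masks)
        assert any(np.array_equal(gold, m) for m in masks)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            AnnotatorConfig(k=1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotators(np.zeros((8, 8), dtype=np.uint8), AnnotatorConfig(seed=0))

    def test_determinism(self, disk_mask):
        cfg = AnnotatorConfig(k=3, boundary_jitter=2.0, seed=7)
        a = simulate_annotators(disk_mask, cfg)
        b = simulate_annotators(disk_mask, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestCohort:
    def test_default_group_sizes(self):
        patients = generate_cohort(CohortConfig(seed=0))
        assert len(patients) == 100
        groups = pd.Series([p.group for p in patients]).value_counts()
        assert set(groups.index) == {"doppler", "contrast", "elastic", "multimodal"}
        assert (groups == 25).all()

    def test_zero_prevalence_all_benign(self):
        patients = generate_cohort(CohortConfig(malignancy_prevalence=0.0, seed=1))
        for p in patients:
            for lesion in p.lesions:
                assert lesion.pathology == "benign"
                assert lesion.grade is None

    def test_malignant_lesions_carry_grade_and_findings(self):
        frame = cohort_to_frame(generate_cohort(CohortConfig(seed=3)))
        malignant = frame[frame["pathology"] == "malignant"]
        assert malignant["grade"].notna().all()
        assert malignant["flow_grade"].between(0, 3).all()
        assert malignant["elasticity_score"].between(1, 5).all()

    def test_diameters_in_configured_range(self):
        frame = cohort_to_frame(generate_cohort(CohortConfig(seed=4)))
        assert frame["diameter_cm"].between(0.8, 3.0).all()

    def test_determinism(self):
        a = cohort_to_frame(generate_cohort(CohortConfig(seed=9)))
        b = cohort_to_frame(generate_cohort(CohortConfig(seed=9)))
        pd.testing.assert_frame_equal(a, b)

    def test_expected_lesion_count_near_152(self):
        # E[lesions] = 100 (0.74 + 0.26 * 3) = 152; check a loose band
        frame = cohort_to_frame(generate_cohort(CohortConfig(seed=12)))
        assert 120 <= len(frame) <= 190

    def test_group_sizes_must_sum(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=100, group_sizes=(25, 25, 25))

    def test_irregular_shape_frequency_recovered_at_large_n(self):
        cfg = CohortConfig(
            n_patients=6600, group_sizes=(1650, 1650, 1650, 1650), seed=21
        )
        frame = cohort_to_frame(generate_cohort(cfg))
        poor = frame[(frame["pathology"] == "malignant") & (frame["grade"] == "poor")]
        freq = (poor["shape"] == "irregular").mean()
        p = DEFAULT_FEATURE_PROBABILITIES["poor"]["irregular_shape"]
        assert freq == pytest.approx(p, abs=0.02)


class TestIHCCohort:
    def test_all_positive_probabilities(self):
        cfg = IHCCohortConfig(
            positive_probabilities={
                "EZH2": {"lesional": 1.0, "perilesional": 1.0, "normal": 1.0}
            },
            seed=0,
        )
        df = generate_ihc_cohort(cfg)
        assert df["EZH2_positive"].all()

    def test_default_group_sizes(self):
        df = generate_ihc_cohort(IHCCohortConfig(seed=1))
        sizes = df["group"].value_counts()
        assert sizes["lesional"] == 79
        assert sizes["perilesional"] == 79
        assert sizes["normal"] == 39
        assert set(df.columns) >= {"EZH2_positive", "p57_positive"}

    def test_determinism(self):
        a = generate_ihc_cohort(IHCCohortConfig(seed=8))
        b = generate_ihc_cohort(IHCCohortConfig(seed=8))
        pd.testing.assert_frame_equal(a, b)

    def test_scaled_cohort_recovers_configured_rate(self):
        cfg = IHCCohortConfig(n_lesional=7900, n_perilesional=7900, n_normal=3900, seed=13)
        df = generate_ihc_cohort(cfg)
        lesional = df[df["group"] == "lesional"]
        assert 100 * lesional["EZH2_positive"].mean() == pytest.approx(75.95, abs=1.5)
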