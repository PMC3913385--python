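"""Synthetic image and cohort generators: determinism and ground truth."""

import numpy as np
import pytest

from plaquantify import (
    CohortSimConfig,
    ImageSimConfig,
    coverage,
    simulate_cohort,
    simulate_cohort_frame,
    simulate_tooth_image,
)
from plaquantify.errors import ConfigError
from plaquantify.synthetic_data import calibrate_delta_r_link


class TestImageGenerator:
    def test_same_seed_byte_identical(self):
        cfg = ImageSimConfig(noise_sd=4.0, seed=42)
        a, _, _, ta = simulate_tooth_image(cfg)
        b, _, _, tb = simulate_tooth_image(cfg)
        assert (a.pixels == b.pixels).all()
        assert (ta.pixels == tb.pixels).all()

    def test_zero_fraction_clean_tooth(self):
        img, roi, _, truth = simulate_tooth_image(ImageSimConfig(plaque_fraction=0.0))
        assert truth.count == 0
        assert coverage(img, roi, deinterlace_first=False).coverage_pct <= 1.0

    def test_full_fraction_covered_tooth(self):
        img, roi, ref, truth = simulate_tooth_image(
            ImageSimConfig(plaque_fraction=1.0, seed=1)
        )
        assert coverage(img, roi, deinterlace_first=False).coverage_pct >= 99.0

    @pytest.mark.parametrize("f", [0.1, 0.25, 0.5])
    def test_coverage_recovers_fraction_noiseless(self, f):
        img, roi, _, truth = simulate_tooth_image(
            ImageSimConfig(plaque_fraction=f, seed=2)
        )
        got = coverage(img, roi, deinterlace_first=False).coverage_pct
        assert got == pytest.approx(100 * f, abs=1.0)

    def test_truth_mask_fraction_exact(self):
        cfg = ImageSimConfig(plaque_fraction=0.3, seed=3)
        _, _, _, truth = simulate_tooth_image(cfg)
        from plaquantify.synthetic_data import _tooth_mask

        n_tooth = _tooth_mask(cfg).sum()
        assert truth.count == int(np.ceil(0.3 * n_tooth))

    def test_interlace_artifact_removed_by_deinterlace(self):
        from plaquantify import deinterlace

        clean_img, roi, _, _ = simulate_tooth_image(
            ImageSimConfig(plaque_fraction=0.25, interlace_amplitude=0.0, seed=4)
        )
        striped_img, _, _, _ = simulate_tooth_image(
            ImageSimConfig(plaque_fraction=0.25, interlace_amplitude=30.0, seed=4)
        )
        before = np.abs(
            striped_img.pixels.astype(int) - clean_img.pixels.astype(int)
        ).mean()
        fixed = deinterlace(striped_img, field="odd_rows")
        after = np.abs(fixed.pixels.astype(int) - clean_img.pixels.astype(int)).mean()
        assert after < 0.25 * before  # the row artifact is largely removed
        got = coverage(striped_img, roi, deinterlace_first=True).coverage_pct
        assert got == pytest.approx(25.0, abs=1.5)

    def test_scattered_mode_same_fraction(self):
        img, roi, _, truth = simulate_tooth_image(
            ImageSimConfig(plaque_fraction=0.2, scattered=True, seed=5)
        )
        got = coverage(img, roi, deinterlace_first=False).coverage_pct
        assert got == pytest.approx(20.0, abs=1.0)

    def test_infeasible_configs_rejected(self):
        with pytest.raises(ConfigError):
            ImageSimConfig(plaque_fraction=1.2)
        with pytest.raises(ConfigError):
            ImageSimConfig(r_enamel=1.1)
        with pytest.raises(ConfigError):
            simulate_tooth_image(ImageSimConfig(enamel_green=200, r_plaque=1.6))


class TestCohortGenerator:
    def test_same_seed_identical_tables(self):
        cfg = CohortSimConfig(seed=9)
        a = simulate_cohort_frame(cfg)
        b = simulate_cohort_frame(cfg)
        assert a.equals(b)

    def test_null_logistic_case_fraction(self):
        cfg = CohortSimConfig(
            n_case=1000, n_control=1000, mode="logistic",
            beta_coverage=0.0, beta_delta_r=0.0, beta_smoking=0.0,
            beta_bmi=0.0, beta_age=0.0, intercept=0.5, seed=10,
        )
        frame = simulate_cohort_frame(cfg)
        target = 1 / (1 + np.exp(-0.5))
        frac = (frame["group"] == "case").mean()
        # binomial 3-sigma at n = 2000
        assert abs(frac - target) < 3 * np.sqrt(target * (1 - target) / 2000)

    def test_correlation_target_hit_on_average(self):
        from scipy.stats import pearsonr

        from plaquantify.synthetic_data import realized_coverage_moments

        base = CohortSimConfig()
        cov_mean, cov_sd = realized_coverage_moments(base)
        slope, intercept, noise = calibrate_delta_r_link(0.55, cov_sd, 16.5, cov_mean, 66.6)
        rs = []
        for seed in range(500):
            cfg = CohortSimConfig(
                dr_slope=slope, dr_intercept=intercept, dr_noise_sd=noise, seed=seed
            )
            f = simulate_cohort_frame(cfg)
            rs.append(pearsonr(f["mean_coverage_pct"], f["mean_delta_r_pct"]).statistic)
        rs = np.asarray(rs)
        # single n=91 draws scatter widely; nearly all sit within +-0.2
        assert np.mean(np.abs(rs - 0.55) < 0.2) >= 0.95
        assert rs.mean() == pytest.approx(0.55, abs=0.03)

    def test_records_carry_10_to_12_teeth_near_subject_mean(self):
        records = simulate_cohort(CohortSimConfig(n_case=20, n_control=20, seed=12))
        assert len(records) == 40
        for rec in records:
            n = len(rec.tooth_measurements)
            assert 10 <= n <= 12
            covs = [c.coverage_pct for c, _ in rec.tooth_measurements]
            assert 0 <= min(covs) and max(covs) <= 100

    def test_preterm_probability_increases_with_coverage(self):
        cfg = CohortSimConfig(n_case=3000, n_control=3000, seed=13)
        f = simulate_cohort_frame(cfg)
        pre = f["delivery_weeks"] < 37
        lo = pre[f["mean_coverage_pct"] < 15].mean()
        hi = pre[f["mean_coverage_pct"] > 35].mean()
        assert hi > lo

    def test_delivery_weeks_in_plausible_range(self):
        f = simulate_cohort_frame(CohortSimConfig(seed=14))
        assert f["delivery_weeks"].between(20, 45).all()

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ConfigError):
            CohortSimConfig(coverage_sd=(-1.0, 14.0))
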