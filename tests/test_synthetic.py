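"""Generators: determinism, null-effect exchangeability, parameter recovery,
speckle statistics and waveform calibration."""

import numpy as np
import pandas as pd
import pytest

from husphen import CohortConfig, Gaussian, PhantomSpec, Region, WaveformSpec
from husphen.errors import (
    GeometryError,
    InfeasibleTargetError,
    ValidationError,
)
from husphen.synthetic import (
    generate_cohort,
    generate_phantom,
    generate_score_sheet,
    generate_waveform,
    liver_kidney_phantom,
    mv_feasible_range,
    rect_mask,
    solve_decay_rate,
    _cycle_mean,
)


class TestCohort:
    def test_same_seed_identical_tables(self):
        cfg = CohortConfig(seed=11)
        pd.testing.assert_frame_equal(generate_cohort(cfg),
                                      generate_cohort(CohortConfig(seed=11)))
        assert not generate_cohort(CohortConfig(seed=12)).equals(
            generate_cohort(cfg))

    def test_null_quiet_config_makes_diets_identical(self):
        cfg = CohortConfig(seed=3).null(quiet=True)
        df = generate_cohort(cfg)
        drop = ["mouse_id", "diet", "kcal_per_g"]
        sd = df[df.diet == "SD"].drop(columns=drop).reset_index(drop=True)
        wd = df[df.diet == "WD"].drop(columns=drop).reset_index(drop=True)
        pd.testing.assert_frame_equal(sd, wd)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"n_per_group": 1}, "n_per_group"),
            ({"ages_weeks": (8, 8, 9)}, "ages_weeks"),
            ({"ages_weeks": (10, 9)}, "ages_weeks"),
            ({"attrition_prob": 1.5}, "attrition_prob"),
            ({"bw_noise_sd": -1.0}, "bw_noise_sd"),
            ({"hyperphagia_delta": Gaussian(0.5, -0.1)}, "hyperphagia_delta"),
            ({"sexes": ("male", "dog")}, "sexes"),
        ],
    )
    def test_invalid_config_names_the_field(self, kwargs, match):
        with pytest.raises(ValidationError, match=match):
            CohortConfig(**kwargs)

    def test_structure_one_row_per_mouse_timepoint(self, default_config):
        df = generate_cohort(default_config.null(quiet=True))
        assert len(df) == 2 * 2 * 8 * 17
        assert df.groupby("mouse_id").age_weeks.is_monotonic_increasing.all()
        base = df[df.age_weeks == 8]
        assert (base.groupby(["sex", "diet"]).size() == 8).all()

    def test_attrition_truncates_whole_mice(self):
        cfg = CohortConfig(seed=5, attrition_prob=0.5)
        df = generate_cohort(cfg)
        lengths = df.groupby("mouse_id").size()
        assert lengths.min() >= 1 and lengths.max() == 17
        assert (lengths < 17).any()
        # truncation keeps a contiguous prefix of ages
        for _, sub in df.groupby("mouse_id"):
            ages = sub.age_weeks.tolist()
            assert ages == list(cfg.ages_weeks[: len(ages)])

    def test_wd_slope_effect_recovered_by_ols(self):
        """A +0.5 g/week WD slope effect is recovered by per-mouse OLS."""
        diffs = []
        for seed in range(200):
            cfg = CohortConfig(
                seed=seed, sexes=("male",), attrition_prob=0.0,
                bw_slope_wd_extra={"male": Gaussian(0.5, 0.08)})
            df = generate_cohort(cfg)
            slopes = df.groupby(["diet", "mouse_id"]).apply(
                lambda g: np.polyfit(g.age_weeks, g.bw, 1)[0],
                include_groups=False)
            diffs.append(slopes["WD"].mean() - slopes["SD"].mean())
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 0.5) < 3 * se + 1e-12


class TestPhantom:
    def test_noiseless_phantom_is_exact(self):
        img = liver_kidney_phantom(speckle=False, liver_het=0.0,
                                   cortex_het=0.0)
        assert np.array_equal(np.unique(img.pixels[img.masks["liver"]]), [95])
        assert np.array_equal(
            np.unique(img.pixels[img.masks["renal_cortex"]]), [120])

    def test_same_seed_identical_image(self):
        a = liver_kidney_phantom(seed=9)
        b = liver_kidney_phantom(seed=9)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, liver_kidney_phantom(seed=10).pixels)

    def test_speckle_preserves_region_mean(self):
        """Multiplicative speckle keeps the regional mean within 0.5%."""
        shape = (400, 400)   # 1.6e5 px single region
        spec = PhantomSpec(
            regions=[Region("liver", np.ones(shape, dtype=bool), 120.0)],
            image_shape=shape, seed=1)
        img = generate_phantom(spec)
        assert abs(img.pixels.mean() - 120.0) / 120.0 < 0.005

    def test_region_mean_relative_error_small(self):
        img = liver_kidney_phantom(seed=2)
        for label, target in (("liver", 94.8), ("renal_cortex", 120.0)):
            mean = img.pixels[img.masks[label]].mean()
            assert abs(mean - target) / target < 0.02

    def test_equal_target_means_indistinguishable(self):
        """Two regions with equal targets differ within 3x the pooled SE."""
        diffs = []
        for seed in range(100):
            img = liver_kidney_phantom(liver_mean=110.0, cortex_mean=110.0,
                                       seed=seed)
            diffs.append(img.pixels[img.masks["liver"]].mean()
                         - img.pixels[img.masks["renal_cortex"]].mean())
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-12

    def test_overlapping_masks_rejected(self):
        shape = (50, 50)
        with pytest.raises(GeometryError):
            PhantomSpec(regions=[
                Region("a", rect_mask(shape, 0, 30, 0, 30), 100.0),
                Region("b", rect_mask(shape, 20, 50, 20, 50), 120.0),
            ], image_shape=shape)

    def test_target_mean_bounds_validated(self):
        shape = (20, 20)
        with pytest.raises(ValidationError):
            Region("a", rect_mask(shape, 0, 10, 0, 10), 300.0)


class TestWaveform:
    def test_noiseless_construction_hits_psv_and_edv(self, clean_trace):
        assert clean_trace.velocity.max() == pytest.approx(30.0, abs=1e-9)
        assert clean_trace.velocity[-1] == pytest.approx(15.0, abs=1e-9)
        assert clean_trace.velocity[0] == pytest.approx(15.0, abs=1e-9)

    def test_duration_matches_cycle_count(self):
        tr = generate_waveform(WaveformSpec(hr=400, n_cycles=4,
                                            sampling_rate=1000))
        assert tr.time[-1] - tr.time[0] == pytest.approx(0.6, abs=1e-9)

    def test_mv_calibration_against_trapezoid_integral(self):
        """The solved decay rate reproduces the target cycle mean."""
        spec = WaveformSpec(mv_target=12.71)
        tr = generate_waveform(spec)
        period = 60.0 / spec.hr
        n_per = int(round(period * spec.sampling_rate))
        mv = np.trapezoid(tr.velocity[: n_per + 1], tr.time[: n_per + 1]) / period
        assert mv == pytest.approx(12.71, abs=0.01)

    @pytest.mark.parametrize("target", [6.0, 10.0, 12.71, 20.0, 26.0])
    def test_solver_matches_closed_form(self, target):
        k = solve_decay_rate(30.0, 15.0, target)
        assert _cycle_mean(30.0, 15.0, k) == pytest.approx(target, rel=1e-6)

    def test_infeasible_mean_target_rejected(self):
        lo, hi = mv_feasible_range(30.0, 15.0)
        for target in (lo - 1.0, hi + 1.0, 29.9):
            with pytest.raises(InfeasibleTargetError):
                generate_waveform(WaveformSpec(mv_target=target))

    @pytest.mark.parametrize(
        "kwargs", [{"edv": 40.0}, {"edv": -1.0}, {"n_cycles": 2},
                   {"hr": 0.0}, {"noise_sd": -0.5}])
    def test_invalid_waveform_spec(self, kwargs):
        with pytest.raises(ValidationError):
            WaveformSpec(**kwargs)

    def test_noise_is_seeded(self):
        a = generate_waveform(WaveformSpec(noise_sd=1.0, seed=4))
        b = generate_waveform(WaveformSpec(noise_sd=1.0, seed=4))
        assert np.array_equal(a.velocity, b.velocity)


class TestScoreSheet:
    def test_degenerate_distribution_all_zero(self, default_config):
        sheet = generate_score_sheet(
            default_config,
            {("female", "WD"): {"renal_score": {0: 1.0, 1: 0.0, 2: 0.0}}})
        assert (sheet.renal_score == 0).all() and len(sheet) == 8

    def test_bad_probability_vector_rejected(self, default_config):
        with pytest.raises(ValidationError, match="sum"):
            generate_score_sheet(
                default_config,
                {("female", "WD"): {"renal_score": {0: 0.5, 1: 0.4}}})

    def test_empirical_frequencies_near_binomial_expectation(self):
        cfg = CohortConfig(n_per_group=3000, sexes=("female",),
                           diets=("WD",), seed=21)
        probs = {0: 0.5, 1: 0.3, 2: 0.2}
        sheet = generate_score_sheet(cfg, {("female", "WD"):
                                           {"renal_score": probs}})
        n = len(sheet)
        for level, p in probs.items():
            freq = (sheet.renal_score == level).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * se

    def test_renal_table_frequencies_in_expectation(self):
        """The 6-of-7 score-1 prevalence is reproduced in expectation."""
        cfg = CohortConfig(n_per_group=7000, sexes=("female",), diets=("WD",),
                           seed=5)
        probs = {0: 0.0, 1: 6 / 7, 2: 1 / 7}
        sheet = generate_score_sheet(cfg, {("female", "WD"):
                                           {"renal_score": probs}})
        freq1 = (sheet.renal_score == 1).mean()
        se = np.sqrt((6 / 7) * (1 / 7) / len(sheet))
        assert abs(freq1 - 6 / 7) < 3 * se
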