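"""Synthetic-cohort generator: planted structure, determinism, round-trip."""

import numpy as np
import pandas as pd
import pytest

from boldvar import synthgen
from boldvar.signalprep import condition, sd_bold_map
from boldvar.synthgen import (
    SynthConfig,
    composite_attenuation,
    effect_voxel_ids,
    generate_behavior,
    generate_cohort,
    generate_timeseries,
    latent_signal,
    load_cohort,
    simulate_cohort,
    fast_preset,
)


class TestConfigValidation:
    def test_effect_set_cannot_exceed_mask(self):
        with pytest.raises(ValueError):
            SynthConfig(n_voxels=10, n_effect_voxels=11)

    def test_interval_range_must_be_ordered(self):
        with pytest.raises(ValueError):
            SynthConfig(retest_interval_range=(3.0, 2.0))

    def test_coupling_rho_bounded(self):
        with pytest.raises(ValueError):
            SynthConfig(coupling_rho=1.5)

    def test_zero_voxels_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_voxels=0)

    def test_defaults_mirror_study_design(self):
        cfg = SynthConfig()
        assert cfg.n_subjects == 74
        assert cfg.n_timepoints == 200
        assert cfg.tr_seconds == 2.5
        assert cfg.retest_interval_range == (1.92, 3.91)
        assert sum(cfg.n_indicators_per_domain.values()) == 16
        assert cfg.n_metabolic_indicators == 5


class TestTimeseries:
    def test_deterministic_given_seed(self):
        cfg = fast_preset(seed=5)
        a = generate_timeseries(cfg, 0.7, 2)
        b = generate_timeseries(cfg, 0.7, 2)
        assert np.array_equal(a.values, b.values)

    def test_gain_free_generator_equalizes_expected_sd(self):
        # With integration_gain = 0 effect and non-effect voxels are
        # exchangeable: compare mean SD over replicate series.
        cfg = fast_preset(integration_gain=0.0, n_voxels=100, n_effect_voxels=30, seed=2)
        eff = effect_voxel_ids(cfg)
        non = np.setdiff1d(np.arange(cfg.n_voxels), eff)
        diffs = []
        for rep in range(30):
            rng = np.random.default_rng([cfg.seed, rep])
            ts = generate_timeseries(cfg, 1.5, 2, rng=rng)
            sd = ts.values.std(axis=1)
            diffs.append(sd[eff].mean() - sd[non].mean())
        diffs = np.array(diffs)
        t_stat = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert abs(t_stat) < 4.0

    def test_noiseless_limit_gives_unit_correlations_in_effect_set(self):
        cfg = fast_preset(noise_sd=1e-9, n_voxels=50, n_effect_voxels=10, seed=3)
        ts = generate_timeseries(cfg, 1.0, 2)
        eff = effect_voxel_ids(cfg)
        corr = np.corrcoef(ts.values[eff])
        assert np.allclose(np.abs(corr), 1.0, atol=1e-6)

    def test_positive_factor_raises_effect_voxel_sd(self):
        # Monte-Carlo over replicate series: empirical SD of effect voxels
        # exceeds non-effect voxels at occasion 2 for a positive factor.
        cfg = SynthConfig(
            n_voxels=200, n_effect_voxels=50, integration_gain=1.0,
            noise_sd=1.0, n_timepoints=150, seed=7,
        )
        eff = effect_voxel_ids(cfg)
        non = np.setdiff1d(np.arange(cfg.n_voxels), eff)
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng([cfg.seed, 1000 + rep])
            ts = generate_timeseries(cfg, 1.0, 2, rng=rng)
            sd = ts.values.std(axis=1)
            wins += sd[eff].mean() > sd[non].mean()
        assert wins >= 95

    def test_occasion_one_has_no_factor_dependence(self):
        cfg = fast_preset(seed=9)
        rng_a = np.random.default_rng(1)
        rng_b = np.random.default_rng(1)
        a = generate_timeseries(cfg, -2.0, 1, rng=rng_a)
        b = generate_timeseries(cfg, 2.0, 1, rng=rng_b)
        assert np.array_equal(a.values, b.values)

    def test_invalid_occasion_rejected(self):
        with pytest.raises(ValueError):
            generate_timeseries(fast_preset(), 0.0, 3)

    def test_nonfinite_factor_rejected(self):
        with pytest.raises(ValueError):
            generate_timeseries(fast_preset(), np.nan, 1)


class TestLatentSignalSpectrum:
    def test_band_compliance(self):
        # < 5% of total power outside 0.01-0.10 Hz (periodogram check).
        cfg = SynthConfig()
        from scipy.signal import periodogram

        out_fracs = []
        for rep in range(20):
            c = latent_signal(cfg, np.random.default_rng(rep))
            f, p = periodogram(c - c.mean(), fs=1.0 / cfg.tr_seconds, detrend=False)
            keep = f > 0
            inside = (f >= 0.01) & (f <= 0.10)
            out_fracs.append(p[keep & ~inside].sum() / p[keep].sum())
        assert np.mean(out_fracs) < 0.05

    def test_unit_population_sd(self):
        c = latent_signal(SynthConfig(), np.random.default_rng(0))
        assert c.std() == pytest.approx(1.0, abs=1e-12)


class TestBehavior:
    def test_null_coupling_gives_null_composite_correlation(self):
        cfg = fast_preset(coupling_rho=0.0, seed=21)
        f = np.random.default_rng(0).standard_normal(400)
        bundle = generate_behavior(cfg, f, rng=np.random.default_rng(1))
        comp = _composite_change(bundle)
        r = np.corrcoef(comp, f)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(400)

    def test_perfect_coupling_without_noise_is_rank_identical(self):
        cfg = fast_preset(coupling_rho=1.0, indicator_noise_sd=0.0, seed=22)
        f = np.random.default_rng(2).standard_normal(50)
        bundle = generate_behavior(cfg, f, rng=np.random.default_rng(3))
        comp = _composite_change(bundle)
        assert np.array_equal(np.argsort(comp), np.argsort(f))

    def test_recovered_correlation_matches_closed_form_attenuation(self):
        # Large-n Monte-Carlo band around rho * closed-form attenuation.
        cfg = fast_preset(coupling_rho=0.5, seed=11)
        n = 500
        f = np.random.default_rng(42).standard_normal(n)
        bundle = generate_behavior(cfg, f, rng=np.random.default_rng(11))
        r = np.corrcoef(_composite_change(bundle), f)[0, 1]
        expected = 0.5 * composite_attenuation(cfg)
        se = (1 - expected**2) / np.sqrt(n)
        assert expected - 4 * se < r < expected + 4 * se
        assert 0.4 < r < 0.6

    def test_direction_flags_mark_rt_and_error_indicators(self):
        cfg = fast_preset(seed=1)
        bundle = generate_behavior(cfg, np.zeros(10), rng=np.random.default_rng(0))
        d = bundle.t1.directions
        assert d["nb1_rt_verbal"] == "lower_better"
        assert d["nb3_errors_verbal"] == "lower_better"
        assert d["cfit1"] == "higher_better"
        assert d["hdl_cholesterol"] == "higher_better"

    def test_declining_subject_worsens_rt_in_natural_units(self):
        # Direction is metadata only: a cognitive decline (negative change
        # factor) must RAISE reaction times, not lower them.
        cfg = fast_preset(coupling_rho=1.0, indicator_noise_sd=0.0, seed=4)
        f = np.array([-3.0, 0.0, 3.0])
        bundle = generate_behavior(cfg, f, rng=np.random.default_rng(5))
        change = bundle.t2.data - bundle.t1.data
        assert change["nb1_rt_verbal"].iloc[0] > 0  # decline -> slower
        assert change["nb1_rt_verbal"].iloc[2] < 0
        assert change["cfit1"].iloc[0] < 0

    def test_retest_intervals_within_range(self):
        cfg = fast_preset(seed=8)
        bundle = generate_behavior(cfg, np.zeros(200), rng=np.random.default_rng(6))
        iv = bundle.retest_interval_years
        assert (iv >= 1.92).all() and (iv <= 3.91).all()

    def test_metabolic_independent_of_subject_factor(self):
        cfg = fast_preset(seed=13)
        f = np.random.default_rng(7).standard_normal(500)
        bundle = generate_behavior(cfg, f, rng=np.random.default_rng(8))
        for col in ("systolic_bp", "hdl_cholesterol"):
            r = np.corrcoef(bundle.t1.data[col], f)[0, 1]
            assert abs(r) < 4.0 / np.sqrt(500)


class TestCohortIO:
    def test_same_seed_twice_gives_identical_truth_files(self, tmp_path):
        cfg = SynthConfig(n_subjects=3, n_voxels=40, n_effect_voxels=10,
                          n_timepoints=80, seed=77)
        a = generate_cohort(cfg, tmp_path / "a")
        b = generate_cohort(cfg, tmp_path / "b")
        assert (a / "truth.json").read_bytes() == (b / "truth.json").read_bytes()
        assert (a / "behavior_t1.tsv").read_bytes() == (b / "behavior_t1.tsv").read_bytes()

    def test_cohort_round_trips_through_readers(self, tmp_path):
        cfg = SynthConfig(n_subjects=3, n_voxels=40, n_effect_voxels=10,
                          n_timepoints=80, seed=78)
        path = generate_cohort(cfg, tmp_path / "c")
        mem = simulate_cohort(cfg)
        disk = load_cohort(path)
        assert disk.truth.subject_ids == mem.truth.subject_ids
        assert np.array_equal(disk.truth.effect_voxel_ids, mem.truth.effect_voxel_ids)
        key = (mem.truth.subject_ids[0], 1)
        # float32 NIfTI storage bounds the round-trip error
        assert np.allclose(disk.series[key].values, mem.series[key].values,
                           rtol=1e-5, atol=1e-4)
        assert disk.series[key].tr_seconds == pytest.approx(2.5)
        pd.testing.assert_frame_equal(
            disk.behavior.t1.data, mem.behavior.t1.data, check_exact=False
        )

    def test_truth_marks_real_effect_voxels(self, small_cohort):
        cfg = small_cohort.config
        truth = small_cohort.truth
        assert truth.effect_voxel_ids.size == cfg.n_effect_voxels
        assert truth.effect_voxel_ids.max() < cfg.n_voxels
        assert len(truth.subject_factor) == cfg.n_subjects


class TestPlantedSdChange:
    def test_mean_effect_sd_change_tracks_subject_factor(self, small_cohort):
        # Generator truth: subjects with positive factor gain SD in the
        # effect set; correlation across subjects should be strongly positive.
        cohort = small_cohort
        eff = cohort.truth.effect_voxel_ids
        changes = []
        for sid in cohort.truth.subject_ids:
            sd1 = sd_bold_map(condition(cohort.series[(sid, 1)])).values
            sd2 = sd_bold_map(condition(cohort.series[(sid, 2)])).values
            changes.append((sd2 - sd1)[eff].mean())
        r = np.corrcoef(changes, cohort.truth.subject_factor)[0, 1]
        assert r > 0.8


def _composite_change(bundle):
    """Direction-aligned mean of standardized cognitive change scores."""
    change = bundle.t2.data - bundle.t1.data
    cols = [c for c in change.columns if bundle.t1.domains[c] != "Metabolic"]
    z = []
    for c in cols:
        x = change[c].to_numpy()
        x = (x - x.mean()) / x.std()
        if bundle.t1.directions[c] == "lower_better":
            x = -x
        z.append(x)
    return np.mean(z, axis=0)
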