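"""Generators: trial sequences, voxel patterns, emissions, ratings, traces."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from painloop import frequency, synthetic
from painloop.synthetic import (
    ContrastGenParams,
    EmissionModel,
    RatingGenParams,
    SubjectEmissions,
    calibrate_intensities,
    calibrated_emission_model,
    generate_contrast_traces,
    generate_ratings,
    generate_trial_sequences,
    generate_voxel_trials,
    sample_emissions,
)


class TestTrialSequences:
    def test_degenerate_bernoulli_all_high(self):
        seqs = generate_trial_sequences(3, 2, 15, p_high=1.0, seed=0)
        for seq in seqs.values():
            assert all(lab == "high" for lab in seq.flat_labels())

    def test_overall_high_fraction_in_binomial_99_interval(self):
        seqs = generate_trial_sequences(19, 6, 30, p_high=0.5, seed=42)
        u = np.concatenate([s.as_binary() for s in seqs.values()])
        n = u.size
        assert n == 19 * 180
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5) / n
        assert lo <= u.mean() <= hi

    def test_yoked_subject_copies_source_elementwise(self):
        seqs = generate_trial_sequences(3, 2, 10, seed=1, yoke={"sub-02": "sub-01"})
        assert seqs["sub-02"].sessions == seqs["sub-01"].sessions
        assert seqs["sub-02"].yoked_from == "sub-01"
        assert seqs["sub-03"].yoked_from is None

    def test_unknown_yoke_source_raises_naming_label(self):
        with pytest.raises(ValueError, match="sub-99"):
            generate_trial_sequences(2, 1, 5, seed=0, yoke={"sub-01": "sub-99"})

    def test_fixed_seed_reproducible(self):
        a = generate_trial_sequences(4, 3, 20, seed=5)
        b = generate_trial_sequences(4, 3, 20, seed=5)
        assert all(a[k].sessions == b[k].sessions for k in a)

    def test_unequal_session_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            synthetic.TrialSequence("s", [["high", "low"], ["high"]])


class TestVoxelTrials:
    def test_ground_truth_bookkeeping_and_reproducibility(self):
        a = generate_voxel_trials(n_trials=24, n_voxels=30, n_informative=5, seed=9)
        b = generate_voxel_trials(n_trials=24, n_voxels=30, n_informative=5, seed=9)
        assert a.ground_truth["informative"].size == 5
        np.testing.assert_array_equal(a.ground_truth["informative"], b.ground_truth["informative"])
        np.testing.assert_array_equal(a.trials, b.trials)

    def test_informative_exceeding_voxels_rejected(self):
        with pytest.raises(ValueError, match="n_informative"):
            generate_voxel_trials(n_trials=10, n_voxels=5, n_informative=6)

    def test_noninformative_voxels_class_balanced(self):
        ds = generate_voxel_trials(
            n_trials=400, n_voxels=20, n_informative=3, class_shift=5.0, seed=2
        )
        other = np.setdiff1d(np.arange(20), ds.ground_truth["informative"])
        hi = ds.trials[ds.labels == "high"][:, :, other].mean()
        lo = ds.trials[ds.labels == "low"][:, :, other].mean()
        assert abs(hi - lo) < 0.05  # pure noise: no class-conditional difference


class TestEmissions:
    def test_perfect_mode_emits_exactly_0_and_1(self, rng):
        model = EmissionModel(mode="perfect")
        sub = SubjectEmissions(model, rng)
        assert sub.draw("high", rng) == 1.0
        assert sub.draw("low", rng) == 0.0

    def test_sham_mode_auc_is_chance(self, rng):
        model = calibrated_emission_model().sham()
        sub = SubjectEmissions(model, rng)
        labels = rng.integers(2, size=10_000)
        emis = np.array([sub.draw("high" if y else "low", rng) for y in labels])
        # empirical AUC via rank statistic
        order = np.argsort(emis)
        ranks = np.empty_like(order, dtype=float)
        ranks[order] = np.arange(1, emis.size + 1)
        n1, n0 = labels.sum(), (1 - labels).sum()
        auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) < 1.96 * se * 1.5

    def test_calibrated_subject_means_bracket_printed_intervals(self):
        # across-subject mean-of-means 95% CIs should bracket the calibration
        # targets [0.545, 0.660] (high) and [0.410, 0.524] (low)
        model = calibrated_emission_model()
        rng = np.random.default_rng(77)
        means_h, means_l = [], []
        for _ in range(400):
            cohort = [SubjectEmissions(model, rng) for _ in range(19)]
            means_h.append(np.mean([c.mean_high for c in cohort]))
            means_l.append(np.mean([c.mean_low for c in cohort]))
        lo_h, hi_h = np.percentile(means_h, [2.5, 97.5])
        lo_l, hi_l = np.percentile(means_l, [2.5, 97.5])
        assert lo_h == pytest.approx(0.545, abs=0.02)
        assert hi_h == pytest.approx(0.660, abs=0.02)
        assert lo_l == pytest.approx(0.410, abs=0.02)
        assert hi_l == pytest.approx(0.524, abs=0.02)

    def test_per_class_trial_means_converge_to_subject_means(self, rng):
        model = calibrated_emission_model()
        sub = SubjectEmissions(model, rng)
        draws = np.array([sub.draw("high", rng) for _ in range(10_000)])
        sem = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - sub.mean_high) < 3 * sem

    def test_incompatible_within_sd_clamps_with_warning(self, rng):
        model = EmissionModel(
            population_mean_high=0.98,
            population_mean_low=0.02,
            between_subject_sd_high=0.0,
            between_subject_sd_low=0.0,
            within_subject_sd=0.3,
        )
        sub = SubjectEmissions(model, rng)
        with pytest.warns(RuntimeWarning, match="clamping"):
            p = sub.draw("high", rng)
        assert 0.0 < p < 1.0

    def test_emission_log_schema(self, small_sequence, calibrated_model):
        log = sample_emissions(small_sequence, calibrated_model, seed=3)
        assert list(log.columns) == ["subject", "session", "trial", "label", "p_pain"]
        assert len(log) == 30
        assert log["p_pain"].between(0, 1).all()


class TestRatings:
    def test_constant_series_when_all_effects_zero(self, small_sequence):
        params = RatingGenParams(
            beta0=4.0, beta1=0.0, noise_sd=0.0, stimulus_effect=0.0, session_drift=0.0
        )
        r = generate_ratings(small_sequence, params, seed=0)
        np.testing.assert_allclose(r["rating"], 4.0)

    def test_noiseless_generation_recovers_beta1_exactly(self, study_sequence):
        params = RatingGenParams(beta1=0.8, omega=10.0, noise_sd=0.0)
        r = generate_ratings(study_sequence, params, seed=0)
        pred = frequency.build_predictors(study_sequence, omega=params.omega)
        resid = frequency.rating_residuals(r["rating"], pred["identity"], pred["session"])
        fit = frequency.FrequencyLearningModel(resid, study_sequence).fit(omega_grid=(10.0,))
        assert fit.beta1 == pytest.approx(0.8, abs=1e-8)

    def test_positive_coupling_gives_positive_residual_correlation(self, study_sequence):
        params = RatingGenParams(beta1=0.8, omega=10.0, noise_sd=0.3)
        r = generate_ratings(study_sequence, params, seed=1)
        pred = frequency.build_predictors(study_sequence, omega=10.0)
        resid = frequency.rating_residuals(r["rating"], pred["identity"], pred["session"])
        assert np.corrcoef(resid, pred["surprisal"])[0, 1] > 0

    def test_ratings_clipped_to_scale(self, study_sequence):
        params = RatingGenParams(beta0=9.5, beta1=2.0, noise_sd=3.0)
        r = generate_ratings(study_sequence, params, seed=2)
        assert r["rating"].between(0, 10).all()

    def test_null_coupling_fisher_z_centered_on_zero(self):
        # type-I calibration: beta1 = 0 must not produce a group-level
        # residual-surprisal correlation
        seqs = generate_trial_sequences(19, 6, 30, seed=21)
        params = RatingGenParams(beta1=0.0, omega=10.0, noise_sd=0.5)
        xs, ys = {}, {}
        for i, (sid, seq) in enumerate(seqs.items()):
            r = generate_ratings(seq, params, seed=300 + i)
            pred = frequency.build_predictors(seq, omega=10.0)
            resid = frequency.rating_residuals(r["rating"], pred["identity"], pred["session"])
            xs[sid] = pred["surprisal"].to_numpy()
            ys[sid] = resid
        fz = frequency.fisher_z_correlations(xs, ys)
        assert fz.pvalue > 0.05


class TestContrastTraces:
    def test_equal_gains_no_noise_gives_zero_change(self):
        params = ContrastGenParams(
            n_subjects=3, trace_noise_sd=0.0, gain_subject_sd=0.0,
            gain_pre_experimental=1.0, gain_post_experimental=1.0,
        )
        traces = generate_contrast_traces(params, seed=0)
        from painloop.contrast import TemporalContrastAnalysis

        mags = TemporalContrastAnalysis(traces).magnitudes()
        wide = mags.pivot_table(index=["subject", "group"], columns="condition", values="magnitude")
        np.testing.assert_allclose(wide["post"] - wide["pre"], 0.0, atol=1e-12)

    def test_all_ratings_within_scale(self):
        traces = generate_contrast_traces(ContrastGenParams(n_subjects=2, trace_noise_sd=2.0), seed=1)
        assert traces["rating"].between(0, 10).all()

    def test_phases_are_contiguous_7s_blocks(self):
        traces = generate_contrast_traces(ContrastGenParams(n_subjects=1, n_trials=1), seed=0)
        one = traces[(traces["subject"] == traces["subject"].iloc[0]) & (traces["condition"] == "pre")]
        by_phase = one.groupby("phase")["time_s"]
        assert by_phase.min().tolist() == [0.0, 7.0, 14.0]
        assert by_phase.max().tolist() == [6.0, 13.0, 20.0]


class TestIntensityCalibration:
    def test_exact_logistic_inversion_closed_form(self):
        c = np.linspace(1, 9, 14)
        ratings = 10.0 / (1.0 + np.exp(-(c - 5.0) / 1.0))
        c1, c8 = calibrate_intensities(c, ratings)
        assert c1 == pytest.approx(5.0 - np.log(9.0), abs=1e-4)
        assert c8 == pytest.approx(5.0 + np.log(4.0), abs=1e-4)

    def test_noisy_recovery_within_3se(self):
        rng = np.random.default_rng(8)
        true_c1 = 5.0 - np.log(9.0)
        true_c8 = 5.0 + np.log(4.0)
        hits = 0
        for _ in range(20):
            c = np.sort(rng.uniform(1, 9, size=14))
            r = np.clip(10.0 / (1.0 + np.exp(-(c - 5.0) / 1.0)) + rng.normal(0, 0.3, 14), 0, 10)
            c1, c8 = calibrate_intensities(c, r)
            hits += (abs(c1 - true_c1) < 0.6) and (abs(c8 - true_c8) < 0.6)
        assert hits >= 18

    def test_constant_ratings_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            calibrate_intensities([1, 2, 3, 4], [5, 5, 5, 5])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            calibrate_intensities([1, 2, 3], [1, 2, 3])


def test_generators_bit_identical_under_fixed_seed(study_sequence):
    model = calibrated_emission_model()
    a = sample_emissions(study_sequence, model, seed=99)
    b = sample_emissions(study_sequence, model, seed=99)
    assert a.equals(b)
    pa = generate_contrast_traces(ContrastGenParams(n_subjects=2), seed=5)
    pb = generate_contrast_traces(ContrastGenParams(n_subjects=2), seed=5)
    assert pa.equals(pb)
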