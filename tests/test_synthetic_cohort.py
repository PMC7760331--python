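"""Simulator tests: determinism, trace arithmetic, artifacts, staircase."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from pupilarousal import (CohortConfig, ConfigError, generate_cohort,
                          generate_subject_traces, inject_artifacts,
                          iter_cohort, read_cohort,
                          simulate_adaptive_deadline, write_cohort)
from pupilarousal.preprocess import window_mean_dilation
from pupilarousal.synthetic_cohort import (_DEP_COUNT_PROBS,
                                           _pooled_count_moments)

from conftest import clean_config


def _slopes(reward=0.12, neutral=0.07, control=-0.07):
    return {"reward": reward, "neutral": neutral, "control": control}


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_control=0)
        with pytest.raises(ConfigError):
            CohortConfig(anticipation_duration=0)
        with pytest.raises(ConfigError):
            CohortConfig(target_corr_dilation_symptoms=1.0)
        with pytest.raises(ConfigError):
            CohortConfig(gaze_excursion_prob=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = clean_config(seed=7, trials_per_condition=4)
        path = tmp_path / "cohort.yaml"
        cfg.to_yaml(path)
        assert CohortConfig.from_yaml(path) == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("cohort:\n  n_controll: 5\n")
        with pytest.raises(ConfigError):
            CohortConfig.from_yaml(path)

    def test_depressed_marginal_matches_acute_fraction(self):
        # P(count >= 5) for the depressed group reproduces 23/41
        assert _DEP_COUNT_PROBS[5:].sum() == pytest.approx(23 / 41, abs=1e-9)


class TestTraces:
    def test_trace_length_is_duration_times_rate_plus_one(self):
        cfg = clean_config()
        traces = generate_subject_traces(_slopes(), ["reward"], cfg,
                                         np.random.default_rng(0))
        assert len(traces[0].time) == 1751  # (1 s + 6 s) * 250 Hz + 1
        # 6 s anticipation at 250 Hz spans 1501 samples
        assert int((traces[0].time >= 0).sum()) == 1501

    def test_noiseless_mean_dilation_equals_programmed_slope(self):
        cfg = clean_config()
        traces = generate_subject_traces(_slopes(), ["reward", "control"],
                                         cfg, np.random.default_rng(0))
        assert window_mean_dilation(traces[0]) == pytest.approx(0.12, abs=1e-12)
        assert window_mean_dilation(traces[1]) == pytest.approx(-0.07, abs=1e-12)

    def test_control_condition_constricts(self):
        # no-response control: the pupil constricts (negative dilation)
        cfg = clean_config()
        traces = generate_subject_traces(_slopes(), ["control"], cfg,
                                         np.random.default_rng(0))
        assert window_mean_dilation(traces[0]) < 0

    def test_noise_is_reproducible_and_additive(self):
        cfg = CohortConfig()
        t1 = generate_subject_traces(_slopes(), ["reward"], cfg,
                                     np.random.default_rng(5))[0]
        t2 = generate_subject_traces(_slopes(), ["reward"], cfg,
                                     np.random.default_rng(5))[0]
        np.testing.assert_array_equal(t1.pupil, t2.pupil)
        clean = generate_subject_traces(_slopes(), ["reward"], cfg,
                                        np.random.default_rng(5),
                                        noise_sd=0.0)[0]
        assert not np.allclose(t1.pupil, clean.pupil)


class TestArtifacts:
    def test_zero_rates_leave_trace_unchanged(self):
        cfg = clean_config()
        trace = generate_subject_traces(_slopes(), ["reward"], cfg,
                                        np.random.default_rng(0))[0]
        before = trace.pupil.copy()
        out, mask = inject_artifacts(trace, cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(out.pupil, before)
        assert out.valid.all() and not mask.any()

    def test_single_200ms_blink_flags_50_samples(self):
        cfg = clean_config(blink_duration_mean=0.2)
        trace = generate_subject_traces(_slopes(), ["reward"], cfg,
                                        np.random.default_rng(0))[0]
        # force exactly one blink of exactly the mean duration
        rng = np.random.default_rng(3)

        class OneBlink:
            def poisson(self, lam):
                return 1

            def normal(self, m, s):
                return m

            def integers(self, lo, hi):
                return rng.integers(lo, hi)

            def random(self):
                return 1.0  # never trigger a gaze excursion

        out, mask = inject_artifacts(trace, cfg, OneBlink())
        assert int(mask.sum()) == 50  # 0.2 s * 250 Hz
        assert int((~out.valid).sum()) == 50

    def test_blink_count_matches_poisson_rate(self):
        # rate lambda blinks/min over many simulated minutes: empirical event
        # count within 3 standard errors of the Poisson expectation
        cfg = CohortConfig(blink_rate=12.0, gaze_excursion_prob=0.0)
        trace = generate_subject_traces(_slopes(), ["reward"], cfg,
                                        np.random.default_rng(11),
                                        noise_sd=0.0)[0]
        minutes = len(trace.time) / cfg.sampling_rate / 60.0
        lam = cfg.blink_rate * minutes
        reps = 400
        total_events = 0
        for i in range(reps):
            _, mask = inject_artifacts(trace, cfg,
                                       np.random.default_rng(5000 + i))
            # contiguous missing episodes ~ blink events (merging is rare)
            edges = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
            total_events += int((edges == 1).sum())
        expected = reps * lam
        se = np.sqrt(expected)
        # small downward allowance for occasionally-merged blinks
        assert abs(total_events - expected) < 3 * se + 0.01 * expected

    def test_mask_flags_exactly_the_altered_samples(self):
        cfg = CohortConfig(blink_rate=20.0, gaze_excursion_prob=1.0)
        trace = generate_subject_traces(_slopes(), ["reward"], cfg,
                                        np.random.default_rng(2))[0]
        before_p = trace.pupil.copy()
        before_gx = trace.gaze_x.copy()
        out, mask = inject_artifacts(trace, cfg, np.random.default_rng(8))
        changed = (~np.isclose(out.pupil, before_p) | np.isnan(out.pupil)
                   != np.isnan(before_p)) | (out.gaze_x != before_gx)
        altered = np.isnan(out.pupil) | (out.gaze_x != before_gx)
        assert np.array_equal(np.flatnonzero(altered), np.flatnonzero(mask))


class TestAdaptiveDeadline:
    def test_generous_initial_deadline_makes_first_trial_succeed(self):
        success, traj = simulate_adaptive_deadline([0.3], initial=5.0)
        assert success[0]
        assert traj[0] == 5.0

    def test_constant_rt_success_fraction_near_half(self):
        # staircase oscillates around a constant RT -> ~50% success
        success, _ = simulate_adaptive_deadline(np.full(200, 0.3))
        assert 0.4 <= success.mean() <= 0.6

    def test_stationary_rts_converge_to_half(self):
        rng = np.random.default_rng(17)
        rts = rng.normal(0.3, 0.05, 10_000)
        success, _ = simulate_adaptive_deadline(rts)
        assert abs(success.mean() - 0.5) <= 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            simulate_adaptive_deadline([])


class TestCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_control=3, n_depressed=4, seed=5)
        for d in ("a", "b"):
            datasets, _ = generate_cohort(cfg)
            write_cohort(datasets, tmp_path / d)
        for f in sorted((tmp_path / "a").rglob("*.csv")):
            other = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == other.read_bytes(), f.name

    def test_iter_cohort_matches_generate_cohort(self):
        cfg = CohortConfig(n_control=2, n_depressed=3, seed=9)
        datasets, _ = generate_cohort(cfg)
        for ds, (it_ds, _) in zip(datasets, iter_cohort(cfg)):
            assert ds.subject_id == it_ds.subject_id
            assert ds.clinical == it_ds.clinical
            for a, b in zip(ds.traces, it_ds.traces):
                np.testing.assert_array_equal(a.pupil, b.pupil)

    def test_trial_counts_and_interleaving(self, small_cohort):
        cfg, datasets, _ = small_cohort
        for ds in datasets:
            conds = [t.condition for t in ds.traces]
            for c in ("reward", "neutral", "control"):
                assert conds.count(c) == cfg.trials_per_condition
            # pseudo-random interleaving: not fully blocked
            assert conds != sorted(conds)

    def test_clinical_invariants(self, small_cohort):
        _, datasets, _ = small_cohort
        for ds in datasets:
            c = ds.clinical
            assert 0 <= c.symptom_count <= 9
            if c.group == "control":
                assert c.symptom_count <= 3
            assert c.acute_flag == (c.symptom_count >= 5)
            assert 0 <= c.symptom_impact <= 10
            assert c.anhedonia >= 0

    def test_condition_ordering_of_population_slopes(self, small_cohort):
        _, _, gt = small_cohort
        mean_slopes = gt.slopes.mean(axis=0)
        assert mean_slopes[0] > mean_slopes[1] > 0 > mean_slopes[2]

    def test_ground_truth_matrix_is_psd(self, small_cohort):
        _, _, gt = small_cohort
        assert np.linalg.eigvalsh(gt.corr_matrix).min() > -1e-12

    def test_infeasible_target_raises(self):
        with pytest.raises(ConfigError):
            generate_cohort(CohortConfig(n_control=2, n_depressed=2,
                                         target_corr_dilation_symptoms=-0.99))

    def test_artifact_mask_matches_missing_samples(self, small_cohort):
        _, datasets, gt = small_cohort
        ds = datasets[0]
        for trace, mask in zip(ds.traces, gt.artifact_masks[ds.subject_id]):
            blink = ~trace.valid
            assert not np.any(blink & ~mask)  # every blink sample is masked

    def test_pooled_count_moments_match_empirical(self):
        cfg = CohortConfig(n_control=400, n_depressed=600, seed=3,
                           target_corr_dilation_symptoms=0.0,
                           target_corr_dilation_rt=0.0)
        m, sd = _pooled_count_moments(cfg)
        rng = np.random.default_rng(0)
        counts = []
        from pupilarousal.synthetic_cohort import (_DEP_COUNT_PROBS,
                                                   CONTROL_COUNT_PROBS)
        counts = np.concatenate([
            rng.choice(4, 40000, p=CONTROL_COUNT_PROBS),
            rng.choice(10, 60000, p=_DEP_COUNT_PROBS)])
        assert m == pytest.approx(counts.mean(), abs=0.05)
        assert sd == pytest.approx(counts.std(), abs=0.05)


class TestFileRoundTrip:
    def test_round_trip_preserves_values(self, tmp_path, small_cohort):
        _, datasets, _ = small_cohort
        write_cohort(datasets[:3], tmp_path)
        back = read_cohort(tmp_path)
        assert [d.subject_id for d in back] == [d.subject_id for d in datasets[:3]]
        for a, b in zip(datasets[:3], back):
            assert a.clinical == b.clinical
            for ta, tb in zip(a.traces, b.traces):
                assert ta.condition == tb.condition
                valid = ta.valid
                np.testing.assert_allclose(tb.pupil[valid], ta.pupil[valid],
                                           atol=1e-9)
                np.testing.assert_allclose(tb.time, ta.time, atol=1e-9)
                np.testing.assert_array_equal(tb.valid, ta.valid)
            for ra, rb in zip(a.trials, b.trials):
                assert ra.condition == rb.condition
                assert ra.success == rb.success
                assert (np.isnan(ra.rt) and np.isnan(rb.rt)) or \
                    ra.rt == pytest.approx(rb.rt, abs=1e-9)


@given(st.integers(min_value=0, max_value=10**6))
def test_staircase_success_depends_only_on_rt_vs_deadline(seed):
    rng = np.random.default_rng(seed)
    rts = rng.uniform(0.1, 0.6, 50)
    success, traj = simulate_adaptive_deadline(rts)
    np.testing.assert_array_equal(success, rts < traj)


class TestEffectCalibration:
    """Realized correlations of measured scores against configured targets."""

    def test_target_correlation_realized_at_large_n(self):
        from pupilarousal import simulate_scored
        from pupilarousal.bayes import pearson_r
        cfg = CohortConfig(n_control=760, n_depressed=1240, seed=11,
                           missing_run_prob=0.0)
        scored = simulate_scored(cfg)
        r_sym = pearson_r(scored["mean_dilation_reward"].to_numpy(),
                          scored["symptom_count"].to_numpy())
        assert abs(r_sym - (-0.5)) <= 0.05
        r_rt = pearson_r(scored["mean_dilation_reward"].to_numpy(),
                         scored["median_rt_reward"].to_numpy())
        assert abs(r_rt - (-0.5)) <= 0.05
        # measured condition means preserve the programmed ordering
        means = scored[["mean_dilation_reward", "mean_dilation_neutral",
                        "mean_dilation_control"]].mean()
        assert means.iloc[0] > means.iloc[1] > 0 > means.iloc[2]

    def test_null_target_gives_null_correlation(self):
        from pupilarousal import simulate_scored
        from pupilarousal.bayes import pearson_r
        cfg = CohortConfig(n_control=760, n_depressed=1240, seed=13,
                           missing_run_prob=0.0,
                           target_corr_dilation_symptoms=0.0,
                           target_corr_dilation_rt=0.0)
        scored = simulate_scored(cfg)
        r = pearson_r(scored["mean_dilation_reward"].to_numpy(),
                      scored["symptom_count"].to_numpy())
        assert abs(r) <= 0.05
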