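"""Adaptation regimes over the retrainable classifier state."""

import numpy as np
import pytest

from cvepbci.adaptation import (
    calibrate_batch,
    classify_trial,
    errp_calibrate_2target,
    errp_gated_adapt,
    init_random_templates,
    run_adaptation_loop,
    supervised_adapt,
    unsupervised_adapt,
)
from cvepbci.synthetic import ForwardModel, simulate_trial
from cvepbci.templates import classify

from conftest import SMALL_CHANNELS, SMALL_FS, make_trials

N_CH = len(SMALL_CHANNELS)


def fresh_state(layout, samples_per_trial, seed=0):
    return init_random_templates(layout, samples_per_trial, seed=seed,
                                 fs=SMALL_FS, n_channels=N_CH)


class TestRandomInit:
    def test_deterministic_given_seed(self, layout, samples_per_trial):
        a = fresh_state(layout, samples_per_trial, seed=5)
        b = fresh_state(layout, samples_per_trial, seed=5)
        np.testing.assert_array_equal(a.template_set.base_template,
                                      b.template_set.base_template)

    def test_different_seeds_differ(self, layout, samples_per_trial):
        a = fresh_state(layout, samples_per_trial, seed=1)
        b = fresh_state(layout, samples_per_trial, seed=2)
        assert not np.allclose(a.template_set.base_template,
                               b.template_set.base_template)

    def test_random_templates_classify_at_chance(self, layout, code, samples_per_trial):
        state = fresh_state(layout, samples_per_trial, seed=3)
        model = ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=0.0)
        rng = np.random.default_rng(0)
        targets = rng.integers(0, 32, size=320)
        hits = sum(
            classify_trial(state, simulate_trial(model, layout, code, int(k), rng))[0] == k
            for k in targets
        )
        # Binomial(320, 1/32): 99% interval roughly [2, 20]
        assert hits <= 25


class TestSupervisedAdaptation:
    def test_calibration_reaches_perfect_accuracy_at_high_snr(self, layout, code):
        model = ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=1.0)
        ns = 126
        state = fresh_state(layout, ns, seed=0)
        targets = (list(range(32)) * 2)
        for i, (trial, k) in enumerate(
            zip(make_trials(model, layout, code, targets, seed=10), targets)
        ):
            state = supervised_adapt(state, trial, k)
        assert state.generation == 64
        fresh = make_trials(model, layout, code, list(range(32)) * 2, seed=99)
        hits = sum(classify_trial(state, t)[0] == t.attended_target for t in fresh)
        assert hits == 64

    def test_shift_commutation(self, layout, code, calibrated_state):
        # classifying a target-k trial against the full set equals
        # classifying the frame-0-aligned trial against template 0 alone
        model = ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=2.0)
        k = 11
        trial = simulate_trial(model, layout, code, k, seed=0)
        state = calibrated_state
        filt = state.spatial_filter.apply(trial.data)
        d_raw = classify(filt, state.template_set)[1][k]
        aligned = state.spatial_filter.apply(state.align_to_base(trial.data, k))
        d_aligned = classify(aligned, state.template_set)[1][0]
        assert d_raw == pytest.approx(d_aligned, rel=1e-9)

    def test_buffer_is_a_multiset(self, layout, code, small_model):
        trial = make_trials(small_model, layout, code, [4], seed=0)[0]
        state = fresh_state(layout, trial.n_samples, seed=0)
        state = supervised_adapt(state, trial, 4)
        state = supervised_adapt(state, trial, 4)
        assert len(state.buffer) == 2
        np.testing.assert_array_equal(state.buffer[0][0], state.buffer[1][0])

    def test_contamination_is_zero(self, layout, code, small_model):
        targets = [3, 17, 3, 8]
        trials = make_trials(small_model, layout, code, targets, seed=1)
        state = fresh_state(layout, trials[0].n_samples, seed=0)
        for t, k in zip(trials, targets):
            state = supervised_adapt(state, t, k)
        assert all(ev.buffer_label == ev.true_label for ev in state.events)


class TestUnsupervisedAdaptation:
    def test_correct_prediction_equals_supervised_step(self, layout, code,
                                                       calibrated_state):
        model = ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=1.0)
        trial = simulate_trial(model, layout, code, 7, seed=1)
        s1 = calibrated_state.clone()
        s2 = calibrated_state.clone()
        assert classify_trial(s1, trial)[0] == 7  # high SNR: prediction correct
        s1 = unsupervised_adapt(s1, trial)
        s2 = supervised_adapt(s2, trial, 7)
        np.testing.assert_allclose(s1.template_set.base_template,
                                   s2.template_set.base_template, atol=1e-9)

    def test_misclassified_trial_contaminates_buffer(self, layout, code,
                                                     calibrated_state):
        model = ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=12.0)
        rng = np.random.default_rng(3)
        state = calibrated_state.clone()
        clean_template = state.template_set.base_template.copy()
        n0 = len(state.buffer)
        wrong = 0
        for i in range(12):
            trial = simulate_trial(model, layout, code, int(rng.integers(32)), rng)
            pred, _ = classify_trial(state, trial)
            state = unsupervised_adapt(state, trial)
            wrong += pred != trial.attended_target
        assert wrong > 0  # noisy regime indeed produces label errors
        contaminated = [ev for ev in state.events[-12:]
                        if ev.buffer_label != ev.true_label]
        assert len(contaminated) == wrong


class TestErrPGatedAdaptation:
    def test_detected_errp_leaves_state_untouched(self, layout, code,
                                                  calibrated_state, small_model):
        state = calibrated_state.clone()
        trial = make_trials(small_model, layout, code, [5], seed=2)[0]
        gen = state.generation
        n = len(state.buffer)
        state = errp_gated_adapt(state, trial, errp_detected=True)
        assert state.generation == gen
        assert len(state.buffer) == n
        assert state.events[-1].action == "rejected"

    def test_oracle_detector_keeps_buffer_clean(self, layout, code, calibrated_state):
        # perfect gating at ~70% base accuracy: zero contamination
        model = ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=6.0)
        rng = np.random.default_rng(4)
        state = calibrated_state.clone()
        for i in range(25):
            k = int(rng.integers(32))
            trial = simulate_trial(model, layout, code, k, rng)
            pred, _ = classify_trial(state, trial)
            state = errp_gated_adapt(state, trial, errp_detected=pred != k)
        added = [ev for ev in state.events[-25:] if ev.action != "rejected"]
        assert all(ev.buffer_label == ev.true_label for ev in added)

    def test_blind_detector_equals_unsupervised(self, layout, code, calibrated_state):
        model = ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=8.0)
        s1 = calibrated_state.clone()
        s2 = calibrated_state.clone()
        rng1 = np.random.default_rng(5)
        for i in range(8):
            trial = simulate_trial(model, layout, code, int(rng1.integers(32)), rng1)
            s1 = errp_gated_adapt(s1, trial, errp_detected=False)  # sensitivity 0
            s2 = unsupervised_adapt(s2, trial)
        np.testing.assert_allclose(s1.template_set.base_template,
                                   s2.template_set.base_template)


class TestErrPCalibration2Target:
    def test_flip_rule(self, layout, code, calibrated_state, small_model):
        pair = (9, 22)
        state = calibrated_state.clone()
        trial = make_trials(small_model, layout, code, [9], seed=6)[0]
        pred, _ = classify_trial(state, trial, candidates=list(pair))
        state = errp_calibrate_2target(state, trial, errp_detected=True, pair=pair)
        ev = state.events[-1]
        assert ev.action == "added_as_flipped"
        assert ev.buffer_label == ({9, 22} - {pred}).pop()

    def test_no_errp_keeps_predicted_label(self, layout, code, calibrated_state,
                                           small_model):
        state = calibrated_state.clone()
        trial = make_trials(small_model, layout, code, [22], seed=7)[0]
        pred, _ = classify_trial(state, trial, candidates=[9, 22])
        state = errp_calibrate_2target(state, trial, errp_detected=False, pair=(9, 22))
        assert state.events[-1].buffer_label == pred

    def test_identical_pair_rejected(self, layout, code, calibrated_state, small_model):
        trial = make_trials(small_model, layout, code, [9], seed=8)[0]
        with pytest.raises(ValueError):
            errp_calibrate_2target(calibrated_state.clone(), trial, False, (9, 9))


class TestRetrainLoopContract:
    def test_synchronous_generation_counts_accepted_trials(self, layout, code,
                                                           small_model):
        targets = [1, 2, 3, 4, 5, 6]
        trials = make_trials(small_model, layout, code, targets, seed=9)
        state = fresh_state(layout, trials[0].n_samples, seed=0)
        run_adaptation_loop(state, trials, regime="supervised", true_labels=targets)
        assert state.generation == len(targets)

    def test_deferred_mode_reaches_identical_buffer(self, layout, code, small_model):
        targets = [7, 1, 30, 12, 0, 25, 9]
        trials = make_trials(small_model, layout, code, targets, seed=10)
        sync = fresh_state(layout, trials[0].n_samples, seed=0)
        run_adaptation_loop(sync, trials, regime="supervised", true_labels=targets,
                            retrain_latency_trials=0)
        deferred = fresh_state(layout, trials[0].n_samples, seed=0)
        events = run_adaptation_loop(deferred, trials, regime="supervised",
                                     true_labels=targets, retrain_latency_trials=2)
        assert len(sync.buffer) == len(deferred.buffer)
        for (d1, l1), (d2, l2) in zip(sync.buffer, deferred.buffer):
            assert l1 == l2
            np.testing.assert_array_equal(d1, d2)
        assert all(ev.retrain_latency_trials == 2 for ev in events)
        assert deferred.generation < sync.generation  # batched retrains

    def test_zero_trials_no_events(self, layout, samples_per_trial):
        state = fresh_state(layout, samples_per_trial, seed=0)
        assert run_adaptation_loop(state, [], regime="unsupervised") == []

    def test_unknown_regime_rejected(self, layout, samples_per_trial):
        state = fresh_state(layout, samples_per_trial, seed=0)
        with pytest.raises(ValueError):
            run_adaptation_loop(state, [], regime="bogus")


class TestBufferAudit:
    def test_unsupervised_contamination_equals_online_error_rate(self, layout, code,
                                                                 calibrated_state):
        model = ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=7.0)
        rng = np.random.default_rng(11)
        state = calibrated_state.clone()
        targets = [int(rng.integers(32)) for _ in range(20)]
        trials = [simulate_trial(model, layout, code, k, rng, trial_index=i)
                  for i, k in enumerate(targets)]
        events = run_adaptation_loop(state, trials, regime="unsupervised")
        errors = sum(ev.predicted_label != ev.true_label for ev in events)
        contamination = sum(ev.buffer_label != ev.true_label for ev in events)
        assert contamination == errors

    def test_generation_strictly_increases(self, layout, code, small_model):
        trials = make_trials(small_model, layout, code, [0, 1, 2], seed=12)
        state = fresh_state(layout, trials[0].n_samples, seed=0)
        gens = []
        for t in trials:
            state = unsupervised_adapt(state, t)
            gens.append(state.generation)
        assert gens == sorted(set(gens))
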