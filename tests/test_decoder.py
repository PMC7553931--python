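"""Correlation scoring, synchronous classification, and dynamic-window mechanics."""

import copy

import numpy as np
import pytest

import cvep
from cvep.decoder import DecoderState, classify_window, correlation_scores, run_session
from cvep.model import CvepDecoder


class TestCorrelationScores:
    def test_template_buffer_scores_near_one(self, clean_results32, clean_model32, cb32):
        for k in (1, 13, 32):
            trial = cvep.simulate_trial(clean_model32, cb32, k)
            scores = correlation_scores(trial, clean_results32)
            assert np.argmax(scores) + 1 == k
            # zero-phase filter transients sit at the trial edges of the
            # buffer but are circularly shifted in the class templates, so
            # the self-match is close to, not exactly, 1
            assert scores[k - 1] > 0.95

    def test_short_buffer_rejected(self, clean_results32):
        with pytest.raises(ValueError, match="minimum window"):
            correlation_scores(np.ones((8, 120)), clean_results32)

    def test_all_zero_buffer_rejected(self, clean_results32):
        with pytest.raises(ValueError):
            correlation_scores(np.zeros((8, 300)), clean_results32)

    def test_single_class_yields_single_score(self, clean_model32):
        cb1 = cvep.build_codebook(cvep.DEFAULT_MSEQUENCE, 1, 0)
        trials = cvep.simulate_training_set(clean_model32, cb1, 2, seed=1)
        res = CvepDecoder(trials, cb1).fit()
        scores = correlation_scores(trials.trials[0], res)
        assert scores.shape == (1,)

    def test_pearson_single_band_matches_direct_formula(self, clean_trials32, cb32):
        res = CvepDecoder(clean_trials32, cb32, s=1, filterbank=False,
                          score_method="pearson").fit()
        buf = clean_trials32.trials[5]
        scores = correlation_scores(buf, res)
        bm = res.band_models[0]
        filt = cvep.apply_subband(buf, res.bank, 0)
        p = (bm.filters.T @ filt).ravel()
        for k in range(cb32.K):
            r = bm.projected[k].ravel()
            expected = abs(np.corrcoef(p, r)[0, 1])
            assert scores[k] == pytest.approx(expected, abs=1e-10)

    def test_sign_invariance_of_filters(self, clean_results32, clean_trials32):
        """Negating any spatial filter leaves all scores unchanged."""
        buf = clean_trials32.trials[10]
        base = correlation_scores(buf, clean_results32)
        flipped = copy.deepcopy(clean_results32)
        for bm in flipped.band_models:
            bm.filters = bm.filters * np.array([-1, 1, -1, 1])
            bm.projected = np.stack([bm.filters.T @ X for X in bm.templates.class_templates])
        assert np.allclose(correlation_scores(buf, flipped), base, atol=1e-9)

    def test_weight_concentration_reduces_to_single_band(self, clean_trials32, cb32):
        """Combined score with weights (1,0,0) equals the single-band score."""
        fb = CvepDecoder(clean_trials32, cb32).fit()
        fb.bank.weights = np.array([1.0, 0.0, 0.0])
        single = CvepDecoder(clean_trials32, cb32, bands=((8.0, 60.0),)).fit()
        buf = clean_trials32.trials[7]
        assert np.allclose(correlation_scores(buf, fb),
                           correlation_scores(buf, single), atol=1e-9)


class TestClassifyWindow:
    def test_noise_free_trials_classified_correctly(self, clean_results32, clean_trials32):
        pred = clean_results32.predict(clean_trials32)
        assert np.array_equal(pred, clean_trials32.labels)

    def test_margin_definition(self, clean_results32, clean_trials32):
        d = classify_window(clean_trials32.trials[0], clean_results32)
        top2 = np.sort(d.scores)[::-1][:2]
        assert d.margin == pytest.approx(top2[0] - top2[1])
        assert d.window_used == pytest.approx(2.1)

    def test_accuracy_nondecreasing_in_snr(self, cb4):
        """Monte-Carlo: mean accuracy rises with SNR."""
        accs = []
        for snr in (0.05, 0.4):
            vals = []
            for seed in range(3):
                fm = cvep.make_forward_model(4, 600, snr=snr, alpha_amp=0.5, seed=50 + seed)
                tr = cvep.simulate_training_set(fm, cb4, 2, seed=60 + seed)
                te = cvep.simulate_training_set(fm, cb4, 1, seed=70 + seed)
                res = CvepDecoder(tr, cb4).fit()
                vals.append(np.mean(res.predict(te) == te.labels))
            accs.append(np.mean(vals))
        assert accs[1] > accs[0]


class TestPushBlock:
    def test_no_classification_before_min_window(self, clean_results32, clean_trials32):
        state = DecoderState(clean_results32, beta=0.0)
        trial = clean_trials32.trials[2]
        for b in range(4):  # 4 blocks = 120 samples < 150
            assert state.push_block(trial[:, b * 30:(b + 1) * 30]) is None
        assert state.n_y == 120

    def test_block_shape_enforced(self, clean_results32):
        state = DecoderState(clean_results32)
        with pytest.raises(ValueError, match="block"):
            state.push_block(np.zeros((8, 31)))

    def test_shuffle_out_bookkeeping(self, noisy_results32, cb32):
        """At n_y = 1260 the next push drops 630 columns: n_y becomes 660."""
        fm, res = noisy_results32
        state = DecoderState(res, beta=2.0)  # unreachable: window only extends
        noise = cvep.simulate_noise(fm, 50 * 630, seed=5)
        i = 0
        while state.n_y < 1260:
            state.push_block(noise[:, i * 30:(i + 1) * 30])
            i += 1
        assert state.n_y == 1260
        state.push_block(noise[:, i * 30:(i + 1) * 30])
        assert state.n_y == 660

    def test_buffer_never_exceeds_template_length(self, noisy_results32):
        fm, res = noisy_results32
        state = DecoderState(res, beta=2.0)
        noise = cvep.simulate_noise(fm, 100 * 30, seed=6)
        for b in range(100):
            state.push_block(noise[:, b * 30:(b + 1) * 30])
            assert state.n_y <= 1260
            assert state.n_y % 30 == 0

    def test_async_decision_matches_synchronous(self, clean_results32, clean_model32, cb32):
        """With beta = 0 and a full-trial buffer, push_block equals classify_window."""
        trial = cvep.simulate_trial(clean_model32, cb32, 19)
        state = DecoderState(clean_results32, beta=2.0)
        for b in range(41):
            state.push_block(trial[:, b * 30:(b + 1) * 30])
        state.beta = 0.0
        decision = state.push_block(trial[:, 41 * 30: 42 * 30])
        ref = classify_window(trial, clean_results32)
        assert decision is not None
        assert decision.target == ref.target
        assert np.allclose(decision.scores, ref.scores)
        assert state.n_y == 0  # buffer cleared after the decision

    def test_first_eligible_window_on_clean_data(self, clean_results32, clean_model32, cb32):
        """Noise-free data triggers at 0.25 s with the correct target."""
        trial = cvep.simulate_trial(clean_model32, cb32, 7)
        state = DecoderState(clean_results32, beta=0.1)
        decision = None
        for b in range(42):
            decision = state.push_block(trial[:, b * 30:(b + 1) * 30])
            if decision:
                break
        assert decision.target == 7
        assert decision.window_used == pytest.approx(0.25)
        assert decision.margin > 0.1


class TestRunSession:
    def test_noise_free_intents_all_recovered(self, clean_results32, clean_model32, cb32):
        intents = [3, 17, 25, 1, 32]
        stream = cvep.simulate_online_stream(clean_model32, cb32, intents, seed=5)
        session = run_session(stream, clean_results32)
        assert [e.decision.target for e in session.events] == intents
        assert all(e.correct for e in session.events)
        for e in session.events:
            assert e.selection_time == pytest.approx(e.decision.elapsed + 1.0)
            assert e.decision.margin > clean_results32.beta

    def test_unreachable_threshold_preserves_non_control(self, noisy_results32, cb32):
        fm, res = noisy_results32
        stream = cvep.simulate_online_stream(fm, cb32, [4], seed=7, max_duration=3.0)
        session = run_session(stream, res, beta=1.1)
        assert session.decisions == []
        assert session.n_timeouts == 1

    def test_false_positives_decrease_with_beta(self, noisy_results32):
        """Non-control state: pure-noise selections drop as beta grows."""
        fm, res = noisy_results32
        noise = cvep.simulate_noise(fm, 40 * 600, seed=8)  # 40 s of rest EEG
        counts = []
        for beta in (0.0, 0.05, 0.1, 1.1):
            state = DecoderState(res, beta=beta)
            n = 0
            for b in range(noise.shape[1] // 30):
                if state.push_block(noise[:, b * 30:(b + 1) * 30]) is not None:
                    n += 1
            counts.append(n)
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_default_betas_by_layout(self, clean_results32, clean_results4):
        assert clean_results32.beta == pytest.approx(0.1)
        assert clean_results4.beta == pytest.approx(0.15)
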