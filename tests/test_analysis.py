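"""Onset detection, amplitude/magnitude quantification, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import apakit as ak
from apakit.types import TrialWindow


def _trace(samples, rate=32.0, channel="left_foot", t0=0.0):
    return ak.ForceTrace(np.asarray(samples, float), rate, channel, t0)


class TestBaselineStats:
    def test_constant(self):
        mean, sd = ak.baseline_stats(_trace([7.0] * 64), (0.0, 2.0))
        assert (mean, sd) == (7.0, 0.0)

    def test_hand_computed_sd(self):
        # {1,2,3,4,5}: mean 3, n-1 SD sqrt(2.5) = 1.5811...
        mean, sd = ak.baseline_stats(_trace([1, 2, 3, 4, 5], rate=1.0),
                                     (0.0, 5.0))
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(1.5811, abs=1e-4)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ak.ValidationError, match="baseline window"):
            ak.baseline_stats(_trace([1.0] * 32), (10.0, 12.0))


class TestDetectCrossing:
    def _oracle(self, trace, window, thr, direction, hold):
        """Independent scan: first index starting a run of `hold` samples
        beyond the threshold, all within the window."""
        t, x = trace.times, trace.samples
        for i in range(len(x) - hold + 1):
            idx = range(i, i + hold)
            if all(window[0] <= t[j] < window[1] for j in idx) and \
               all((x[j] > thr) if direction == "above" else (x[j] < thr)
                   for j in idx):
                return t[i]
        return None

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), hold=st.integers(1, 4),
           direction=st.sampled_from(["above", "below"]))
    def test_matches_brute_force_oracle(self, seed, hold, direction):
        rng = np.random.default_rng(seed)
        trace = _trace(rng.normal(0, 1, 80))
        window = (0.5, 2.2)
        onset = ak.detect_crossing(trace, window, mean=0.0, sd=1.0, k_sd=1.0,
                                   direction=direction, hold=hold)
        assert onset == self._oracle(trace, window, 1.0 if direction == "above"
                                     else -1.0, direction, hold)

    def test_step_function_onset(self):
        x = np.zeros(64)
        x[40:] = 10.0
        onset = ak.detect_crossing(_trace(x), (0.0, 2.0), 0.0, 1.0, 2.0,
                                   "above", hold=1)
        assert onset == 40 / 32.0

    def test_never_crossing_returns_none(self):
        assert ak.detect_crossing(_trace(np.zeros(64)), (0.0, 2.0), 0.0, 1.0,
                                  2.0, "above", hold=1) is None

    def test_single_sample_spike_debounced(self):
        x = np.zeros(64)
        x[30] = 10.0
        assert ak.detect_crossing(_trace(x), (0.0, 2.0), 0.0, 1.0, 2.0,
                                  "above", hold=3) is None

    def test_translation_equivariance(self, rng):
        x = rng.normal(0, 1, 200)
        x[120:] += 6.0
        for dt in (0.0, 1.5, 7.25):
            onset = ak.detect_crossing(_trace(x, t0=dt), (dt, dt + 6.0),
                                       0.0, 1.0, 2.0, "above", hold=2)
            base = ak.detect_crossing(_trace(x, t0=0.0), (0.0, 6.0),
                                      0.0, 1.0, 2.0, "above", hold=2)
            assert onset == pytest.approx(base + dt)


class TestStepAPA:
    def test_noiseless_amplitude_normalized(self, noiseless_step):
        rec, truth = noiseless_step()   # default fml_amplitude = 20 N
        res = ak.analyze_step_recording(rec, foot_length_cm=25.0)
        assert res.valid
        assert res.fml_amplitude_norm == pytest.approx(20.0 / 25.0, rel=1e-2)
        assert res.apa_onset < res.step_onset

    def test_zero_foot_length_rejected(self, noiseless_step):
        rec, _ = noiseless_step()
        with pytest.raises(ak.ValidationError, match="foot_length"):
            ak.analyze_step_recording(rec, foot_length_cm=0.0)

    def test_flat_marker_flags_invalid(self, noiseless_step):
        rec, _ = noiseless_step(marker_excursion=0.0)
        res = ak.analyze_step_recording(rec, foot_length_cm=25.0)
        assert not res.valid
        assert "step onset" in res.reason

    def test_matched_suppression_halves_amplitude(self, noiseless_step):
        rec_u, _ = noiseless_step(condition="unsupported")
        rec_s, _ = noiseless_step(condition="supported",
                                  suppression_factor=0.5)
        amp_u = ak.analyze_step_recording(rec_u, 25.0).fml_amplitude_norm
        amp_s = ak.analyze_step_recording(rec_s, 25.0).fml_amplitude_norm
        assert amp_s / amp_u == pytest.approx(0.5, abs=0.02)

    def test_onset_recovery_on_noisy_trials(self, step_run, schedule):
        recs, truths = step_run
        errors, biases = [], []
        for rec, truth in zip(recs, truths):
            res = ak.analyze_step_recording(rec, 25.0)
            assert res.valid
            errors.append(abs(res.apa_onset - truth.true_apa_onset))
            biases.append(res.fml_amplitude / truth.apa_amplitude_effective - 1)
        assert np.median(errors) < 2 / 1000.0 * 2  # within 2 force periods
        assert abs(np.mean(biases)) < 0.05


class TestScannerAPA:
    def test_degenerate_apa_window_gives_100pct(self):
        trace = _trace(np.full(128, 3.0))
        pct = ak.force_magnitude_pct(trace, (0.0, 4.0), (0.0, 4.0))
        assert pct == pytest.approx(100.0)

    def test_constant_force_window_fraction(self):
        # constant c: a window covering exactly 10% of the curve → 10%
        trace = _trace(np.full(321, 5.0), rate=32.0)
        pct = ak.force_magnitude_pct(trace, (1.0, 2.0), (0.0, 10.0))
        assert pct == pytest.approx(10.0)

    def test_supine_magnitude_direction(self, schedule):
        mags = {}
        for cond in ("supported", "unsupported"):
            vals = []
            for seed in range(12):
                rec, _ = ak.simulate_supine_trial(
                    ak.SupineTrialParams(seed=seed, condition=cond),
                    schedule.events.for_trial(seed))
                res = ak.analyze_scanner_recording(rec)
                if res.valid:
                    vals.append(res.force_magnitude_pct)
            mags[cond] = np.median(vals)
        assert mags["supported"] < mags["unsupported"]

    def test_onset_recovery_on_noisy_trials(self, supine_run):
        recs, truths = supine_run
        errors = []
        for rec, truth in zip(recs, truths):
            res = ak.analyze_scanner_recording(rec)
            if res.valid:
                errors.append(abs(res.apa_onset - truth.true_apa_onset))
        assert len(errors) >= 8
        assert np.median(errors) < 2 / 32.0

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 10**6), scale=st.floats(0.01, 100.0))
    def test_magnitude_bounded_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.0, 10.0, 160)
        a, b = sorted(rng.uniform(0.2, 4.8, 2))
        if b - a < 0.1:
            b = a + 0.1
        trace = _trace(x)
        pct = ak.force_magnitude_pct(trace, (a, b), (0.0, 5.0))
        assert 0.0 <= pct <= 100.0
        scaled = _trace(x * scale)
        assert ak.force_magnitude_pct(scaled, (a, b), (0.0, 5.0)) == \
            pytest.approx(pct, rel=1e-9)


class TestLowpassFilter:
    def test_dc_unchanged(self):
        tr = ak.MarkerTrace(np.full(400, 2.5), 200.0)
        np.testing.assert_allclose(ak.lowpass_filter(tr).displacement, 2.5)

    def test_50hz_attenuated_20db(self):
        t = np.arange(2000) / 200.0
        tr = ak.MarkerTrace(np.sin(2 * np.pi * 50 * t), 200.0)
        out = ak.lowpass_filter(tr, cutoff_hz=10.0).displacement
        assert np.max(np.abs(out[400:-400])) < 0.1   # > 20 dB down

    def test_1hz_preserved_within_1pct(self):
        t = np.arange(2000) / 200.0
        tr = ak.MarkerTrace(np.sin(2 * np.pi * 1.0 * t), 200.0)
        out = ak.lowpass_filter(tr, cutoff_hz=10.0).displacement
        assert np.max(np.abs(out[400:-400])) == pytest.approx(1.0, abs=0.01)

    def test_cutoff_above_nyquist_rejected(self):
        tr = ak.MarkerTrace(np.zeros(100), 200.0)
        with pytest.raises(ak.ValidationError, match="Nyquist"):
            ak.lowpass_filter(tr, cutoff_hz=150.0)


class TestWindows:
    def test_baseline_must_precede_movement(self):
        with pytest.raises(ak.ValidationError):
            TrialWindow(baseline=(5.0, 8.0), movement=(6.0, 10.0))

    def test_windows_from_events(self, supine_run):
        rec = supine_run[0][0]
        w = ak.trial_windows_from_events(rec)
        f = rec.events.frame
        assert w.baseline[0] == float(f[f.trial_type == "cross"].onset.iloc[0])
        assert w.movement[0] == float(
            f[f.trial_type == "go_circle"].onset.iloc[0])
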