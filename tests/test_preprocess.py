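"""Preprocessing chain: filtering, epoching, baseline, rejection, reference."""

import numpy as np
import pytest
from scipy import signal

from eegvuln.containers import TrialEvent
from eegvuln.preprocess import (
    bandpass_filter,
    baseline_correct,
    butter_bandpass_sos,
    interpolate_bad_channels,
    preprocess_recording,
    reject_artifacts,
    rereference_average,
    rest_to_epochs,
    segment_epochs,
    trim_epochs,
)

from conftest import make_epochs, make_recording


def _event(onset, ttype="go"):
    return TrialEvent(onset_s=onset, trial_type=ttype, block=1, cross_duration_ms=1800)


class TestBandpass:
    def test_dc_offset_removed(self):
        rec = make_recording(np.full((2, 4096), 7.0))
        out = bandpass_filter(rec, 0.5, 40.0)
        mid = out.data[:, 1024:-1024]
        assert np.max(np.abs(mid)) < 0.05

    def test_passband_sinusoid_preserved(self):
        t = np.arange(4096) / 512.0
        rec = make_recording(np.sin(2 * np.pi * 10 * t)[None, :])
        out = bandpass_filter(rec, 0.5, 40.0)
        amp = np.ptp(out.data[0, 1024:-1024]) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_matches_designed_response(self):
        # oracle: |H(f)|^2 of the designed SOS (forward-backward squares it)
        fs, f0 = 512.0, 45.0
        sos = butter_bandpass_sos(0.5, 40.0, fs)
        _, h = signal.sosfreqz(sos, worN=[2 * np.pi * f0 / fs])
        expected_gain = np.abs(h[0]) ** 2
        t = np.arange(8192) / fs
        rec = make_recording(np.sin(2 * np.pi * f0 * t)[None, :])
        out = bandpass_filter(rec, 0.5, 40.0)
        measured = np.ptp(out.data[0, 2048:-2048]) / 2
        assert measured == pytest.approx(expected_gain, rel=0.1)

    def test_zero_phase_preserves_pulse_symmetry(self):
        x = np.zeros((1, 4096))
        x[0, 2048] = 1.0
        out = bandpass_filter(make_recording(x), 0.5, 40.0)
        assert int(np.argmax(out.data[0])) == 2048

    def test_invalid_band_edges_rejected(self):
        rec = make_recording(np.zeros((1, 1024)))
        with pytest.raises(ValueError):
            bandpass_filter(rec, 40.0, 0.5)
        with pytest.raises(ValueError):
            bandpass_filter(rec, 0.5, 300.0)

    def test_input_unmodified(self):
        data = np.random.default_rng(0).standard_normal((2, 2048))
        rec = make_recording(data.copy())
        bandpass_filter(rec)
        assert np.array_equal(rec.data, data)


class TestSegment:
    def test_epoch_length_922_samples_at_512hz(self):
        rec = make_recording(np.zeros((2, 512 * 10)))
        ep = segment_epochs(rec, [_event(2.0)], -0.5, 1.3)
        assert ep.n_times == 922
        assert ep.n_trials == 1

    def test_out_of_bounds_events_dropped(self):
        rec = make_recording(np.zeros((1, 512 * 4)))
        ep = segment_epochs(rec, [_event(0.1), _event(2.0), _event(3.9)], -0.5, 1.3)
        assert ep.n_trials == 1
        assert ep.info["onset_s"].tolist() == [2.0]

    def test_cardinality_and_order_preserved(self):
        rec = make_recording(np.zeros((1, 512 * 100)))
        events = [_event(1.0 + 1.9 * i) for i in range(50)]
        ep = segment_epochs(rec, events, -0.5, 1.3)
        assert ep.n_trials == 50
        assert ep.info["onset_s"].tolist() == [e.onset_s for e in events]

    def test_epoch_contains_expected_samples(self):
        data = np.arange(512 * 4, dtype=float)[None, :]
        rec = make_recording(data)
        ep = segment_epochs(rec, [_event(1.0)], -0.5, 1.3)
        start = 512 + int(round(-0.5 * 512))
        assert np.array_equal(ep.data[0, 0], data[0, start : start + 922])

    def test_empty_event_list_gives_empty_epochset(self):
        rec = make_recording(np.zeros((1, 1024)))
        ep = segment_epochs(rec, [], -0.5, 1.3)
        assert ep.n_trials == 0


class TestBaselineTrim:
    def test_constant_epoch_becomes_zero(self):
        ep = make_epochs(np.full((3, 2, 922), 5.0), tmin=-0.5)
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_baseline_window_mean_is_zero_after_correction(self, rng):
        ep = make_epochs(rng.standard_normal((4, 3, 922)), tmin=-0.5)
        out = baseline_correct(ep, (-0.5, 0.0))
        n_base = int(round(0.5 * 512))
        assert np.allclose(out.data[:, :, :n_base].mean(axis=2), 0.0, atol=1e-9)

    def test_equals_direct_recomputation(self, rng):
        data = rng.standard_normal((2, 2, 922))
        ep = make_epochs(data, tmin=-0.5)
        out = baseline_correct(ep, (-0.2, 0.0))
        i0 = int(round(0.3 * 512))
        i1 = int(round(0.5 * 512))
        expected = data - data[:, :, i0:i1].mean(axis=2, keepdims=True)
        assert np.allclose(out.data, expected)

    def test_window_after_onset_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 922)), tmin=-0.5)
        with pytest.raises(ValueError):
            baseline_correct(ep, (0.0, 0.5))

    def test_trim_to_768_samples(self):
        ep = make_epochs(np.zeros((2, 2, 922)), tmin=-0.5)
        out = trim_epochs(ep, -0.2, 1.3)
        assert out.n_times == 768
        assert out.tmin_s == pytest.approx(-0.2, abs=1e-3)

    def test_trim_identity_and_idempotence(self, rng):
        ep = make_epochs(rng.standard_normal((2, 2, 922)), tmin=-0.5)
        same = trim_epochs(ep, ep.tmin_s, ep.tmax_s)
        assert np.array_equal(same.data, ep.data)
        once = trim_epochs(ep, -0.2, 1.0)
        twice = trim_epochs(trim_epochs(ep, -0.3, 1.2), -0.2, 1.0)
        assert np.array_equal(once.data, twice.data)

    def test_non_nested_trim_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 922)), tmin=-0.5)
        with pytest.raises(ValueError):
            trim_epochs(ep, -0.6, 1.0)


class TestRejection:
    def test_planted_spike_trial_rejected(self, rng):
        data = rng.standard_normal((10, 3, 500)) * 10
        data[4, 1, 250] += 500.0
        ep = make_epochs(data)
        out, rep = reject_artifacts(ep, ptp_threshold_uv=150.0)
        assert rep.n_rejected == 1
        assert rep.reasons[4] == "ptp"
        assert out.n_trials == 9

    def test_clean_set_keeps_everything(self, rng):
        ep = make_epochs(rng.standard_normal((5, 2, 100)))
        out, rep = reject_artifacts(ep, 150.0)
        assert rep.proportion_rejected == 0.0
        assert out.n_trials == 5

    def test_k_planted_artifacts_all_counted(self, rng):
        n, k = 20, 6
        data = rng.standard_normal((n, 2, 300))
        bad = rng.choice(n, size=k, replace=False)
        data[bad, 0, 100] = 400.0
        _, rep = reject_artifacts(make_epochs(data), 150.0)
        assert rep.n_rejected == k

    def test_eog_channels_do_not_trigger_rejection(self, rng):
        data = rng.standard_normal((4, 3, 200))
        data[2, 2, 50] = 900.0  # huge excursion on the EOG channel only
        ep = make_epochs(data, roles=("scalp", "scalp", "eog"))
        _, rep = reject_artifacts(ep, 150.0)
        assert rep.n_rejected == 0


class TestInterpolationReference:
    def test_bad_channel_becomes_neighbor_mean(self, montage, rng):
        names = montage.channel_names
        data = rng.standard_normal((2, 32, 100))
        ep = make_epochs(data, names=names)
        out = interpolate_bad_channels(ep, ["Pz"], montage)
        neigh_idx = [names.index(n) for n in montage.neighbors["Pz"]]
        expected = data[:, neigh_idx, :].mean(axis=1)
        assert np.allclose(out.data[:, names.index("Pz"), :], expected)
        untouched = [i for i in range(32) if i != names.index("Pz")]
        assert np.array_equal(out.data[:, untouched, :], data[:, untouched, :])

    def test_identical_neighbors_reproduce_their_signal(self, montage):
        names = montage.channel_names
        c = np.sin(np.linspace(0, 4 * np.pi, 100))
        data = np.tile(c, (1, 32, 1))
        data[0, names.index("Pz")] = 99.0
        out = interpolate_bad_channels(make_epochs(data, names=names), ["Pz"], montage)
        assert np.allclose(out.data[0, names.index("Pz")], c)

    def test_empty_bad_list_is_identity(self, montage, rng):
        ep = make_epochs(rng.standard_normal((1, 32, 50)), names=montage.channel_names)
        out = interpolate_bad_channels(ep, [], montage)
        assert np.array_equal(out.data, ep.data)

    def test_all_neighbors_bad_raises(self, montage, rng):
        ep = make_epochs(rng.standard_normal((1, 32, 50)), names=montage.channel_names)
        bad = ["Oz"] + list(montage.neighbors["Oz"])
        with pytest.raises(ValueError):
            interpolate_bad_channels(ep, bad, montage)

    def test_average_reference_zeroes_scalp_mean(self, rng):
        data = rng.standard_normal((3, 5, 80))
        ep = make_epochs(data, roles=("scalp",) * 4 + ("eog",))
        out = rereference_average(ep)
        assert np.allclose(out.data[:, :4, :].mean(axis=1), 0.0, atol=1e-9)
        assert np.array_equal(out.data[:, 4, :], data[:, 4, :])  # EOG untouched

    def test_common_mode_exactly_removed(self, rng):
        base = rng.standard_normal((2, 3, 60))
        common = rng.standard_normal((2, 1, 60))
        ep_clean = make_epochs(base)
        ep_noisy = make_epochs(base + common)
        a = rereference_average(ep_clean)
        b = rereference_average(ep_noisy)
        assert np.allclose(a.data, b.data, atol=1e-9)


class TestChain:
    def test_default_chain_runs_and_returns_768_sample_epochs(self, montage, rng):
        from eegvuln.synth import CohortSpec, generate_recording, generate_sart_events

        events = generate_sart_events(1, 12, 0.2, seed=3)
        spec = CohortSpec(n_high=1, n_low=1, rest_duration_s=2.0, seed=3)
        rec = generate_recording(spec, "high", 1, events=events)
        ep, rep = preprocess_recording(rec, events, montage)
        assert ep.n_times == 768
        assert rep.n_total == 12
        assert ep.n_trials == 12 - rep.n_rejected

    def test_rest_to_epochs_tiles_recording(self):
        rec = make_recording(np.arange(2 * 512 * 5, dtype=float).reshape(2, -1))
        ep = rest_to_epochs(rec, 2.0)
        assert ep.n_trials == 2
        assert ep.n_times == 1024
        assert np.array_equal(ep.data[1, 0], rec.data[0, 1024:2048])
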