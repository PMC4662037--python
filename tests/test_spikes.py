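"""Tests for spike detection, PSTH alignment, typing and viability analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtmkit.params import InvalidParameterError
from mtmkit.spikes import (
    PSTH,
    InputError,
    SpikeTrain,
    StimulusProtocol,
    align_and_bin,
    classify_response,
    detect_spikes,
    rate_timecourse,
    read_spike_table,
    write_spike_table,
)
from mtmkit.synth import NoiseModel, default_spike_template, generate_session, type_i_response


class TestProtocol:
    def test_block_structure_invariant(self):
        with pytest.raises(InvalidParameterError):
            StimulusProtocol(train_length_min=1.0, rest_length_min=1.0, block_length_min=3.0)

    def test_interstimulus_interval_at_default_rate(self):
        assert StimulusProtocol().interstimulus_ms == pytest.approx(666.667, abs=0.01)

    def test_stimulus_times_follow_block_design(self):
        p = StimulusProtocol(n_blocks=2)
        times = p.stimulus_times_ms()
        assert len(times) == 2 * 90  # 1 min at 1.5 Hz per block
        # train occupies only the first minute of each 3-min block
        assert times[89] < 60_000.0 <= 180_000.0
        assert times[90] == pytest.approx(180_000.0)

    def test_single_train_pulse_count(self):
        assert StimulusProtocol.single_train(32).pulses_per_train == 32


class TestSpikeTrainInvariants:
    def test_unsorted_rejected(self):
        with pytest.raises(InputError):
            SpikeTrain("ch0", np.array([5.0, 3.0]), 100.0)

    def test_out_of_session_rejected(self):
        with pytest.raises(InputError):
            SpikeTrain("ch0", np.array([5.0, 150.0]), 100.0)

    def test_refractory_violation_rejected(self):
        with pytest.raises(InputError):
            SpikeTrain("ch0", np.array([5.0, 5.3]), 100.0)


class TestDetection:
    def test_flat_trace_yields_empty_train(self):
        train = detect_spikes(np.zeros(1000), 25.0)
        assert train.n_spikes == 0

    def test_three_template_spikes_in_noise_at_snr_10(self):
        rng = np.random.default_rng(42)
        fs = 25.0
        trace = rng.normal(0, 0.1, 25_000)  # 1 s
        template = default_spike_template(fs)
        peak_off = int(np.argmin(template))
        true_ms = [200.0, 450.0, 700.0]
        for t in true_ms:
            i = int(round(t * fs)) - peak_off
            trace[i : i + template.size] += template  # SNR 10 vs 0.1 noise
        train = detect_spikes(trace, fs)
        assert train.n_spikes == 3
        assert np.max(np.abs(train.timestamps_ms - true_ms)) <= 1.0 / fs + 1e-9

    def test_threshold_above_signal_detects_nothing(self):
        fs = 25.0
        trace = np.zeros(5000)
        template = default_spike_template(fs) * 0.5
        trace[1000 : 1000 + template.size] += template
        rng = np.random.default_rng(0)
        trace += rng.normal(0, 0.2, trace.size)  # spike at 2.5 SD < 4.5 SD
        assert detect_spikes(trace, fs, threshold_sd=6.0).n_spikes == 0

    def test_noiseless_sessions_perfect_recall_precision(self):
        proto = StimulusProtocol.single_train(10)
        resp = type_i_response(baseline_rate_hz=0.0)
        for seed in range(10):
            truth, trace = generate_session(
                resp, proto, NoiseModel(noise_sd=0.0, seed=seed), seed=seed, render=True
            )
            det = detect_spikes(trace, 25.0)
            assert det.n_spikes == truth.n_spikes
            if truth.n_spikes:
                assert np.max(np.abs(det.timestamps_ms - truth.timestamps_ms)) <= 0.05

    def test_recall_at_snr_8(self):
        proto = StimulusProtocol.single_train(5)
        resp = type_i_response(baseline_rate_hz=0.0)
        tp = fn = 0
        for seed in range(100):
            truth, trace = generate_session(
                resp, proto, NoiseModel(noise_sd=1 / 8, seed=seed), seed=seed, render=True
            )
            det = detect_spikes(trace, 25.0)
            for t in truth.timestamps_ms:
                if det.n_spikes and np.min(np.abs(det.timestamps_ms - t)) <= 0.5:
                    tp += 1
                else:
                    fn += 1
        assert tp / (tp + fn) >= 0.95


class TestAlignAndBin:
    def test_empty_train_gives_zero_psth(self, protocol20):
        train = SpikeTrain("ch0", np.empty(0), protocol20.session_length_ms)
        psth, raster = align_and_bin(train, protocol20)
        assert psth.total_count == 0
        assert all(r.size == 0 for r in raster)

    def test_one_spike_per_stimulus_lands_in_first_bin(self, protocol20):
        stim = protocol20.stimulus_times_ms()
        train = SpikeTrain("ch0", stim + 5.0, protocol20.session_length_ms)
        psth, raster = align_and_bin(train, protocol20)
        assert psth.counts[0] == 20
        assert psth.counts[1:].sum() == 0
        assert len(raster) == 20

    def test_blanking_removes_artifact_window(self, protocol20):
        stim = protocol20.stimulus_times_ms()
        train = SpikeTrain("ch0", stim + 2.0, protocol20.session_length_ms)
        psth_blanked, _ = align_and_bin(train, protocol20)  # default blank = 5 ms
        psth_kept, _ = align_and_bin(train, protocol20, blank_ms=0.0)
        assert psth_blanked.total_count == 0
        assert psth_kept.total_count == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_count_conservation(self, seed, protocol20):
        # PSTH total equals an independent direct count of in-window spikes
        truth, _ = generate_session(type_i_response(), protocol20, seed=seed)
        window = protocol20.interstimulus_ms
        psth, raster = align_and_bin(truth, protocol20)
        direct = sum(
            np.count_nonzero(
                (truth.timestamps_ms >= t0 + 5.0) & (truth.timestamps_ms < t0 + window)
            )
            for t0 in protocol20.stimulus_times_ms()
        )
        assert psth.total_count == direct
        assert sum(r.size for r in raster) == direct

    def test_bad_bin_width_rejected(self, protocol20):
        train = SpikeTrain("ch0", np.empty(0), protocol20.session_length_ms)
        with pytest.raises(InvalidParameterError):
            align_and_bin(train, protocol20, bin_width_ms=0.0)


class TestClassification:
    def _psth(self, counts, n_repeats=20):
        return PSTH(10.0, np.asarray(counts), n_repeats, 666.7)

    def test_single_early_cluster_is_type_i(self):
        counts = np.zeros(66, dtype=int)
        counts[0:2] = [30, 22]
        assert classify_response(self._psth(counts)) == "I"

    def test_two_separated_clusters_is_type_iii(self):
        counts = np.zeros(66, dtype=int)
        counts[0:2] = [30, 22]
        counts[4:6] = [25, 18]
        assert classify_response(self._psth(counts)) == "III"

    def test_three_clusters_is_type_iii(self):
        counts = np.zeros(66, dtype=int)
        counts[0], counts[4], counts[8] = 30, 25, 20
        assert classify_response(self._psth(counts)) == "III"

    def test_uniform_counts_unclassified(self):
        assert classify_response(self._psth(np.full(66, 7))) == "unclassified"

    def test_all_zero_unclassified(self):
        assert classify_response(self._psth(np.zeros(66, dtype=int))) == "unclassified"

    def test_late_single_burst_unclassified(self):
        counts = np.zeros(66, dtype=int)
        counts[30:32] = [30, 22]  # onset 300 ms, far beyond 20 ms
        assert classify_response(self._psth(counts)) == "unclassified"

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.integers(2, 10), seed=st.integers(0, 100))
    def test_invariant_under_repeat_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(0.2, 66)
        counts[0:2] += rng.poisson(25, 2)
        if rng.random() < 0.5:
            counts[4:6] += rng.poisson(20, 2)
        base = classify_response(self._psth(counts, 20))
        scaled = classify_response(self._psth(counts * scale, 20 * scale))
        assert base == scaled


class TestRateTimecourse:
    def _train_from_rates(self, rates_hz, protocol):
        """Deterministic train: evenly spaced spikes in each train minute."""
        times = []
        block_ms = protocol.block_length_min * 60_000.0
        for b, rate in enumerate(rates_hz):
            n = int(round(rate * 60.0))
            if n:
                times.append(b * block_ms + np.linspace(1.0, 59_999.0, n))
        ts = np.sort(np.concatenate(times)) if times else np.empty(0)
        return SpikeTrain("ch0", ts, protocol.session_length_ms)

    def test_constant_rates_no_decline(self):
        proto = StimulusProtocol(n_blocks=10)
        tc = rate_timecourse(self._train_from_rates([15.0] * 10, proto), proto)
        assert tc.decline_onset_min is None
        assert np.allclose(tc.rates_hz, 15.0)

    def test_zero_after_first_block_onset_at_second(self):
        proto = StimulusProtocol(n_blocks=6)
        tc = rate_timecourse(self._train_from_rates([15, 0, 0, 0, 0, 0], proto), proto)
        assert tc.decline_onset_min == pytest.approx(3.0)

    def test_gradual_decay_onset_backs_up_one_block(self):
        # plateau 15 Hz; decay passing through an intermediate 9 Hz block
        proto = StimulusProtocol(n_blocks=12)
        rates = [15] * 8 + [9, 5, 2, 1]
        tc = rate_timecourse(self._train_from_rates(rates, proto), proto)
        # first sub-50% block is index 9 (27 min); index 8 already declining
        assert tc.decline_onset_min == pytest.approx(24.0)

    def test_short_session_rejected(self):
        proto = StimulusProtocol(n_blocks=1)
        train = SpikeTrain("ch0", np.empty(0), proto.session_length_ms)
        with pytest.raises(InputError):
            rate_timecourse(train, proto)

    def test_rate_denominator_is_train_minute(self):
        proto = StimulusProtocol(n_blocks=2)
        # 120 spikes inside the first train minute -> 2 Hz, not 120/180 s
        ts = np.linspace(10.0, 59_000.0, 120)
        tc = rate_timecourse(SpikeTrain("ch0", ts, proto.session_length_ms), proto)
        assert tc.rates_hz[0] == pytest.approx(2.0)


def test_spike_table_round_trip(tmp_path, protocol20):
    truth, _ = generate_session(type_i_response(), protocol20, seed=3)
    path = tmp_path / "spikes.tsv"
    write_spike_table([truth], path)
    (loaded,) = read_spike_table(path, protocol20.session_length_ms)
    assert loaded.channel == truth.channel
    assert np.allclose(loaded.timestamps_ms, truth.timestamps_ms)
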