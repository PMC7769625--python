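"""Spike detection, burst segmentation, ISI maps and regime classification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cscburst as cb
from cscburst.features import DetectorSettings, extract_features


class TestDetectSpikes:
    def test_constant_subthreshold_trace_has_no_spikes(self):
        t = np.arange(0.0, 100.0, 0.05)
        assert cb.detect_spikes(t, np.full(t.size, -60.0)).size == 0

    def test_surrogate_counts_recovered(self):
        spec = cb.SurrogateSpec(spikes_per_burst=(7,), noise_sd=0.0)
        tr = cb.generate_surrogate_trace(spec)
        det = cb.detect_spikes(tr.times, tr.V)
        assert det.size == 7
        assert np.all(np.abs(det - tr.spike_times) <= 0.1)

    def test_min_separation_suppresses_double_peaks(self):
        t = np.arange(0.0, 20.0, 0.05)
        V = -60 + 50 * (np.exp(-0.5 * ((t - 10) / 0.3) ** 2)
                        + 0.9 * np.exp(-0.5 * ((t - 10.6) / 0.3) ** 2))
        assert cb.detect_spikes(t, V, min_separation=2.0).size == 1


class TestSegmentBursts:
    def test_constructed_gap_splits(self):
        st_ = np.array([0.0, 10.0, 20.0, 500.0, 510.0, 520.0])
        bursts = cb.segment_bursts(st_)
        assert [len(b) for b in bursts] == [3, 3]

    def test_periodic_train_single_burst(self):
        bursts = cb.segment_bursts(np.arange(0.0, 1000.0, 25.0))
        assert len(bursts) == 1

    def test_surrogate_pattern_recovered(self):
        spec = cb.SurrogateSpec(spikes_per_burst=(4, 4, 4), noise_sd=1.0, seed=3)
        tr = cb.generate_surrogate_trace(spec)
        det = cb.detect_spikes(tr.times, tr.V)
        assert [len(b) for b in cb.segment_bursts(det)] == [4, 4, 4]

    @settings(max_examples=25, deadline=None)
    @given(counts=st.lists(st.integers(1, 8), min_size=1, max_size=5),
           seed=st.integers(0, 1000))
    def test_counts_sum_preserved(self, counts, seed):
        spec = cb.SurrogateSpec(spikes_per_burst=tuple(counts),
                                noise_sd=0.5, seed=seed)
        tr = cb.generate_surrogate_trace(spec)
        det = cb.detect_spikes(tr.times, tr.V)
        bursts = cb.segment_bursts(det)
        assert sum(len(b) for b in bursts) == det.size == sum(counts)


class TestSpikesPerBurst:
    def test_sw_isola_count(self, sw_traj):
        assert cb.spikes_per_burst(sw_traj) == 14

    def test_alternating_pattern_returns_sequence(self):
        spec = cb.SurrogateSpec(spikes_per_burst=(5, 3, 5, 3, 5, 3),
                                noise_sd=0.0)
        tr = cb.generate_surrogate_trace(spec)
        det = cb.detect_spikes(tr.times, tr.V)
        out = cb.spikes_per_burst(det)
        assert not np.isscalar(out)
        assert set(np.asarray(out).tolist()) == {3, 5}

    def test_no_bursting_raises(self):
        with pytest.raises(ValueError):
            cb.spikes_per_burst(np.array([10.0]))


class TestIsiReturnMap:
    def test_periodic_train_on_diagonal(self):
        pairs, disp = cb.isi_return_map(np.arange(0, 500, 20.0))
        assert disp == pytest.approx(0.0)
        assert np.allclose(pairs[:, 0], pairs[:, 1])

    def test_two_isi_alternation_mirror_points(self):
        st_ = np.cumsum([0] + [10.0, 30.0] * 5)
        pairs, disp = cb.isi_return_map(st_)
        uniq = {tuple(q) for q in pairs}
        assert uniq == {(10.0, 30.0), (30.0, 10.0)}
        assert disp > 0.1

    def test_too_few_spikes_raises(self):
        with pytest.raises(ValueError):
            cb.isi_return_map(np.array([1.0, 2.0]))


class TestClassifyRegime:
    def test_tonic_default(self, tonic_traj):
        assert cb.classify_regime(tonic_traj) == "T"

    def test_square_wave_isola(self, sw_traj):
        assert cb.classify_regime(sw_traj) == "SW"

    def test_pseudo_plateau_surrogate_morphology(self):
        spec = cb.SurrogateSpec(spikes_per_burst=(3, 3, 3, 3, 3, 3),
                                plateau=True, noise_sd=0.5, seed=11)
        tr = cb.generate_surrogate_trace(spec)
        states = np.zeros((tr.times.size, 8))
        states[:, 0] = tr.V
        traj = cb.Trajectory(tr.times, states, cb.ModelParameters.post_runup(),
                             cb.StimulusProtocol())
        assert cb.classify_regime(traj) == "PB"

    def test_depolarization_block(self, post):
        traj = cb.integrate(post.replace(g_HVA=1.5), duration=8000.0)
        assert cb.classify_regime(traj) == "ESS"

    def test_hyperpolarized_rest(self, post):
        traj = cb.integrate(post.replace(I_app=-2.0), duration=8000.0)
        assert cb.classify_regime(traj) == "Q"

    def test_features_tile_window(self, sw_traj):
        f = extract_features(sw_traj)
        assert f.regime == "SW"
        assert f.spikes_per_burst.sum() == f.spike_times.size
        total = f.active_durations.sum() + f.silent_durations.sum()
        span = f.window[1] - f.window[0]
        assert total == pytest.approx(span, rel=0.02)


class TestFirstSpikeLatency:
    def test_no_spike_gives_sentinel(self, post):
        traj = cb.integrate(post, duration=500.0,
                            protocol=cb.StimulusProtocol(kind="hold_release",
                                                         V_hold=-70.0,
                                                         I_bias=-2.0))
        assert cb.first_spike_latency(traj) == np.inf

    def test_wrong_protocol_rejected(self, tonic_traj):
        with pytest.raises(ValueError):
            cb.first_spike_latency(tonic_traj)

    def test_latency_decreases_far_above_threshold(self, post):
        lats = []
        for I in (0.5, 2.0, 5.0):
            traj = cb.integrate(post, duration=1500.0,
                                protocol=cb.StimulusProtocol(
                                    kind="step", I_bias=-1.0, I_test=I,
                                    t_step=500.0))
            lats.append(cb.first_spike_latency(traj))
        assert lats[0] > lats[1] > lats[2]


def test_detector_threshold_robustness(sw_traj):
    # the square-wave count is insensitive to +-10% threshold changes
    for thr in (-22.0, -20.0, -18.0):
        s = DetectorSettings(threshold=thr)
        assert cb.spikes_per_burst(sw_traj, s) == 14
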