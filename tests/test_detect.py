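import numpy as np
import pytest
from hypothesis import given, strategies as st

from ephysync.detect import (
    AmplitudeDiscriminator,
    Burst,
    BurstDetectorSpec,
    SpikeTrain,
    detect_bursts,
    find_peaks,
)
from ephysync.errors import DetectError
from ephysync.io import Epoch, SignalSet
from oracles import burst_enumeration, peak_scan


def sig_of(samples, fs=100.0, name="ch"):
    return SignalSet([name], [""], fs, 0.0, np.asarray(samples, float)[:, None])


class TestDiscriminatorValidation:
    def test_window_must_not_straddle_zero(self):
        with pytest.raises(DetectError, match="straddles"):
            AmplitudeDiscriminator("u", "c", -5.0, 5.0)

    def test_window_must_be_increasing(self):
        with pytest.raises(DetectError):
            AmplitudeDiscriminator("u", "c", 3.0, 1.0)

    @pytest.mark.parametrize("lo,hi", [(0.0, 5.0), (-5.0, 0.0), (1.0, 2.0), (-2.0, -1.0)])
    def test_one_sided_windows_accepted(self, lo, hi):
        AmplitudeDiscriminator("u", "c", lo, hi)


class TestFindPeaks:
    def test_flat_signal_has_no_peaks(self):
        train = find_peaks(sig_of(np.ones(50)), AmplitudeDiscriminator("u", "ch", 0.5, 2))
        assert len(train) == 0

    def test_single_triangular_pulse(self):
        x = np.zeros(101)
        x[45:56] = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        train = find_peaks(sig_of(x), AmplitudeDiscriminator("u", "ch", 0.5, 2.0))
        assert list(train.times) == [0.5]
        assert list(train.amplitudes) == [1.0]

    def test_peak_above_window_excluded(self):
        x = np.zeros(100)
        x[20] = 1.0
        x[60] = 3.0
        train = find_peaks(sig_of(x), AmplitudeDiscriminator("u", "ch", 0.5, 2.0))
        assert list(train.times) == [0.2]

    def test_plateau_counts_once_at_first_sample(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        train = find_peaks(sig_of(x), AmplitudeDiscriminator("u", "ch", 0.5, 2.0))
        assert list(train.times) == [0.01]

    def test_endpoints_never_peaks(self):
        x = np.array([5.0, 1.0, 0.0, 1.0, 5.0])
        train = find_peaks(sig_of(x), AmplitudeDiscriminator("u", "ch", 0.0, 10.0))
        assert len(train) == 0

    def test_negative_window_finds_minima(self):
        x = np.zeros(100)
        x[30] = -1.0
        train = find_peaks(sig_of(x), AmplitudeDiscriminator("u", "ch", -2.0, -0.5))
        assert list(train.times) == [0.3]
        assert list(train.amplitudes) == [-1.0]

    def test_epoch_constraint_uses_half_open_union(self):
        x = np.zeros(200)
        x[[20, 50, 100, 150]] = 1.0
        d = AmplitudeDiscriminator("u", "ch", 0.5, 2.0, epoch_label="go")
        epochs = [Epoch(0.1, 0.3, "go"), Epoch(0.9, 1.0, "go"), Epoch(0.4, 0.6, "stop")]
        train = find_peaks(sig_of(x), d, epochs)
        # 0.2 in [0.1,0.3); 1.0 excluded (half-open); 0.5 has wrong label
        assert list(train.times) == [0.2]

    def test_epoch_label_requires_epochs(self):
        d = AmplitudeDiscriminator("u", "ch", 0.5, 2.0, epoch_label="go")
        with pytest.raises(DetectError, match="epochs"):
            find_peaks(sig_of(np.zeros(10)), d, None)

    @given(st.integers(0, 500))
    def test_matches_brute_force_scan_on_noise(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=120)
        lo, hi = sorted(np.abs(rng.normal(size=2)))
        if rng.random() < 0.5:
            lo, hi = -hi, -lo
        epochs = [Epoch(0.1, 0.5, "go"), Epoch(0.8, 1.1, "go")]
        label = "go" if rng.random() < 0.5 else None
        d = AmplitudeDiscriminator("u", "ch", lo, hi, epoch_label=label)
        sig = sig_of(x)
        train = find_peaks(sig, d, epochs)
        expect = peak_scan(x, lo, hi, 0.0, 100.0, epochs, label)
        np.testing.assert_allclose(train.times, np.array(expect) / 100.0)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=300)
        pos = find_peaks(sig_of(x), AmplitudeDiscriminator("u", "ch", 0.2, 1.5))
        neg = find_peaks(sig_of(-x), AmplitudeDiscriminator("u", "ch", -1.5, -0.2))
        np.testing.assert_array_equal(pos.times, neg.times)
        np.testing.assert_allclose(pos.amplitudes, -neg.amplitudes)


class TestSpikeTrain:
    def test_times_must_strictly_increase(self):
        with pytest.raises(DetectError):
            SpikeTrain("u", [0.0, 0.0, 1.0])


class TestDetectBursts:
    SPEC = BurstDetectorSpec("u", f_init=5.0, f_term=2.0)

    @pytest.mark.parametrize("times", [[], [1.0]])
    def test_too_few_spikes_give_no_bursts(self, times):
        assert detect_bursts(SpikeTrain("u", times), self.SPEC) == []

    def test_slow_edge_spikes_excluded_from_burst(self):
        train = SpikeTrain("u", [0.0, 0.5, 0.6, 0.7, 0.8, 2.0])
        assert detect_bursts(train, self.SPEC) == [Burst(0.5, 0.8, 4)]

    def test_single_fast_isi_is_a_burst(self):
        assert detect_bursts(SpikeTrain("u", [0.0, 0.1]), self.SPEC) == [Burst(0.0, 0.1, 2)]

    def test_burst_continues_at_termination_rate(self):
        # opens at 10 Hz, continues at 2.5 Hz >= f_term, closes at 1 Hz
        train = SpikeTrain("u", [0.0, 0.1, 0.5, 1.5])
        assert detect_bursts(train, self.SPEC) == [Burst(0.0, 0.5, 3)]

    def test_subthreshold_opening_rate_never_opens(self):
        # 4 Hz < f_init even though >= f_term
        train = SpikeTrain("u", [0.0, 0.25, 0.5, 0.75])
        assert detect_bursts(train, self.SPEC) == []

    def test_two_separate_bursts(self):
        train = SpikeTrain("u", [0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        assert detect_bursts(train, self.SPEC) == [Burst(0.0, 0.2, 3), Burst(5.0, 5.2, 3)]

    def test_bursts_disjoint_and_ordered(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 30, 200))
        times = times[np.insert(np.diff(times) > 0, 0, True)]
        bursts = detect_bursts(SpikeTrain("u", times), self.SPEC)
        for a, b in zip(bursts, bursts[1:]):
            assert a.end < b.start
        assert all(b.n_spikes >= 2 for b in bursts)

    @given(st.integers(0, 300))
    def test_matches_enumeration_oracle_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 9))
        times = np.sort(rng.choice(np.arange(0, 41) * 0.05, size=n, replace=False))
        f_init, f_term = 5.0, 2.0
        got = [(b.start, b.end, b.n_spikes)
               for b in detect_bursts(SpikeTrain("u", times), BurstDetectorSpec("u", f_init, f_term))]
        want = burst_enumeration(list(times), f_init, f_term)
        assert got == want

    @given(st.floats(-1e3, 1e3))
    def test_time_shift_equivariance(self, delta):
        base = np.array([0.0, 0.1, 0.2, 0.3, 2.0, 2.05, 2.1, 9.0])
        a = detect_bursts(SpikeTrain("u", base), self.SPEC)
        b = detect_bursts(SpikeTrain("u", base + delta), self.SPEC)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert y.start == pytest.approx(x.start + delta, abs=1e-6)
            assert y.end == pytest.approx(x.end + delta, abs=1e-6)
            assert y.n_spikes == x.n_spikes

    def test_detector_threshold_validation(self):
        with pytest.raises(DetectError):
            BurstDetectorSpec("u", f_init=1.0, f_term=2.0)
        with pytest.raises(DetectError):
            BurstDetectorSpec("u", f_init=1.0, f_term=0.0)
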