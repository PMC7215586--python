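import numpy as np
import pytest

from ephysync.config import parse_config_path
from ephysync.detect import detect_bursts, find_peaks
from ephysync.io import read_epochs, read_signals
from ephysync.sync import estimate_offset_from_counter
from ephysync.synth import (
    SynthSpec,
    UnitSpec,
    generate,
    load_ground_truth,
    write_dataset,
)


class TestSpecValidation:
    def test_amplitudes_closer_than_four_sigma_rejected(self):
        units = (UnitSpec("a", 10.0), UnitSpec("b", 14.0))
        with pytest.raises(ValueError, match="noise_sd"):
            SynthSpec(units=units, noise_sd=2.0)

    def test_overlapping_windows_rejected(self):
        units = (UnitSpec("a", 10.0), UnitSpec("b", 25.0))
        with pytest.raises(ValueError, match="window"):
            SynthSpec(units=units, noise_sd=0.0)

    def test_within_burst_rate_must_exceed_burst_rate(self):
        with pytest.raises(ValueError, match="exceed"):
            UnitSpec("a", 10.0, burst_rate=30.0, within_burst_rate=20.0)

    def test_from_dict_builds_nested_units(self):
        spec = SynthSpec.from_dict(
            {"duration": 10.0, "units": [{"name": "u", "amplitude": 5.0}], "noise_sd": 0.5}
        )
        assert spec.units[0].name == "u"


class TestDeterminism:
    def test_same_seed_same_output(self):
        a = generate(SynthSpec(duration=15.0, seed=9))
        b = generate(SynthSpec(duration=15.0, seed=9))
        np.testing.assert_array_equal(a.signals.samples, b.signals.samples)
        for name in a.truth.spike_times:
            np.testing.assert_array_equal(a.truth.spike_times[name],
                                          b.truth.spike_times[name])

    def test_same_seed_identical_files(self, tmp_path):
        spec = SynthSpec(duration=15.0, seed=9)
        p1 = write_dataset(generate(spec), tmp_path / "one")
        p2 = write_dataset(generate(spec), tmp_path / "two")
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_noise_level_does_not_move_spike_times(self, small_bundle, noiseless_bundle):
        for name in small_bundle.truth.spike_times:
            np.testing.assert_array_equal(
                small_bundle.truth.spike_times[name],
                noiseless_bundle.truth.spike_times[name],
            )


class TestGroundTruthConsistency:
    def test_noiseless_recovery_is_exact(self, noiseless_bundle):
        b = noiseless_bundle
        for d in b.config.amplitude_discriminators:
            train = find_peaks(b.signals, d, b.truth.epochs)
            np.testing.assert_array_equal(train.times, b.truth.spike_times[d.name])
            np.testing.assert_allclose(
                train.amplitudes,
                np.full(len(train), dict((u.name, u.amplitude) for u in b.spec.units)[d.name]),
            )

    def test_bursts_self_consistent_with_emitted_thresholds(self, noiseless_bundle):
        b = noiseless_bundle
        for det in b.config.burst_detectors:
            train = find_peaks(
                b.signals,
                next(d for d in b.config.amplitude_discriminators if d.name == det.unit),
                b.truth.epochs,
            )
            assert detect_bursts(train, det) == b.truth.bursts[det.unit]

    def test_counter_reading_recovers_offset(self, small_bundle):
        t = small_bundle.truth
        count, video_time = t.counter_reading
        est = estimate_offset_from_counter(count, video_time, t.counter_pulse_times)
        assert est == pytest.approx(t.video_offset, abs=1e-9)

    def test_empty_units_make_pure_noise_with_zero_detections(self):
        from ephysync.detect import AmplitudeDiscriminator

        # window floor at 6 sigma: with ~25k samples per run the expected
        # count of Gaussian excursions above 6 sigma is ~1e-5, i.e. zero
        for seed in range(10):
            bundle = generate(SynthSpec(duration=5.0, units=(), noise_sd=2.0, seed=seed))
            d = AmplitudeDiscriminator("probe", "BN2", 6 * 2.0, 1e9)
            assert len(find_peaks(bundle.signals, d)) == 0


class TestWriteDataset:
    def test_emits_files_and_valid_config(self, small_bundle, tmp_path):
        paths = write_dataset(small_bundle, tmp_path)
        assert len(paths) >= 4
        cfgs = parse_config_path(paths["config"])
        assert set(cfgs) == {"synthetic", "synthetic-binary"}

    def test_text_and_binary_dialects_agree(self, small_bundle, tmp_path):
        paths = write_dataset(small_bundle, tmp_path)
        cfgs = parse_config_path(paths["config"])
        text = read_signals(cfgs["synthetic"].data_file)
        binary = read_signals(cfgs["synthetic-binary"].data_file,
                              cfgs["synthetic-binary"].signal_meta)
        assert text.fs == pytest.approx(binary.fs, rel=1e-9)
        np.testing.assert_allclose(text.samples, binary.samples, atol=1e-4)

    def test_ground_truth_reloads(self, small_bundle, tmp_path):
        paths = write_dataset(small_bundle, tmp_path)
        truth = load_ground_truth(paths["ground_truth"])
        assert truth.video_offset == small_bundle.truth.video_offset
        for name in small_bundle.truth.spike_times:
            np.testing.assert_allclose(truth.spike_times[name],
                                       small_bundle.truth.spike_times[name])
            assert truth.bursts[name] == small_bundle.truth.bursts[name]
        assert truth.epochs == small_bundle.truth.epochs

    def test_epochs_file_matches_truth(self, small_bundle, tmp_path):
        paths = write_dataset(small_bundle, tmp_path)
        back = read_epochs(paths["epochs"])
        assert len(back) == len(small_bundle.truth.epochs)
        for got, want in zip(back, small_bundle.truth.epochs):
            assert got.start == pytest.approx(want.start, abs=1e-9)
            assert got.end == pytest.approx(want.end, abs=1e-9)
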