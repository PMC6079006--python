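"""Epoching, power spectra, gradiometer combination and neighbour-ratio SNR."""

import numpy as np
import pandas as pd
import pytest

from freqtag.simulate import SimulationConfig, simulate_recording
from freqtag.spectral import (
    FOIS,
    Epoch,
    InsufficientDataError,
    MisalignedFrequencyError,
    PowerSpectrum,
    average_epochs,
    combine_gradiometers,
    extract_epoch,
    foi_bin,
    harmonic_of,
    power_spectrum,
    snr_spectrum,
)
from freqtag.stimuli import TRITONE_PERIOD, generate_stat_sequence


def _toy_channels(n):
    return pd.DataFrame(
        {"name": [f"ch{i}" for i in range(n)], "chipset": range(n), "type": "grad_comb"}
    )


@pytest.fixture(scope="module")
def recording(sensor_array):
    seq = generate_stat_sequence(120, seed=0)
    cfg = SimulationConfig(noise_sd=0.2, white_noise_sd=0.05, seed=0)
    return simulate_recording(cfg, seq, sensor_array)


class TestExtractEpoch:
    def test_minute_window_duration(self, recording):
        ep = extract_epoch(recording, n_cycles=112)
        assert ep.duration == pytest.approx(61.04)

    def test_epoch_starts_after_skipped_tones(self, recording):
        ep = extract_epoch(recording, n_cycles=10, skip_tones=12)
        start = recording.trigger_samples[4]
        assert np.array_equal(
            ep.data[:, :50], recording.data[:, start : start + 50]
        )

    def test_insufficient_data_raises(self, recording):
        with pytest.raises(InsufficientDataError):
            extract_epoch(recording, n_cycles=560)

    def test_five_minute_duration_arithmetic(self):
        assert 560 * TRITONE_PERIOD == pytest.approx(305.20)


class TestAverageEpochs:
    def test_identity_and_single(self, recording):
        ep = extract_epoch(recording, n_cycles=10)
        assert np.allclose(average_epochs([ep, ep]).data, ep.data)
        assert np.allclose(average_epochs([ep]).data, ep.data)

    def test_shape_mismatch_rejected(self, recording):
        a = extract_epoch(recording, n_cycles=10)
        b = extract_epoch(recording, n_cycles=20)
        with pytest.raises(ValueError):
            average_epochs([a, b])


class TestPowerSpectrum:
    def test_resolution_of_canonical_epochs(self, recording):
        ps = power_spectrum(extract_epoch(recording, n_cycles=112))
        assert round(ps.resolution, 4) == 0.0164
        # 560-cycle resolution follows the same 1/duration rule
        assert round(1.0 / (560 * TRITONE_PERIOD), 4) == 0.0033

    def test_band_cropping(self, recording):
        ps = power_spectrum(extract_epoch(recording, n_cycles=56), band=(1.5, 12.0))
        assert ps.freqs[0] >= 1.5 and ps.freqs[-1] <= 12.0

    def test_pure_sinusoid_peaks_at_its_bin(self):
        fs, n_cycles = 1000.0, 56
        n = round(n_cycles * TRITONE_PERIOD * fs)
        t = np.arange(n) / fs
        f0 = FOIS["tone"]
        data = np.sin(2 * np.pi * f0 * t)[None, :]
        ep = Epoch(data=data, fs=fs, n_cycles=n_cycles, channels=_toy_channels(1))
        ps = power_spectrum(ep)
        assert ps.freqs[np.argmax(ps.power[0])] == pytest.approx(f0, abs=1e-9)

    def test_band_limited_energy_containment(self):
        # all spectral mass of in-band exact-bin sinusoids stays in band
        fs, n_cycles = 1000.0, 56
        n = round(n_cycles * TRITONE_PERIOD * fs)
        t = np.arange(n) / fs
        data = (
            np.sin(2 * np.pi * FOIS["tone"] * t)
            + 0.5 * np.sin(2 * np.pi * FOIS["tritone"] * t)
        )[None, :]
        ep = Epoch(data=data, fs=fs, n_cycles=n_cycles, channels=_toy_channels(1))
        in_band = power_spectrum(ep, band=(1.5, 12.0)).power.sum()
        total = power_spectrum(ep, band=(0.0, fs / 2)).power.sum()
        assert in_band / total > 1 - 1e-9


class TestCombineGradiometers:
    def test_sum_of_orientations(self, sensor_array, recording):
        ps = power_spectrum(extract_epoch(recording, n_cycles=10))
        comb = combine_gradiometers(ps, sensor_array)
        assert comb.power.shape[0] == 102
        ch = ps.channels.reset_index(drop=True)
        g1 = ch.index[ch["type"] == "grad1"].to_numpy()
        g2 = ch.index[ch["type"] == "grad2"].to_numpy()
        assert np.allclose(comb.power, ps.power[g1] + ps.power[g2])
        assert np.all(comb.power >= ps.power[g1])

    def test_unpaired_channels_rejected(self):
        ps = PowerSpectrum(
            freqs=np.linspace(2, 10, 16),
            power=np.ones((2, 16)),
            resolution=0.5,
            channels=pd.DataFrame(
                {"name": ["a", "b"], "chipset": [0, 0], "type": ["mag", "grad1"]}
            ),
        )
        from freqtag.simulate import make_sensor_array

        with pytest.raises(ValueError):
            combine_gradiometers(ps, make_sensor_array(0))


def _flat_spectrum(n_bins=64, value=1.0):
    return PowerSpectrum(
        freqs=np.linspace(1.5, 12.0, n_bins),
        power=np.full((3, n_bins), value),
        resolution=(12.0 - 1.5) / (n_bins - 1),
        channels=_toy_channels(3),
    )


class TestSNRSpectrum:
    def test_flat_spectrum_gives_unit_snr(self):
        snr = snr_spectrum(_flat_spectrum(), n_neighbors=10)
        assert np.allclose(snr.snr, 1.0)

    def test_single_line_on_flat_background(self):
        ps = _flat_spectrum(64, 1.0)
        ps.power[:, 30] = 100.0
        snr = snr_spectrum(ps, n_neighbors=10, n_skip_per_side=2)
        assert np.allclose(snr.snr[:, 30], 100.0)
        # the line sits in the skip zone of its direct neighbour, and far
        # bins never see it
        assert np.allclose(snr.snr[:, 28], 1.0)
        assert np.allclose(snr.snr[:, 10], 1.0)

    def test_matches_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(0)
        n_bins, half, skip = 64, 5, 2
        ps = _flat_spectrum(n_bins)
        ps.power = rng.uniform(0.5, 2.0, size=(3, n_bins))
        snr = snr_spectrum(ps, n_neighbors=2 * half, n_skip_per_side=skip)
        for i in range(n_bins):
            left = list(range(max(0, i - skip - half), max(0, i - skip)))
            right = list(range(min(n_bins, i + skip + 1), min(n_bins, i + skip + 1 + half)))
            deficit = 2 * half - len(left) - len(right)
            while deficit > 0 and right and right[-1] + 1 < n_bins:
                right.append(right[-1] + 1)
                deficit -= 1
            while deficit > 0 and left and left[0] - 1 >= 0:
                left.insert(0, left[0] - 1)
                deficit -= 1
            neigh = left + right
            expected = ps.power[:, i] / ps.power[:, neigh].mean(axis=1)
            assert np.allclose(snr.snr[:, i], expected), f"bin {i}"

    def test_edge_bins_flagged(self):
        snr = snr_spectrum(_flat_spectrum(64), n_neighbors=20, n_skip_per_side=2)
        assert snr.edge_flag[0] and snr.edge_flag[-1]
        assert not snr.edge_flag[32]

    def test_odd_neighbour_count_rejected(self):
        with pytest.raises(ValueError):
            snr_spectrum(_flat_spectrum(), n_neighbors=7)


class TestFoiBin:
    def test_tag_frequencies_fall_on_exact_bins(self, recording):
        ps = power_spectrum(extract_epoch(recording, n_cycles=112))
        ib_trit = foi_bin(ps, FOIS["tritone"])
        ib_tone = foi_bin(ps, FOIS["tone"])
        assert ps.freqs[ib_trit] == pytest.approx(FOIS["tritone"], abs=1e-9)
        # harmonic relation between the two tag bins
        offset = round(FOIS["tritone"] / ps.resolution)
        assert ib_tone - ib_trit == 2 * offset

    def test_out_of_band_rejected(self, recording):
        ps = power_spectrum(extract_epoch(recording, n_cycles=112))
        with pytest.raises(MisalignedFrequencyError):
            foi_bin(ps, 20.0)

    def test_misaligned_frequency_rejected(self):
        ps = _flat_spectrum(64)
        with pytest.raises(MisalignedFrequencyError):
            foi_bin(ps, ps.freqs[10] + 0.4 * ps.resolution)


class TestHarmonics:
    @pytest.mark.parametrize(
        "foi,k,expected",
        [(1.835, 1, 3.67), (5.505, 1, 11.01), (2.0, 0, 2.0), (1.835, 2, 5.505)],
    )
    def test_harmonic_values(self, foi, k, expected):
        assert harmonic_of(foi, k) == pytest.approx(expected)

    def test_first_tone_harmonic_inside_band(self):
        assert 1.5 <= harmonic_of(5.505, 1) <= 12.0
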