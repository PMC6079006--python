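"""Epoching, Hanning-taper power spectra and neighbour-ratio SNR.

The frequency-tagging readout: extract trigger-locked epochs spanning an
integer number of 0.545 s triple cycles (so the two tagging frequencies,
5.505 and 1.835 Hz, fall on exact DFT bins), average epochs in the time
domain to cancel non-phase-locked activity, compute Hann-windowed power
spectra in the 1.5-12 Hz band, sum the spectra of each planar-gradiometer
pair, and express power at every bin as a ratio to the mean power of its
flanking bins (skipping the closest two per side). That ratio — the SNR
spectrum — has baseline 1 in the absence of a tagged response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.signal.windows import hann

from .simulate import Recording, SensorArray
from .stimuli import TRITONE_PERIOD, TONE_RATE, TRITONE_RATE

__all__ = [
    "Epoch",
    "PowerSpectrum",
    "SNRSpectrum",
    "InsufficientDataError",
    "MisalignedFrequencyError",
    "FOIS",
    "extract_epoch",
    "average_epochs",
    "power_spectrum",
    "combine_gradiometers",
    "snr_spectrum",
    "foi_bin",
    "harmonic_of",
]

#: The two frequencies of interest: tone rate and triple (tritone) rate.
FOIS = {"tone": TONE_RATE, "tritone": TRITONE_RATE}


class InsufficientDataError(ValueError):
    """Recording too short for the requested epoch (the "< 5 minutes of
    exposure" exclusion surfaces as this error)."""


class MisalignedFrequencyError(ValueError):
    """Requested frequency does not fall on a DFT bin of this spectrum."""


@dataclass
class Epoch:
    """Trigger-locked data segment spanning an integer number of triple cycles."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    n_cycles: int
    channels: pd.DataFrame

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def pick_types(self, *types: str) -> "Epoch":
        """Subset to the given channel types (e.g. drop magnetometers
        before a gradiometer-only analysis)."""
        ch = self.channels.reset_index(drop=True)
        mask = ch["type"].isin(types).to_numpy()
        return Epoch(
            data=self.data[mask],
            fs=self.fs,
            n_cycles=self.n_cycles,
            channels=ch.loc[mask].reset_index(drop=True),
        )


def extract_epoch(
    rec: Recording,
    n_cycles: int,
    skip_tones: int = 12,
    start_cycle: int = 0,
) -> Epoch:
    """Cut an epoch of ``n_cycles`` triple periods from a recording.

    The epoch begins at the trigger following the first ``skip_tones`` tones
    (transient-response guard), optionally offset by ``start_cycle`` further
    cycles (used for minute-wise windows).
    """
    if skip_tones % 3 != 0:
        raise ValueError("skip_tones must be a multiple of 3 (trigger spacing)")
    trig_idx = skip_tones // 3
    if trig_idx >= len(rec.trigger_samples):
        raise InsufficientDataError("not enough triggers to skip the transient")
    start = int(rec.trigger_samples[trig_idx]) + int(round(start_cycle * TRITONE_PERIOD * rec.fs))
    n_samp = int(round(n_cycles * TRITONE_PERIOD * rec.fs))
    if start + n_samp > rec.n_samples:
        raise InsufficientDataError(
            f"recording holds {rec.n_samples} samples, epoch needs {start + n_samp}"
        )
    return Epoch(
        data=np.asarray(rec.data[:, start : start + n_samp], dtype=np.float32),
        fs=rec.fs,
        n_cycles=n_cycles,
        channels=rec.channels,
    )


def average_epochs(epochs: list[Epoch]) -> Epoch:
    """Pointwise time-domain mean; dampens signal not phase-locked to the triggers."""
    if not epochs:
        raise ValueError("no epochs to average")
    first = epochs[0]
    for ep in epochs[1:]:
        if ep.data.shape != first.data.shape or ep.fs != first.fs:
            raise ValueError("epochs must share shape and sampling rate")
    acc = np.zeros(first.data.shape, dtype=np.float32)
    for ep in epochs:
        acc += ep.data
    acc /= len(epochs)
    return Epoch(data=acc, fs=first.fs, n_cycles=first.n_cycles, channels=first.channels)


@dataclass
class PowerSpectrum:
    """Per-channel power versus frequency, cropped to the analysis band."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    resolution: float
    channels: pd.DataFrame
    band: tuple[float, float] = (1.5, 12.0)


def power_spectrum(
    ep: Epoch, band: tuple[float, float] = (1.5, 12.0)
) -> PowerSpectrum:
    """Hann-tapered FFT power in ``band``; resolution = 1/duration.

    Power is |X|^2 normalised by the squared window sum. The normalisation
    cancels in the SNR ratio, so the choice is documented but uncritical.
    """
    n = ep.data.shape[1]
    w = hann(n, sym=False)
    tapered = ep.data * w.astype(ep.data.dtype)
    spec = sp_fft.rfft(tapered, axis=1)
    freqs = np.fft.rfftfreq(n, 1.0 / ep.fs)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    power = (np.abs(spec[:, keep]).astype(np.float64) ** 2) / (np.sum(w) ** 2)
    return PowerSpectrum(
        freqs=freqs[keep],
        power=power,
        resolution=ep.fs / n,
        channels=ep.channels,
        band=band,
    )


def combine_gradiometers(ps: PowerSpectrum, array: SensorArray) -> PowerSpectrum:
    """Sum the power of both planar-gradiometer orientations per chipset.

    Yields one orientation-invariant power spectrum per chipset (102
    "combined" channels); magnetometers are dropped.
    """
    ch = ps.channels.reset_index(drop=True)
    g1 = ch.index[ch["type"] == "grad1"].to_numpy()
    g2 = ch.index[ch["type"] == "grad2"].to_numpy()
    if len(g1) != len(g2) or len(g1) == 0:
        raise ValueError("channel table does not define gradiometer pairs")
    c1 = ch.loc[g1, "chipset"].to_numpy()
    c2 = ch.loc[g2, "chipset"].to_numpy()
    if not np.array_equal(c1, c2):
        raise ValueError("gradiometer pairs are misaligned across chipsets")
    combined = ps.power[g1] + ps.power[g2]
    channels = pd.DataFrame(
        {
            "name": [f"CMB{c:03d}" for c in c1],
            "chipset": c1,
            "type": "grad_comb",
        }
    )
    return PowerSpectrum(
        freqs=ps.freqs,
        power=combined,
        resolution=ps.resolution,
        channels=channels,
        band=ps.band,
    )


@dataclass
class SNRSpectrum:
    """Neighbour-bin power ratio per channel; baseline 1 under flat spectra."""

    freqs: np.ndarray
    snr: np.ndarray  # (n_channels, n_freqs)
    resolution: float
    channels: pd.DataFrame
    n_neighbors: int
    n_skip_per_side: int
    edge_flag: np.ndarray = field(default=None)  # bins with re-balanced neighbourhoods
    fois: dict = field(default_factory=lambda: dict(FOIS))


def snr_spectrum(
    ps: PowerSpectrum,
    n_neighbors: int = 200,
    n_skip_per_side: int = 2,
) -> SNRSpectrum:
    """Power of each bin over the mean power of its flanking bins.

    ``n_neighbors`` is the total neighbour count (half per side), skipping
    the ``n_skip_per_side`` closest bins on each side against spectral
    leakage. Near the band edges the short side is truncated and the long
    side extended so the total neighbour count is preserved where possible;
    such bins are flagged.
    """
    if n_neighbors % 2 != 0 or n_neighbors < 2:
        raise ValueError("n_neighbors must be a positive even count")
    half = n_neighbors // 2
    skip = n_skip_per_side
    n_freqs = ps.power.shape[1]
    if n_freqs < n_neighbors // 4:
        raise ValueError("band too narrow for the requested neighbourhood")
    csum = np.concatenate(
        [np.zeros((ps.power.shape[0], 1)), np.cumsum(ps.power, axis=1)], axis=1
    )

    def _range_sum(lo: int, hi: int) -> np.ndarray:
        # sum of bins lo..hi-1, clipped to valid range
        lo = min(max(lo, 0), n_freqs)
        hi = min(max(hi, 0), n_freqs)
        return csum[:, hi] - csum[:, lo]

    snr = np.empty_like(ps.power)
    edge = np.zeros(n_freqs, dtype=bool)
    for i in range(n_freqs):
        l_avail = max(0, i - skip)  # bins strictly left of the skip zone
        r_avail = max(0, n_freqs - 1 - i - skip)
        n_left = min(half, l_avail)
        n_right = min(half, r_avail)
        deficit = n_neighbors - n_left - n_right
        if deficit > 0:
            add_r = min(deficit, r_avail - n_right)
            n_right += add_r
            deficit -= add_r
            add_l = min(deficit, l_avail - n_left)
            n_left += add_l
            edge[i] = True
        total = n_left + n_right
        if total == 0:
            snr[:, i] = np.nan
            continue
        s = _range_sum(i - skip - n_left, i - skip) + _range_sum(
            i + skip + 1, i + skip + 1 + n_right
        )
        snr[:, i] = ps.power[:, i] / (s / total)
    return SNRSpectrum(
        freqs=ps.freqs,
        snr=snr,
        resolution=ps.resolution,
        channels=ps.channels,
        n_neighbors=n_neighbors,
        n_skip_per_side=n_skip_per_side,
        edge_flag=edge,
    )


def foi_bin(ps: PowerSpectrum | SNRSpectrum, foi: float) -> int:
    """Index of the DFT bin carrying ``foi``.

    Raises if the frequency lies outside the band or misses the nearest bin
    by more than a quarter of the resolution — the signature of an epoch
    that does not span an integer number of triple cycles. (A quarter bin
    rather than half: on a uniform grid some bin is always within half a
    bin, so the misalignment guard would otherwise never fire.)
    """
    freqs = ps.freqs
    if foi < freqs[0] or foi > freqs[-1]:
        raise MisalignedFrequencyError(f"{foi} Hz outside the analysis band")
    idx = int(np.argmin(np.abs(freqs - foi)))
    if abs(freqs[idx] - foi) > ps.resolution / 4.0:
        raise MisalignedFrequencyError(
            f"{foi} Hz is {abs(freqs[idx] - foi):.4g} Hz off the nearest bin"
        )
    return idx


def harmonic_of(foi: float, k: int) -> float:
    """k-th harmonic: the first harmonic is twice the fundamental."""
    if k < 0:
        raise ValueError("harmonic order must be >= 0")
    return (k + 1) * foi
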