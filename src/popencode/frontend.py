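"""Stimulus and response preprocessing.

Converts sound waveforms into the log-compressed gammatone spectrogram that
all encoding models take as input, and spike times into binned trial rasters
/ peristimulus time histograms (PSTHs).  The frontend is fixed: its
parameters are never fit alongside the models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal


__all__ = [
    "Spectrogram",
    "TrialRaster",
    "gammatone_spectrogram",
    "bin_spikes",
    "gammatone_frequency_response",
    "load_wav",
]


def load_wav(path):
    """Read a WAV file; returns ``(waveform, sample_rate)``.

    Multi-channel audio is averaged to mono; integer PCM is rescaled to
    [-1, 1] floats.
    """
    import scipy.io.wavfile
    sample_rate, data = scipy.io.wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    peak = np.abs(data).max()
    if peak > 1.5:            # integer PCM: rescale to unit range
        data = data / peak
    return data, float(sample_rate)


@dataclass
class Spectrogram:
    """Log-compressed power spectrogram, frequency x time.

    Attributes
    ----------
    values : ndarray, shape (F, T)
        Nonnegative log-compressed power; channel 0 is the lowest frequency.
    center_freqs : ndarray, shape (F,)
        Filter center frequencies in Hz, strictly increasing.
    bin_size : float
        Time-bin width in seconds (10 ms default, i.e. 100 Hz sampling).
    seg_lens : ndarray of int, optional
        Lengths of independent stimulus snippets concatenated along the time
        axis.  Convolutional models treat snippet boundaries as silence
        (zero-padding) rather than letting responses bleed across snippets.
        Defaults to one segment covering the whole array.
    """

    values: np.ndarray
    center_freqs: np.ndarray
    bin_size: float = 0.010
    seg_lens: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (F x T)")
        if self.values.shape[0] != self.center_freqs.size:
            raise ValueError("channel count does not match center_freqs")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("center_freqs must be strictly increasing")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.isnan(self.values).any():
            raise ValueError("spectrogram contains NaN")
        if self.seg_lens is None:
            self.seg_lens = np.array([self.values.shape[1]], dtype=int)
        else:
            self.seg_lens = np.asarray(self.seg_lens, dtype=int)
            if self.seg_lens.sum() != self.values.shape[1]:
                raise ValueError("seg_lens must sum to the number of time bins")

    @property
    def F(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def seg_ids(self) -> np.ndarray:
        """Snippet index of every time bin (used for boundary handling)."""
        return np.repeat(np.arange(self.seg_lens.size), self.seg_lens)

    def subset_segments(self, idx) -> "Spectrogram":
        """New Spectrogram keeping only the snippets listed in ``idx``."""
        idx = np.asarray(idx, dtype=int)
        starts = np.concatenate([[0], np.cumsum(self.seg_lens)])
        cols = np.concatenate(
            [np.arange(starts[i], starts[i + 1]) for i in idx]
        ) if idx.size else np.array([], dtype=int)
        return Spectrogram(
            self.values[:, cols], self.center_freqs, self.bin_size,
            seg_lens=self.seg_lens[idx],
        )


@dataclass
class TrialRaster:
    """Trial-resolved spike-rate raster, neurons x time x repeats."""

    rates: np.ndarray                      # (N, T, M), spikes/s
    bin_size: float = 0.010
    neuron_ids: np.ndarray = None
    site_ids: np.ndarray = None

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be 3-D (N x T x M)")
        if not np.isfinite(self.rates).all():
            raise ValueError("rates must be finite")
        if (self.rates < 0).any():
            raise ValueError("rates must be nonnegative")
        if self.rates.shape[2] < 1:
            raise ValueError("need at least one repeat")
        n = self.rates.shape[0]
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(n)
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
        if self.site_ids is None:
            self.site_ids = np.zeros(n, dtype=int)
        else:
            self.site_ids = np.asarray(self.site_ids)
        if self.neuron_ids.size != n or self.site_ids.size != n:
            raise ValueError("neuron_ids / site_ids length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.rates.shape[2]

    def psth(self) -> np.ndarray:
        """Trial-averaged rate, shape (N, T)."""
        return self.rates.mean(axis=2)

    def subset_neurons(self, rows) -> "TrialRaster":
        rows = np.asarray(rows, dtype=int)
        return TrialRaster(self.rates[rows], self.bin_size,
                           self.neuron_ids[rows], self.site_ids[rows])

    def subset_time(self, cols, seg_lens=None) -> "TrialRaster":
        return TrialRaster(self.rates[:, cols, :], self.bin_size,
                           self.neuron_ids, self.site_ids)


def _gammatone_centers(n_channels: int, f_low: float, f_high: float) -> np.ndarray:
    """Log-spaced center frequencies from f_low to f_high inclusive."""
    return np.geomspace(f_low, f_high, n_channels)


def gammatone_frequency_response(center_freq: float, freqs, order: int = 2,
                                 sample_rate: float = 44100.0,
                                 numtaps: int | None = None) -> np.ndarray:
    """Magnitude response of one gammatone channel at the given frequencies.

    Evaluates the FIR impulse response used by :func:`gammatone_spectrogram`
    directly, so it can serve as an independent check of which channel a pure
    tone should drive hardest.
    """
    if numtaps is None:
        numtaps = int(0.05 * sample_rate)
    b, _ = scipy.signal.gammatone(center_freq, "fir", order=order,
                                  numtaps=numtaps, fs=sample_rate)
    w, h = scipy.signal.freqz(b, 1, worN=2 * np.pi * np.atleast_1d(freqs) / sample_rate)
    return np.abs(h)


def gammatone_spectrogram(waveform, sample_rate: float, n_channels: int = 18,
                          f_low: float = 200.0, f_high: float = 20000.0,
                          out_rate: float = 100.0, order: int = 2,
                          compression_eps: float = 1e-5,
                          envelope: str = "power") -> Spectrogram:
    """Convert an audio waveform to a log-compressed gammatone spectrogram.

    The filterbank applies ``n_channels`` gammatone filters of the given
    order with center frequencies log-spaced from ``f_low`` to ``f_high``
    inclusive.  The per-channel envelope (squared filter output by default,
    half-wave rectified if ``envelope='halfwave'``) is averaged within each
    output bin, then log-compressed as ``log10(1 + power / eps)`` where
    ``eps = compression_eps * max(power)`` — so silence maps exactly to the
    floor value 0, never to -inf, and the output is nonnegative.

    Parameters
    ----------
    waveform : 1-D array
        Sound pressure waveform.
    sample_rate : float
        Waveform sampling rate in Hz; must exceed twice ``f_high``.
    out_rate : float
        Output frame rate in Hz (100 Hz -> 10 ms bins).
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if f_low >= f_high:
        raise ValueError("f_low must be below f_high")
    if sample_rate <= 2 * f_high:
        raise ValueError("f_high is at or above the Nyquist frequency")
    if envelope not in ("power", "halfwave"):
        raise ValueError(f"unknown envelope mode {envelope!r}")

    centers = _gammatone_centers(n_channels, f_low, f_high)
    numtaps = int(0.05 * sample_rate)
    dec = sample_rate / out_rate
    n_out = int(np.ceil(waveform.size / dec))

    power = np.zeros((n_channels, n_out))
    # bin index of every waveform sample; envelope averaged within each bin
    bin_idx = np.minimum((np.arange(waveform.size) / dec).astype(int), n_out - 1)
    counts = np.bincount(bin_idx, minlength=n_out)
    for j, fc in enumerate(centers):
        b, _ = scipy.signal.gammatone(fc, "fir", order=order,
                                      numtaps=numtaps, fs=sample_rate)
        y = scipy.signal.fftconvolve(waveform, b, mode="full")[: waveform.size]
        env = y * y if envelope == "power" else np.maximum(y, 0.0)
        power[j] = np.bincount(bin_idx, weights=env, minlength=n_out) / counts

    ref = power.max()
    if ref <= 0:                       # silence: all bins sit on the floor
        values = np.zeros_like(power)
    else:
        eps = compression_eps * ref
        values = np.log10(1.0 + power / eps)
    return Spectrogram(values, centers, bin_size=1.0 / out_rate)


def bin_spikes(spike_times, duration: float, bin_size: float = 0.010,
               neuron_ids=None, site_ids=None) -> TrialRaster:
    """Bin spike times into a rate raster.

    Parameters
    ----------
    spike_times : nested sequence
        ``spike_times[n][m]`` is an array of spike times (seconds) for neuron
        ``n`` on trial ``m``; all times must lie in ``[0, duration)``.
    duration : float
        Trial duration in seconds; ``T = ceil(duration / bin_size)`` bins.

    Returns
    -------
    TrialRaster
        Rates in spikes/s, so ``sum(rate * bin_size)`` over bins recovers the
        exact spike count of each trial.
    """
    n_neurons = len(spike_times)
    if n_neurons == 0:
        raise ValueError("no neurons")
    n_trials = len(spike_times[0])
    T = int(np.ceil(duration / bin_size))
    edges = np.arange(T + 1) * bin_size
    rates = np.zeros((n_neurons, T, n_trials))
    for n, trials in enumerate(spike_times):
        if len(trials) != n_trials:
            raise ValueError("all neurons must have the same trial count")
        for m, st in enumerate(trials):
            st = np.asarray(st, dtype=float)
            if st.size and (st.min() < 0 or st.max() >= duration):
                raise ValueError("spike time outside [0, duration)")
            counts, _ = np.histogram(st, bins=edges)
            rates[n, :, m] = counts / bin_size
    return TrialRaster(rates, bin_size, neuron_ids, site_ids)
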