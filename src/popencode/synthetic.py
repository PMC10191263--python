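"""Synthetic stimuli and ground-truth populations for testing the pipeline.

The generator emulates the statistical structure the analyses assume:

* a stimulus ensemble of concatenated ~1 s naturalistic spectrogram
  snippets (low-pass 1/f modulation spectra in time and frequency, sparse
  nonnegative values, brief silent gaps);
* a neural population whose tuning lies in a shared low-dimensional
  spectro-temporal subspace — the ground truth is itself a 1D-CNN whose
  convolutional bank defines the subspace, with random per-neuron readouts;
* trial-to-trial variability calibrated per neuron so that the repeat-wise
  signal-variance fraction (SNR) matches a target in (0, 1], giving
  TTRC < 1 on the validation raster;
* the estimation/validation design of the recordings: many single-repeat
  estimation snippets and a few high-repeat (M = 20) validation snippets,
  disjoint, with neurons grouped into recording sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage

from .frontend import Spectrogram, TrialRaster
from .models import ModelSpec, ParameterSet, build_network
from .layers import Network

__all__ = ["GroundTruthPopulation", "SyntheticDataset", "generate_stimuli",
           "generate_population", "simulate_responses", "make_dataset"]


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def generate_stimuli(n_snippets: int, snippet_duration: float = 1.0,
                     F: int = 18, seed: int = 0, bin_size: float = 0.010,
                     slope: float = 1.0, amplitude: float = 1.0,
                     gap: float = 0.1) -> Spectrogram:
    """Naturalistic spectrogram snippets with 1/f modulation spectra.

    White Gaussian noise per snippet is shaped in the 2-D Fourier domain
    with amplitude ``(1 + f/f0)^-slope`` along both the temporal and
    spectral modulation axes, normalized to unit variance, then half-wave
    shifted (``max(field + 1, 0) * amplitude``) so values are nonnegative
    with silence at 0, matching the frontend's log-compression floor
    convention.  The last ``gap`` seconds of each snippet are silent.
    ``amplitude=0`` yields all-floor spectrograms.
    """
    if n_snippets < 2:
        raise ValueError("need at least 2 snippets")
    rng = np.random.default_rng(seed)
    Ts = int(round(snippet_duration / bin_size))
    gap_bins = min(int(round(gap / bin_size)), Ts // 2)
    ft = np.fft.fftfreq(Ts)[None, :]
    fx = np.fft.fftfreq(F)[:, None]
    f0 = 0.02
    shaper = ((1 + np.abs(ft) / f0) ** -slope) * ((1 + np.abs(fx) / f0) ** -slope)
    pieces = []
    for _ in range(n_snippets):
        z = rng.normal(size=(F, Ts))
        field = np.fft.ifft2(np.fft.fft2(z) * shaper).real
        sd = field.std()
        if sd > 0:
            field /= sd
        vals = amplitude * np.maximum(field + 1.0, 0.0)
        if gap_bins:
            vals[:, Ts - gap_bins:] = 0.0
        pieces.append(vals)
    values = np.concatenate(pieces, axis=1)
    centers = np.geomspace(200.0, 20000.0, F)
    return Spectrogram(values, centers, bin_size,
                       seg_lens=np.full(n_snippets, Ts))


# ---------------------------------------------------------------------------
# ground-truth population
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthPopulation:
    """A known population encoding model used to simulate responses."""

    spec: ModelSpec
    params: ParameterSet
    site_ids: np.ndarray
    snr_per_neuron: np.ndarray          # target signal-variance fraction
    subspace_dim: int
    seed: int
    network: Network = None

    def __post_init__(self):
        if self.network is None:
            self.network = build_network(self.spec)
            self.params.apply_to(self.network)

    def rates(self, stim: Spectrogram) -> np.ndarray:
        """Noise-free firing rates (N x T) for a stimulus."""
        return self.network.forward(stim.values, stim.seg_ids)


def _smooth_taps(rng, n_units, n_taps):
    taps = rng.normal(size=(n_units, n_taps))
    taps = scipy.ndimage.gaussian_filter1d(taps, sigma=1.5, axis=1)
    taps *= np.exp(-np.arange(n_taps) / 8.0)
    taps /= np.linalg.norm(taps, axis=1, keepdims=True)
    return taps


def generate_population(N: int, subspace_dim: int = 10, sites: int = 3,
                        snr_range=(0.3, 0.9), seed: int = 0, F: int = 18,
                        n_taps: int = 25,
                        orthogonal_site: int | None = None
                        ) -> GroundTruthPopulation:
    """Build a ground-truth 1D-CNN population with shared-subspace tuning.

    The convolutional bank has ``subspace_dim`` units (the shared subspace);
    hidden and readout weights are random, and the output nonlinearity of
    each neuron is calibrated on an internally generated probe stimulus so
    its drive is well-modulated (threshold at the median drive, gain scaled
    by the drive's spread).  Per-neuron target SNR is drawn uniformly from
    ``snr_range``.

    ``orthogonal_site`` gives one site its own private convolutional/hidden
    block, disjoint from the shared subspace — a control population in which
    that site's tuning cannot be predicted from the others'.
    """
    if N < 1 or subspace_dim < 1:
        raise ValueError("N and subspace_dim must be >= 1")
    rng = np.random.default_rng(seed)
    site_ids = np.arange(N) % sites
    n_blocks = 2 if orthogonal_site is not None else 1
    C = subspace_dim * n_blocks
    H = subspace_dim * n_blocks
    spec = ModelSpec("1D-CNN", n_neurons=N, n_freq=F, conv_units=C,
                     n_taps=n_taps, hidden_units=H)
    net = build_network(spec)
    conv, hidden, readout, dexp = net.layers

    conv.params["mu"] = rng.uniform(1.0, F - 2.0, C)
    conv.params["sigma"] = rng.uniform(0.7, 2.5, C)
    conv.params["taps"] = _smooth_taps(rng, C, n_taps)

    Wh = np.zeros((H, C))
    for blk in range(n_blocks):
        rows = slice(blk * subspace_dim, (blk + 1) * subspace_dim)
        Wh[rows, rows] = rng.normal(0, 1.0 / np.sqrt(subspace_dim),
                                    (subspace_dim, subspace_dim))
    hidden.params["w"] = Wh

    Wr = np.zeros((N, H))
    for n in range(N):
        blk = 1 if (orthogonal_site is not None
                    and site_ids[n] == orthogonal_site) else 0
        cols = slice(blk * subspace_dim, (blk + 1) * subspace_dim)
        Wr[n, cols] = rng.normal(0, 1.0 / np.sqrt(subspace_dim), subspace_dim)
    readout.params["w"] = Wr

    # calibrate offsets and the output nonlinearity on a probe ensemble
    probe = generate_stimuli(16, 1.0, F=F,
                             seed=int(rng.integers(2**31 - 1)))
    conv.forward(probe.values, probe.seg_ids)
    conv.params["offset"] = np.quantile(conv._y, 0.4, axis=1)  # pre-activation
    h1 = conv.forward(probe.values, probe.seg_ids)
    pre = hidden.params["w"] @ h1
    hidden.params["offset"] = np.quantile(pre, 0.4, axis=1)
    feats = hidden.forward(h1, probe.seg_ids)
    drive = Wr @ feats
    spread = np.maximum(drive.std(axis=1), 1e-6)
    dexp.params["s"] = np.quantile(drive, 0.5, axis=1)
    dexp.params["k"] = -2.0 / spread
    dexp.params["a"] = rng.uniform(20.0, 60.0, N)
    dexp.params["b"] = rng.uniform(1.0, 8.0, N)

    snr_per_neuron = rng.uniform(*snr_range, N)
    return GroundTruthPopulation(spec, ParameterSet.from_network(net),
                                 site_ids, snr_per_neuron, subspace_dim,
                                 seed, network=net)


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

def simulate_responses(pop: GroundTruthPopulation, stim: Spectrogram,
                       n_repeats: int = 1, noise_model: str = "gaussian",
                       seed: int = 0) -> TrialRaster:
    """Simulate a trial raster from the ground-truth rates.

    ``gaussian``: trial rate = true rate + independent Gaussian noise whose
    variance is set per neuron so the signal-variance fraction equals the
    neuron's target SNR ``q`` (noise_var = signal_var * (1-q)/q); rates are
    clipped at zero.  ``poisson``: per-bin spike counts drawn from the rate,
    converted back to spikes/s.
    """
    if noise_model not in ("gaussian", "poisson"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    R = pop.rates(stim)
    N, T = R.shape
    out = np.empty((N, T, n_repeats))
    if noise_model == "gaussian":
        sig_var = R.var(axis=1)
        q = np.clip(pop.snr_per_neuron, 1e-6, 1.0)
        noise_sd = np.sqrt(sig_var * (1 - q) / q)
        noise = rng.normal(size=(N, T, n_repeats)) * noise_sd[:, None, None]
        out = np.maximum(R[:, :, None] + noise, 0.0)
    else:
        binw = stim.bin_size
        counts = rng.poisson(np.maximum(R[:, :, None], 0.0) * binw,
                             size=(N, T, n_repeats))
        out = counts / binw
    return TrialRaster(out, stim.bin_size,
                       neuron_ids=np.arange(N), site_ids=pop.site_ids)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Estimation + validation stimulus/response pairs with ground truth.

    Mirrors the recording design: a large single-repeat estimation set and
    a small 20-repeat validation set with disjoint snippets.
    """

    est_stim: Spectrogram
    est_resp: TrialRaster
    val_stim: Spectrogram
    val_resp: TrialRaster
    truth: GroundTruthPopulation = None
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self):
        return self.est_resp.n_neurons

    @property
    def site_ids(self):
        return self.est_resp.site_ids

    @property
    def neuron_ids(self):
        return self.est_resp.neuron_ids

    def subset_neurons(self, rows) -> "SyntheticDataset":
        return replace(self, est_resp=self.est_resp.subset_neurons(rows),
                       val_resp=self.val_resp.subset_neurons(rows))


def make_dataset(N: int = 60, subspace_dim: int = 10, sites: int = 3,
                 n_est_snippets: int = 120, n_val_snippets: int = 12,
                 snippet_duration: float = 1.0, n_val_repeats: int = 20,
                 snr_range=(0.3, 0.9), F: int = 18, seed: int = 0,
                 noise_model: str = "gaussian",
                 orthogonal_site: int | None = None) -> SyntheticDataset:
    """Default desk-scale fixture: N=60 neurons in 3 sites, 120 estimation
    snippets of 1 s (single repeat) and 12 validation snippets with 20
    repeats, F=18 channels at 100 Hz."""
    root = np.random.default_rng(seed)
    s_stim, s_pop, s_est, s_val, s_vstim = root.integers(2**31 - 1, size=5)
    est_stim = generate_stimuli(n_est_snippets, snippet_duration, F=F,
                                seed=int(s_stim))
    val_stim = generate_stimuli(n_val_snippets, snippet_duration, F=F,
                                seed=int(s_vstim))
    pop = generate_population(N, subspace_dim, sites, snr_range,
                              seed=int(s_pop), F=F,
                              orthogonal_site=orthogonal_site)
    est_resp = simulate_responses(pop, est_stim, 1, noise_model, int(s_est))
    val_resp = simulate_responses(pop, val_stim, n_val_repeats, noise_model,
                                  int(s_val))
    return SyntheticDataset(est_stim, est_resp, val_stim, val_resp, pop,
                            meta={"seed": seed, "noise_model": noise_model})
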