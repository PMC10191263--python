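"""Model architectures: LN and convolutional spectro-temporal encoders.

Six architectures predict time-varying firing rates from a spectrogram:

* ``LN`` — rank-D factorized linear filter (Gaussian spectral weighting x
  temporal FIR) plus a double-exponential output nonlinearity; one neuron.
* ``single-CNN`` — one 1-D convolutional layer (Gaussian spectral units,
  offset ReLU) and one dense output unit; one neuron.
* ``pop-LN`` — a shared bank of linear 1-D convolutional units (no
  activation) with per-neuron dense readouts; the minimal population model.
* ``1D-CNN`` — convolutional layer + hidden dense layer + per-neuron output.
* ``1Dx2-CNN`` — two convolutional layers (150 ms then 100 ms filters,
  250 ms total context) + hidden dense + per-neuron output.
* ``2D-CNN`` — three stacked 2-D convolutional layers (3 spectral x 8
  temporal kernels) + hidden dense + per-neuron output.

All population outputs pass through a per-neuron double exponential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .frontend import Spectrogram
from .layers import (Conv1D, Conv2D, Dense, DoubleExp, Flatten, Network,
                     SumChannels, WIDTH_FLOOR, _EXP_CLIP)

__all__ = [
    "GaussianSpectralUnit", "TemporalFIRUnit", "OffsetReLU",
    "DoubleExponential", "Conv2DUnit", "DenseUnit", "ModelSpec",
    "ParameterSet", "build_network", "double_exponential", "ln_forward",
    "conv1d_layer_forward", "conv2d_layer_forward", "population_forward",
    "count_parameters",
]

ARCHITECTURES = ("LN", "pop-LN", "single-CNN", "1D-CNN", "1Dx2-CNN", "2D-CNN")


# ---------------------------------------------------------------------------
# unit-level domain types (thin views used by the functional ops and tests)
# ---------------------------------------------------------------------------

@dataclass
class GaussianSpectralUnit:
    center: float                  # mu, channel-index units
    width: float                   # sigma, channel-index units

    def weights(self, n_channels: int) -> np.ndarray:
        j = np.arange(n_channels)
        sig = max(self.width, WIDTH_FLOOR)
        return np.exp(-((j - self.center) ** 2) / (2.0 * sig**2))


@dataclass
class TemporalFIRUnit:
    taps: np.ndarray               # length U; U * bin_size = filter memory


@dataclass
class OffsetReLU:
    offset: float = 0.0

    def __call__(self, x):
        return np.maximum(0.0, x - self.offset)


@dataclass
class DoubleExponential:
    b: float = 0.0                 # baseline rate
    a: float = 1.0                 # saturation amplitude
    s: float = 0.0                 # threshold
    k: float = 1.0                 # gain


@dataclass
class Conv2DUnit:
    kernel: np.ndarray             # (n_in, 3, 8)
    offset: float = 0.0


@dataclass
class DenseUnit:
    weights: np.ndarray
    offset: float = 0.0


# ---------------------------------------------------------------------------
# ModelSpec
# ---------------------------------------------------------------------------

_EXEMPLAR_SIZES = {
    # layer sizes of the exemplar model of each architecture
    "LN": dict(rank=5, n_taps=25),
    "pop-LN": dict(conv_units=120, n_taps=25),
    "single-CNN": dict(conv_units=6, n_taps=25),
    "1D-CNN": dict(conv_units=100, n_taps=25, hidden_units=120),
    "1Dx2-CNN": dict(conv_units=70, n_taps=15, conv2_units=80, conv2_taps=10,
                     hidden_units=100),
    "2D-CNN": dict(conv2d_units=10, conv2d_layers=3, kf=3, kt=8,
                   hidden_units=90),
}


@dataclass
class ModelSpec:
    """Declarative architecture description.

    ``n_neurons`` must be 1 for the single-neuron architectures (LN,
    single-CNN).  Unspecified sizes default to the exemplar models.
    """

    architecture: str
    n_neurons: int = 1
    n_freq: int = 18
    rank: int = 0                       # LN only; 0 -> exemplar default
    n_taps: int = 0
    conv_units: int = 0
    conv2_units: int = 0
    conv2_taps: int = 0
    hidden_units: int = 0
    conv2d_units: int = 0
    conv2d_layers: int = 0
    kf: int = 0
    kt: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture in ("LN", "single-CNN") and self.n_neurons != 1:
            raise ValueError(f"{self.architecture} predicts a single neuron")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        defaults = dict(rank=5, n_taps=25, conv2_taps=10, conv2d_units=10,
                        conv2d_layers=3, kf=3, kt=8)
        defaults.update(_EXEMPLAR_SIZES[self.architecture])
        for key, val in defaults.items():
            if getattr(self, key, 0) in (0, None):
                setattr(self, key, val)
        for key in ("rank", "n_taps", "n_freq"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be positive")

    @classmethod
    def exemplar(cls, architecture: str, n_neurons: int = 1) -> "ModelSpec":
        return cls(architecture=architecture, n_neurons=n_neurons)

    def to_json(self) -> str:
        return json.dumps({"schema": "popencode-modelspec-1", **asdict(self)},
                          indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        if d.pop("schema", None) != "popencode-modelspec-1":
            raise ValueError("not a popencode model spec")
        return cls(**d)


def build_network(spec: ModelSpec) -> Network:
    """Instantiate the layer stack for a ModelSpec (parameters zeroed /
    defaults; see :mod:`popencode.fitting` for initialization)."""
    F, N = spec.n_freq, spec.n_neurons
    a = spec.architecture
    if a == "LN":
        layers = [Conv1D(spec.rank, spec.n_taps, F, "gaussian", None),
                  SumChannels(), DoubleExp(1)]
        return Network(layers, output_start=1)
    if a == "single-CNN":
        layers = [Conv1D(spec.conv_units, spec.n_taps, F, "gaussian", "relu"),
                  Dense(1, spec.conv_units, None), DoubleExp(1)]
        return Network(layers, output_start=1)
    if a == "pop-LN":
        layers = [Conv1D(spec.conv_units, spec.n_taps, F, "gaussian", None),
                  Dense(N, spec.conv_units, None), DoubleExp(N)]
        return Network(layers, output_start=1)
    if a == "1D-CNN":
        layers = [Conv1D(spec.conv_units, spec.n_taps, F, "gaussian", "relu"),
                  Dense(spec.hidden_units, spec.conv_units, "relu"),
                  Dense(N, spec.hidden_units, None), DoubleExp(N)]
        return Network(layers, output_start=2)
    if a == "1Dx2-CNN":
        layers = [Conv1D(spec.conv_units, spec.n_taps, F, "gaussian", "relu"),
                  Conv1D(spec.conv2_units, spec.conv2_taps, spec.conv_units,
                         "dense", "relu"),
                  Dense(spec.hidden_units, spec.conv2_units, "relu"),
                  Dense(N, spec.hidden_units, None), DoubleExp(N)]
        return Network(layers, output_start=3)
    # 2D-CNN
    layers = [Conv2D(spec.conv2d_units, 1, spec.kf, spec.kt, "relu")]
    for _ in range(spec.conv2d_layers - 1):
        layers.append(Conv2D(spec.conv2d_units, spec.conv2d_units,
                             spec.kf, spec.kt, "relu"))
    layers += [Flatten(),
               Dense(spec.hidden_units, spec.conv2d_units * F, "relu"),
               Dense(N, spec.hidden_units, None), DoubleExp(N)]
    return Network(layers, output_start=len(layers) - 2)


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------

class ParameterSet:
    """Flat, labelled collection of every trainable value of a network."""

    def __init__(self, vector: np.ndarray, labels):
        self.vector = np.asarray(vector, dtype=float)
        self.labels = list(labels)      # (layer_idx, role, shape) per block
        n = sum(int(np.prod(s)) for _, _, s in self.labels)
        if n != self.vector.size:
            raise ValueError("parameter vector does not match its layout")

    def __len__(self):
        return self.vector.size

    @classmethod
    def from_network(cls, net: Network) -> "ParameterSet":
        labels = [(i, name, v.shape) for i, name, v in net.param_items()]
        return cls(net.get_flat(), labels)

    def apply_to(self, net: Network):
        net.set_flat(self.vector)


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def double_exponential(y, params: DoubleExponential):
    """r = b + a * exp(-exp(k (y - s))); elementwise over ``y``.

    The inner exponent is clipped so extreme drives saturate instead of
    overflowing.
    """
    y = np.asarray(y, dtype=float)
    z = np.clip(params.k * (y - params.s), -_EXP_CLIP, _EXP_CLIP)
    return params.b + params.a * np.exp(-np.exp(z))


def ln_forward(stim: Spectrogram, spectral, temporal,
               out_nl: DoubleExponential) -> np.ndarray:
    """Rank-D LN model prediction for one neuron.

    The linear drive is ``r_lin(t) = sum_f sum_u h[f,u] s(f, t-u)`` with
    ``h = sum_d g_d (x) taps_d``, evaluated causally with zero padding before
    each snippet; the returned rate applies the double exponential.
    """
    taps = np.atleast_2d(np.asarray(
        [u.taps if isinstance(u, TemporalFIRUnit) else u for u in temporal]
        if not isinstance(temporal, np.ndarray) else temporal, dtype=float))
    D = len(spectral)
    if taps.shape[0] != D:
        raise ValueError("spectral / temporal rank mismatch")
    spec = ModelSpec("LN", rank=D, n_taps=taps.shape[1], n_freq=stim.F)
    net = build_network(spec)
    conv = net.layers[0]
    conv.params["mu"] = np.array([u.center for u in spectral], dtype=float)
    conv.params["sigma"] = np.array([u.width for u in spectral], dtype=float)
    conv.params["taps"] = taps
    dexp = net.layers[2]
    for role in ("b", "a", "s", "k"):
        dexp.params[role] = np.array([getattr(out_nl, role)], dtype=float)
    return net.forward(stim.values, stim.seg_ids)[0]


def conv1d_layer_forward(inputs: np.ndarray, units, seg_ids=None,
                         activation="relu") -> np.ndarray:
    """Forward pass of one 1-D convolutional layer.

    ``units`` is a list of ``(weighting, TemporalFIRUnit, OffsetReLU)``
    triples where ``weighting`` is a :class:`GaussianSpectralUnit` (first
    layer) or a plain weight vector / :class:`DenseUnit` (deeper layers).
    Pass ``activation=None`` for the linear convolutional bank of pop-LN.
    """
    inputs = np.asarray(inputs, dtype=float)
    n_in, T = inputs.shape
    if seg_ids is None:
        seg_ids = np.zeros(T, dtype=int)
    rows = []
    for wspec, fir, relu in units:
        if isinstance(wspec, GaussianSpectralUnit):
            w = wspec.weights(n_in)
        elif isinstance(wspec, DenseUnit):
            w = np.asarray(wspec.weights, dtype=float)
        else:
            w = np.asarray(wspec, dtype=float)
        if w.size != n_in:
            raise ValueError("input weighting length mismatch")
        taps = np.asarray(fir.taps if isinstance(fir, TemporalFIRUnit) else fir,
                          dtype=float)
        from .layers import _causal_conv
        y = _causal_conv((w @ inputs)[None], taps[None], seg_ids)[0]
        if activation == "relu":
            off = relu.offset if isinstance(relu, OffsetReLU) else float(relu)
            y = np.maximum(0.0, y - off)
        rows.append(y)
    return np.array(rows)


def conv2d_layer_forward(inputs: np.ndarray, units, seg_ids=None) -> np.ndarray:
    """Forward pass of one 2-D convolutional layer (channel x freq x time)."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim == 2:
        inputs = inputs[None]
    n_in = inputs.shape[0]
    T = inputs.shape[2]
    if seg_ids is None:
        seg_ids = np.zeros(T, dtype=int)
    kf, kt = units[0].kernel.shape[-2:]
    layer = Conv2D(len(units), n_in, kf, kt, "relu")
    layer.params["kernel"] = np.array([u.kernel for u in units], dtype=float)
    layer.params["offset"] = np.array([u.offset for u in units], dtype=float)
    return layer.forward(inputs, seg_ids)


def population_forward(stim: Spectrogram, spec: ModelSpec,
                       params: ParameterSet) -> np.ndarray:
    """Predicted rate matrix (N x T) for any architecture: shared layers are
    computed once, then each neuron's dense readout and double exponential."""
    net = build_network(spec)
    if len(params) != net.n_params:
        raise ValueError("parameter set does not match the model spec")
    params.apply_to(net)
    out = net.forward(stim.values, stim.seg_ids)
    return out


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def count_parameters(spec: ModelSpec, count_offsets: str = "exclude_first_conv"):
    """Total trainable-value count and per-layer breakdown.

    Convention: a Gaussian spectral unit contributes 2 values (center,
    width), a temporal FIR unit U values, a dense unit its fan-in, an offset
    ReLU 1 per unit, a double exponential 4 per output neuron.

    ``count_offsets`` controls activation offsets: ``'all'`` counts every
    offset; ``'exclude_first_conv'`` (default) omits the offsets of the
    spectrogram-facing convolutional layer, matching the convention in which
    a 70-unit, 15-tap first layer totals 70*2 + 70*15 = 1,190.

    Returns
    -------
    total : int
    breakdown : list of dict
        Per layer: name, count under both conventions.
    """
    if count_offsets not in ("all", "exclude_first_conv"):
        raise ValueError(count_offsets)
    net = build_network(spec)
    breakdown = []
    total = 0
    for i, lyr in enumerate(net.layers):
        full = lyr.n_params
        no_off = full - lyr.params.get("offset", np.zeros(0)).size
        first_conv = i == 0 and isinstance(lyr, (Conv1D, Conv2D))
        counted = no_off if (count_offsets == "exclude_first_conv"
                             and first_conv) else full
        breakdown.append({"layer": i, "type": type(lyr).__name__,
                          "count": counted, "count_with_offsets": full,
                          "count_without_offsets": no_off})
        total += counted
    return total, breakdown
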