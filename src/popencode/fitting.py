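"""Two-stage gradient fitting of encoding models to a population raster.

Stage 1 fits the whole model to all neurons of one population at once with a
mean-squared-error loss averaged over neurons and time.  Each of ``n_init``
initializations (``n_init - 1`` random draws plus one set to the means of the
initialization distributions) runs a three-step heuristic:

  A. fit the shared core with the output layer replaced by a temporary
     per-neuron linear readout (weights + offset, no output nonlinearity);
  B. fit the real output layer with all other layers frozen;
  C. (best initialization only, judged by early-stop-split MSE) fit all
     parameters jointly.

Early stopping holds out a fraction of the estimation snippets (20% by
default); the parameters reported for every step are those of the epoch with
the minimum early-stop-split loss.

Stage 2 refits the output layer one neuron at a time with the core frozen,
which also serves to fit readouts of neurons excluded from stage 1
(held-out-site generalization).

The optimizer is full-batch Adam (adaptive-moment stochastic gradient
descent); the datasets involved are small enough that mini-batching buys
nothing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .frontend import Spectrogram, TrialRaster
from .layers import Conv1D, Conv2D, Dense, DoubleExp, Network
from .models import ModelSpec, ParameterSet, build_network

__all__ = ["FitConfig", "FitResult", "split_estimation", "initialize",
           "fit_stage1", "fit_stage2", "predict"]


@dataclass
class FitConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 5000
    patience: int = 30          # early-stop epochs without improvement
    es_fraction: float = 0.2    # estimation fraction held out for early stop
    n_init: int = 10
    seed: int = 0
    tolerance: float = 1e-6     # relative improvement threshold
    dtype: str = "float64"      # optimizer precision ("float32" is ~2x
                                # faster on large fits; results stay
                                # deterministic for a given seed)
    pre_epochs: int | None = None   # epoch cap for stage-1 steps A and B
                                    # (initialization screening); None ->
                                    # same as max_epochs

    def __post_init__(self):
        if not 0 < self.es_fraction < 1:
            raise ValueError("es_fraction must be in (0, 1)")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass
class FitResult:
    params: ParameterSet
    spec: ModelSpec
    es_loss: float
    chosen_init: int
    stage: int
    seed: int
    loss_trace: dict = field(default_factory=dict)
    n_epochs: int = 0
    failed_inits: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# data splitting
# ---------------------------------------------------------------------------

def split_estimation(stim: Spectrogram, resp: TrialRaster,
                     es_fraction: float = 0.2, seed: int = 0):
    """Split estimation data into fit and early-stop sets by whole snippets.

    The early-stop set gets ``max(1, floor(n * es_fraction))`` snippets,
    chosen by a seeded permutation; the two sets are disjoint and the split
    is reproducible from the seed.

    Returns ``((stim_fit, resp_fit), (stim_es, resp_es))``.
    """
    n = stim.seg_lens.size
    if n < 5:
        raise ValueError("need at least 5 stimulus snippets to split")
    if not 0 < es_fraction < 1:
        raise ValueError("es_fraction must be in (0, 1)")
    n_es = max(1, int(np.floor(n * es_fraction)))
    order = np.random.default_rng(seed).permutation(n)
    es_idx = np.sort(order[:n_es])
    fit_idx = np.sort(order[n_es:])
    return (_take(stim, resp, fit_idx), _take(stim, resp, es_idx))


def _take(stim, resp, idx):
    sub = stim.subset_segments(idx)
    starts = np.concatenate([[0], np.cumsum(stim.seg_lens)])
    cols = np.concatenate([np.arange(starts[i], starts[i + 1]) for i in idx])
    return sub, resp.subset_time(cols)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _response_stats(resp: TrialRaster | None):
    if resp is None:
        return None
    psth = resp.psth()
    return psth.mean(axis=1), psth.std(axis=1)


def _draw_layer(lyr, rng, resp_stats, mean_init: bool):
    """Per-role initialization distributions.

    Gaussian spectral centers uniform over the channel range, widths uniform
    between 0.5 and F/4 channels; FIR taps zero-mean Gaussian except a small
    positive lag-0 mean (so the mean initialization is a weak passthrough
    rather than an exactly dead network); dense weights Gaussian around the
    uniform-average 1/fan_in; ReLU offsets zero-mean.  Output nonlinearity:
    baseline and amplitude scaled to each neuron's response range (if
    response statistics are supplied), gain mean -1 so the mean
    initialization is an increasing function of drive.
    """
    out = {}
    for name, v in lyr.params.items():
        if name == "mu":
            # spectral centers are stratified: unit c draws from the c-th
            # band of the channel axis, so the mean initialization tiles
            # the spectrum like a filterbank instead of collapsing every
            # unit onto the center channel (a perfectly symmetric start
            # leaves identical units identical under gradient descent)
            C = v.shape[0]
            edges = np.linspace(0.0, lyr.n_in - 1.0, C + 1)
            centers = (edges[:-1] + edges[1:]) / 2
            out[name] = (centers.copy() if mean_init
                         else rng.uniform(edges[:-1], edges[1:]))
        elif name == "sigma":
            lo, hi = 0.5, max(1.0, lyr.n_in / 4.0)
            out[name] = (np.full(v.shape, (lo + hi) / 2) if mean_init
                         else rng.uniform(lo, hi, v.shape))
        elif name == "taps":
            m = np.zeros(v.shape)
            m[:, 0] = 0.1
            sd = 0.5 / np.sqrt(v.shape[1])
            out[name] = m if mean_init else m + rng.normal(0, sd, v.shape)
        elif name == "w":
            fan_in = v.shape[1]
            m = np.full(v.shape, 1.0 / fan_in)
            # hidden and convolutional dense weights draw around an
            # identity tiling (unit c emphasizes input c mod fan-in) so
            # the mean initialization stays diverse at every layer;
            # per-neuron readouts have their own targets and keep the
            # plain uniform-average mean
            hidden_like = isinstance(lyr, Conv1D) or (
                isinstance(lyr, Dense) and lyr.activation == "relu")
            if hidden_like:
                rows = np.arange(v.shape[0]) % fan_in
                m[np.arange(v.shape[0]), rows] += 1.0 / np.sqrt(fan_in)
            out[name] = m if mean_init else m + rng.normal(
                0, np.sqrt(2.0 / fan_in), v.shape)
        elif name == "kernel":
            o, i, kf, kt = v.shape
            m = np.zeros(v.shape)
            m[:, :, kf // 2, 0] = 0.1 / i
            sd = 0.2 / np.sqrt(i * kf * kt)
            out[name] = m if mean_init else m + rng.normal(0, sd, v.shape)
        elif name == "offset":
            out[name] = (np.zeros(v.shape) if mean_init
                         else rng.normal(0, 0.05, v.shape))
        elif name in ("b", "a", "s", "k"):
            n = v.shape[0]
            if resp_stats is not None:
                mean_r, std_r = resp_stats
                scale = np.resize(mean_r + 3 * std_r, n)
                scale = np.maximum(scale, 1e-3)
            else:
                scale = np.ones(n)
            if name == "b":
                out[name] = (0.1 * scale if mean_init
                             else rng.uniform(0, 0.2, n) * scale)
            elif name == "a":
                out[name] = (1.0 * scale if mean_init
                             else rng.uniform(0.5, 1.5, n) * scale)
            elif name == "s":
                out[name] = (np.zeros(n) if mean_init
                             else rng.normal(0, 1.0, n))
            else:  # k; negative mean -> rate increases with drive
                out[name] = (np.full(n, -1.0) if mean_init
                             else -rng.uniform(0.5, 1.5, n))
        else:                            # pragma: no cover
            raise KeyError(name)
    return out


def initialize(spec: ModelSpec, n_init: int = 10, seed: int = 0,
               resp: TrialRaster | None = None):
    """Draw ``n_init`` parameter sets; the final entry is always the
    deterministic mean of the initialization distributions."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    stats = _response_stats(resp)
    sets = []
    for i in range(n_init):
        mean_init = i == n_init - 1
        net = build_network(spec)
        for lyr in net.layers:
            if lyr.params:
                drawn = _draw_layer(lyr, rng, stats, mean_init)
                lyr.params.update(drawn)
        sets.append(ParameterSet.from_network(net))
    return sets


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def _mse(pred, y):
    d = pred - y
    return float(np.mean(d * d))


def _optimize(net: Network, layer_idx, fit_data, es_data, config: FitConfig,
              lr: float):
    """Full-batch Adam on the selected layers with early stopping.

    Returns ``(best_es_loss, traces, n_epochs)`` with the network left at
    the best-epoch parameters, or None if the loss diverged to NaN.
    """
    dt = np.dtype(config.dtype)
    Xf, segf, Yf = fit_data
    Xe, sege, Ye = es_data
    if dt != np.float64:
        Xf, Yf, Xe, Ye = (a.astype(dt) for a in (Xf, Yf, Xe, Ye))
        net.set_flat(net.get_flat().astype(dt))
    theta = net.get_flat(layer_idx)
    if theta.size == 0:
        raise ValueError("no trainable parameters selected")
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    b1, b2, eps = 0.9, 0.999, 1e-8
    best_es = _mse(net.forward(Xe, sege), Ye)
    best_theta = theta.copy()
    trace_fit, trace_es = [], [best_es]
    stall = 0
    t = 0
    for epoch in range(config.max_epochs):
        pred = net.forward(Xf, segf)
        loss = _mse(pred, Yf)
        if not np.isfinite(loss):
            return None
        net.zero_grads()
        net.backward(2.0 * (pred - Yf) / Yf.size)
        g = net.grad_flat(layer_idx)
        t += 1
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mh = m / (1 - b1**t)
        vh = v / (1 - b2**t)
        theta = theta - lr * mh / (np.sqrt(vh) + eps)
        net.set_flat(theta, layer_idx)
        es = _mse(net.forward(Xe, sege), Ye)
        trace_fit.append(loss)
        trace_es.append(es)
        if not np.isfinite(es):
            return None
        if es < best_es * (1 - config.tolerance):
            best_es = es
            best_theta = theta.copy()
            stall = 0
        else:
            stall += 1
            if stall > config.patience:
                break
    net.set_flat(best_theta, layer_idx)
    return best_es, {"fit": trace_fit, "es": trace_es}, len(trace_fit)


def _optimize_with_restart(net, layer_idx, fit_data, es_data, config):
    res = _optimize(net, layer_idx, fit_data, es_data, config,
                    config.learning_rate)
    if res is None:       # diverged: one retry at half the learning rate
        res = _optimize(net, layer_idx, fit_data, es_data, config,
                        config.learning_rate / 2)
    return res


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def _core_out_channels(net: Network, n_freq: int) -> int:
    """Channel count of the last shared-core layer's output."""
    ch = n_freq
    for lyr in net.layers[: net.output_start]:
        if isinstance(lyr, Conv1D):
            ch = lyr.n_units
        elif isinstance(lyr, Conv2D):
            ch = lyr.n_units * n_freq   # flattened downstream
        elif isinstance(lyr, Dense):
            ch = lyr.n_out
    return ch


def fit_stage1(spec: ModelSpec, stim: Spectrogram, resp: TrialRaster,
               config: FitConfig) -> FitResult:
    """Population fit of all model parameters (stage 1).

    ``resp`` is the estimation raster; the target is its PSTH and the loss
    is MSE over all neurons and time bins simultaneously.
    """
    if resp.n_neurons != spec.n_neurons:
        raise ValueError("raster neuron count does not match the model spec")
    (stim_f, resp_f), (stim_e, resp_e) = split_estimation(
        stim, resp, config.es_fraction, config.seed)
    fit_data = (stim_f.values, stim_f.seg_ids, resp_f.psth())
    es_data = (stim_e.values, stim_e.seg_ids, resp_e.psth())

    inits = initialize(spec, config.n_init, config.seed, resp)
    pre_config = config if config.pre_epochs is None else replace(
        config, max_epochs=config.pre_epochs)
    rng = np.random.default_rng(config.seed + 1)
    N = spec.n_neurons
    candidates = []
    failed = []
    traces = {}
    for i, ps in enumerate(inits):
        net = build_network(spec)
        ps.apply_to(net)
        # -- step A: core + temporary linear readout ----------------------
        H = _core_out_channels(net, spec.n_freq)
        tmp = Dense(N, H, activation=None, bias=True)
        tmp.params["w"] = rng.normal(0, 1.0 / np.sqrt(H), (N, H))
        tmp.params["b"] = resp.psth().mean(axis=1).copy()
        tmp.zero_grads()
        sub = Network(net.layers[: net.output_start] + [tmp],
                      output_start=net.output_start)
        resA = _optimize_with_restart(sub, None, fit_data, es_data,
                                      pre_config)
        if resA is None:
            failed.append(i)
            continue
        # -- step B: real output layer, core frozen ------------------------
        # the frozen core's features are computed once and reused per epoch
        Hf = net.forward(fit_data[0], fit_data[1], upto=net.output_start)
        He = net.forward(es_data[0], es_data[1], upto=net.output_start)
        head = Network(net.layers[net.output_start:], output_start=0)
        resB = _optimize_with_restart(head, None,
                                      (Hf, fit_data[1], fit_data[2]),
                                      (He, es_data[1], es_data[2]),
                                      pre_config)
        if resB is None:
            failed.append(i)
            continue
        candidates.append((resB[0], i, net.get_flat()))
        traces[i] = {"stepA": resA[1], "stepB": resB[1]}
    if not candidates:
        raise RuntimeError("all initializations diverged")
    # -- step C: joint fit from the best initialization -------------------
    best_es, best_i, theta = min(candidates, key=lambda c: (c[0], c[1]))
    net = build_network(spec)
    net.set_flat(theta)
    resC = _optimize_with_restart(net, None, fit_data, es_data, config)
    if resC is None:
        raise RuntimeError("joint fit diverged")
    traces[best_i]["stepC"] = resC[1]
    return FitResult(params=ParameterSet.from_network(net), spec=spec,
                     es_loss=resC[0], chosen_init=best_i, stage=1,
                     seed=config.seed, loss_trace=traces[best_i],
                     n_epochs=resC[2], failed_inits=failed)


# ---------------------------------------------------------------------------
# stage 2: per-neuron readout refits
# ---------------------------------------------------------------------------

def _core_features(spec, net, stim):
    """Activations feeding the final readout (computed once, reused for
    every per-neuron fit)."""
    x = stim.values
    for lyr in net.layers[: net.output_start]:
        x = lyr.forward(x, stim.seg_ids)
    return x


def fit_stage2(stage1: FitResult, stim: Spectrogram, resp: TrialRaster,
               config: FitConfig, neuron_rows=None,
               readout_init: str = "stage1",
               warm_rows=None) -> list[FitResult]:
    """Refit the output layer one neuron at a time, core frozen (stage 2).

    The frozen core's activations are computed once and every per-neuron
    readout (dense weights + double exponential) is optimized against them.

    ``neuron_rows`` selects which rows of ``resp`` to fit (default: all).
    ``readout_init='stage1'`` warm-starts each neuron from its stage-1
    output weights (``warm_rows`` maps response rows to stage-1 output rows
    when they differ); ``'fresh'`` is for neurons that were excluded from
    stage 1 (held-out-site protocol), where no stage-1 readout exists.
    Because the per-neuron loss is nonconvex in the readout, each neuron is
    fit from the warm start (if any) plus ``config.n_init - 1`` random
    draws, keeping the early-stop-split winner.
    """
    spec = stage1.spec
    net = build_network(spec)
    stage1.params.apply_to(net)
    (stim_f, resp_f), (stim_e, resp_e) = split_estimation(
        stim, resp, config.es_fraction, config.seed)
    Hf = _core_features(spec, net, stim_f)
    He = _core_features(spec, net, stim_e)
    segf, sege = stim_f.seg_ids, stim_e.seg_ids
    Yf, Ye = resp_f.psth(), resp_e.psth()
    if neuron_rows is None:
        neuron_rows = np.arange(resp.n_neurons)
    if warm_rows is None and readout_init == "stage1":
        warm_rows = {int(n): int(n) for n in neuron_rows}
    elif warm_rows is None:
        warm_rows = {}
    out_dense = net.layers[net.output_start]
    out_dexp = net.layers[net.output_start + 1]
    H = Hf.shape[0]
    rng = np.random.default_rng(config.seed + 2)
    stats = _response_stats(resp)
    results = []
    for n in neuron_rows:
        inits = []
        if int(n) in warm_rows:
            src = warm_rows[int(n)]
            w = out_dense.params["w"][src : src + 1].copy()
            nl = {r: out_dexp.params[r][src : src + 1].copy()
                  for r in ("b", "a", "s", "k")}
            inits.append((w, nl))
        while len(inits) < max(1, config.n_init):
            w = rng.normal(0, 1.0 / np.sqrt(H), (1, H))
            # drive-aware nonlinearity start: place the threshold inside
            # the drive distribution and scale the gain to its spread, so
            # the double exponential never starts saturated (where its
            # gradients vanish)
            y0 = w @ Hf
            mu, sd = float(np.median(y0)), max(float(y0.std()), 1e-6)
            nl = {"b": rng.uniform(0, 0.2, 1) * stats[0][n : n + 1],
                  "a": rng.uniform(0.5, 1.5, 1)
                       * (stats[0][n : n + 1] + 3 * stats[1][n : n + 1]),
                  "s": np.array([mu + rng.normal(0, 0.3) * sd]),
                  "k": np.array([-rng.uniform(0.5, 2.0) / sd])}
            inits.append((w, nl))
        best = None
        for w, nl in inits:
            dense = Dense(1, H, activation=None)
            dexp = DoubleExp(1)
            dense.params["w"] = w.copy()
            for r in ("b", "a", "s", "k"):
                dexp.params[r] = nl[r].copy()
            dense.zero_grads(); dexp.zero_grads()
            mini = Network([dense, dexp], output_start=0)
            res = _optimize_with_restart(
                mini, None, (Hf, segf, Yf[n : n + 1]),
                (He, sege, Ye[n : n + 1]), config)
            if res is None:
                continue
            if best is None or res[0] < best[0]:
                best = (res[0], res[1], res[2],
                        ParameterSet.from_network(mini))
        if best is None:
            raise RuntimeError(f"stage-2 fit diverged for neuron row {n}")
        results.append(FitResult(
            params=best[3], spec=spec, es_loss=best[0],
            chosen_init=stage1.chosen_init, stage=2, seed=config.seed,
            loss_trace=best[1], n_epochs=best[2]))
    return results


def stage2_predictions(stage1: FitResult, stage2: list[FitResult],
                       stim: Spectrogram) -> np.ndarray:
    """Stack per-neuron stage-2 predictions into an (n, T) matrix."""
    spec = stage1.spec
    net = build_network(spec)
    stage1.params.apply_to(net)
    H = _core_features(spec, net, stim)
    rows = []
    for fr in stage2:
        mini = Network([Dense(1, H.shape[0], activation=None), DoubleExp(1)],
                       output_start=0)
        fr.params.apply_to(mini)
        rows.append(mini.forward(H, stim.seg_ids)[0])
    return np.array(rows)


def predict(spec: ModelSpec, params: ParameterSet,
            stim: Spectrogram) -> np.ndarray:
    """Model prediction (N x T) for fitted parameters."""
    net = build_network(spec)
    params.apply_to(net)
    return net.forward(stim.values, stim.seg_ids)
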