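"""Layer primitives, architectures, forward-pass oracles, parameter counts."""

import numpy as np
import pytest

from popencode.frontend import Spectrogram
from popencode.layers import WIDTH_FLOOR
from popencode.models import (Conv2DUnit, DenseUnit, DoubleExponential,
                              GaussianSpectralUnit, ModelSpec, OffsetReLU,
                              ParameterSet, TemporalFIRUnit, build_network,
                              conv1d_layer_forward, conv2d_layer_forward,
                              count_parameters, double_exponential,
                              ln_forward, population_forward)
from popencode.fitting import initialize


def brute_force_filter(stim_values, h, seg_ids=None):
    """Oracle: direct double-sum evaluation of the causal filter equation,
    r_lin(t) = sum_f sum_u h[f,u] s(f, t-u), zero-padded per snippet."""
    F, T = stim_values.shape
    _, U = h.shape
    if seg_ids is None:
        seg_ids = np.zeros(T, dtype=int)
    out = np.zeros(T)
    for t in range(T):
        for f in range(F):
            for u in range(U):
                if t - u >= 0 and seg_ids[t - u] == seg_ids[t]:
                    out[t] += h[f, u] * stim_values[f, t - u]
    return out


class TestDoubleExponential:
    def test_threshold_point(self):
        p = DoubleExponential(b=2.0, a=10.0, s=0.7, k=-3.0)
        assert double_exponential(0.7, p) == pytest.approx(2.0 + 10.0 / np.e)

    def test_zero_amplitude_gives_baseline(self):
        p = DoubleExponential(b=1.5, a=0.0, s=0.0, k=1.0)
        y = np.linspace(-5, 5, 11)
        assert np.allclose(double_exponential(y, p), 1.5)

    def test_high_precision_scalar_oracle(self):
        # exp(-exp(y)) evaluated with 25-digit arbitrary precision
        expected = {-4: 0.9818510730616664829200759,
                    0: 0.3678794411714423215955238,
                    4: 1.942337604956401838579231e-24}
        p = DoubleExponential(b=0.0, a=1.0, s=0.0, k=1.0)
        for y, v in expected.items():
            assert double_exponential(float(y), p) == pytest.approx(v, rel=1e-12)

    def test_bounded_and_monotone(self):
        p = DoubleExponential(b=1.0, a=5.0, s=0.2, k=-2.0)
        y = np.linspace(-50, 50, 2001)
        r = double_exponential(y, p)
        assert np.all(r >= 1.0 - 1e-12) and np.all(r <= 6.0 + 1e-12)
        assert np.all(np.diff(r) >= 0)          # k < 0: increasing

    def test_extreme_drive_saturates_without_overflow(self):
        p = DoubleExponential(b=0.0, a=1.0, s=0.0, k=5.0)
        r = double_exponential(np.array([-1e6, 1e6]), p)
        assert np.isfinite(r).all()


class TestLnForward:
    def test_delta_filter_passes_stimulus_channel_through_nonlinearity(self):
        F, T = 18, 60
        values = np.zeros((F, T))
        values[7] = np.abs(np.sin(np.arange(T) / 3.0))
        stim = Spectrogram(values, np.geomspace(200, 20000, F))
        nl = DoubleExponential(b=1.0, a=20.0, s=0.3, k=-2.0)
        out = ln_forward(stim,
                         [GaussianSpectralUnit(center=7, width=WIDTH_FLOOR)],
                         np.array([[1.0, 0.0, 0.0]]), nl)
        assert np.allclose(out, double_exponential(values[7], nl))

    def test_zero_filter_gives_constant_rate(self, random_spectrogram):
        nl = DoubleExponential(b=0.5, a=3.0, s=0.1, k=-1.0)
        out = ln_forward(random_spectrogram,
                         [GaussianSpectralUnit(4.0, 1.0)],
                         np.zeros((1, 25)), nl)
        assert np.allclose(out, double_exponential(0.0, nl))

    def test_rank3_matches_brute_force_double_sum(self, rng,
                                                  random_spectrogram):
        spectral = [GaussianSpectralUnit(rng.uniform(0, 17),
                                         rng.uniform(0.5, 3)) for _ in range(3)]
        taps = rng.normal(size=(3, 12))
        nl = DoubleExponential(b=0.2, a=8.0, s=0.1, k=-1.5)
        # oracle: assemble the full-rank filter h = sum_d g_d (x) taps_d
        # and evaluate the double sum bin by bin
        h = sum(np.outer(s.weights(18), taps[d])
                for d, s in enumerate(spectral))
        r_lin = brute_force_filter(random_spectrogram.values, h,
                                   random_spectrogram.seg_ids)
        expected = double_exponential(r_lin, nl)
        got = ln_forward(random_spectrogram, spectral, taps, nl)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)


class TestConv1DLayer:
    def test_one_hot_delta_unit_is_identity_on_channel(self, rng):
        x = np.abs(rng.normal(size=(5, 40)))
        w = np.zeros(5); w[2] = 1.0
        units = [(w, TemporalFIRUnit(np.array([1.0, 0, 0])), OffsetReLU(0.0))]
        out = conv1d_layer_forward(x, units, activation=None)
        np.testing.assert_allclose(out[0], x[2])

    def test_offset_above_max_rectifies_to_zero(self, rng):
        x = np.abs(rng.normal(size=(4, 30)))
        units = [(np.ones(4), TemporalFIRUnit(rng.normal(size=6)),
                  OffsetReLU(1e6))]
        out = conv1d_layer_forward(x, units)
        assert np.all(out == 0)

    def test_matches_composition_of_primitives(self, rng,
                                               random_spectrogram):
        # oracle: weighted channel sum, numpy full convolution truncated,
        # then rectification, composed independently per snippet
        x = random_spectrogram.values
        seg = random_spectrogram.seg_ids
        g = GaussianSpectralUnit(6.0, 1.5)
        taps = rng.normal(size=9)
        off = 0.3
        out = conv1d_layer_forward(x, [(g, TemporalFIRUnit(taps),
                                        OffsetReLU(off))], seg_ids=seg)
        z = g.weights(18) @ x
        expected = []
        for s in np.unique(seg):
            zs = z[seg == s]
            expected.append(np.convolve(zs, taps)[: zs.size])
        expected = np.maximum(0.0, np.concatenate(expected) - off)
        np.testing.assert_allclose(out[0], expected, rtol=1e-6, atol=1e-12)


class TestConv2DLayer:
    def test_identity_kernel_passthrough(self, rng):
        x = np.abs(rng.normal(size=(1, 18, 50)))
        k = np.zeros((1, 3, 8)); k[0, 1, 0] = 1.0
        out = conv2d_layer_forward(x, [Conv2DUnit(k, 0.0)])
        np.testing.assert_allclose(out[0], x[0])

    def test_all_zero_kernels_silent(self, rng):
        x = np.abs(rng.normal(size=(2, 6, 20)))
        out = conv2d_layer_forward(x, [Conv2DUnit(np.zeros((2, 3, 8)), 0.0)])
        assert np.all(out == 0)

    def test_matches_brute_force_quadruple_loop(self, rng,
                                                random_spectrogram):
        x = random_spectrogram.values[None]
        seg = random_spectrogram.seg_ids
        units = [Conv2DUnit(rng.normal(size=(1, 3, 8)), rng.normal())
                 for _ in range(3)]
        out = conv2d_layer_forward(x, units, seg_ids=seg)
        F, T = x.shape[1:]
        expected = np.zeros((3, F, T))
        for o, u in enumerate(units):
            for f in range(F):
                for t in range(T):
                    acc = 0.0
                    for a in range(3):
                        for b in range(8):
                            ff, tt = f + a - 1, t - b
                            if 0 <= ff < F and tt >= 0 and seg[tt] == seg[t]:
                                acc += u.kernel[0, a, b] * x[0, ff, tt]
                    expected[o, f, t] = max(0.0, acc - u.offset)
        np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-12)

    def test_three_stacked_layers_impulse_support_22_bins(self):
        # three causal 8-tap layers: an impulse at t0 can spread no further
        # than t0 + 21 (3*8 - 2 bins of cumulative memory)
        x = np.zeros((1, 6, 60)); t0 = 10
        x[0, 3, t0] = 1.0
        rng = np.random.default_rng(3)
        stack = [[Conv2DUnit(rng.normal(size=((1 if i == 0 else 2), 3, 8)),
                             -10.0) for _ in range(2)] for i in range(3)]
        y, y0 = x, np.zeros_like(x)     # impulse vs silent baseline
        for units in stack:
            y = conv2d_layer_forward(y, units)
            y0 = conv2d_layer_forward(y0, units)
        active = np.flatnonzero(np.abs(y - y0).sum(axis=(0, 1)) > 1e-12)
        assert active.size > 0
        assert active.min() >= t0
        assert active.max() <= t0 + 21

    def test_too_few_frequency_rows_rejected(self):
        with pytest.raises(ValueError):
            conv2d_layer_forward(np.zeros((1, 2, 10)),
                                 [Conv2DUnit(np.zeros((1, 3, 8)), 0.0)])


class TestPopulationForward:
    def test_duplicated_readout_rows_give_identical_predictions(
            self, random_spectrogram):
        spec = ModelSpec("pop-LN", n_neurons=3, conv_units=4)
        ps = initialize(spec, 2, seed=0)[0]
        net = build_network(spec)
        ps.apply_to(net)
        dense, dexp = net.layers[1], net.layers[2]
        dense.params["w"][1] = dense.params["w"][0]
        for r in ("b", "a", "s", "k"):
            dexp.params[r][1] = dexp.params[r][0]
        ps2 = ParameterSet.from_network(net)
        out = population_forward(random_spectrogram, spec, ps2)
        np.testing.assert_array_equal(out[0], out[1])

    def test_matches_manual_layer_composition(self, rng, random_spectrogram):
        spec = ModelSpec("1Dx2-CNN", n_neurons=2, conv_units=3, n_taps=5,
                         conv2_units=4, conv2_taps=3, hidden_units=4)
        ps = initialize(spec, 2, seed=1)[0]
        out = population_forward(random_spectrogram, spec, ps)
        # oracle: functional per-unit composition through the same params
        net = build_network(spec)
        ps.apply_to(net)
        c1, c2, hid, rd, dx = net.layers
        seg = random_spectrogram.seg_ids
        u1 = [(GaussianSpectralUnit(c1.params["mu"][i], c1.params["sigma"][i]),
               TemporalFIRUnit(c1.params["taps"][i]),
               OffsetReLU(c1.params["offset"][i])) for i in range(3)]
        h1 = conv1d_layer_forward(random_spectrogram.values, u1, seg_ids=seg)
        u2 = [(DenseUnit(c2.params["w"][i]),
               TemporalFIRUnit(c2.params["taps"][i]),
               OffsetReLU(c2.params["offset"][i])) for i in range(4)]
        h2 = conv1d_layer_forward(h1, u2, seg_ids=seg)
        h3 = np.maximum(0.0, hid.params["w"] @ h2
                        - hid.params["offset"][:, None])
        expected = np.array([
            double_exponential(rd.params["w"][n] @ h3,
                               DoubleExponential(*(dx.params[r][n]
                                                   for r in "bask")))
            for n in range(2)])
        np.testing.assert_allclose(out, expected, rtol=1e-10, atol=1e-12)

    def test_wrong_parameter_length_rejected(self, random_spectrogram):
        spec = ModelSpec("pop-LN", n_neurons=2, conv_units=3)
        ps = initialize(ModelSpec("pop-LN", n_neurons=3, conv_units=3),
                        1, seed=0)[0]
        with pytest.raises(ValueError):
            population_forward(random_spectrogram, spec, ps)


class TestReductionIdentities:
    def test_pop_ln_with_one_neuron_reduces_to_ln(self, random_spectrogram):
        rng = np.random.default_rng(4)
        mu, sig = rng.uniform(2, 15, 3), rng.uniform(0.5, 2, 3)
        taps = rng.normal(size=(3, 25))
        nl = DoubleExponential(b=0.5, a=10.0, s=0.2, k=-1.0)
        ln_out = ln_forward(random_spectrogram,
                            [GaussianSpectralUnit(m, s)
                             for m, s in zip(mu, sig)], taps, nl)
        spec = ModelSpec("pop-LN", n_neurons=1, conv_units=3)
        net = build_network(spec)
        conv, dense, dexp = net.layers
        conv.params.update(mu=mu, sigma=sig, taps=taps)
        dense.params["w"] = np.ones((1, 3))      # readout = channel sum
        dexp.params.update(b=np.array([nl.b]), a=np.array([nl.a]),
                           s=np.array([nl.s]), k=np.array([nl.k]))
        pop_out = population_forward(random_spectrogram, spec,
                                     ParameterSet.from_network(net))
        np.testing.assert_array_equal(pop_out[0], ln_out)

    def test_single_cnn_with_one_unit_reduces_to_rank1_ln(
            self, random_spectrogram):
        rng = np.random.default_rng(5)
        mu, sig = 8.3, 1.7
        taps = rng.normal(size=(1, 25))
        nl = DoubleExponential(b=0.3, a=6.0, s=0.4, k=-2.0)
        ln_out = ln_forward(random_spectrogram,
                            [GaussianSpectralUnit(mu, sig)], taps, nl)
        # map: ReLU offset -c acts as passthrough shift y + c, absorbed by
        # moving the output threshold to s + c with unit dense weight
        c = 50.0
        spec = ModelSpec("single-CNN", conv_units=1)
        net = build_network(spec)
        conv, dense, dexp = net.layers
        conv.params.update(mu=np.array([mu]), sigma=np.array([sig]),
                           taps=taps, offset=np.array([-c]))
        dense.params["w"] = np.ones((1, 1))
        dexp.params.update(b=np.array([nl.b]), a=np.array([nl.a]),
                           s=np.array([nl.s + c]), k=np.array([nl.k]))
        out = population_forward(random_spectrogram, spec,
                                 ParameterSet.from_network(net))
        np.testing.assert_allclose(out[0], ln_out, rtol=1e-12, atol=1e-12)

    def test_full_rank_free_weights_reproduce_arbitrary_filter(
            self, rng, random_spectrogram):
        # a rank-F stage with free (dense) spectral weights can express any
        # full F x U filter: use identity weights, one unit per channel
        h = rng.normal(size=(18, 10))
        units = [(np.eye(18)[f], TemporalFIRUnit(h[f]), OffsetReLU(0.0))
                 for f in range(18)]
        rows = conv1d_layer_forward(random_spectrogram.values, units,
                                    seg_ids=random_spectrogram.seg_ids,
                                    activation=None)
        r_lin = rows.sum(axis=0)
        expected = brute_force_filter(random_spectrogram.values, h,
                                      random_spectrogram.seg_ids)
        np.testing.assert_allclose(r_lin, expected, rtol=1e-6, atol=1e-9)


@pytest.mark.parametrize("arch,kw", [
    ("LN", dict(rank=2)),
    ("pop-LN", dict(n_neurons=3, conv_units=4)),
    ("single-CNN", dict(conv_units=3)),
    ("1D-CNN", dict(n_neurons=3, conv_units=4, hidden_units=5)),
    ("1Dx2-CNN", dict(n_neurons=3, conv_units=4, conv2_units=5,
                      hidden_units=6, n_taps=6, conv2_taps=4)),
    ("2D-CNN", dict(n_neurons=2, conv2d_units=3, hidden_units=4)),
])
class TestArchitectureProperties:
    def test_causality(self, arch, kw, random_spectrogram):
        spec = ModelSpec(arch, **kw)
        ps = initialize(spec, 2, seed=7)[0]
        base = population_forward(random_spectrogram, spec, ps)
        t_perturb = 120
        bumped = random_spectrogram.values.copy()
        bumped[:, t_perturb] += 1.0
        stim2 = Spectrogram(bumped, random_spectrogram.center_freqs,
                            seg_lens=random_spectrogram.seg_lens)
        out2 = population_forward(stim2, spec, ps)
        np.testing.assert_array_equal(base[:, :t_perturb],
                                      out2[:, :t_perturb])

    def test_forward_deterministic(self, arch, kw, random_spectrogram):
        spec = ModelSpec(arch, **kw)
        ps = initialize(spec, 1, seed=3)[0]
        a = population_forward(random_spectrogram, spec, ps)
        b = population_forward(random_spectrogram, spec, ps)
        np.testing.assert_array_equal(a, b)

    def test_count_matches_instantiated_parameters(self, arch, kw):
        spec = ModelSpec(arch, **kw)
        total, _ = count_parameters(spec, count_offsets="all")
        net = build_network(spec)
        assert total == net.n_params == len(ParameterSet.from_network(net))


class TestParameterCounting:
    def test_first_conv_layer_of_seventy_unit_model(self):
        # 70 Gaussian units (2 values each) + 70 fifteen-tap FIRs = 1,190,
        # with first-layer activation offsets excluded by convention
        spec = ModelSpec.exemplar("1Dx2-CNN", n_neurons=100)
        _, breakdown = count_parameters(spec)
        assert breakdown[0]["count"] == 70 * 2 + 70 * 15 == 1190
        assert breakdown[0]["count_with_offsets"] == 1190 + 70

    def test_rank1_ln_is_31(self):
        spec = ModelSpec("LN", rank=1, n_taps=25)
        total, _ = count_parameters(spec)
        assert total == 2 + 25 + 4 == 31

    def test_exemplar_totals_equal_enumerated_parameters(self):
        for arch in ("LN", "pop-LN", "single-CNN", "1D-CNN", "1Dx2-CNN",
                     "2D-CNN"):
            n = 1 if arch in ("LN", "single-CNN") else 40
            spec = ModelSpec.exemplar(arch, n_neurons=n)
            total, _ = count_parameters(spec, count_offsets="all")
            assert total == build_network(spec).n_params


class TestModelSpec:
    def test_json_roundtrip(self):
        spec = ModelSpec("1D-CNN", n_neurons=7, conv_units=9)
        assert ModelSpec.from_json(spec.to_json()) == spec

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("LN", n_neurons=2)
        with pytest.raises(ValueError):
            ModelSpec("nope")
        with pytest.raises(ValueError):
            ModelSpec("pop-LN", n_neurons=0)
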