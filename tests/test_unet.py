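"""Architecture spec, parameter accounting, and the numpy network engine."""

import numpy as np
import pytest

from gutseg.metrics import training_loss_and_grad
from gutseg.unet import (
    BACKBONES,
    BackboneAdapter,
    LayerSpec,
    ModelSpec,
    PRINTED_TOTAL_PARAMETERS,
    ShapeError,
    TABLE1_TRANSCRIPTION,
    TopologyError,
    UNet,
    UnknownBackboneError,
    attach_backbone,
    build_model,
    count_parameters,
    get_backbone,
    parameter_report,
)

ENCODER_CENTER_ROWS = TABLE1_TRANSCRIPTION[:10]


class TestParameterAccounting:
    @pytest.mark.parametrize(
        "cin, cout, expected",
        [(row[3], row[4], row[5]) for row in ENCODER_CENTER_ROWS],
        ids=[f"{r[0]}-{r[1]}" for r in ENCODER_CENTER_ROWS],
    )
    def test_encoder_center_counts_match_published_summary(self, cin, cout, expected):
        layer = LayerSpec("x", "conv", (3, 3), cin, cout)
        assert count_parameters(layer) == expected

    def test_output_conv_1x1_count(self):
        assert count_parameters(LayerSpec("out", "conv", (1, 1), 64, 3)) == 195

    def test_transcription_sums_to_printed_total(self):
        assert sum(r[5] for r in TABLE1_TRANSCRIPTION) == PRINTED_TOTAL_PARAMETERS

    def test_pooling_and_concat_hold_no_parameters(self):
        assert count_parameters(LayerSpec("p", "maxpool", (2, 2), 64, 64)) == 0
        assert count_parameters(LayerSpec("c", "concat", (0, 0), 64, 128)) == 0

    def test_unbiased_conv(self):
        assert count_parameters(LayerSpec("x", "conv", (3, 3), 4, 8, has_bias=False)) == 288

    def test_doubling_input_channels_exact_relation(self):
        for c in (1, 3, 16, 64, 200):
            single = count_parameters(LayerSpec("a", "conv", (3, 3), c, 10))
            double = count_parameters(LayerSpec("b", "conv", (3, 3), 2 * c, 10))
            assert double * (9 * c + 1) == single * (9 * 2 * c + 1)


class TestModelSpec:
    def test_reference_progressions(self):
        spec = ModelSpec.reference()
        assert spec.encoder_filters == (64, 128, 256, 512)
        assert all(b == 2 * a for a, b in zip(spec.encoder_filters, spec.encoder_filters[1:]))
        assert spec.center_filters == 1024
        assert spec.decoder_filters() == (1024, 512, 256, 128, 64)
        assert spec.bottleneck_spatial() == (10, 10)

    def test_report_reproduces_encoder_center_rows(self):
        rep = parameter_report(ModelSpec.reference())
        by_name = rep.layers.set_index("name")["parameters"]
        expected = {
            "down1_conv1": 640, "down1_conv2": 36_928,
            "down2_conv1": 73_856, "down2_conv2": 147_584,
            "down3_conv1": 295_168, "down3_conv2": 590_080,
            "down4_conv1": 1_180_160, "down4_conv2": 2_359_808,
            "center_conv1": 4_719_616, "center_conv2": 9_438_208,
            "output_conv": 195,
        }
        for name, count in expected.items():
            assert by_name[name] == count
        assert rep.reference_total == PRINTED_TOTAL_PARAMETERS

    def test_report_flags_inconsistent_decoder_rows_only(self):
        rep = parameter_report(ModelSpec.reference())
        ref = rep.reference
        enc = ref[~ref["block"].str.startswith("Upsampling")]
        assert enc["consistent"].all()
        flagged = ref[~ref["consistent"]]
        assert set(zip(flagged["block"], flagged["layer"])) == {
            ("Upsampling Block 1", "Conv1"),
            ("Upsampling Block 2", "Conv2"),
            ("Upsampling Block 3", "Conv1"),
            ("Upsampling Block 4", "Conv1"),
            ("Upsampling Block 4", "Conv3"),
        }

    def test_empty_spec_empty_report(self):
        rep = parameter_report(ModelSpec(encoder_filters=(), center_filters=1))
        assert len(rep.layers) == 0 and rep.implemented_total == 0

    def test_spec_total_matches_instantiated_network(self):
        spec = ModelSpec.scaled(4, (32, 32))
        assert build_model(spec).n_parameters() == spec.total_parameters()


@pytest.fixture(scope="module")
def small_net():
    return build_model(ModelSpec.scaled(4, (32, 32)), seed=0)


class TestExecutableNetwork:
    def test_forward_shape_contract(self, small_net, rng):
        y = small_net.forward(rng.random((2, 32, 32, 1)), train=False)
        assert y.shape == (2, 32, 32, 3)
        assert (y >= 0).all() and (y <= 1).all()

    def test_divisible_by_16_generalization(self, small_net, rng):
        y = small_net.forward(rng.random((1, 64, 64, 1)), train=False)
        assert y.shape == (1, 64, 64, 3)

    def test_indivisible_size_rejected_with_message(self, small_net):
        with pytest.raises(ShapeError, match="divisible by 16"):
            small_net.forward(np.zeros((1, 40, 40, 1)), train=False)

    def test_bottleneck_trace(self, small_net, rng):
        small_net.forward(rng.random((1, 32, 32, 1)), train=False)
        assert small_net.last_trace["bottleneck"][:2] == (2, 2)

    def test_seeded_init_deterministic(self):
        spec = ModelSpec.scaled(4, (32, 32))
        a, b = build_model(spec, seed=9), build_model(spec, seed=9)
        for (wa, ba), (wb, bb) in zip(a.state_dict(), b.state_dict()):
            assert (wa == wb).all() and (ba == bb).all()
        c = build_model(spec, seed=10)
        assert any((wa != wc).any() for (wa, _), (wc, _) in zip(a.state_dict(), c.state_dict()))

    def test_untrained_output_near_foreground_prior(self, small_net, rng):
        y = small_net.forward(rng.random((1, 32, 32, 1)), train=False)
        assert y.mean() < 0.3  # prior-logit bias puts mass near background

    def test_gradients_match_numeric_differences(self, rng):
        spec = ModelSpec(input_size=(16, 16), encoder_filters=(2, 4, 6, 8),
                         center_filters=16)
        net = UNet(spec, seed=1)
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        t = (rng.random((2, 16, 16, 3)) > 0.7).astype(np.float32)

        def loss():
            return training_loss_and_grad(net.forward(x, train=True), t)[0]

        _, g = training_loss_and_grad(net.forward(x, train=True), t)
        net.backward(g.astype(np.float32))
        eps = 1e-3
        layers = net.param_layers()
        for li in (0, 5, 9, 12, len(layers) - 1):
            layer = layers[li]
            analytic = layer.gW.copy()
            idx = tuple(rng.integers(0, s) for s in layer.W.shape)
            orig = layer.W[idx]
            layer.W[idx] = orig + eps
            lp = loss()
            layer.W[idx] = orig - eps
            lm = loss()
            layer.W[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            # float32 forward noise limits the numeric difference to ~1e-4
            diff = abs(numeric - analytic[idx])
            assert diff < 1e-4 or diff / (abs(numeric) + abs(analytic[idx])) < 5e-2

    def test_state_roundtrip(self, small_net, tmp_path, rng):
        x = rng.random((1, 32, 32, 1))
        y0 = small_net.forward(x, train=False)
        path = tmp_path / "weights.npz"
        small_net.save(path)
        other = build_model(small_net.spec, seed=99)
        assert not np.allclose(other.forward(x, train=False), y0)
        other.load(path)
        assert np.allclose(other.forward(x, train=False), y0)


class TestBackbones:
    def test_vgg19_declared_metadata(self):
        ad = get_backbone("vgg19")
        assert ad.declared_layer_count == 19
        assert ad.declared_parameter_millions == 138

    def test_all_six_supported(self):
        assert len(BACKBONES) == 6
        for name in BACKBONES:
            assert get_backbone(name).name == name

    def test_unknown_backbone_lists_supported(self):
        with pytest.raises(UnknownBackboneError, match="efficientnetb0"):
            get_backbone("resnet18")

    def test_too_few_stages_rejected(self):
        ad = BackboneAdapter("stub", (8, 16), 3, 0.1)
        with pytest.raises(TopologyError):
            attach_backbone(ad)

    def test_attached_network_shape_contract(self, rng):
        ad = BackboneAdapter("stub", (4, 8, 12, 16), 10, 0.5)
        net = attach_backbone(ad, ModelSpec(input_size=(32, 32), encoder_filters=(4, 8, 12, 16), center_filters=32), seed=0)
        y = net.forward(rng.random((1, 32, 32, 1)), train=False)
        assert y.shape == (1, 32, 32, 3)
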