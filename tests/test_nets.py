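"""Architecture contracts: shapes, channel plans, and parameter counting.

The parameter counts are checked against closed-form layer-by-layer
arithmetic written out here, independently of the framework's counter.
"""

import numpy as np
import pytest

from tribrats.nets import (
    EFFICIENTNETV2S_STAGES,
    ModelConfig,
    SegmentationModel,
    build_efficientnetv2s_encoder,
    build_efficientunet,
    build_model,
    build_unet,
    round_channels,
)


# ---------------------------------------------------------------------------
# closed-form parameter oracles


def _round8(c, wm):
    return max(8, int(np.floor(c * wm / 8 + 0.5)) * 8)


def unet_param_oracle(depth=5, base=32, in_ch=4, width_mult=1.0):
    base = _round8(base, width_mult)
    widths = [base * 2**i for i in range(depth)]
    conv = lambda ci, co: ci * co * 9 + 2 * co  # 3x3 conv (no bias) + BN
    total = 0
    cin = in_ch
    for w in widths:
        total += conv(cin, w) + conv(w, w)
        cin = w
    for i in range(depth - 2, -1, -1):
        total += conv(widths[i + 1] + widths[i], widths[i]) + conv(widths[i], widths[i])
    return total + widths[0] * 1 + 1  # 1x1 sigmoid head with bias


def effunet_param_oracle(width_mult=1.0, in_ch=3):
    conv = lambda ci, co, k: ci * co * k * k + 2 * co  # conv + BN
    stages = [s for s in EFFICIENTNETV2S_STAGES if s.operator != "head"]
    widths = [_round8(s.out_channels, width_mult) for s in stages]
    total = conv(in_ch, widths[0], 3)  # stem
    cin = widths[0]
    for s, cout in zip(stages[1:], widths[1:]):
        for r in range(s.repeats):
            if s.operator == "fused_mbconv":
                if s.expansion == 1:
                    total += conv(cin, cout, 3)
                else:
                    mid = cin * s.expansion
                    total += conv(cin, mid, 3) + conv(mid, cout, 1)
            else:  # mbconv with squeeze-excitation
                mid = cin * s.expansion
                hidden = max(1, round(cin * s.se_ratio))
                total += conv(cin, mid, 1)  # expand
                total += mid * 9 + 2 * mid  # depthwise 3x3 + BN
                total += mid * hidden + hidden + hidden * mid + mid  # SE (biased 1x1s)
                total += conv(mid, cout, 1)  # project
            cin = cout
    c1, c2, c3, c5, c6 = widths[1], widths[2], widths[3], widths[5], widths[6]
    plan = [(c6, c5, c5), (c5, c3, c3), (c3, c2, c2), (c2, c1, c1), (c1, 0, c1)]
    for cin_up, cskip, cout in plan:
        total += conv(cin_up + cskip, cout, 3) + conv(cout, cout, 3)
    return total + c1 * 1 + 1


# ---------------------------------------------------------------------------
# tests


def test_channel_rounding_rule():
    assert round_channels(24, 0.5) == 16  # round(12/8)=round(1.5) -> 2 (half up)
    assert round_channels(24, 1.0) == 24
    assert round_channels(24, 0.1) == 8  # floor at 8
    assert round_channels(160, 0.25) == 40
    with pytest.raises(ValueError):
        round_channels(24, 0.0)


def test_encoder_stage_channels_match_published_plan():
    cfg = ModelConfig(architecture="efficientunet", input_size=64, in_channels=3)
    enc, taps = build_efficientnetv2s_encoder(cfg)
    assert enc.stage_channels == [24, 24, 48, 64, 128, 160, 256]
    assert taps == [24, 48, 64, 160, 256]
    spec_channels = [s.out_channels for s in EFFICIENTNETV2S_STAGES]
    assert spec_channels == [24, 24, 48, 64, 128, 160, 256, 1280]
    repeats = [s.repeats for s in EFFICIENTNETV2S_STAGES[1:7]]
    assert repeats == [2, 4, 4, 6, 9, 15]


def test_encoder_tap_resolutions():
    cfg = ModelConfig(architecture="efficientunet", input_size=128, in_channels=3,
                      width_mult=0.25)
    enc, _ = build_efficientnetv2s_encoder(cfg)
    from tribrats.nn import core as C

    with C.no_grad():
        taps = enc(C.Tensor(np.zeros((1, 3, 128, 128), dtype=np.float32)))
    assert [t.data.shape[2] for t in taps] == [64, 32, 16, 8, 4]


@pytest.mark.parametrize("width_mult", [0.25, 1.0])
def test_efficientunet_parameter_count_matches_oracle(width_mult):
    cfg = ModelConfig(architecture="efficientunet", input_size=64, in_channels=3,
                      width_mult=width_mult)
    model = build_efficientunet(cfg)
    assert model.parameter_count == effunet_param_oracle(width_mult)


@pytest.mark.parametrize("width_mult", [0.25, 1.0])
def test_unet_parameter_count_matches_oracle(width_mult):
    cfg = ModelConfig(architecture="unet", input_size=64, in_channels=4,
                      width_mult=width_mult)
    model = build_unet(cfg)
    assert model.parameter_count == unet_param_oracle(width_mult=width_mult)


def test_desk_scale_efficientunet_is_small():
    cfg = ModelConfig(architecture="efficientunet", input_size=64, in_channels=3,
                      width_mult=0.25)
    assert build_efficientunet(cfg).parameter_count < 2_000_000


def test_width_mult_doubling_increases_parameters():
    counts = []
    for wm in (0.25, 0.5, 1.0):
        cfg = ModelConfig(architecture="efficientunet", input_size=64, in_channels=3,
                          width_mult=wm)
        counts.append(build_efficientunet(cfg).parameter_count)
    assert counts[0] < counts[1] < counts[2]
    u = [build_unet(ModelConfig(architecture="unet", width_mult=wm)).parameter_count
         for wm in (0.5, 1.0)]
    assert u[0] < u[1]


@pytest.mark.parametrize(
    "arch,in_ch", [("unet", 4), ("efficientunet", 3)]
)
def test_output_contract_shape_and_range(arch, in_ch):
    cfg = ModelConfig(architecture=arch, input_size=64, in_channels=in_ch,
                      width_mult=0.25, base_filters=8)
    model = build_model(cfg)
    x = np.random.default_rng(0).normal(size=(2, in_ch, 64, 64)).astype(np.float32)
    from tribrats.nn import core as C

    with C.no_grad():
        probs = model.net(C.Tensor(x)).data  # batch-statistics forward
    assert probs.shape == (2, 1, 64, 64)
    assert probs.min() > 0.0 and probs.max() < 1.0
    # inference path agrees on shape
    assert model.predict_proba(x).shape == (2, 1, 64, 64)


def test_unet_depth5_has_four_poolings_and_skips():
    cfg = ModelConfig(architecture="unet", input_size=64, in_channels=4,
                      width_mult=0.25, depth=5)
    net = build_unet(cfg).net
    assert len(net.enc_blocks) == 5
    assert len(net.dec_blocks) == 4  # one skip concatenation per decoder block


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(architecture="unet", input_size=100, depth=5)
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(architecture="efficientunet", input_size=48, in_channels=3)
    with pytest.raises(ValueError, match="three-channel"):
        ModelConfig(architecture="efficientunet", input_size=64, in_channels=4)
    with pytest.raises(ValueError, match="architecture"):
        ModelConfig(architecture="segnet")


def test_one_gradient_step_runs_on_two_slice_batch():
    from tribrats.nn.loss import generalized_dice_loss
    from tribrats.nn.optim import Adam

    cfg = ModelConfig(architecture="efficientunet", input_size=64, in_channels=3,
                      width_mult=0.25)
    model = build_efficientunet(cfg)
    x = np.random.default_rng(1).normal(size=(2, 3, 64, 64)).astype(np.float32)
    y = np.zeros((2, 1, 64, 64), dtype=np.float32)
    y[:, :, 20:40, 20:40] = 1
    opt = Adam(model.net.parameters())
    loss = generalized_dice_loss(model.forward(x), y)
    loss.backward()
    opt.step()
    assert np.isfinite(float(loss.data))


def test_checkpoint_round_trip(tmp_path):
    cfg = ModelConfig(architecture="unet", input_size=32, in_channels=4,
                      width_mult=0.25, base_filters=8, depth=3, seed=5)
    model = build_unet(cfg)
    x = np.random.default_rng(2).normal(size=(1, 4, 32, 32)).astype(np.float32)
    before = model.predict_proba(x)
    path = model.save(tmp_path / "ckpt.npz")
    assert path.with_suffix(".npz.json").exists()  # architecture sidecar
    restored = SegmentationModel.load(path)
    np.testing.assert_array_equal(restored.predict_proba(x), before)
    assert restored.config == cfg
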