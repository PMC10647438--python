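"""Architecture contracts: shapes, wiring, sharing, receptive fields."""

import numpy as np
import pytest

from mhseg.errors import ValidationError
from mhseg.models import (HeadWiring, ModelConfig, build_model, describe,
                          load_checkpoint, save_checkpoint)
from mhseg.nn import Tensor

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")

VARIANTS = ["multichannel", "multihead_1", "multihead_2", "multihead_3"]


def tiny(variant, width=0.125, channels=("t2w", "b1000", "adc"), seed=0):
    return build_model(ModelConfig(variant=variant, input_channels=channels,
                                   width_multiplier=width), seed=seed)


class TestConfig:
    def test_multihead_requires_t2w_plus_dwi(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="multihead_2", input_channels=("b1000", "adc"))
        with pytest.raises(ValueError):
            ModelConfig(variant="multihead_3", input_channels=("t2w",))
        with pytest.raises(ValueError):
            ModelConfig(input_channels=())

    def test_first_head_must_be_non_dilated(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="multihead_1", head_dilations=(2, 2, 4))

    def test_width_multiplier_arithmetic(self):
        f, fb = ModelConfig(width_multiplier=0.25).scaled_filters()
        assert f == [8, 16, 32, 64] and fb == 128

    def test_wiring_tables(self):
        w1 = HeadWiring.from_config(ModelConfig(variant="multihead_1"))
        assert w1.heads == ((("t2w",), 1), (("t2w", "b1000", "adc"), 2),
                            (("t2w", "b1000", "adc"), 4))
        assert (w1.sharing, w1.fusion) == ("shared", "sum")
        w2 = HeadWiring.from_config(ModelConfig(variant="multihead_2"))
        assert w2.heads == ((("t2w",), 1), (("b1000", "adc"), 2), (("b1000", "adc"), 4))
        w3 = HeadWiring.from_config(ModelConfig(variant="multihead_3"))
        assert (w3.sharing, w3.fusion) == ("independent", "concat_project_sum")


class TestForward:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_shape_preserved_on_multiple_of_16(self, variant):
        m = tiny(variant)
        out = m.predict_logits(np.zeros((3, 32, 32, 16), dtype=np.float32))
        assert out.shape == (1, 32, 32, 16)

    def test_multichannel_single_channel_input(self):
        m = tiny("multichannel", channels=("t2w",))
        out = m.predict_logits(np.zeros((1, 16, 16, 16), dtype=np.float32))
        assert out.shape == (1, 16, 16, 16)

    def test_wrong_channel_count_raises_naming_expectation(self):
        m = tiny("multihead_2")
        with pytest.raises(ValidationError, match="t2w"):
            m.predict_logits(np.zeros((2, 16, 16, 16), dtype=np.float32))

    def test_zero_final_layer_gives_half_probabilities(self):
        m = tiny("multichannel")
        m.out_conv.weight.data[:] = 0.0
        m.out_conv.bias.data[:] = 0.0
        out = m.predict_logits(np.random.default_rng(0).normal(
            size=(3, 16, 16, 16)).astype(np.float32))
        assert np.all(out == 0.0)

    def test_eval_determinism(self):
        m = tiny("multihead_3")
        x = np.random.default_rng(1).normal(size=(3, 16, 16, 16)).astype(np.float32)
        assert np.array_equal(m.predict_logits(x), m.predict_logits(x))


class TestSharing:
    def test_multihead_3_has_more_parameters_than_multihead_2(self):
        assert tiny("multihead_3").num_parameters() > tiny("multihead_2").num_parameters()

    def test_perturbing_shared_tensor_changes_both_dilated_heads(self):
        m = tiny("multihead_2")
        x = Tensor(np.random.default_rng(2).normal(
            size=(1, 3, 16, 16, 16)).astype(np.float32))
        m(x)
        before = {k: v.data.copy() for k, v in m.last_head_outputs.items()}
        m.dwi_head_shared.b1.conv1.weight.data += 0.5
        m(x)
        after = m.last_head_outputs
        assert not np.allclose(before["dwi@2"], after["dwi@2"].data)
        assert not np.allclose(before["dwi@4"], after["dwi@4"].data)
        assert np.allclose(before["t2w@1"], after["t2w@1"].data)

    def test_multihead_3_t2w_perturbation_never_reaches_dwi_path(self):
        m = tiny("multihead_3")
        x = Tensor(np.random.default_rng(2).normal(
            size=(1, 3, 16, 16, 16)).astype(np.float32))
        m(x)
        before = {k: v.data.copy() for k, v in m.last_head_outputs.items()}
        m.t2w_head.b1.conv1.weight.data += 0.5
        m(x)
        after = m.last_head_outputs
        assert np.array_equal(before["dwi@2"], after["dwi@2"].data)
        assert np.array_equal(before["dwi@4"], after["dwi@4"].data)
        assert not np.allclose(before["t2w@1"], after["t2w@1"].data)


def test_gradient_footprints_follow_closed_form_dilated_reach():
    """Four stacked kernel-3 convolutions at dilation d reach +-4d voxels;
    the dilated supports are sparse lattices (holes at non-multiples of d),
    so width is measured as per-axis extent."""
    from mhseg.models import head_gradient_footprint
    m = tiny("multihead_3", width=0.25)
    f1 = head_gradient_footprint(m.t2w_head, 1)
    f2 = head_gradient_footprint(m.dwi_head_d2, 2)
    f4 = head_gradient_footprint(m.dwi_head_d4, 2)

    def extent(mask, axis):
        idx = np.unique(np.argwhere(mask)[:, axis])
        return idx.max() - idx.min() + 1

    assert extent(f1, 0) < extent(f2, 0) < extent(f4, 0)
    assert f1[16 + 4, 16, 4] and not f1[16 + 5, 16, 4]
    assert f2[16 + 8, 16, 4] and not f2[16 + 9, 16, 4]
    assert f4[16, 16 + 16, 4]  # dilation-4 reach: +-16 voxels
    assert not f4[16 + 1, 16, 4]  # the lattice hole at a non-multiple of 4


class TestDescribe:
    def test_summary_lists_three_heads_with_dilations(self):
        d = describe(tiny("multihead_2"))
        assert len(d["heads"]) == 3
        assert d["head_dilations"] == [1, 2, 4]

    def test_shared_tensor_lists(self):
        assert describe(tiny("multihead_1"))["shared_tensors"]
        assert describe(tiny("multihead_2"))["shared_tensors"]
        assert describe(tiny("multihead_3"))["shared_tensors"] == []
        assert describe(tiny("multichannel"))["shared_tensors"] == []

    def test_filters_at_full_width(self):
        d = describe(build_model(ModelConfig()))
        assert d["filters"] == [32, 64, 128, 256, 512]


def test_checkpoint_roundtrip(tmp_path):
    m = tiny("multihead_3")
    x = np.random.default_rng(5).normal(size=(3, 16, 16, 16)).astype(np.float32)
    ref = m.predict_logits(x)
    save_checkpoint(m, tmp_path / "ckpt.npz", extra={"note": 1})
    m2, extra = load_checkpoint(tmp_path / "ckpt.npz")
    assert extra == {"note": 1}
    assert m2.config == m.config
    assert np.array_equal(m2.predict_logits(x), ref)
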