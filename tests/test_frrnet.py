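import numpy as np
import pytest

from frrreg import autodiff as ad
from frrreg.autodiff import Tensor
from frrreg.frrnet import (PAPER_SPECS, REDUCED_SPECS, SubnetworkSpec,
                           build_cascade, build_subnetwork, cascade_forward,
                           ladder_levels, load_checkpoint, predict_dvf,
                           save_checkpoint)
from frrreg.losses import total_loss
from frrreg.warp import ShapeMismatchError, warp_scalar

from conftest import numerical_gradient

TINY_SPEC = SubnetworkSpec(3, 8, base_channels=4)


def test_spec_validation():
    with pytest.raises(ValueError):
        SubnetworkSpec(0, 128)
    with pytest.raises(ValueError):
        SubnetworkSpec(5, 16, base_channels=32)  # cap below base


def test_production_specs_are_the_three_cascades():
    assert [(s.n_frru_blocks, s.max_channels) for s in PAPER_SPECS] == \
        [(5, 128), (7, 256), (9, 512)]
    assert all(s.base_channels == 32 for s in PAPER_SPECS)


def test_ladder_levels_symmetric():
    assert ladder_levels(5) == [1, 2, 3, 2, 1]
    assert ladder_levels(7) == [1, 2, 3, 4, 3, 2, 1]
    assert ladder_levels(9) == [1, 2, 3, 4, 5, 4, 3, 2, 1]
    assert ladder_levels(4) == [1, 2, 2, 1]


def test_parameter_counts_strictly_increase_across_cascades():
    counts = [build_subnetwork(spec, seed=0, dtype=np.float32).n_parameters()
              for spec in PAPER_SPECS]
    assert counts[0] < counts[1] < counts[2]


def test_subnetwork_output_shape_contract():
    rng = np.random.default_rng(0)
    for spec in [SubnetworkSpec(5, 32, base_channels=8),
                 SubnetworkSpec(7, 32, base_channels=8),
                 SubnetworkSpec(9, 32, base_channels=8)]:
        net = build_subnetwork(spec, seed=0, dtype=np.float32)
        with ad.no_grad():
            out = net(Tensor(rng.random((2, 32, 32, 32), dtype=np.float32)))
        assert out.data.shape == (3, 32, 32, 32)


def test_untrained_subnetwork_predicts_zero_field():
    net = build_subnetwork(TINY_SPEC, seed=1)
    rng = np.random.default_rng(1)
    phi = predict_dvf(net, rng.random((8, 8, 8)), rng.random((8, 8, 8)))
    np.testing.assert_array_equal(phi, 0.0)
    assert phi.shape == (3, 8, 8, 8)


def test_frru_residual_identity_when_projection_zeroed():
    """With the 1x1x1 projection zeroed, the residual stream passes through."""
    net = build_subnetwork(SubnetworkSpec(3, 16, base_channels=4), seed=2)
    frru = net.frrus[0]
    frru.project.weight.data[:] = 0.0
    frru.project.bias.data[:] = 0.0
    rng = np.random.default_rng(2)
    x = Tensor(rng.random((4, 8, 8, 8)))
    y = Tensor(rng.random((4, 4, 4, 4)))  # pooling stream enters with base channels
    x_next, y_next = frru(x, y)
    np.testing.assert_array_equal(x_next.data, x.data)
    assert y_next.data.shape == (8, 4, 4, 4)


def test_frru_pooling_stream_sees_residual_stream():
    """Perturbing one voxel of the residual stream changes the pooled output."""
    net = build_subnetwork(SubnetworkSpec(3, 16, base_channels=4), seed=3)
    frru = net.frrus[0]
    rng = np.random.default_rng(3)
    x = rng.random((4, 8, 8, 8))
    y = Tensor(rng.random((4, 4, 4, 4)))
    frru.eval()
    _, y0 = frru(Tensor(x), y)
    x2 = x.copy()
    x2[0, 0, 0, 0] += 1.0
    _, y1 = frru(Tensor(x2), y)
    assert np.abs(y1.data - y0.data).max() > 0.0


def test_grid_not_divisible_raises():
    net = build_subnetwork(SubnetworkSpec(5, 16, base_channels=4), seed=0)  # level 3
    with pytest.raises(ShapeMismatchError):
        net(Tensor(np.zeros((2, 12, 12, 12))))


def test_cascade_count_guard():
    with pytest.raises(ValueError):
        build_cascade((TINY_SPEC, TINY_SPEC))  # non-standard without override
    two = build_cascade((TINY_SPEC, TINY_SPEC), allow_custom=True)
    assert len(two.subnets) == 2


def test_untrained_cascade_is_identity_and_wiring_exact():
    cascade = build_cascade((TINY_SPEC,) * 3, seed=0, allow_custom=True)
    rng = np.random.default_rng(4)
    fixed = rng.random((8, 8, 8))
    moving = rng.random((8, 8, 8))
    out = cascade_forward(cascade, fixed, moving)
    # zero-init heads: every field zero, warped output identical to moving
    for phi in out.dvfs_np:
        np.testing.assert_array_equal(phi, 0.0)
    np.testing.assert_array_equal(out.final_warped_np, moving)
    # exact recursion: Iw3 == warp(Iw2, phi3)
    np.testing.assert_array_equal(
        out.warped_np[2], warp_scalar(out.warped_np[1], out.dvfs_np[2]))


def test_trained_heads_give_different_fields_for_different_seeds():
    rng = np.random.default_rng(5)
    fixed, moving = rng.random((8, 8, 8)), rng.random((8, 8, 8))
    fields = []
    for seed in (0, 1):
        net = build_subnetwork(TINY_SPEC, seed=seed)
        # one gradient step on the head so the prediction becomes nontrivial
        out = predict_dvf(net, Tensor(fixed), Tensor(moving))
        loss = ad.reduce_mean(ad.square(out + 0.1))
        loss.backward()
        for p in net.parameters():
            if p.grad is not None:
                p.data -= 1.0 * p.grad
        fields.append(predict_dvf(net, fixed, moving))
    assert np.abs(fields[0] - fields[1]).max() > 1e-8


def test_end_to_end_gradient_check_tiny_cascade():
    """Finite-difference check through the full chain (2 cascades, 8^3)."""
    cascade = build_cascade((TINY_SPEC, TINY_SPEC), seed=0, allow_custom=True)
    rng = np.random.default_rng(6)
    fixed = rng.random((8, 8, 8))
    moving = rng.random((8, 8, 8))
    # give the heads nonzero weights so gradients flow through the warps
    for net in cascade.subnets:
        net.head.weight.data = rng.normal(0, 0.01, net.head.weight.data.shape)
    params = [cascade.subnets[0].head.bias, cascade.subnets[1].conv_in.weight]

    def run():
        out = cascade_forward(cascade, fixed, moving)
        return total_loss(fixed, out.warped[-1], out)

    loss = run()
    cascade.zero_grad()
    loss.backward()
    for p in params:
        analytic = p.grad.copy()
        flat = p.data.ravel()
        idx = rng.choice(flat.size, size=min(4, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            eps = 1e-5
            flat[i] = orig + eps
            fp = run().item()
            flat[i] = orig - eps
            fm = run().item()
            flat[i] = orig
            num = (fp - fm) / (2 * eps)
            scale = max(1.0, abs(analytic.ravel()[i]))
            assert abs(num - analytic.ravel()[i]) / scale < 1e-3


def test_checkpoint_round_trip(tmp_path):
    cascade = build_cascade((TINY_SPEC,) * 3, seed=3, allow_custom=True)
    rng = np.random.default_rng(7)
    for p in cascade.parameters():
        p.data += rng.normal(0, 0.01, p.data.shape)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(cascade, path, seed=3)
    restored, meta = load_checkpoint(path)
    assert meta["seed"] == 3
    fixed, moving = rng.random((8, 8, 8)), rng.random((8, 8, 8))
    a = cascade_forward(cascade, fixed, moving)
    b = cascade_forward(restored, fixed, moving)
    np.testing.assert_allclose(a.final_warped_np, b.final_warped_np, atol=1e-12)
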