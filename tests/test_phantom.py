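import numpy as np
import pytest

from frrreg.losses import smoothness_loss
from frrreg.metrics import ncc, rmse, ssim
from frrreg.phantom import (Organ, PhantomSpec, evaluation_pairs, make_phantom,
                            phase_amplitudes, random_smooth_dvf, training_pairs)
from frrreg.warp import warp_volume


def small_spec(**kw):
    defaults = dict(grid_shape=(16, 16, 16), n_phases=3, max_displacement=2.0,
                    smoothness_sigma=3.0, seed=0)
    defaults.update(kw)
    return PhantomSpec(**defaults)


def test_random_dvf_zero_displacement_is_zero_field():
    phi = random_smooth_dvf((8, 8, 8), 0.0, 2.0, seed=0)
    np.testing.assert_array_equal(phi, 0.0)


def test_random_dvf_peak_magnitude_contract():
    phi = random_smooth_dvf((12, 12, 12), 3.5, 2.0, seed=1)
    mags = np.sqrt((phi ** 2).sum(axis=0))
    assert mags.max() == pytest.approx(3.5, abs=1e-6)


def test_random_dvf_deterministic_per_seed():
    a = random_smooth_dvf((8, 8, 8), 2.0, 2.0, seed=5)
    b = random_smooth_dvf((8, 8, 8), 2.0, 2.0, seed=5)
    np.testing.assert_array_equal(a, b)
    c = random_smooth_dvf((8, 8, 8), 2.0, 2.0, seed=6)
    assert np.abs(a - c).max() > 0


def test_random_dvf_smoothness_decreases_with_sigma():
    """Wider smoothing kernels give smoother fields (averaged over seeds)."""
    means = []
    for sigma in (1.0, 2.0, 4.0):
        vals = [smoothness_loss(random_smooth_dvf((12, 12, 12), 2.0, sigma, seed=s))
                for s in range(10)]
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


def test_phase_amplitudes_shape():
    amps = phase_amplitudes(11)
    assert amps[0] == 0.0
    assert amps.max() == 1.0
    assert np.argmax(amps) == 5  # peak mid-cycle


def test_phantom_deterministic_per_seed():
    a = make_phantom(small_spec())
    b = make_phantom(small_spec())
    for va, vb in zip(a.volumes, b.volumes):
        np.testing.assert_array_equal(va.data, vb.data)
    for fa, fb in zip(a.fields, b.fields):
        np.testing.assert_array_equal(fa, fb)


def test_phase0_is_base_and_field_zero():
    ph = make_phantom(small_spec())
    np.testing.assert_array_equal(ph.fields[0], 0.0)
    # warping phase 0 by the zero field is the identity, so volume 0 is the base
    assert ph.volumes[0].window is not None
    assert ph.volumes[0].data.min() >= 0 and ph.volumes[0].data.max() <= 1


def test_peak_phase_reaches_max_displacement():
    ph = make_phantom(small_spec(n_phases=5, max_displacement=3.0))
    peak = max(np.sqrt((f ** 2).sum(axis=0)).max() for f in ph.fields)
    assert peak == pytest.approx(3.0, abs=1e-6)


def test_construction_consistency_warp_reproduces_phases():
    """Warping phase 0 by the stored phase-k field reproduces phase k."""
    ph = make_phantom(small_spec())
    for k in range(ph.n_phases):
        rewarped = warp_volume(ph.volumes[0], ph.fields[k])
        assert np.abs(rewarped.data - ph.volumes[k].data).max() < 1e-6


def test_motion_confined_to_body():
    ph = make_phantom(small_spec(n_phases=3, max_displacement=3.0))
    mags = np.sqrt((ph.fields[1] ** 2).sum(axis=0))
    body = ph.labels[0] > 0
    # away from the body the field tapers off; deep tissue carries the motion
    from scipy import ndimage
    near_body = ndimage.binary_dilation(body, iterations=4)
    assert mags[~near_body].mean() < 0.5 * mags[body].mean()


def test_metrics_degrade_with_displacement():
    """Before-registration misalignment grows monotonically with amplitude."""
    rmses, nccs, ssims = [], [], []
    for amp in (1.0, 3.0, 5.0):
        ph = make_phantom(small_spec(n_phases=3, max_displacement=amp))
        ep = evaluation_pairs(ph, phases=[1])[0]
        f_hu = ep.fixed.window.denormalize(ep.fixed.data)
        m_hu = ep.fixed.window.denormalize(ep.moving.data)
        rmses.append(rmse(m_hu, f_hu))
        nccs.append(ncc(ep.moving.data, ep.fixed.data))
        ssims.append(ssim(ep.moving.data, ep.fixed.data))
    assert rmses[0] < rmses[1] < rmses[2]
    assert nccs[0] > nccs[1] > nccs[2]
    assert ssims[0] > ssims[1] > ssims[2]


def test_pair_helpers_counts():
    ph = make_phantom(small_spec(n_phases=3))
    assert len(training_pairs(ph)) == 6  # 3 phases, ordered pairs
    assert len(training_pairs(ph, "fixed_reference")) == 2
    eps = evaluation_pairs(ph)
    assert [e.phase for e in eps] == [1, 2]
    for e in eps:
        assert e.true_field.shape == (3, 16, 16, 16)


def test_organ_validation():
    with pytest.raises(ValueError):
        Organ((0.5, 0.5, 0.5), (0.6, 0.1, 0.1), 0.0)  # extends outside
    with pytest.raises(ValueError):
        PhantomSpec(n_phases=1)
    with pytest.raises(ValueError):
        PhantomSpec(max_displacement=-1.0)


def test_cbct_variant_is_noisier():
    """The CBCT-like mode raises the noise floor over the same anatomy."""
    clean = make_phantom(small_spec())
    noisy = make_phantom(small_spec(cbct_like=True))
    diff = noisy.volumes[0].data - clean.volumes[0].data
    # same seed, same anatomy: the difference is pure extra noise + streaks
    assert diff.std() > 0.005
    np.testing.assert_array_equal(clean.labels[0], noisy.labels[0])
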