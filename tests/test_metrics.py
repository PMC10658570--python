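import numpy as np
import pytest

from frrreg.metrics import (ConstantImageError, ROIBox, dice, evaluate_pair,
                            extract_roi, ncc, rmse, ssim)
from frrreg.volumes_io import IntensityWindow, Volume

RNG = np.random.default_rng(5)


def loop_rmse(w, f):
    total, n = 0.0, 0
    for wi, fi in zip(w.ravel(), f.ravel()):
        total += (wi - fi) ** 2
        n += 1
    return np.sqrt(total / n)


def loop_ncc(w, f):
    wm = sum(w.ravel()) / w.size
    fm = sum(f.ravel()) / f.size
    num = den_w = den_f = 0.0
    for wi, fi in zip(w.ravel(), f.ravel()):
        num += (wi - wm) * (fi - fm)
        den_w += (wi - wm) ** 2
        den_f += (fi - fm) ** 2
    return num / (np.sqrt(den_w) * np.sqrt(den_f))


def loop_ssim(w, f, L=1.0):
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    n = w.size
    wm = sum(w.ravel()) / n
    fm = sum(f.ravel()) / n
    vw = sum((x - wm) ** 2 for x in w.ravel()) / n
    vf = sum((x - fm) ** 2 for x in f.ravel()) / n
    cov = sum((a - wm) * (b - fm) for a, b in zip(w.ravel(), f.ravel())) / n
    return ((2 * wm * fm + c1) * (2 * cov + c2)) / ((wm ** 2 + fm ** 2 + c1) * (vw + vf + c2))


def loop_dice(mw, mf):
    inter = both = 0
    for a, b in zip(mw.ravel(), mf.ravel()):
        inter += bool(a) and bool(b)
        both += bool(a) + bool(b)
    return 1.0 if both == 0 else 2.0 * inter / both


def test_metrics_match_loop_oracles_on_random_grids():
    for _ in range(10):
        shape = tuple(RNG.integers(2, 7, size=3))
        w = RNG.random(shape)
        f = RNG.random(shape)
        assert rmse(w, f) == pytest.approx(loop_rmse(w, f), abs=1e-6)
        assert ncc(w, f) == pytest.approx(loop_ncc(w, f), abs=1e-6)
        assert ssim(w, f) == pytest.approx(loop_ssim(w, f), abs=1e-6)
        mw, mf = w > 0.5, f > 0.5
        assert dice(mw, mf) == pytest.approx(loop_dice(mw, mf), abs=1e-6)


def test_identity_values():
    a = RNG.random((4, 4, 4))
    assert rmse(a, a) == 0.0
    assert ncc(a, a) == pytest.approx(1.0)
    assert ssim(a, a) == pytest.approx(1.0)
    m = a > 0.5
    assert dice(m, m) == 1.0


def test_rmse_hand_values():
    assert rmse(np.ones(4).reshape(1, 1, 4), np.zeros((1, 1, 4))) == pytest.approx(1.0)
    assert rmse(np.array([[[0.0, 2.0]]]), np.zeros((1, 1, 2))) == pytest.approx(np.sqrt(2))


def test_ncc_linear_and_anticorrelated():
    w = np.array([[[1.0, 2.0, 3.0, 4.0]]])
    assert ncc(w, 2 * w) == pytest.approx(1.0)
    centered = w - w.mean()
    assert ncc(centered, -centered) == pytest.approx(-1.0)
    with pytest.raises(ConstantImageError):
        ncc(np.full((2, 2, 2), 3.0), RNG.random((2, 2, 2)))


def test_ssim_constant_images_closed_form():
    """Constant grids 0.2 and 0.8 at L=1: variance terms vanish and the value
    reduces to (2*0.16+1e-4)*9e-4 / ((0.04+0.64+1e-4)*9e-4) ~ 0.4707."""
    w = np.full((3, 3, 3), 0.2)
    f = np.full((3, 3, 3), 0.8)
    expected = (2 * 0.2 * 0.8 + 1e-4) / (0.2 ** 2 + 0.8 ** 2 + 1e-4)
    assert expected == pytest.approx(0.4707, abs=5e-5)
    assert ssim(w, f, L=1.0) == pytest.approx(expected)


def test_symmetry():
    a, b = RNG.random((3, 3, 3)), RNG.random((3, 3, 3))
    assert rmse(a, b) == rmse(b, a)
    assert ncc(a, b) == pytest.approx(ncc(b, a))
    assert ssim(a, b) == pytest.approx(ssim(b, a))
    ma, mb = a > 0.5, b > 0.5
    assert dice(ma, mb) == dice(mb, ma)


def test_dice_cases():
    a = np.zeros((2, 2, 2), bool)
    b = np.zeros((2, 2, 2), bool)
    assert dice(a, b) == 1.0  # both empty
    a[0, 0, 0] = True
    b[1, 1, 1] = True
    assert dice(a, b) == 0.0  # disjoint
    a[0, 0, 1] = True
    b[0, 0, 1] = True
    assert dice(a, b) == pytest.approx(0.5)  # |W|=|F|=2, overlap 1


def test_extract_roi_contract():
    # the canonical 30x30 in-plane, 5-slice box must fit the volume
    grid = RNG.random((40, 40, 10))
    with pytest.raises(ValueError):  # x extent 5+30 exceeds 10
        extract_roi(grid, ROIBox(origin=(2, 5, 5), size=(5, 30, 30), label="lung"))
    grid = RNG.random((10, 40, 40))
    sub = extract_roi(grid, ROIBox(origin=(2, 5, 5), size=(5, 30, 30)))
    assert sub.shape == (5, 30, 30)
    np.testing.assert_array_equal(sub, grid[2:7, 5:35, 5:35])
    with pytest.raises(ValueError):
        extract_roi(grid, ROIBox(origin=(8, 0, 0), size=(5, 30, 30)))


def test_roi_metrics_equal_subgrid_metrics():
    w = RNG.random((12, 12, 12))
    f = RNG.random((12, 12, 12))
    box = ROIBox(origin=(2, 3, 4), size=(4, 5, 6))
    ws, fs = extract_roi(w, box), extract_roi(f, box)
    win = IntensityWindow(0.0, 1.0)
    report = evaluate_pair(Volume(w, window=win), Volume(f, window=win), [box])
    roi = report.regions["roi_1"]
    assert roi.rmse_hu == pytest.approx(rmse(ws, fs))
    assert roi.ncc == pytest.approx(ncc(ws, fs))
    assert roi.ssim == pytest.approx(ssim(ws, fs))


def test_evaluate_pair_layout_and_perfect_case():
    win = IntensityWindow(-1000.0, 1000.0)
    a = RNG.random((10, 10, 10))
    vol = Volume(a, window=win)
    box = ROIBox(origin=(1, 1, 1), size=(4, 4, 4), label="liver")
    report = evaluate_pair(vol, Volume(a.copy(), window=win), [box])
    assert report.regions["global"].dice is None  # no Dice on the global row
    assert report.regions["liver"].dice == 1.0
    assert report.regions["global"].rmse_hu == 0.0
    assert report.regions["global"].ncc == pytest.approx(1.0)
    assert report.regions["global"].ssim == pytest.approx(1.0)
    df = report.to_dataframe()
    assert list(df.columns) == ["region", "rmse_hu", "ncc", "ssim", "dice"]
    assert np.isnan(df.set_index("region").loc["global", "dice"])
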