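"""Self-contained desk-scale validation studies.

These are the standard experiments the package runs on CPU to validate the
whole method end to end against synthetic ground truth:

* :func:`overfit_study` — single-pair overfit: the unsupervised loss must
  drive the similarity term far below its starting value on one phantom pair.
* :func:`recovery_study` — patient-specific parameter recovery: a reduced
  cascade is trained on 8 phase pairs of one 4D phantom and evaluated on two
  held-out ground-truth pairs (phase combinations never seen in training),
  measuring endpoint error against the known field and the before/after image
  metrics.  This mirrors the clinical within-patient 4D-CT protocol where all
  phases of one series are registered to a reference.
* :func:`composition_study` — consistency of single-step warping by the
  composed field with sequential three-step warping.

Problem sizes (16^3 grids, 8-channel base, hundreds of iterations) are chosen
so each study completes in minutes on one CPU; the methods note discusses what
these scaled-down runs do and do not demonstrate.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .frrnet import REDUCED_SPECS, build_cascade, cascade_forward
from .losses import LossConfig, similarity_loss
from .metrics import dice, ncc, rmse, ssim
from .phantom import PhantomSpec, evaluation_pairs, make_phantom, random_smooth_dvf
from .training import desk_config, train
from .volumes_io import to_hu
from .warp import compose, warp_nearest, warp_scalar

#: training pairs of the patient-specific recovery protocol, as
#: (fixed phase, moving phase); the ground-truth pairs (2, 0) and (3, 0)
#: are held out for evaluation
RECOVERY_TRAIN_PAIRS = ((1, 0), (4, 0), (2, 1), (3, 1), (1, 2), (4, 3), (3, 4), (2, 4))

#: loss used for the desk-scale studies: diffusion penalty on the composed
#: transform, strength calibrated on the direct-optimization control
STUDY_LOSS = LossConfig(alpha=0.02, smooth_target="composed_field")


def _study_phantom(seed: int, n_phases: int = 5, max_displacement: float = 3.0):
    return make_phantom(PhantomSpec(
        grid_shape=(16, 16, 16), n_phases=n_phases,
        max_displacement=max_displacement, smoothness_sigma=4.0, seed=seed))


def overfit_study(seed: int = 0, iterations: int = 300) -> dict:
    """Overfit one phantom pair; returns initial/final similarity and history.

    With a single pair the network can and should drive the similarity term
    far below its starting value; the smoothed loss curve is expected to be
    non-increasing.
    """
    ph = _study_phantom(seed, n_phases=3, max_displacement=2.0)
    fixed, moving = ph.volumes[1], ph.volumes[0]
    initial = similarity_loss(fixed, moving)
    cascade = build_cascade(REDUCED_SPECS, seed=seed, allow_custom=True)
    cascade, history = train(cascade, [(fixed, moving)],
                             desk_config(iterations=iterations, seed=seed))
    final = float(history["similarity"].iloc[-1])
    smoothed = history["total"].rolling(50).mean().dropna()
    return {
        "initial_similarity": float(initial),
        "final_similarity": final,
        "similarity_ratio": final / float(initial),
        "smoothed_loss_nonincreasing": bool(
            (np.diff(smoothed.to_numpy()) <= 1e-12).all()),
        "history": history,
        "cascade": cascade,
    }


def recovery_study(seed: int = 0, iterations: int = 600) -> dict:
    """Patient-specific field recovery on held-out phase pairs.

    Trains the reduced cascade on the 8 ``RECOVERY_TRAIN_PAIRS`` of one
    phantom (peak displacement 3 voxels) and evaluates on the two held-out
    ground-truth pairs (reference phase onto phases 2 and 3).  Reports the
    mean endpoint error relative to the mean true displacement magnitude,
    before/after RMSE (HU), NCC, SSIM and liver Dice, and the per-cascade
    RMSE used for the progressive-registration check.
    """
    ph = _study_phantom(seed)
    vols = ph.volumes
    pairs = [(vols[f], vols[m]) for f, m in RECOVERY_TRAIN_PAIRS]
    cascade = build_cascade(REDUCED_SPECS, seed=seed, allow_custom=True)
    cfg = desk_config(iterations=iterations, seed=seed, loss=STUDY_LOSS)
    cascade, history = train(cascade, pairs, cfg)

    results = {"pairs": [], "history": history, "cascade": cascade}
    liver = 2  # label index of the liver ellipsoid
    for ep in evaluation_pairs(ph, phases=[2, 3]):
        with ad.no_grad():
            out = cascade_forward(cascade, ep.fixed, ep.moving)
        pred, true = out.composed_np, ep.true_field
        err = np.sqrt(((pred - true) ** 2).sum(axis=0))
        mag = np.sqrt((true ** 2).sum(axis=0))
        window = ep.fixed.window
        fixed_hu = to_hu(ep.fixed)
        pred_labels = warp_nearest(ep.moving_labels, pred)
        results["pairs"].append({
            "phase": ep.phase,
            "epe": float(err.mean()),
            "true_magnitude": float(mag.mean()),
            "epe_ratio": float(err.mean() / mag.mean()),
            "rmse_before": rmse(window.denormalize(ep.moving.data), fixed_hu),
            "rmse_after": rmse(window.denormalize(out.final_warped_np), fixed_hu),
            "rmse_per_cascade": [rmse(window.denormalize(w), fixed_hu)
                                 for w in out.warped_np],
            "ncc_before": ncc(ep.moving.data, ep.fixed.data),
            "ncc_after": ncc(out.final_warped_np, ep.fixed.data),
            "ssim_before": ssim(ep.moving.data, ep.fixed.data),
            "ssim_after": ssim(out.final_warped_np, ep.fixed.data),
            "dice_before": dice(ep.moving_labels == liver, ep.fixed_labels == liver),
            "dice_after": dice(pred_labels == liver, ep.fixed_labels == liver),
        })
    rows = results["pairs"]
    results["epe_ratio_mean"] = float(np.mean([r["epe_ratio"] for r in rows]))
    results["rmse_per_cascade_mean"] = [
        float(np.mean([r["rmse_per_cascade"][i] for r in rows])) for i in range(3)]
    return results


def composition_study(seed: int = 0) -> float:
    """Mean |intensity| difference between composed and sequential warping.

    Uses a smooth 32^3 phantom volume (correlated tissue mottle only — no
    focal features or white noise, since interpolation error scales with the
    image's second derivatives) and three random smooth fields of the
    magnitude the cascades produce.
    """
    ph = make_phantom(PhantomSpec(grid_shape=(32, 32, 32), n_phases=3,
                                  max_displacement=2.0, smoothness_sigma=6.0,
                                  noise_sigma=0.0, n_focal=0,
                                  seed=seed))
    img = ph.volumes[0].data
    fields = [random_smooth_dvf((32, 32, 32), 2.0, 6.0, seed=seed + 10 + i)
              for i in range(3)]
    sequential = img
    for f in fields:
        sequential = warp_scalar(sequential, f)
    composed = fields[0]
    for f in fields[1:]:
        composed = compose(composed, f)
    one_step = warp_scalar(img, composed)
    return float(np.abs(one_step - sequential).mean())
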