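"""Unsupervised registration objective: image similarity + field smoothness.

The training loss is

    L = MSE(fixed, final_warped) + alpha * L_smooth(phi)

where the smoothness term is a diffusion regularizer: squared forward finite
differences of every field component along every axis.  By default the
regularized field is the final cascade's own field (phi_3); the composed field
or all per-cascade fields can be selected instead, since regularizing only the
last cascade leaves the earlier fields formally unconstrained.

The smoothness term is mean-reduced by default so that the weight ``alpha``
(default 0.01) keeps its meaning across grid sizes; the literal sum is
available with ``reduction="sum"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .volumes_io import Volume
from .warp import ShapeMismatchError

SMOOTH_TARGETS = ("final_field", "composed_field", "all_fields")
REDUCTIONS = ("mean", "sum")


@dataclass(frozen=True)
class LossConfig:
    """Weights and options of the unsupervised training objective."""

    alpha: float = 0.01
    smooth_target: str = "final_field"
    reduction: str = "mean"

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.smooth_target not in SMOOTH_TARGETS:
            raise ValueError(f"smooth_target must be one of {SMOOTH_TARGETS}")
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"reduction must be one of {REDUCTIONS}")


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    if isinstance(x, Volume):
        x = x.data
    return Tensor(np.asarray(x, dtype=np.float64)), False


def similarity_loss(fixed, warped):
    """Mean squared intensity difference between fixed and warped volumes.

    Returns a float for array inputs, a Tensor when either input carries a
    gradient graph.
    """
    f, f_t = _as_tensor(fixed)
    w, w_t = _as_tensor(warped)
    if f.data.shape != w.data.shape:
        raise ShapeMismatchError(f"fixed {f.data.shape} != warped {w.data.shape}")
    out = ad.reduce_mean(ad.square(f - w))
    return out if (f_t or w_t) else out.item()


def smoothness_loss(phi, reduction: str = "mean"):
    """Diffusion regularizer: squared forward differences of the field.

    Differences are taken per component along each spatial axis (interior
    voxels only, i.e. the last slice along the differenced axis is dropped)
    and reduced over all components and axes — ``mean`` divides by the total
    number of difference terms, ``sum`` is the raw sum of squares.
    """
    if reduction not in REDUCTIONS:
        raise ValueError(f"reduction must be one of {REDUCTIONS}")
    p, p_t = _as_tensor(phi)
    if p.data.ndim != 4 or p.data.shape[0] != 3:
        raise ShapeMismatchError(f"field must be (3, D, H, W), got {p.data.shape}")
    total = None
    count = 0
    for ax in (1, 2, 3):
        hi = [slice(None)] * 4
        lo = [slice(None)] * 4
        hi[ax] = slice(1, None)
        lo[ax] = slice(None, -1)
        d = p[tuple(hi)] - p[tuple(lo)]
        count += d.data.size
        s = ad.reduce_sum(ad.square(d))
        total = s if total is None else total + s
    if reduction == "mean":
        total = total / count
    return total if p_t else total.item()


def total_loss(fixed, final_warped, fields, cfg: LossConfig = LossConfig()):
    """Similarity plus ``alpha`` times the smoothness of the selected field(s).

    ``fields`` is a cascade output (anything with ``dvfs`` and ``composed``
    attributes) or, for convenience, a single displacement field.
    """
    sim = similarity_loss(fixed, final_warped)
    if cfg.alpha == 0:
        return sim
    if hasattr(fields, "dvfs"):
        if cfg.smooth_target == "final_field":
            smooth = smoothness_loss(fields.dvfs[-1], cfg.reduction)
        elif cfg.smooth_target == "composed_field":
            smooth = smoothness_loss(fields.composed, cfg.reduction)
        else:  # all_fields: average the per-cascade penalties
            terms = [smoothness_loss(d, cfg.reduction) for d in fields.dvfs]
            smooth = terms[0]
            for t in terms[1:]:
                smooth = smooth + t
            smooth = smooth / len(terms)
    else:
        smooth = smoothness_loss(fields, cfg.reduction)
    return sim + cfg.alpha * smooth
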