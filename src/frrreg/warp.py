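"""Backward warping by displacement fields and field composition.

A displacement field ``phi`` is a ``(3, D, H, W)`` array of voxel-unit
displacements in ``(z, y, x)`` component order, same spatial shape as the
volume it warps.  Warping follows the backward convention:

    ``out(v) = moving(v + phi(v))``

sampled by trilinear interpolation, with out-of-domain coordinates clamped to
the volume border.  The sampler is differentiable with respect to both the
moving image and the field, so registration losses backpropagate through it.

Fields compose as ``compose(earlier, later)(v) = later(v) + earlier(v +
later(v))``, which makes a single warp by the composed field agree with
sequential warping by ``earlier`` then ``later``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .volumes_io import Volume, with_data


class ShapeMismatchError(ValueError):
    """Volume and displacement-field shapes disagree."""


def _check_field(shape: tuple[int, ...], phi_shape: tuple[int, ...]) -> None:
    if len(phi_shape) != 4 or phi_shape[0] != 3:
        raise ShapeMismatchError(f"field must be (3, D, H, W), got {phi_shape}")
    if tuple(phi_shape[1:]) != tuple(shape):
        raise ShapeMismatchError(f"volume shape {shape} != field spatial shape {phi_shape[1:]}")


def _trilinear_parts(img: np.ndarray, phi: np.ndarray):
    """Forward trilinear sampling with border clamping, plus backward cache."""
    D, H, W = img.shape
    base = np.indices((D, H, W), dtype=phi.dtype)
    coords = base + phi
    dims = (D, H, W)
    lo = []
    frac = []
    inside = []
    for ax, n in enumerate(dims):
        cc = np.clip(coords[ax], 0.0, n - 1.0)
        i0 = np.clip(np.floor(cc).astype(np.intp), 0, max(n - 2, 0))
        lo.append(i0)
        frac.append(cc - i0)
        inside.append((coords[ax] >= 0.0) & (coords[ax] <= n - 1.0))
    z0, y0, x0 = lo
    fz, fy, fx = frac
    z1 = np.minimum(z0 + 1, D - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    flat = img.ravel()

    def at(zi, yi, xi):
        return flat[(zi * H + yi) * W + xi]

    c = {}
    for bz, zi in ((0, z0), (1, z1)):
        for by, yi in ((0, y0), (1, y1)):
            for bx, xi in ((0, x0), (1, x1)):
                c[(bz, by, bx)] = at(zi, yi, xi)
    wz = (1 - fz, fz)
    wy = (1 - fy, fy)
    wx = (1 - fx, fx)
    out = np.zeros_like(fz)
    for (bz, by, bx), val in c.items():
        out += val * wz[bz] * wy[by] * wx[bx]
    cache = dict(c=c, wz=wz, wy=wy, wx=wx, inside=inside,
                 corners=((z0, z1), (y0, y1), (x0, x1)), shape=(D, H, W))
    return out, cache


def _backward_to_image(g: np.ndarray, cache, img_shape) -> np.ndarray:
    D, H, W = img_shape
    (z0, z1), (y0, y1), (x0, x1) = cache["corners"]
    wz, wy, wx = cache["wz"], cache["wy"], cache["wx"]
    dimg = np.zeros(D * H * W, dtype=g.dtype)
    for bz, zi in ((0, z0), (1, z1)):
        for by, yi in ((0, y0), (1, y1)):
            for bx, xi in ((0, x0), (1, x1)):
                idx = (zi * H + yi) * W + xi
                np.add.at(dimg, idx.ravel(), (g * wz[bz] * wy[by] * wx[bx]).ravel())
    return dimg.reshape(D, H, W)


def _backward_to_field(g: np.ndarray, cache) -> np.ndarray:
    c = cache["c"]
    wz, wy, wx = cache["wz"], cache["wy"], cache["wx"]
    inside = cache["inside"]
    # d out / d coordinate along each axis, zero where the sample was clamped
    dz = np.zeros_like(g)
    dy = np.zeros_like(g)
    dx = np.zeros_like(g)
    for by in (0, 1):
        for bx in (0, 1):
            dz += (c[(1, by, bx)] - c[(0, by, bx)]) * wy[by] * wx[bx]
    for bz in (0, 1):
        for bx in (0, 1):
            dy += (c[(bz, 1, bx)] - c[(bz, 0, bx)]) * wz[bz] * wx[bx]
    for bz in (0, 1):
        for by in (0, 1):
            dx += (c[(bz, by, 1)] - c[(bz, by, 0)]) * wz[bz] * wy[by]
    return np.stack([g * dz * inside[0], g * dy * inside[1], g * dx * inside[2]])


def warp_scalar(img, phi):
    """Warp one scalar grid ``(D, H, W)`` by ``phi``; Tensor-aware."""
    if isinstance(img, Tensor) or isinstance(phi, Tensor):
        img_t = img if isinstance(img, Tensor) else Tensor(np.asarray(img))
        phi_t = phi if isinstance(phi, Tensor) else Tensor(np.asarray(phi))
        _check_field(img_t.data.shape, phi_t.data.shape)
        out, cache = _trilinear_parts(img_t.data, phi_t.data)

        def backward(g):
            if img_t.requires_grad:
                img_t._accumulate(_backward_to_image(g, cache, img_t.data.shape))
            if phi_t.requires_grad:
                phi_t._accumulate(_backward_to_field(g, cache))

        return ad._make(out, (img_t, phi_t), backward)
    img = np.asarray(img)
    phi = np.asarray(phi)
    _check_field(img.shape, phi.shape)
    out, _ = _trilinear_parts(img, phi.astype(np.result_type(phi.dtype, np.float64)))
    return out


def warp_volume(moving, phi):
    """Backward-warp a volume by a displacement field.

    ``moving`` may be a :class:`~frrreg.volumes_io.Volume` (a Volume is
    returned), a plain ndarray, or an autodiff Tensor (differentiable path).
    """
    if isinstance(moving, Volume):
        return with_data(moving, warp_scalar(moving.data, phi))
    return warp_scalar(moving, phi)


def warp_nearest(labels: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Warp an integer label grid with nearest-neighbour sampling."""
    labels = np.asarray(labels)
    phi = np.asarray(phi, dtype=np.float64)
    _check_field(labels.shape, phi.shape)
    D, H, W = labels.shape
    base = np.indices((D, H, W), dtype=np.float64)
    coords = base + phi
    idx = []
    for ax, n in enumerate((D, H, W)):
        idx.append(np.clip(np.rint(coords[ax]).astype(np.intp), 0, n - 1))
    return labels[idx[0], idx[1], idx[2]]


def compose(phi_earlier, phi_later):
    """Compose two displacement fields (earlier applied first when warping).

    ``compose(a, b)(v) = b(v) + a(v + b(v))`` so that warping once by the
    composed field matches warping by ``a`` and then by ``b`` sequentially.
    """
    if isinstance(phi_earlier, Tensor) or isinstance(phi_later, Tensor):
        a = phi_earlier if isinstance(phi_earlier, Tensor) else Tensor(np.asarray(phi_earlier))
        b = phi_later if isinstance(phi_later, Tensor) else Tensor(np.asarray(phi_later))
        _check_field(a.data.shape[1:], b.data.shape)
        _check_field(b.data.shape[1:], a.data.shape)
        parts = []
        for d in range(3):
            sampled = warp_scalar(a[d], b)
            parts.append(ad.reshape(b[d] + sampled, (1,) + b.data.shape[1:]))
        return ad.concat(parts, axis=0)
    a = np.asarray(phi_earlier, dtype=np.float64)
    b = np.asarray(phi_later, dtype=np.float64)
    _check_field(a.shape[1:], b.shape)
    _check_field(b.shape[1:], a.shape)
    return b + np.stack([warp_scalar(a[d], b) for d in range(3)])


def endpoint_error(phi_pred, phi_true) -> float:
    """Mean Euclidean norm of the per-voxel difference of two fields (voxels)."""
    a = phi_pred.data if isinstance(phi_pred, Tensor) else np.asarray(phi_pred, dtype=np.float64)
    b = phi_true.data if isinstance(phi_true, Tensor) else np.asarray(phi_true, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"field shapes differ: {a.shape} vs {b.shape}")
    _check_field(a.shape[1:], a.shape)
    return float(np.sqrt(((a - b) ** 2).sum(axis=0)).mean())


def field_magnitude(phi) -> float:
    """Mean Euclidean norm of a field's displacement vectors (voxels)."""
    a = phi.data if isinstance(phi, Tensor) else np.asarray(phi, dtype=np.float64)
    _check_field(a.shape[1:], a.shape)
    return float(np.sqrt((a ** 2).sum(axis=0)).mean())
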