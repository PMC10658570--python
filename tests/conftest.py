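import numpy as np


def brute_force_warp(img: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Nested-loop trilinear backward warp with border clamping (oracle)."""
    D, H, W = img.shape
    out = np.zeros_like(img, dtype=np.float64)
    for z in range(D):
        for y in range(H):
            for x in range(W):
                cz = min(max(z + phi[0, z, y, x], 0.0), D - 1)
                cy = min(max(y + phi[1, z, y, x], 0.0), H - 1)
                cx = min(max(x + phi[2, z, y, x], 0.0), W - 1)
                z0 = min(int(np.floor(cz)), max(D - 2, 0))
                y0 = min(int(np.floor(cy)), max(H - 2, 0))
                x0 = min(int(np.floor(cx)), max(W - 2, 0))
                fz, fy, fx = cz - z0, cy - y0, cx - x0
                v = 0.0
                for bz in (0, 1):
                    for by in (0, 1):
                        for bx in (0, 1):
                            wz = fz if bz else 1 - fz
                            wy = fy if by else 1 - fy
                            wx = fx if bx else 1 - fx
                            v += (img[min(z0 + bz, D - 1), min(y0 + by, H - 1),
                                      min(x0 + bx, W - 1)] * wz * wy * wx)
                out[z, y, x] = v
    return out


def numerical_gradient(arr: np.ndarray, f, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``f()`` w.r.t. ``arr`` in place."""
    g = np.zeros_like(arr)
    flat, gf = arr.ravel(), g.ravel()
    for i in range(arr.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
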