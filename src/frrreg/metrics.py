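"""Registration quality metrics: RMSE, NCC, SSIM, Dice, and ROI reporting.

RMSE is reported in Hounsfield units (the normalization window is inverted
first); NCC and SSIM operate on the normalized intensities.  SSIM is the
single global value computed from whole-region means, variances and the
cross-covariance — not a sliding-window average.  Dice compares binary masks;
for image pairs without label maps the masks come from a fixed intensity
threshold applied inside each ROI box.

Metrics are reported for the global volume and for axis-aligned ROI boxes
(canonically 30x30 in-plane by 5 slices, placed over organs with large
respiratory motion); the global row carries no Dice score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes_io import Volume, to_hu


class ConstantImageError(ValueError):
    """NCC is undefined for a constant image (zero variance)."""


def rmse(warped: np.ndarray, fixed: np.ndarray) -> float:
    """Root mean squared intensity difference (input scale, typically HU)."""
    w = np.asarray(warped, dtype=np.float64)
    f = np.asarray(fixed, dtype=np.float64)
    if w.shape != f.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {f.shape}")
    return float(np.sqrt(np.mean((w - f) ** 2)))


def ncc(warped: np.ndarray, fixed: np.ndarray) -> float:
    """Pearson correlation of the two intensity vectors over all voxels."""
    w = np.asarray(warped, dtype=np.float64).ravel()
    f = np.asarray(fixed, dtype=np.float64).ravel()
    if w.shape != f.shape:
        raise ValueError(f"shape mismatch: {warped.shape} vs {fixed.shape}")
    wc = w - w.mean()
    fc = f - f.mean()
    denom = np.sqrt((wc ** 2).sum()) * np.sqrt((fc ** 2).sum())
    if denom == 0.0:
        raise ConstantImageError("NCC undefined: at least one image is constant")
    return float((wc * fc).sum() / denom)


def ssim(warped: np.ndarray, fixed: np.ndarray, L: float = 1.0) -> float:
    """Global structural similarity from whole-region statistics.

    ``L`` is the dynamic range of the inputs (1 for normalized volumes);
    the stabilizing constants are C1 = (0.01 L)^2 and C2 = (0.03 L)^2.
    """
    w = np.asarray(warped, dtype=np.float64).ravel()
    f = np.asarray(fixed, dtype=np.float64).ravel()
    if w.shape != f.shape:
        raise ValueError(f"shape mismatch: {warped.shape} vs {fixed.shape}")
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mw, mf = w.mean(), f.mean()
    vw, vf = w.var(), f.var()
    cov = ((w - mw) * (f - mf)).mean()
    return float(((2 * mw * mf + c1) * (2 * cov + c2))
                 / ((mw ** 2 + mf ** 2 + c1) * (vw + vf + c2)))


def dice(mask_w: np.ndarray, mask_f: np.ndarray) -> float:
    """Overlap index 2|W n F| / (|W| + |F|); 1.0 when both masks are empty."""
    w = np.asarray(mask_w).astype(bool)
    f = np.asarray(mask_f).astype(bool)
    if w.shape != f.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {f.shape}")
    total = int(w.sum()) + int(f.sum())
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(w, f).sum() / total)


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned region of interest: 0-based voxel corner and extent."""

    origin: tuple[int, int, int]  # (z, y, x)
    size: tuple[int, int, int]
    label: str = ""

    def __post_init__(self):
        if any(o < 0 for o in self.origin):
            raise ValueError(f"ROI origin must be non-negative, got {self.origin}")
        if any(s < 1 for s in self.size):
            raise ValueError(f"ROI size must be positive, got {self.size}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))


def extract_roi(v, box: ROIBox) -> np.ndarray:
    """Slice the ROI box out of a Volume or grid (shape equals ``box.size``)."""
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    for o, s, n in zip(box.origin, box.size, data.shape):
        if o + s > n:
            raise ValueError(f"ROI box {box.origin}+{box.size} exceeds volume shape {data.shape}")
    return data[box.slices()]


@dataclass
class RegionMetrics:
    rmse_hu: float
    ncc: float
    ssim: float
    dice: float | None = None  # absent for the global row


@dataclass
class MetricReport:
    """Per-region metric rows: the global volume plus each ROI box."""

    regions: dict[str, RegionMetrics]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, m in self.regions.items():
            rows.append({"region": name, "rmse_hu": m.rmse_hu, "ncc": m.ncc,
                         "ssim": m.ssim,
                         "dice": np.nan if m.dice is None else m.dice})
        return pd.DataFrame(rows)


def evaluate_pair(warped: Volume, fixed: Volume, rois=(), mask_rule=0.5) -> MetricReport:
    """Compute the full metric table for one registered pair.

    RMSE is computed on HU grids recovered through each volume's intensity
    window; NCC and SSIM on normalized intensities (dynamic range 1).  Dice is
    computed per ROI on binary masks: ``mask_rule`` is either a normalized
    intensity threshold (default 0.5) or a callable mapping a subgrid to a
    boolean mask.
    """
    if warped.data.shape != fixed.data.shape:
        raise ValueError(f"shape mismatch: {warped.data.shape} vs {fixed.data.shape}")
    w_hu, f_hu = to_hu(warped), to_hu(fixed)
    regions = {
        "global": RegionMetrics(
            rmse_hu=rmse(w_hu, f_hu),
            ncc=ncc(warped.data, fixed.data),
            ssim=ssim(warped.data, fixed.data, L=1.0),
        )
    }
    to_mask = mask_rule if callable(mask_rule) else (lambda sub: sub >= mask_rule)
    for i, box in enumerate(rois):
        name = box.label or f"roi_{i + 1}"
        w_sub, f_sub = extract_roi(warped, box), extract_roi(fixed, box)
        regions[name] = RegionMetrics(
            rmse_hu=rmse(extract_roi(w_hu, box), extract_roi(f_hu, box)),
            ncc=ncc(w_sub, f_sub),
            ssim=ssim(w_sub, f_sub, L=1.0),
            dice=dice(to_mask(w_sub), to_mask(f_sub)),
        )
    return MetricReport(regions=regions)
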