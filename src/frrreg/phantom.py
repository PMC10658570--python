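"""Synthetic 4D respiratory-motion phantoms with exact ground-truth fields.

A phantom is a base abdominal-like volume (ellipsoidal organs with distinct
pseudo-HU intensities over an air background, plus seeded Gaussian noise that
acts as trackable CT texture) deformed through a respiratory cycle.  Motion is
separable: a single smooth random displacement field is drawn once and its
amplitude is modulated sinusoidally across phases — zero at phase 0 (the
reference), peaking mid-cycle.  Phase k is the base volume backward-warped by
the phase-k field, so the stored field is exact ground truth for registering
the phase-0 volume onto phase k, and organ label masks follow the same field
with nearest-neighbour sampling.

The fields are smooth, bounded and identical in structure to the quasi-periodic
organ motion the registration method assumes; they are not a physical CT/CBCT
simulation (no projection physics, no sliding interfaces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes_io import IntensityWindow, Volume
from .warp import warp_nearest, warp_volume


@dataclass(frozen=True)
class Organ:
    """A superellipsoid in fractional grid coordinates with a pseudo-HU intensity.

    ``exponent`` 2 gives an ordinary ellipsoid; larger exponents flatten the
    profile toward a rounded box (used for the torso-like body outline).
    """

    center: tuple[float, float, float]  # fractions of the grid extent, (z, y, x)
    semiaxes: tuple[float, float, float]
    hu: float
    name: str = ""
    exponent: float = 2.0

    def __post_init__(self):
        if self.exponent < 2.0:
            raise ValueError("exponent must be >= 2")
        for c, a in zip(self.center, self.semiaxes):
            if a <= 0:
                raise ValueError(f"semiaxes must be positive: {self.semiaxes}")
            if c - a < 0 or c + a > 1:
                raise ValueError(f"organ {self.name!r} extends outside the grid")


def default_organs() -> tuple[Organ, ...]:
    """Four ellipsoids standing in for body outline, liver, stomach and lung.

    The body is a torso-like slab spanning the axial (z) extent and most of
    the in-plane crop, as in clinical abdominal scans cropped to the patient.
    """
    return (
        Organ((0.50, 0.50, 0.50), (0.50, 0.46, 0.44), 40.0, "body", exponent=4.0),
        Organ((0.58, 0.42, 0.36), (0.22, 0.20, 0.18), 90.0, "liver"),
        Organ((0.62, 0.44, 0.68), (0.14, 0.13, 0.12), -30.0, "stomach"),
        Organ((0.24, 0.52, 0.50), (0.16, 0.19, 0.17), -700.0, "lung"),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic 4D series.

    Tissue carries spatially correlated intensity texture (``texture_sigma_hu``
    at correlation length ``texture_corr`` voxels), standing in for vessels and
    parenchymal structure — the image content that makes dense registration
    well-posed inside otherwise uniform organs.  White acquisition noise
    (``noise_sigma``) covers the whole field of view.  Motion is confined to
    the patient: the smooth random field is attenuated by a blurred body mask
    so the surrounding air is static, as in real respiratory series.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    organs: tuple[Organ, ...] = field(default_factory=default_organs)
    background_hu: float = -1000.0
    noise_sigma: float = 15.0  # white acquisition noise, pseudo-HU
    texture_sigma_hu: float = 150.0  # fat/muscle/parenchyma mottle amplitude
    texture_corr: float = 2.0  # texture correlation length, voxels
    n_focal: int = 40  # vessel/gas-like focal features inside the body
    focal_hu: tuple[float, float] = (200.0, 700.0)  # focal |contrast| range
    focal_radius: tuple[float, float] = (0.8, 2.5)  # focal radius range, voxels
    psf_sigma: float = 1.0  # scanner PSF + resampling blur, voxels
    n_phases: int = 11  # 11 for 4D-CT-like series, 10 for DIRLAB/CBCT-like
    max_displacement: float = 5.0  # voxels, at the peak phase
    smoothness_sigma: float = 8.0  # voxels, Gaussian width of the motion field
    body_taper: float = 2.0  # voxels, blur of the body mask confining motion
    window: IntensityWindow = field(default_factory=lambda: IntensityWindow(-1000.0, 1000.0))
    seed: int = 0
    cbct_like: bool = False  # extra noise + streak pattern, documented non-physical

    def __post_init__(self):
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")
        if self.smoothness_sigma <= 0:
            raise ValueError("smoothness_sigma must be > 0")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")


def random_smooth_dvf(shape, max_displacement: float, smoothness_sigma: float,
                      seed: int) -> np.ndarray:
    """Gaussian-smoothed white-noise vector field, rescaled to a peak magnitude.

    Each of the three components is white noise convolved with an isotropic
    Gaussian of width ``smoothness_sigma``; the whole field is then rescaled so
    the maximum per-voxel displacement norm equals ``max_displacement`` exactly.
    """
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((3,) + shape)
    smooth = np.stack([ndimage.gaussian_filter(raw[d], smoothness_sigma) for d in range(3)])
    if max_displacement == 0:
        return np.zeros_like(smooth)
    mags = np.sqrt((smooth ** 2).sum(axis=0))
    peak = mags.max()
    if peak == 0:
        return smooth
    return smooth * (max_displacement / peak)


def phase_amplitudes(n_phases: int) -> np.ndarray:
    """Sinusoidal amplitude per phase: 0 at phase 0, exactly 1 at the peak."""
    k = np.arange(n_phases)
    amps = np.sin(np.pi * k / (n_phases - 1))
    return amps / amps.max()


def _paint(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Base pseudo-HU volume and integer organ labels (painter's order)."""
    shape = spec.grid_shape
    grids = np.indices(shape, dtype=np.float64)
    hu = np.full(shape, spec.background_hu)
    labels = np.zeros(shape, dtype=np.int16)
    for i, organ in enumerate(spec.organs, start=1):
        dist = np.zeros(shape)
        for ax in range(3):
            c = organ.center[ax] * (shape[ax] - 1)
            a = max(organ.semiaxes[ax] * shape[ax], 1e-9)
            dist += np.abs((grids[ax] - c) / a) ** organ.exponent
        inside = dist <= 1.0
        hu[inside] = organ.hu
        labels[inside] = i
    return hu, labels


@dataclass
class Phantom4D:
    """One synthetic subject: phase volumes, ground-truth fields, labels."""

    volumes: list  # list[Volume], normalized intensities
    fields: list  # list[np.ndarray], (3, D, H, W); fields[0] is all zeros
    labels: list  # list[np.ndarray] integer organ masks per phase
    spec: PhantomSpec

    @property
    def n_phases(self) -> int:
        return len(self.volumes)


def make_phantom(spec: PhantomSpec) -> Phantom4D:
    """Build the full 4D series from a spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    hu, labels0 = _paint(spec)
    body = labels0 > 0
    if spec.texture_sigma_hu > 0:
        # correlated fat/muscle/parenchyma mottle inside the body
        tex = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape),
                                      spec.texture_corr)
        tex *= spec.texture_sigma_hu / max(tex.std(), 1e-12)
        hu = hu + tex * body
    if spec.n_focal > 0 and body.any():
        # vessel / gas-pocket / calcification-like focal features
        grids = np.indices(spec.grid_shape, dtype=np.float64)
        body_idx = np.argwhere(body)
        centers = body_idx[rng.integers(0, len(body_idx), spec.n_focal)]
        for c in centers:
            r = rng.uniform(*spec.focal_radius)
            amp = rng.choice((-1.0, 1.0)) * rng.uniform(*spec.focal_hu)
            d2 = sum((grids[ax] - c[ax]) ** 2 for ax in range(3))
            hu = hu + amp * np.exp(-d2 / (2.0 * r * r)) * body
    if spec.psf_sigma > 0:
        # partial-volume / resampling blur: a resampled CT is band-limited
        hu = ndimage.gaussian_filter(hu, spec.psf_sigma)
    noise_sigma = spec.noise_sigma * (2.5 if spec.cbct_like else 1.0)
    if noise_sigma > 0:
        hu = hu + rng.normal(0.0, noise_sigma, size=spec.grid_shape)
    if spec.cbct_like:
        # crude streak-like pattern along x; a stand-in for CBCT artifacts,
        # not a reconstruction simulation
        x = np.arange(spec.grid_shape[2])
        streaks = spec.noise_sigma * np.sin(2 * np.pi * x / 7.0 + rng.uniform(0, 2 * np.pi))
        hu = hu + streaks[None, None, :]
    base = Volume(data=spec.window.normalize(hu), spacing=(1.0, 1.0, 1.0),
                  window=spec.window)
    motion = random_smooth_dvf(spec.grid_shape, spec.max_displacement,
                               spec.smoothness_sigma, seed=spec.seed + 1)
    # confine motion to the patient: air is static in a respiratory series
    envelope = ndimage.gaussian_filter(body.astype(np.float64), spec.body_taper)
    peak = envelope.max()
    if peak > 0:
        envelope /= peak
    motion = motion * envelope[None]
    mags = np.sqrt((motion ** 2).sum(axis=0))
    if spec.max_displacement > 0 and mags.max() > 0:
        motion *= spec.max_displacement / mags.max()
    amps = phase_amplitudes(spec.n_phases)
    volumes, fields, labels = [], [], []
    for k in range(spec.n_phases):
        phi_k = amps[k] * motion
        fields.append(phi_k)
        if amps[k] == 0.0:
            volumes.append(base)
            labels.append(labels0)
        else:
            volumes.append(warp_volume(base, phi_k))
            labels.append(warp_nearest(labels0, phi_k))
    return Phantom4D(volumes=volumes, fields=fields, labels=labels, spec=spec)


@dataclass
class EvalPair:
    """A (fixed, moving) pair with exact ground truth for evaluation.

    The moving image is the reference phase (phase 0) and the fixed image is
    phase ``k``; ``true_field`` is the field whose backward warp carries the
    moving image exactly onto the fixed one.
    """

    fixed: Volume
    moving: Volume
    true_field: np.ndarray
    fixed_labels: np.ndarray
    moving_labels: np.ndarray
    phase: int


def training_pairs(phantoms, protocol_mode: str = "all_ordered_pairs"):
    """(fixed, moving) Volume pairs across phases of one or more phantoms."""
    if isinstance(phantoms, Phantom4D):
        phantoms = [phantoms]
    pairs = []
    for ph in phantoms:
        n = ph.n_phases
        for m in range(n):
            for f in range(n):
                if m == f:
                    continue
                if protocol_mode == "fixed_reference" and f != 0:
                    continue
                pairs.append((ph.volumes[f], ph.volumes[m]))
    return pairs


def evaluation_pairs(phantom: Phantom4D, phases=None) -> list[EvalPair]:
    """Ground-truth evaluation pairs: register phase 0 onto each later phase."""
    if phases is None:
        phases = range(1, phantom.n_phases)
    out = []
    for k in phases:
        out.append(EvalPair(
            fixed=phantom.volumes[k],
            moving=phantom.volumes[0],
            true_field=phantom.fields[k],
            fixed_labels=phantom.labels[k],
            moving_labels=phantom.labels[0],
            phase=k,
        ))
    return out
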