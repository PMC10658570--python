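"""DVF-prediction networks: full-resolution residual subnetworks and the
three-stage recursive cascade.

Each registration subnetwork maps a 2-channel stack (fixed image, current
moving image) to a 3-component displacement field at the same resolution.  Its
body is a full-resolution residual network: a *residual stream* that stays at
full resolution (carrying boundary detail) and a *pooling stream* that runs
through an encoder-decoder ladder of full-resolution residual units (FRRUs),
doubling channels at each pooling level up to a per-subnetwork cap.  An FRRU
updates both streams,

    x_n = x_{n-1} + Fr(x_{n-1}, y_{n-1})     (residual stream, full res)
    y_n = Fp(x_{n-1}, y_{n-1})               (pooling stream, pooled res)

where Fp max-pools the residual stream to the unit's level, concatenates it
with the pooling stream and applies two 3x3x3 conv + BN + ReLU layers, and Fr
projects that output back to the residual stream's channel count with a 1x1x1
convolution and nearest-neighbour unpooling.

The three cascades deepen progressively — (5 FRRUs, cap 128), (7, 256),
(9, 512) with base 32 channels — so the first learns coarse global motion and
the last refines it.  The final 3x3x3 convolution of every subnetwork is
zero-initialized, so an untrained cascade is exactly the identity transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import BatchNorm3d, Conv3d, Module, Tensor
from .volumes_io import Volume
from .warp import ShapeMismatchError, compose, warp_scalar


@dataclass(frozen=True)
class SubnetworkSpec:
    """Architecture descriptor for one cascade's DVF-prediction network."""

    n_frru_blocks: int
    max_channels: int
    base_channels: int = 32
    n_input_channels: int = 2

    def __post_init__(self):
        if self.n_frru_blocks < 1:
            raise ValueError("n_frru_blocks must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.max_channels < self.base_channels:
            raise ValueError("max_channels must be >= base_channels")


#: the three production cascades, shallowest (global motion) to deepest (refinement)
PAPER_SPECS: tuple[SubnetworkSpec, ...] = (
    SubnetworkSpec(5, 128),
    SubnetworkSpec(7, 256),
    SubnetworkSpec(9, 512),
)

#: small cascades for CPU-scale experiments on 16^3..32^3 grids
REDUCED_SPECS: tuple[SubnetworkSpec, ...] = (
    SubnetworkSpec(3, 16, base_channels=8),
    SubnetworkSpec(5, 32, base_channels=8),
    SubnetworkSpec(7, 64, base_channels=8),
)


def ladder_levels(n_blocks: int) -> list[int]:
    """Pooling level of each FRRU: a symmetric encoder-decoder ladder.

    Odd counts give a single deepest unit (e.g. 5 -> [1,2,3,2,1]); even counts
    repeat the deepest level once (e.g. 4 -> [1,2,2,1]).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    depth = (n_blocks + 1) // 2
    down = list(range(1, depth + 1))
    up = list(range(depth, 0, -1))
    return down + up[1:] if n_blocks % 2 else down + up


class ResidualUnit(Module):
    """Plain full-resolution residual unit: two conv+BN layers with a skip."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.conv1 = Conv3d(channels, channels, 3, rng, dtype)
        self.bn1 = BatchNorm3d(channels, dtype)
        self.conv2 = Conv3d(channels, channels, 3, rng, dtype)
        self.bn2 = BatchNorm3d(channels, dtype)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        return ad.relu(x + h)


class FRRU(Module):
    """Full-resolution residual unit coupling the two streams at one level."""

    def __init__(self, base_channels: int, y_in_channels: int, out_channels: int,
                 level: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.level = level
        self.conv1 = Conv3d(base_channels + y_in_channels, out_channels, 3, rng, dtype)
        self.bn1 = BatchNorm3d(out_channels, dtype)
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng, dtype)
        self.bn2 = BatchNorm3d(out_channels, dtype)
        # residual-branch projection back to the full-resolution stream
        self.project = Conv3d(out_channels, base_channels, 1, rng, dtype)

    def forward(self, x: Tensor, y: Tensor) -> tuple[Tensor, Tensor]:
        xp = x
        for _ in range(self.level):
            xp = ad.maxpool2(xp)
        h = ad.concat([xp, y], axis=0)
        h = ad.relu(self.bn1(self.conv1(h)))
        h = ad.relu(self.bn2(self.conv2(h)))
        y_next = h
        r = self.project(h)
        for _ in range(self.level):
            r = ad.upsample2(r)
        return x + r, y_next


class FRRSubnetwork(Module):
    """One cascade's DVF predictor: (2, D, H, W) stack -> (3, D, H, W) field."""

    def __init__(self, spec: SubnetworkSpec, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.spec = spec
        self.levels = ladder_levels(spec.n_frru_blocks)
        base = spec.base_channels

        def ch(level: int) -> int:
            return min(base * 2 ** level, spec.max_channels)

        self.conv_in = Conv3d(spec.n_input_channels, base, 3, rng, dtype)
        self.bn_in = BatchNorm3d(base, dtype)
        self.entry_rus = [ResidualUnit(base, rng, dtype) for _ in range(2)]
        frrus = []
        y_ch = base  # the pooling stream starts as the pooled residual stream
        for level in self.levels:
            frrus.append(FRRU(base, y_ch, ch(level), level, rng, dtype))
            y_ch = ch(level)
        self.frrus = frrus
        self.exit_rus = [ResidualUnit(base, rng, dtype) for _ in range(2)]
        # zero-initialized head: the untrained subnetwork predicts phi == 0
        self.head = Conv3d(base, 3, 3, rng, dtype, zero_init=True)

    @property
    def max_level(self) -> int:
        return max(self.levels)

    def _check_grid(self, shape: tuple[int, ...]) -> None:
        f = 2 ** self.max_level
        if any(s % f for s in shape):
            raise ShapeMismatchError(
                f"grid {shape} not divisible by 2^{self.max_level} required by "
                f"a {self.spec.n_frru_blocks}-FRRU ladder")

    def forward(self, stacked: Tensor) -> Tensor:
        if stacked.data.ndim != 4 or stacked.data.shape[0] != self.spec.n_input_channels:
            raise ShapeMismatchError(
                f"expected ({self.spec.n_input_channels}, D, H, W) input, got {stacked.data.shape}")
        self._check_grid(stacked.data.shape[1:])
        x = ad.relu(self.bn_in(self.conv_in(stacked)))
        for ru in self.entry_rus:
            x = ru(x)
        y = ad.maxpool2(x)
        cur = 1
        for frru in self.frrus:
            while cur < frru.level:
                y = ad.maxpool2(y)
                cur += 1
            while cur > frru.level:
                y = ad.upsample2(y)
                cur -= 1
            x, y = frru(x, y)
        for ru in self.exit_rus:
            x = ru(x)
        return self.head(x)


def build_subnetwork(spec: SubnetworkSpec, seed: int = 0, dtype=np.float64) -> FRRSubnetwork:
    """Instantiate one DVF-prediction subnetwork with He-initialized weights."""
    rng = np.random.default_rng(seed)
    return FRRSubnetwork(spec, rng, dtype)


def _as_array(x, dtype) -> np.ndarray:
    if isinstance(x, Volume):
        x = x.data
    if isinstance(x, Tensor):
        return x.data.astype(dtype, copy=False)
    return np.asarray(x, dtype=dtype)


def predict_dvf(subnetwork: FRRSubnetwork, fixed, current):
    """Stack (fixed, current) as channels and predict the displacement field."""
    if isinstance(fixed, Tensor) or isinstance(current, Tensor):
        f = fixed if isinstance(fixed, Tensor) else Tensor(_as_array(fixed, np.float64))
        c = current if isinstance(current, Tensor) else Tensor(_as_array(current, np.float64))
        if f.data.shape != c.data.shape:
            raise ShapeMismatchError(f"fixed {f.data.shape} != current {c.data.shape}")
        sp = (1,) + f.data.shape
        return subnetwork(ad.concat([ad.reshape(f, sp), ad.reshape(c, sp)], axis=0))
    dtype = subnetwork.head.weight.data.dtype
    f = _as_array(fixed, dtype)
    c = _as_array(current, dtype)
    if f.shape != c.shape:
        raise ShapeMismatchError(f"fixed {f.shape} != current {c.shape}")
    with ad.no_grad():
        out = subnetwork(Tensor(np.stack([f, c])))
    return out.data


@dataclass
class CascadeOutput:
    """Per-cascade fields and warped images plus the composed field.

    Entries are autodiff Tensors; ``*_np`` accessors return plain arrays.
    """

    dvfs: list
    warped: list
    composed: object

    @property
    def dvfs_np(self) -> list[np.ndarray]:
        return [d.data if isinstance(d, Tensor) else np.asarray(d) for d in self.dvfs]

    @property
    def warped_np(self) -> list[np.ndarray]:
        return [w.data if isinstance(w, Tensor) else np.asarray(w) for w in self.warped]

    @property
    def composed_np(self) -> np.ndarray:
        c = self.composed
        return c.data if isinstance(c, Tensor) else np.asarray(c)

    @property
    def final_warped_np(self) -> np.ndarray:
        return self.warped_np[-1]


class RecursiveCascade(Module):
    """An ordered chain of registration subnetworks applied recursively."""

    def __init__(self, subnets: list[FRRSubnetwork], allow_custom: bool = False):
        super().__init__()
        self.subnets = list(subnets)
        self.allow_custom = allow_custom

    @property
    def specs(self) -> tuple[SubnetworkSpec, ...]:
        return tuple(s.spec for s in self.subnets)

    def forward(self, fixed, moving) -> CascadeOutput:
        return cascade_forward(self, fixed, moving)


def build_cascade(specs=PAPER_SPECS, seed: int = 0, dtype=np.float64,
                  allow_custom: bool = False) -> RecursiveCascade:
    """Build the recursive cascade (default: the three production specs).

    Non-default spec lists (reduced desk-scale cascades, the 1- and 2-cascade
    ablation variants) require ``allow_custom=True``.
    """
    specs = tuple(specs)
    if specs != PAPER_SPECS and not allow_custom:
        raise ValueError(
            "non-standard cascade configuration; pass allow_custom=True for "
            "reduced or ablation variants")
    seq = np.random.SeedSequence(seed)
    subnets = [FRRSubnetwork(spec, np.random.default_rng(child), dtype)
               for spec, child in zip(specs, seq.spawn(len(specs)))]
    return RecursiveCascade(subnets, allow_custom=allow_custom)


def cascade_forward(cascade: RecursiveCascade, fixed, moving) -> CascadeOutput:
    """Run the full recursive registration chain.

    phi_n is predicted from (fixed, warped_{n-1}) and applied to warped_{n-1};
    the composed field warps the original moving image to the final output in
    a single interpolation step.  The whole chain is differentiable.
    """
    if len(cascade.subnets) != 3 and not cascade.allow_custom:
        raise ValueError(
            f"expected exactly 3 cascades, got {len(cascade.subnets)}; "
            "build with allow_custom=True to override")
    dtype = cascade.subnets[0].head.weight.data.dtype
    f = fixed if isinstance(fixed, Tensor) else Tensor(_as_array(fixed, dtype))
    current = moving if isinstance(moving, Tensor) else Tensor(_as_array(moving, dtype))
    if f.data.shape != current.data.shape:
        raise ShapeMismatchError(f"fixed {f.data.shape} != moving {current.data.shape}")
    dvfs, warped = [], []
    for net in cascade.subnets:
        phi = predict_dvf(net, f, current)
        current = warp_scalar(current, phi)
        dvfs.append(phi)
        warped.append(current)
    composed = dvfs[0]
    for phi in dvfs[1:]:
        composed = compose(composed, phi)
    return CascadeOutput(dvfs=dvfs, warped=warped, composed=composed)


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(cascade: RecursiveCascade, path, seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Persist cascade weights, BN statistics, specs and the build seed."""
    import json

    arrays = {}
    for i, net in enumerate(cascade.subnets):
        for name, arr in net.state_arrays().items():
            arrays[f"net{i}/{name}"] = arr
    meta = {
        "specs": [[s.n_frru_blocks, s.max_channels, s.base_channels, s.n_input_channels]
                  for s in cascade.specs],
        "dtype": str(cascade.subnets[0].head.weight.data.dtype),
        "seed": seed,
        "allow_custom": cascade.allow_custom,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[RecursiveCascade, dict]:
    """Rebuild a cascade from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    specs = tuple(SubnetworkSpec(*row) for row in meta["specs"])
    cascade = build_cascade(specs, seed=meta["seed"] or 0, dtype=np.dtype(meta["dtype"]),
                            allow_custom=True if meta["allow_custom"] or specs != PAPER_SPECS else False)
    for i, net in enumerate(cascade.subnets):
        prefix = f"net{i}/"
        net.load_state_arrays({k[len(prefix):]: v for k, v in arrays.items()
                               if k.startswith(prefix)})
    return cascade, meta
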