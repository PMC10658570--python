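"""Pair enumeration, the optimization loop and the learning-rate schedule.

The production schedule runs Adam for 9e4 iterations at batch size 1, starting
from lr 1e-4 and halving it after 3e4 and again after 6e4 iterations.  Pairs
are sampled uniformly with replacement with a seeded generator, so identical
(config, seed) runs reproduce identical loss histories.

``desk_config`` provides the CPU-scale profile used throughout the test suite:
the same schedule shape (two halvings at 1/3 and 2/3 of the run) with a higher
initial rate of 1e-3, appropriate for the reduced cascades on 16^3 grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam
from .frrnet import RecursiveCascade, cascade_forward, save_checkpoint
from .losses import LossConfig, similarity_loss, smoothness_loss, total_loss
from .volumes_io import Volume


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite; carries the offending iteration and pair."""

    def __init__(self, iteration: int, pair_index: int, similarity: float, smoothness: float):
        super().__init__(
            f"non-finite loss at iteration {iteration} (pair {pair_index}): "
            f"similarity={similarity}, smoothness={smoothness}")
        self.iteration = iteration
        self.pair_index = pair_index
        self.similarity = similarity
        self.smoothness = smoothness


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults are the production values)."""

    iterations: int = 90_000
    batch_size: int = 1
    lr_initial: float = 1e-4
    lr_drop_iters: tuple[int, ...] = (30_000, 60_000)
    lr_factor: float = 0.5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.iterations <= 0:
            raise ValueError("iterations must be > 0")
        if not 0 < self.lr_factor <= 1:
            raise ValueError("lr_factor must be in (0, 1]")
        if any(b <= a for a, b in zip(self.lr_drop_iters, self.lr_drop_iters[1:])):
            raise ValueError("lr_drop_iters must be strictly increasing")


def desk_config(iterations: int = 1000, seed: int = 0,
                loss: LossConfig | None = None) -> TrainConfig:
    """CPU-scale training profile: lr 1e-3, halved at 1/3 and 2/3 of the run."""
    return TrainConfig(
        iterations=iterations,
        lr_initial=1e-3,
        lr_drop_iters=(max(1, iterations // 3), max(2, 2 * iterations // 3)),
        lr_factor=0.5,
        seed=seed,
        loss=loss or LossConfig(),
    )


@dataclass(frozen=True)
class PhasePairProtocol:
    """How (moving, fixed) phase pairs are drawn from a 4D series."""

    mode: str  # "all_ordered_pairs" | "fixed_reference"
    n_phases: int
    reference_phase: int = 0

    def __post_init__(self):
        if self.mode not in ("all_ordered_pairs", "fixed_reference"):
            raise ValueError(f"unknown pair mode {self.mode!r}")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")


def enumerate_pairs(n_subjects: int, protocol: PhasePairProtocol):
    """List (subject, moving_phase, fixed_phase) triples under a protocol.

    ``all_ordered_pairs`` yields every ordered phase pair per subject
    (n_phases * (n_phases - 1) each); ``fixed_reference`` registers every
    non-reference phase to the reference phase.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    pairs = []
    if protocol.mode == "all_ordered_pairs":
        for s in range(n_subjects):
            for m in range(protocol.n_phases):
                for f in range(protocol.n_phases):
                    if m != f:
                        pairs.append((s, m, f))
    else:
        ref = protocol.reference_phase
        if not 0 <= ref < protocol.n_phases:
            raise ValueError(
                f"reference phase {ref} outside 0..{protocol.n_phases - 1}")
        for s in range(n_subjects):
            for m in range(protocol.n_phases):
                if m != ref:
                    pairs.append((s, m, ref))
    return pairs


def lr_schedule(iteration: int, cfg: TrainConfig) -> float:
    """Piecewise-constant learning rate: initial value, scaled after each drop."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    lr = cfg.lr_initial
    for drop in cfg.lr_drop_iters:
        if iteration > drop:
            lr *= cfg.lr_factor
    return lr


def _pair_arrays(pair) -> tuple[np.ndarray, np.ndarray]:
    f, m = pair[0], pair[1]
    f = f.data if isinstance(f, Volume) else np.asarray(f)
    m = m.data if isinstance(m, Volume) else np.asarray(m)
    return f, m


def train(cascade: RecursiveCascade, pairs, cfg: TrainConfig,
          checkpoint_every: int | None = None, checkpoint_dir=None):
    """Optimize the cascade on (fixed, moving) pairs; returns (cascade, history).

    Each iteration samples one pair uniformly (seeded), runs the full recursive
    forward pass, evaluates the unsupervised loss and applies one Adam step at
    the scheduled learning rate.  The history is a DataFrame with one row per
    iteration (iteration, pair, similarity, smoothness, total, lr).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one training pair is required")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(cascade.parameters(), lr=cfg.lr_initial,
               betas=cfg.adam_betas, eps=cfg.adam_eps)
    cascade.train()
    hist = {"iteration": [], "pair": [], "similarity": [], "smoothness": [],
            "total": [], "lr": []}
    for it in range(cfg.iterations):
        k = int(rng.integers(len(pairs)))
        f_arr, m_arr = _pair_arrays(pairs[k])
        out = cascade_forward(cascade, f_arr, m_arr)
        loss = total_loss(f_arr, out.warped[-1], out, cfg.loss)
        sim_val = similarity_loss(f_arr, out.warped_np[-1])
        smooth_val = smoothness_loss(out.dvfs_np[-1], cfg.loss.reduction)
        if not np.isfinite(loss.item()):
            raise TrainingDivergedError(it, k, sim_val, smooth_val)
        lr = lr_schedule(it, cfg)
        opt.zero_grad()
        loss.backward()
        opt.step(lr)
        hist["iteration"].append(it)
        hist["pair"].append(k)
        hist["similarity"].append(sim_val)
        hist["smoothness"].append(smooth_val)
        hist["total"].append(loss.item())
        hist["lr"].append(lr)
        if checkpoint_every and checkpoint_dir is not None and (it + 1) % checkpoint_every == 0:
            save_checkpoint(cascade, f"{checkpoint_dir}/checkpoint_{it + 1:06d}.npz",
                            seed=cfg.seed)
    cascade.eval()
    return cascade, pd.DataFrame(hist)
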