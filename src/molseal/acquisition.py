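"""Acquisition: which generated compounds get oracle labels.

Strategies: ``random`` (baseline, also used whenever the surrogate is not
yet fitted), ``greedy`` (expected score), ``ucb`` (mean + beta*sd, the
greedy strategy being the beta=0 special case), and their MPO-distribution
counterparts ``mpo_greedy``/``mpo_ucb`` which rank by the Monte-Carlo mean
and sd of the composite desirability instead of the raw oracle prediction.
Raw strategies respect the oracle's direction (docking scores are
minimized); MPO strategies always maximize since desirability is in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import Molecule
from .scoring import MPOResult
from .surrogate import Prediction

__all__ = ["AcquisitionSpec", "AcquiredSplit", "priority", "select"]

STRATEGIES = ("random", "greedy", "ucb", "mpo_greedy", "mpo_ucb")


@dataclass
class AcquisitionSpec:
    strategy: str = "ucb"
    beta: float = 1.0
    direction: str = "maximize"

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown acquisition strategy {self.strategy!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be maximize or minimize")


@dataclass
class AcquiredSplit:
    acquired: list[Molecule]
    remainder: list[Molecule]


def priority(candidates: Sequence[Molecule],
             predictions: Sequence[Prediction | MPOResult] | None,
             spec: AcquisitionSpec,
             rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Per-candidate acquisition priority (higher = acquired first)."""
    n = len(candidates)
    if spec.strategy == "random":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        return rng.random(n)
    if predictions is None or len(predictions) != n:
        raise ValueError("predictions must align with candidates")
    if spec.strategy.startswith("mpo_"):
        mean = np.array([p.mpo_mean for p in predictions])
        sd = np.array([p.mpo_sd for p in predictions])
        sign = 1.0  # desirability is always maximized
        kind = spec.strategy.removeprefix("mpo_")
    else:
        mean = np.array([p.mean for p in predictions])
        sd = np.array([p.sd for p in predictions])
        sign = 1.0 if spec.direction == "maximize" else -1.0
        kind = spec.strategy
    if kind == "greedy":
        return sign * mean
    # ucb: optimism in the direction of optimization
    if np.any(~np.isfinite(sd)):
        raise ValueError("UCB requires finite uncertainties")
    return sign * mean + spec.beta * sd


def select(candidates: Sequence[Molecule], priorities: np.ndarray,
           k: int) -> AcquiredSplit:
    """Top-k by priority; ties broken by generation order (stable)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    priorities = np.asarray(priorities, dtype=float)
    if len(priorities) != len(candidates):
        raise ValueError("priorities must align with candidates")
    if k >= len(candidates):
        return AcquiredSplit(acquired=list(candidates), remainder=[])
    gen = np.array([m.gen_index for m in candidates])
    order = np.lexsort((gen, -priorities))
    take = set(order[:k].tolist())
    acquired = [m for i, m in enumerate(candidates) if i in take]
    remainder = [m for i, m in enumerate(candidates) if i not in take]
    return AcquiredSplit(acquired=acquired, remainder=remainder)
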