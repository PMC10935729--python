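"""Policy update machinery.

The agent is regressed toward the augmented likelihood

    log P_aug(x) = log P_prior(x) + alpha * MPO(x)

by minimizing the weighted squared difference between augmented and agent
likelihood, batch-averaged (the wDAP loss). Per-molecule weights let the
update trust oracle-labelled compounds fully (weight 1) while down-weighting
or ignoring surrogate-predicted ones. Two REINVENT-style memory mechanisms
modify the reward stream: a Murcko-scaffold diversity filter that zeroes the
reward of over-represented scaffolds, and an experience-replay buffer of the
top-scoring SMILES re-injected into each update batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import Molecule, ScaffoldKey, murcko_scaffold
from .generator import Adam

__all__ = [
    "RLParams",
    "WeightScheme",
    "DiversityFilter",
    "ReplayBuffer",
    "augmented_loglik",
    "assign_weights",
    "wdap_loss",
    "rl_step",
]


@dataclass
class RLParams:
    alpha: float = 128.0
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    # Moving term of the squared difference: "agent" (default) regresses the
    # agent likelihood onto the augmented target; "prior" is the switchable
    # alternative reading and is not exercised by the shipped experiments.
    difference: str = "agent"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.difference not in ("agent", "prior"):
            raise ValueError("difference must be 'agent' or 'prior'")


@dataclass
class WeightScheme:
    """Per-molecule loss weights; oracle-labelled compounds always weigh 1.

    kinds: full_belief (surrogate weight 1), constant (a fixed value such as
    0.75 or 0.25), uncertainty_gate (1 if surrogate sd <= threshold else 0,
    thresholds 0.025 or 0.05 in practice), zero_surrogate (0 — the RL update
    sees only oracle labels).
    """

    kind: str = "full_belief"
    constant_value: float = 0.5
    uncertainty_threshold: float = 0.05

    def __post_init__(self):
        if self.kind not in ("full_belief", "constant", "uncertainty_gate",
                             "zero_surrogate"):
            raise ValueError(f"unknown weight scheme {self.kind!r}")
        if not 0.0 <= self.constant_value <= 1.0:
            raise ValueError("constant_value must lie in [0, 1]")


def augmented_loglik(logp_prior, mpo, params: RLParams):
    """log P_prior + alpha * MPO; accepts scalars or arrays."""
    return np.asarray(logp_prior) + params.alpha * np.asarray(mpo)


def assign_weights(label_sources: Sequence[str], scheme: WeightScheme,
                   uncertainties: Sequence[float] | None = None) -> np.ndarray:
    """Map per-compound label sources ('oracle'/'surrogate') to loss weights."""
    n = len(label_sources)
    w = np.ones(n)
    surr = np.array([s == "surrogate" for s in label_sources])
    if scheme.kind == "full_belief":
        pass
    elif scheme.kind == "constant":
        w[surr] = scheme.constant_value
    elif scheme.kind == "zero_surrogate":
        w[surr] = 0.0
    else:  # uncertainty_gate
        if uncertainties is None:
            raise ValueError("uncertainty_gate requires surrogate uncertainties")
        sd = np.asarray(uncertainties, dtype=float)
        if len(sd) != n:
            raise ValueError("uncertainties must align with label sources")
        w[surr] = (sd[surr] <= scheme.uncertainty_threshold).astype(float)
    return w


def wdap_loss(logp_aug: np.ndarray, logp_agent: np.ndarray,
              weights: np.ndarray) -> float:
    """(1/|X|) * sum_x w(x) (logp_aug(x) − logp_agent(x))^2."""
    logp_aug, logp_agent, weights = map(np.asarray, (logp_aug, logp_agent, weights))
    if not len(logp_aug) == len(logp_agent) == len(weights) >= 1:
        raise ValueError("loss inputs must be equal-length, non-empty vectors")
    diff = logp_aug - logp_agent
    return float(np.mean(weights * diff * diff))


@dataclass
class DiversityFilter:
    """Scaffold-bucket reward memory.

    Compounds scoring >= min_score are recorded under their Murcko scaffold;
    once a scaffold's bucket holds bucket_size compounds, further compounds
    of that scaffold have their score set to zero. Scores below min_score
    pass through unchanged and unrecorded.
    """

    bucket_size: int = 100
    min_score: float = 0.2
    counts: dict[ScaffoldKey, int] = field(default_factory=dict)

    def __call__(self, mol: Molecule, score: float) -> float:
        if not mol.valid:
            return score
        if score < self.min_score:
            return score
        key = murcko_scaffold(mol)
        seen = self.counts.get(key, 0)
        if seen >= self.bucket_size:
            return 0.0
        self.counts[key] = seen + 1
        return score


@dataclass
class ReplayEntry:
    canonical: str
    raw: str
    handle: object
    score: float


class ReplayBuffer:
    """Top-``capacity`` unique SMILES by score; sampled without replacement."""

    def __init__(self, capacity: int = 100, sample_size: int = 10):
        self.capacity = capacity
        self.sample_size = sample_size
        self._entries: dict[str, ReplayEntry] = {}

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> list[ReplayEntry]:
        return sorted(self._entries.values(), key=lambda e: -e.score)

    def add(self, canonical: str, raw: str, handle, score: float) -> None:
        old = self._entries.get(canonical)
        if old is not None:
            if score > old.score:
                self._entries[canonical] = ReplayEntry(canonical, raw, handle, score)
            return
        self._entries[canonical] = ReplayEntry(canonical, raw, handle, score)
        if len(self._entries) > self.capacity:
            worst = min(self._entries.values(), key=lambda e: e.score)
            del self._entries[worst.canonical]

    def sample(self, rng: np.random.Generator | int) -> list[ReplayEntry]:
        """min(sample_size, |buffer|) entries, uniformly without replacement."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        entries = self.entries
        if len(entries) <= self.sample_size:
            return list(entries)
        idx = rng.choice(len(entries), size=self.sample_size, replace=False)
        return [entries[i] for i in idx]


def rl_step(agent, prior, handles: Sequence, mpo_scores: Sequence[float],
            weights: Sequence[float], params: RLParams, optimizer: Adam,
            replay: ReplayBuffer | None = None,
            replay_rng: np.random.Generator | None = None) -> float:
    """One wDAP gradient step on the agent; the prior is never touched.

    Replay entries, if any, are appended to the batch with weight 1 (they
    were curated as genuine oracle-scored top compounds). Returns the loss
    value before the step.
    """
    handles = list(handles)
    mpo = np.asarray(mpo_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any((mpo < 0) | (mpo > 1)):
        raise ValueError("MPO scores must lie in [0, 1]")
    if replay is not None and len(replay):
        extra = replay.sample(replay_rng if replay_rng is not None
                              else np.random.default_rng())
        handles = handles + [e.handle for e in extra]
        mpo = np.concatenate([mpo, [e.score for e in extra]])
        w = np.concatenate([w, np.ones(len(extra))])
    logp_agent = agent.loglik_handles(handles)
    logp_prior = prior.loglik_handles(handles)
    aug = augmented_loglik(logp_prior, mpo, params)
    loss = wdap_loss(aug, logp_agent, w)
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite wDAP loss: {loss}")
    n = len(handles)
    if params.difference == "agent":
        coeffs = 2.0 * w * (logp_agent - aug) / n
        if np.any(coeffs != 0.0):
            agent.grad_step(handles, coeffs, optimizer)
    # difference == "prior": the squared difference does not involve the
    # agent likelihood, so there is no gradient to apply.
    return loss
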