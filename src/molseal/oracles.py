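"""Synthetic oracles and fixture data.

The expensive scoring functions of a real campaign (pharmacophore overlay,
docking) are replaced by deterministic desk-scale stand-ins defined on a
fixed six-descriptor profile (MW, logP, ring count, HBD, HBA, TPSA):

* ``PseudoROCS`` — a similarity-like score in [0, 1], a Gaussian kernel
  exp(−d²/2b²) of the z-scaled descriptor distance to a target profile
  (hit threshold 0.6, maximize);
* ``PseudoDock`` — an affinity-like score, a second kernel affinely mapped
  onto [−13.5, −4.0] kcal/mol (hit threshold −11.4, minimize).

Both are smooth functions of the same descriptor space the surrogate sees,
so active-learning acceleration is demonstrable at desk scale; a harder
variant mixes in a complexity term hidden from the default featurization.
A Gaussian-noise wrapper supports oracle-noise robustness experiments, and
``generate_corpus`` assembles a drug-like SMILES fixture corpus from a
fragment grammar (ring systems, linkers, substituents).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import GraphDescriptors

from .chem import Molecule, canonicalize, _descriptor_row

__all__ = [
    "Oracle",
    "PseudoROCS",
    "PseudoDock",
    "NoisyOracle",
    "ExternalOracleCommand",
    "generate_corpus",
    "corpus_stats",
    "make_oracle",
]

# Fixed reference scale for the oracle descriptor space (MW, logP, rings,
# HBD, HBA, TPSA): roughly the spread of the fixture fragment space.
_REF_MEAN = np.array([300.0, 2.5, 2.5, 1.0, 3.0, 60.0])
_REF_SD = np.array([90.0, 1.5, 1.0, 1.0, 1.5, 30.0])


class Oracle:
    """Ground-truth scorer with call accounting and a hit test."""

    name = "oracle"
    direction = "maximize"
    hit_threshold = 0.0

    def __init__(self):
        self.n_calls = 0

    def _score(self, mol: Molecule) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, mol: Molecule) -> float:
        if not mol.valid:
            raise ValueError("oracles are never called on invalid molecules")
        self.n_calls += 1
        return self._score(mol)

    def score_many(self, mols: Sequence[Molecule]) -> np.ndarray:
        return np.array([self(m) for m in mols])

    def is_hit(self, value: float) -> bool:
        if self.direction == "maximize":
            return value >= self.hit_threshold
        return value <= self.hit_threshold

    def reset(self) -> None:
        self.n_calls = 0


def _oracle_z(mol: Molecule) -> np.ndarray:
    row, _ = _descriptor_row(mol.rdkit_mol(), "oracle")
    return (row - _REF_MEAN) / _REF_SD


class PseudoROCS(Oracle):
    """Similarity-like kernel oracle in [0, 1]; higher is better."""

    name = "pseudo_rocs"
    direction = "maximize"
    hit_threshold = 0.6

    def __init__(self, target: Sequence[float] = (360.0, 3.0, 3.0, 1.0, 4.0, 70.0),
                 bandwidth: float = 1.0, include_hidden: bool = False):
        super().__init__()
        self.target_z = (np.asarray(target, dtype=float) - _REF_MEAN) / _REF_SD
        self.bandwidth = bandwidth
        self.include_hidden = include_hidden

    def _score(self, mol: Molecule) -> float:
        d2 = float(np.sum((_oracle_z(mol) - self.target_z) ** 2))
        if self.include_hidden:
            # molecular-complexity term the default featurization does not see
            bertz = GraphDescriptors.BertzCT(mol.rdkit_mol())
            d2 += ((bertz - 800.0) / 400.0) ** 2
        return float(np.exp(-d2 / (2.0 * self.bandwidth ** 2)))


class PseudoDock(Oracle):
    """Affinity-like kernel oracle mapped onto [−13.5, −4.0]; lower is better.

    The target profile deliberately rewards larger, greasier, donor-rich
    compounds (MW 480, logP 4.5, HBD 4, TPSA 110) — emulating the
    well-known exploitability of docking scores by adding size and hydrogen
    bond donors, which is exactly why generative runs pair a docking
    objective with drug-likeness components and an HBD cap.
    """

    name = "pseudo_dock"
    direction = "minimize"
    hit_threshold = -11.4
    best, worst = -13.5, -4.0

    def __init__(self, target: Sequence[float] = (480.0, 4.5, 4.0, 4.0, 7.0, 110.0),
                 bandwidth: float = 3.0):
        super().__init__()
        self.target_z = (np.asarray(target, dtype=float) - _REF_MEAN) / _REF_SD
        self.bandwidth = bandwidth

    def kernel(self, mol: Molecule) -> float:
        d2 = float(np.sum((_oracle_z(mol) - self.target_z) ** 2))
        return float(np.exp(-d2 / (2.0 * self.bandwidth ** 2)))

    def _score(self, mol: Molecule) -> float:
        return self.worst + (self.best - self.worst) * self.kernel(mol)


class NoisyOracle(Oracle):
    """Base oracle plus additive Gaussian noise, reproducible per seed."""

    def __init__(self, base: Oracle, sd: float, seed: int = 0):
        if sd < 0:
            raise ValueError("noise sd must be >= 0")
        self.base = base
        self.sd = sd
        self.rng = np.random.default_rng(seed)
        self.name = base.name + "+noise"

    @property
    def direction(self):
        return self.base.direction

    @property
    def hit_threshold(self):
        return self.base.hit_threshold

    @property
    def n_calls(self):
        return self.base.n_calls

    def __call__(self, mol: Molecule) -> float:
        value = self.base(mol)
        if self.sd > 0:
            value += self.rng.normal(0.0, self.sd)
        return value

    def reset(self) -> None:
        self.base.reset()


@dataclass
class ExternalOracleCommand:
    """Declared adapter for wrapping an external scoring executable.

    ``command_template`` is formatted with an input SMILES file path;
    ``score_parser`` maps the process stdout to one float per molecule.
    Execution of external overlay/docking tools is out of scope and this
    interface is deliberately untested.
    """

    command_template: str
    score_parser: Callable[[str], "list[float]"]
    direction: str = "maximize"
    hit_threshold: float = 0.0


def make_oracle(name: str, noise_sd: float = 0.0, noise_seed: int = 0,
                **kwargs) -> Oracle:
    if name == "pseudo_rocs":
        oracle: Oracle = PseudoROCS(**kwargs)
    elif name == "pseudo_dock":
        oracle = PseudoDock(**kwargs)
    else:
        raise ValueError(f"unknown oracle {name!r}")
    if noise_sd > 0:
        oracle = NoisyOracle(oracle, noise_sd, seed=noise_seed)
    return oracle


# ---------------------------------------------------------------------------
# Fixture corpus: fragment grammar of ring systems, linkers and substituents.

_RINGS = [
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccsc1", "c1ccoc1", "c1cc[nH]c1",
    "c1ccc2ccccc2c1", "c1ccc2ncccc2c1", "c1ccc2[nH]ccc2c1",
    "C1CCCCC1", "C1CCCC1", "C1CCNCC1", "C1CCOCC1",
]
_RING_W = [0.22, 0.12, 0.07, 0.06, 0.05, 0.05, 0.05, 0.04, 0.04,
           0.10, 0.05, 0.08, 0.07]
_LINKERS = ["", "C", "CC", "O", "N", "OC", "NC", "C(=O)", "C(=O)N", "S(=O)(=O)"]
_LINKER_W = [0.22, 0.16, 0.10, 0.10, 0.08, 0.08, 0.06, 0.08, 0.08, 0.04]
_SUBS = ["F", "Cl", "C", "CC", "O", "OC", "N", "C(F)(F)F", "C#N", "C(=O)O",
         "C(=O)N", "C(C)C", "OCC", "NC"]
_SUB_W = [0.12, 0.08, 0.16, 0.08, 0.10, 0.10, 0.07, 0.05, 0.05, 0.05,
          0.05, 0.04, 0.03, 0.02]


def _insertion_points(s: str) -> list[int]:
    """Character indices after which a branch may be inserted."""
    points = []
    depth = 0
    for i, ch in enumerate(s):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif depth == 0 and ch in "cC":
            j = i + 1
            while j < len(s) and s[j].isdigit():
                j += 1
            points.append(j - 1)
    return points


def _assemble(rng: np.random.Generator) -> str:
    n_rings = rng.choice([1, 2, 3], p=[0.2, 0.5, 0.3])
    parts = [str(rng.choice(_RINGS, p=_RING_W))]
    for _ in range(n_rings - 1):
        parts.append(str(rng.choice(_LINKERS, p=_LINKER_W)))
        parts.append(str(rng.choice(_RINGS, p=_RING_W)))
    smiles = "".join(parts)
    n_subs = int(rng.integers(0, 4))
    for _ in range(n_subs):
        pts = _insertion_points(smiles)
        if not pts:
            break
        i = int(rng.choice(pts))
        sub = str(rng.choice(_SUBS, p=_SUB_W))
        smiles = smiles[:i + 1] + "(" + sub + ")" + smiles[i + 1:]
    return smiles


def generate_corpus(n: int, seed: int = 0, max_attempts_per_mol: int = 20) -> list[Molecule]:
    """n valid drug-like SMILES assembled from the fragment grammar.

    Assembly occasionally produces chemically impossible substitution
    patterns; those are discarded and redrawn, so every returned molecule
    parses. Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("corpus size must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Molecule] = []
    while len(out) < n:
        for _ in range(max_attempts_per_mol):
            mol = canonicalize(_assemble(rng), gen_index=len(out))
            if mol.valid:
                out.append(mol)
                break
        else:  # pragma: no cover - grammar would have to be badly broken
            raise RuntimeError("fragment grammar failed to produce a valid SMILES")
    return out


def corpus_stats(mols: Sequence[Molecule]) -> dict:
    valid = [m for m in mols if m.valid]
    unique = {m.canonical_smiles for m in valid}
    return {
        "n": len(mols),
        "validity": len(valid) / len(mols) if mols else 0.0,
        "uniqueness": len(unique) / len(valid) if valid else 0.0,
    }
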