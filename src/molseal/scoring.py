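"""Multi-parameter (MPO) scoring.

Each scoring component returns a raw value that an optional transform maps
into [0, 1]. Components are either *penalties* (applied multiplicatively,
unweighted, untransformed) or *non-penalties* (aggregated by a weighted
geometric mean). The aggregate desirability is

    MPO(x) = prod_p s_p(x) * ( prod_np t_i(s_i(x))^{w_i} )^{1 / sum_i w_i}

When a component is uncertain (a surrogate prediction with mean and sd), the
MPO score becomes a random variable; its mean and sd are estimated by
Monte-Carlo propagation: draw joint realizations of the uncertain raw values,
transform and aggregate each realization, then summarize.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import QED, rdMolDescriptors
from rdkit.Chem import Descriptors as _Desc

from .chem import Molecule

__all__ = [
    "TransformSpec",
    "ScoreComponentSpec",
    "ComponentValue",
    "MPOResult",
    "transform",
    "evaluate_component",
    "mpo_score",
    "probabilistic_mpo",
    "score_molecule",
    "default_alerts",
    "rocs_transform",
    "docking_transform",
]

TRANSFORM_KINDS = ("identity", "sigmoid", "reverse_sigmoid", "double_sigmoid")


@dataclass(frozen=True)
class TransformSpec:
    """Transform parameters, mirroring the conventional "low"/"high"/"k" names.

    The sigmoid is base-10: t(x) = 1 / (1 + 10^(−k'(x − c))) with midpoint
    c = (low+high)/2 and slope k' = 10k/(high − low); the reverse sigmoid
    negates the exponent. The double sigmoid is the product of a rising
    sigmoid centered at ``low`` and a falling one at ``high``, both with
    base-10 slope coef_steep/coef_div, giving ≈1 mid-range and 0.5 at the
    edges.
    """

    kind: str = "identity"
    low: float = 0.0
    high: float = 1.0
    k: float = 1.0
    coef_div: float = 1.0
    coef_steep: float = 1.0

    def __post_init__(self):
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind != "identity" and not self.low < self.high:
            raise ValueError(f"transform requires low < high, got "
                             f"low={self.low}, high={self.high}")


def transform(x, spec: TransformSpec):
    """Map raw values into [0, 1]; accepts scalars or arrays."""
    arr = np.asarray(x, dtype=np.float64)
    if spec.kind == "identity":
        out = np.clip(arr, 0.0, 1.0)
    elif spec.kind in ("sigmoid", "reverse_sigmoid"):
        c = 0.5 * (spec.low + spec.high)
        kp = 10.0 * spec.k / (spec.high - spec.low)
        expo = -kp * (arr - c)
        if spec.kind == "reverse_sigmoid":
            expo = -expo
        out = 1.0 / (1.0 + np.power(10.0, np.clip(expo, -300, 300)))
    else:  # double_sigmoid
        s = spec.coef_steep / spec.coef_div
        up = 1.0 / (1.0 + np.power(10.0, np.clip(-s * (arr - spec.low), -300, 300)))
        down = 1.0 / (1.0 + np.power(10.0, np.clip(s * (arr - spec.high), -300, 300)))
        out = up * down
    return float(out) if np.isscalar(x) else out


# Printed transform settings for the two oracle flavors.
def rocs_transform() -> TransformSpec:
    return TransformSpec(kind="sigmoid", low=0.3, high=0.65, k=0.3)


def docking_transform() -> TransformSpec:
    return TransformSpec(kind="reverse_sigmoid", low=-13.5, high=-6.0, k=0.2)


EVALUATORS = ("qed", "mol_weight", "hbd_count", "custom_alerts", "oracle", "surrogate")


@dataclass(frozen=True)
class ScoreComponentSpec:
    name: str
    evaluator: str
    is_penalty: bool = False
    weight: float = 1.0
    transform: TransformSpec = field(default_factory=TransformSpec)
    # evaluator-specific, e.g. alert SMARTS; None = shipped defaults,
    # an explicit empty tuple = no alerts at all
    params: tuple | None = None

    def __post_init__(self):
        if self.evaluator not in EVALUATORS:
            raise ValueError(f"unknown evaluator {self.evaluator!r}")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("component weight must lie in [0, 1]")


@dataclass
class ComponentValue:
    name: str
    raw: float
    transformed: float
    is_stochastic: bool = False
    mean: float = 0.0
    sd: float = 0.0


@dataclass
class MPOResult:
    mpo_mean: float
    mpo_sd: float
    n_samples: int
    per_component: list[ComponentValue]


_ALERTS_CACHE: list | None = None


def default_alerts() -> tuple[str, ...]:
    """SMARTS shipped with the package (replaceable configuration)."""
    text = importlib.resources.files("molseal").joinpath("data/alerts.smarts").read_text()
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        # SMARTS never contain whitespace; anything after the first token
        # (e.g. a trailing comment) is ignored.
        patterns.append(line.split()[0])
    return tuple(patterns)


def _compiled_alerts(patterns: Sequence[str]):
    global _ALERTS_CACHE
    key = tuple(patterns)
    if _ALERTS_CACHE is None or _ALERTS_CACHE[0] != key:
        mols = []
        for p in key:
            q = Chem.MolFromSmarts(p)
            if q is None:
                raise ValueError(f"bad alert SMARTS: {p!r}")
            mols.append(q)
        _ALERTS_CACHE = [key, mols]
    return _ALERTS_CACHE[1]


def evaluate_component(mol: Molecule, spec: ScoreComponentSpec,
                       oracle_value: float | None = None,
                       surrogate_pred: tuple[float, float] | None = None) -> ComponentValue:
    """Compute one component's raw and transformed value for a valid molecule.

    ``oracle`` components read ``oracle_value``; ``surrogate`` components read
    ``surrogate_pred`` = (mean, sd) on the raw oracle scale and are the only
    stochastic components.
    """
    ev = spec.evaluator
    if ev == "qed":
        raw = float(QED.qed(mol.rdkit_mol()))
    elif ev == "mol_weight":
        raw = float(_Desc.MolWt(mol.rdkit_mol()))
    elif ev == "hbd_count":
        raw = float(rdMolDescriptors.CalcNumHBD(mol.rdkit_mol()))
    elif ev == "custom_alerts":
        patterns = default_alerts() if spec.params is None else spec.params
        rd = mol.rdkit_mol()
        hit = any(rd.HasSubstructMatch(q) for q in _compiled_alerts(patterns))
        raw = 0.0 if hit else 1.0
    elif ev == "oracle":
        if oracle_value is None:
            raise ValueError("oracle component needs an oracle value")
        raw = float(oracle_value)
    elif ev == "surrogate":
        if surrogate_pred is None:
            raise ValueError("surrogate component needs a (mean, sd) prediction")
        mean, sd = float(surrogate_pred[0]), float(surrogate_pred[1])
        if sd < 0:
            raise ValueError("surrogate sd must be >= 0")
        return ComponentValue(name=spec.name, raw=mean,
                              transformed=transform(mean, spec.transform),
                              is_stochastic=True, mean=mean, sd=sd)
    else:  # pragma: no cover - guarded by the spec dataclass
        raise ValueError(ev)
    return ComponentValue(name=spec.name, raw=raw,
                          transformed=transform(raw, spec.transform))


def mpo_score(components: Sequence[ComponentValue],
              specs: Sequence[ScoreComponentSpec]) -> float:
    """Deterministic aggregate: penalties × weighted geometric mean."""
    if len(components) != len(specs):
        raise ValueError("components and specs must align")
    penalty = 1.0
    wsum = 0.0
    logsum = 0.0
    zero = False
    n_np = 0
    for cv, spec in zip(components, specs):
        if spec.is_penalty:
            penalty *= cv.raw
        else:
            n_np += 1
            wsum += spec.weight
            t = cv.transformed
            if t <= 0.0:
                zero = True
            else:
                logsum += spec.weight * math.log(t)
    if n_np == 0:
        raise ValueError("at least one non-penalty component is required")
    if wsum <= 0.0:
        raise ValueError("all non-penalty weights are zero")
    if penalty == 0.0 or zero:
        return 0.0
    return float(penalty * math.exp(logsum / wsum))


def probabilistic_mpo(components: Sequence[ComponentValue],
                      specs: Sequence[ScoreComponentSpec],
                      n_samples: int = 1000,
                      rng: np.random.Generator | int | None = None) -> MPOResult:
    """Monte-Carlo propagation of component uncertainty into the MPO score.

    Stochastic components are sampled as independent Gaussians on the raw
    scale (mean, sd), transformed per realization, and aggregated per
    realization; the result reports the sample mean and sd of the MPO
    distribution. With fully deterministic inputs this equals the
    deterministic aggregate exactly with sd = 0, for any n_samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not any(cv.is_stochastic for cv in components):
        return MPOResult(mpo_mean=mpo_score(components, specs), mpo_sd=0.0,
                         n_samples=n_samples, per_component=list(components))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    S = n_samples
    penalty = np.ones(S)
    logsum = np.zeros(S)
    dead = np.zeros(S, dtype=bool)
    wsum = 0.0
    n_np = 0
    for cv, spec in zip(components, specs):
        if cv.is_stochastic:
            if cv.sd < 0:
                raise ValueError("stochastic component sd must be >= 0")
            raw = rng.normal(cv.mean, cv.sd, size=S) if cv.sd > 0 else np.full(S, cv.mean)
            t = np.asarray(transform(raw, spec.transform))
        else:
            t = np.full(S, cv.transformed)
            raw = np.full(S, cv.raw)
        if spec.is_penalty:
            penalty *= raw
        else:
            n_np += 1
            wsum += spec.weight
            bad = t <= 0.0
            dead |= bad
            logsum += spec.weight * np.log(np.where(bad, 1.0, t))
    if n_np == 0:
        raise ValueError("at least one non-penalty component is required")
    if wsum <= 0.0:
        raise ValueError("all non-penalty weights are zero")
    samples = np.where(dead, 0.0, penalty * np.exp(logsum / wsum))
    sd = float(samples.std(ddof=1)) if S > 1 else 0.0
    return MPOResult(mpo_mean=float(samples.mean()), mpo_sd=sd,
                     n_samples=S, per_component=list(components))


def score_molecule(mol: Molecule, specs: Sequence[ScoreComponentSpec],
                   oracle_value: float | None = None,
                   surrogate_pred: tuple[float, float] | None = None,
                   n_samples: int = 1000,
                   rng: np.random.Generator | int | None = None) -> MPOResult:
    """Evaluate every component for one molecule and aggregate.

    Invalid molecules receive MPO 0 without component evaluation.
    """
    if not mol.valid:
        return MPOResult(mpo_mean=0.0, mpo_sd=0.0, n_samples=0, per_component=[])
    values = [evaluate_component(mol, s, oracle_value=oracle_value,
                                 surrogate_pred=surrogate_pred) for s in specs]
    if any(v.is_stochastic for v in values):
        return probabilistic_mpo(values, specs, n_samples=n_samples, rng=rng)
    return MPOResult(mpo_mean=mpo_score(values, specs), mpo_sd=0.0,
                     n_samples=0, per_component=values)
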