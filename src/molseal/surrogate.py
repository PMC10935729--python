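"""Uncertainty-aware oracle surrogate.

A random-forest ensemble regresses raw oracle values on z-scaled
physicochemical descriptors; the spread of per-tree predictions supplies the
uncertainty estimate used by UCB acquisition and uncertainty-gated loss
weights. Labelled compounds live in a sliding-window training pool (the m
most recent by default) with an adaptive-subsampling alternative that keeps
the compounds the model is most uncertain about.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .chem import FeatureScaler, Molecule, apply_scaler, fit_scaler

__all__ = [
    "PoolEntry",
    "TrainingPool",
    "Prediction",
    "SurrogateModel",
    "fit_surrogate",
    "adaptive_subsample",
    "lookahead_mae",
]


@dataclass
class PoolEntry:
    canonical: str
    descriptors: np.ndarray
    label: float
    epoch: int


class TrainingPool:
    """Labelled compounds in acquisition order, unique by canonical SMILES.

    ``recent`` mode trims to the ``window`` most recent entries after every
    addition; ``adaptive`` mode keeps everything and relies on
    :func:`adaptive_subsample` at fit time. A duplicate re-acquisition
    replaces the previous entry (newest label, newest position).
    """

    def __init__(self, window: int = 1000, selection_mode: str = "recent"):
        if selection_mode not in ("recent", "adaptive"):
            raise ValueError(f"unknown selection mode {selection_mode!r}")
        self.window = window
        self.selection_mode = selection_mode
        self.entries: list[PoolEntry] = []

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, entries: Sequence[PoolEntry]) -> None:
        for e in entries:
            if not np.isfinite(e.label):
                raise ValueError(f"non-finite oracle label for {e.canonical}")
            self.entries = [x for x in self.entries if x.canonical != e.canonical]
            self.entries.append(e)
        if self.selection_mode == "recent" and len(self.entries) > self.window:
            self.entries = self.entries[-self.window:]

    def matrix(self, entries: Sequence[PoolEntry] | None = None):
        entries = self.entries if entries is None else entries
        X = np.stack([e.descriptors for e in entries])
        y = np.array([e.label for e in entries])
        return X, y

    def to_csv(self, path) -> None:
        """Snapshot (smiles, label, epoch); descriptors are not persisted."""
        import pandas as pd
        pd.DataFrame({"smiles": [e.canonical for e in self.entries],
                      "label": [e.label for e in self.entries],
                      "epoch": [e.epoch for e in self.entries]}).to_csv(
            path, index=False)


@dataclass
class Prediction:
    mean: float
    sd: float


@dataclass
class SurrogateModel:
    """Fitted forest + the scaler it was trained with."""

    forest: RandomForestRegressor
    scaler: FeatureScaler
    fitted: bool = True
    seed: int = 0
    featurizer: object = None  # optional: maps molecules to descriptor rows

    def predict_matrix(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble mean and per-tree sd for each descriptor row."""
        if not self.fitted:
            raise RuntimeError("surrogate model is not fitted")
        Xs = apply_scaler(self.scaler, np.asarray(X, dtype=np.float64))
        per_tree = np.stack([t.predict(Xs) for t in self.forest.estimators_])
        return per_tree.mean(axis=0), per_tree.std(axis=0)

    def predict(self, mols: Sequence[Molecule]) -> list[Prediction]:
        if self.featurizer is None:
            raise RuntimeError("no featurizer attached; use predict_matrix")
        X = np.stack([self.featurizer(m) for m in mols])
        mean, sd = self.predict_matrix(X)
        return [Prediction(float(m), float(s)) for m, s in zip(mean, sd)]

    def save(self, path) -> None:
        """Serialized forest + scaler blob with a JSON hyperparameter sidecar."""
        import json
        from pathlib import Path

        import joblib
        path = Path(path)
        joblib.dump({"forest": self.forest, "scaler": self.scaler},
                    path.with_suffix(".joblib"))
        params = self.forest.get_params()
        meta = {"n_trees": params["n_estimators"],
                "max_depth": params["max_depth"],
                "min_samples_split": params["min_samples_split"],
                "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        import json
        from pathlib import Path

        import joblib
        path = Path(path)
        blob = joblib.load(path.with_suffix(".joblib"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(forest=blob["forest"], scaler=blob["scaler"],
                   seed=meta.get("seed", 0))


def fit_surrogate(pool: TrainingPool | tuple[np.ndarray, np.ndarray],
                  seed: int = 0, n_trees: int = 200, max_depth: int = 30,
                  min_samples_split: int = 2,
                  featurizer=None) -> SurrogateModel | None:
    """Fit scaler + forest on the pool; returns None when |pool| < 2.

    The scaler is refit on the current pool at every call — the pool is the
    only distributional anchor while the generator drifts.
    """
    if isinstance(pool, TrainingPool):
        if len(pool) < 2:
            return None
        X, y = pool.matrix()
    else:
        X, y = pool
        if len(X) < 2:
            return None
    scaler = fit_scaler(X)
    Xs = apply_scaler(scaler, X)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_depth=max_depth,
        min_samples_split=min_samples_split, random_state=int(seed) % (2 ** 31),
        n_jobs=1)
    forest.fit(Xs, y)
    return SurrogateModel(forest=forest, scaler=scaler, seed=seed,
                          featurizer=featurizer)


def adaptive_subsample(pool: TrainingPool, m: int, cycles: int = 3,
                       seed: int = 0, **fit_kwargs) -> list[PoolEntry]:
    """Uncertainty-driven selection of m entries in train/predict/acquire cycles.

    Cycle 1 trains a model on a random seed split of the pool and takes the
    quota of entries with the highest predictive sd; later cycles retrain on
    the selection so far and extend it, until exactly m entries are chosen.
    Returns the whole pool when it is not larger than m.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    entries = list(pool.entries)
    if len(entries) <= m:
        return entries
    rng = np.random.default_rng(seed)
    quota = [m // cycles] * cycles
    quota[-1] += m - sum(quota)
    selected: list[PoolEntry] = []
    remaining = entries
    for c, q in enumerate(quota):
        if c == 0:
            seed_idx = rng.choice(len(remaining), size=max(2, min(q, len(remaining) - 1)),
                                  replace=False)
            train = [remaining[i] for i in seed_idx]
        else:
            train = selected
        model = fit_surrogate(TrainingPoolView(train), seed=int(rng.integers(2 ** 31)),
                              **fit_kwargs)
        X, _ = pool.matrix(remaining)
        _, sd = model.predict_matrix(X)
        order = np.argsort(-sd, kind="stable")[:q]
        picked = set(order.tolist())
        selected.extend(remaining[i] for i in sorted(picked))
        remaining = [e for i, e in enumerate(remaining) if i not in picked]
    return selected


class TrainingPoolView(TrainingPool):
    """Read-only pool facade over an explicit entry list."""

    def __init__(self, entries: Sequence[PoolEntry]):
        self.window = len(entries)
        self.selection_mode = "recent"
        self.entries = list(entries)


def lookahead_mae(model: SurrogateModel, X_next: np.ndarray,
                  labels: Sequence[float]) -> float:
    """MAE of the current model on the next epoch's compounds, pre-retrain."""
    labels = np.asarray(labels, dtype=float)
    if len(labels) == 0:
        raise ValueError("look-ahead MAE needs a non-empty batch")
    mean, _ = model.predict_matrix(X_next)
    return float(np.mean(np.abs(mean - labels)))
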