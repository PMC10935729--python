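"""Experiment orchestration.

The outer reinforcement-learning loop with the inner active-learning loop:

1. the agent samples ``n_batch`` SMILES;
2. cheap scoring components are computed for every valid molecule;
3. an acquisition function selects ``n_acquired/n_loops`` compounds
   (random on the very first loop, while the surrogate is unfitted);
4. the oracle labels them, the labels enter the sliding-window pool and the
   surrogate is refit — repeated ``n_loops`` times per epoch;
5. every compound's MPO score is assembled from its oracle label when it has
   one, otherwise from the surrogate prediction;
6. the diversity filter adjusts scores, per-compound weights are assigned,
   and one wDAP step (with experience replay) updates the agent.

``run_vs_al`` applies the same surrogate/acquisition machinery to a fixed
virtual library (no generator, no RL). ``compute_metrics`` summarizes hits,
oracle-call efficiency and diversity from a run log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec, priority, select
from .chem import Molecule, _descriptor_row, mean_pairwise_similarity, murcko_scaffold
from .config import RunConfig
from .generator import Adam
from .oracles import Oracle
from .rl import DiversityFilter, ReplayBuffer, assign_weights, rl_step
from .scoring import evaluate_component, mpo_score, probabilistic_mpo
from .surrogate import (PoolEntry, Prediction, TrainingPool, TrainingPoolView,
                        adaptive_subsample, fit_surrogate)

__all__ = ["EpochRecord", "RunLog", "MetricsReport", "run_rl_al", "run_vs_al",
           "compute_metrics"]


@dataclass
class EpochRecord:
    epoch: int
    oracle_calls: int
    cumulative_calls: int
    n_valid: int
    mean_mpo: float
    mean_filtered_mpo: float
    loss: float
    surrogate_refits: int
    lookahead_mae: float | None
    cum_hit_smiles: int
    cum_hit_scaffolds: int


@dataclass
class RunLog:
    config: dict
    mode: str
    epochs: list[EpochRecord] = field(default_factory=list)
    compounds: list[dict] = field(default_factory=list)
    total_oracle_calls: int = 0

    def epoch_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.epochs])

    def compound_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.compounds)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"type": "header", "mode": self.mode,
                                 "config": self.config}) + "\n")
            for c in self.compounds:
                fh.write(json.dumps({"type": "compound", **c}) + "\n")
            for e in self.epochs:
                fh.write(json.dumps({"type": "epoch", **asdict(e)}) + "\n")
            fh.write(json.dumps({"type": "footer",
                                 "total_oracle_calls": self.total_oracle_calls}) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "RunLog":
        log = cls(config={}, mode="rl-al")
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                kind = rec.pop("type")
                if kind == "header":
                    log.config = rec["config"]
                    log.mode = rec["mode"]
                elif kind == "compound":
                    log.compounds.append(rec)
                elif kind == "epoch":
                    log.epochs.append(EpochRecord(**rec))
                else:
                    log.total_oracle_calls = rec["total_oracle_calls"]
        return log

    def digest(self) -> str:
        payload = json.dumps({"config": self.config, "mode": self.mode,
                              "compounds": self.compounds,
                              "epochs": [asdict(e) for e in self.epochs],
                              "total": self.total_oracle_calls}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _hit_update(oracle: Oracle, mol: Molecule, value: float,
                hit_smiles: set, hit_scaffolds: set) -> None:
    if oracle.is_hit(value):
        hit_smiles.add(mol.canonical_smiles)
        hit_scaffolds.add(murcko_scaffold(mol).scaffold_smiles)


def run_rl_al(config: RunConfig, prior, oracle: Oracle | None = None) -> RunLog:
    """Run the RL (mode="rl") or RL–AL (mode="rl-al") campaign.

    ``prior`` is a pretrained policy (GRU or mock); the agent starts as an
    exact copy. With ``n_acquired == n_batch`` and one inner loop the AL
    machinery degenerates and the trajectory matches a pure-RL run under the
    same seeds.
    """
    if config.mode not in ("rl", "rl-al"):
        raise ValueError(f"run_rl_al cannot execute mode {config.mode!r}")
    al = config.mode == "rl-al"
    oracle = oracle if oracle is not None else config.build_oracle()
    specs = config.component_specs()
    oracle_ci = next(i for i, s in enumerate(specs) if s.evaluator == "oracle")
    cheap_specs = [(i, s) for i, s in enumerate(specs) if s.evaluator != "oracle"]
    acq_spec = config.acquisition_spec()
    scheme = config.weight_scheme.to_scheme()
    rl_params = config.rl.to_params()

    agent = prior.clone_agent()
    prior_f = prior if getattr(prior, "role", "prior") == "prior" else prior.clone_frozen()
    opt = Adam(lr=config.rl.learning_rate)

    streams = np.random.SeedSequence(config.seed).spawn(5)
    r_sample, r_acq, r_mc, r_replay, r_surr = (np.random.default_rng(s) for s in streams)

    pool = TrainingPool(window=config.surrogate.window,
                        selection_mode=config.surrogate.selection_mode)
    model = None
    divfilter = (DiversityFilter(bucket_size=config.diversity_filter.bucket_size,
                                 min_score=config.diversity_filter.min_score)
                 if config.diversity_filter.enabled else None)
    replay = (ReplayBuffer(capacity=config.replay.capacity,
                           sample_size=config.replay.sample_size)
              if config.replay.enabled else None)

    log = RunLog(config=config.model_dump(), mode=config.mode)
    hit_smiles: set[str] = set()
    hit_scaffolds: set[str] = set()
    gen_counter = 0
    total_calls = 0
    epoch = 0

    def featurize_one(m: Molecule) -> np.ndarray:
        return _descriptor_row(m.rdkit_mol(), config.descriptor_set)[0]

    def refit(seed: int):
        entries = pool.entries
        if pool.selection_mode == "adaptive" and len(entries) > config.surrogate.window:
            entries = adaptive_subsample(pool, config.surrogate.window,
                                         cycles=config.surrogate.adaptive_cycles,
                                         seed=seed,
                                         n_trees=config.surrogate.n_trees,
                                         max_depth=config.surrogate.max_depth,
                                         min_samples_split=config.surrogate.min_samples_split)
        return fit_surrogate(TrainingPoolView(entries), seed=seed,
                             n_trees=config.surrogate.n_trees,
                             max_depth=config.surrogate.max_depth,
                             min_samples_split=config.surrogate.min_samples_split)

    model_cap = getattr(prior, "max_len", None)
    eff_max_len = min(config.max_len, model_cap) if model_cap else config.max_len

    while True:
        epoch += 1
        if config.epochs is not None and epoch > config.epochs:
            break
        res = agent.sample(config.n_batch, r_sample, eff_max_len)
        for m in res.molecules:
            m.gen_index = gen_counter
            gen_counter += 1
        valid_idx = [i for i, m in enumerate(res.molecules) if m.valid]
        X = {i: featurize_one(res.molecules[i]) for i in valid_idx}
        cheap = {i: [evaluate_component(res.molecules[i], s) for _, s in cheap_specs]
                 for i in valid_idx}

        labels: dict[int, float] = {}
        look = None
        refits = 0
        calls_epoch = 0
        if al:
            k_per = config.n_acquired // config.n_loops
            by_gen = {res.molecules[i].gen_index: i for i in valid_idx}
            for loop in range(config.n_loops):
                remaining = [i for i in valid_idx if i not in labels]
                if not remaining:
                    break
                k = min(k_per, len(remaining))
                mols_rem = [res.molecules[i] for i in remaining]
                if model is None:
                    prio = priority(mols_rem, None, AcquisitionSpec(strategy="random"),
                                    rng=r_acq)
                elif acq_spec.strategy == "random":
                    prio = priority(mols_rem, None, acq_spec, rng=r_acq)
                else:
                    mean, sd = model.predict_matrix(np.stack([X[i] for i in remaining]))
                    if acq_spec.strategy.startswith("mpo_"):
                        surr_spec = _surrogate_spec(specs[oracle_ci])
                        preds = []
                        for j, i in enumerate(remaining):
                            values = list(cheap[i])
                            values.insert(oracle_ci, evaluate_component(
                                res.molecules[i], surr_spec,
                                surrogate_pred=(mean[j], sd[j])))
                            preds.append(probabilistic_mpo(
                                values, specs, n_samples=config.mc_samples,
                                rng=r_mc))
                        prio = priority(mols_rem, preds, acq_spec)
                    else:
                        preds = [Prediction(float(m_), float(s_))
                                 for m_, s_ in zip(mean, sd)]
                        prio = priority(mols_rem, preds, acq_spec)
                split = select(mols_rem, prio, k)
                acquired_idx = [by_gen[m.gen_index] for m in split.acquired]
                if loop == 0 and model is not None and acquired_idx:
                    pmean, _ = model.predict_matrix(np.stack([X[i] for i in acquired_idx]))
                new_labels = {}
                for i in acquired_idx:
                    new_labels[i] = float(oracle(res.molecules[i]))
                    calls_epoch += 1
                if loop == 0 and model is not None and acquired_idx:
                    look = float(np.mean(np.abs(
                        pmean - np.array([new_labels[i] for i in acquired_idx]))))
                labels.update(new_labels)
                pool.add([PoolEntry(canonical=res.molecules[i].canonical_smiles,
                                    descriptors=X[i], label=labels[i], epoch=epoch)
                          for i in acquired_idx])
                model = refit(int(r_surr.integers(2 ** 31)))
                refits += 1
        else:
            for i in valid_idx:
                labels[i] = float(oracle(res.molecules[i]))
                calls_epoch += 1
        total_calls += calls_epoch

        # predictions for un-acquired compounds from the freshest model
        unlabelled = [i for i in valid_idx if i not in labels]
        surr_pred: dict[int, tuple[float, float]] = {}
        if unlabelled:
            if model is None:
                raise RuntimeError("surrogate unavailable for unlabelled compounds; "
                                   "increase n_acquired")
            mean, sd = model.predict_matrix(np.stack([X[i] for i in unlabelled]))
            surr_pred = {i: (float(m_), float(s_))
                         for i, m_, s_ in zip(unlabelled, mean, sd)}

        mpo = np.zeros(config.n_batch)
        sources = ["oracle"] * config.n_batch
        uncert = np.zeros(config.n_batch)
        comp_log: dict[int, dict[str, float]] = {}
        for i in valid_idx:
            raw = labels.get(i, surr_pred.get(i, (0.0, 0.0))[0])
            values = list(cheap[i])
            values.insert(oracle_ci, evaluate_component(
                res.molecules[i], specs[oracle_ci], oracle_value=raw))
            mpo[i] = mpo_score(values, specs)
            comp_log[i] = {v.name: round(float(v.transformed), 6) for v in values}
            if i not in labels:
                sources[i] = "surrogate"
                uncert[i] = surr_pred[i][1]
        filtered = mpo.copy()
        if divfilter is not None:
            for i in range(config.n_batch):
                filtered[i] = divfilter(res.molecules[i], float(mpo[i]))
        weights = assign_weights(sources, scheme, uncert)

        for i, v in labels.items():
            _hit_update(oracle, res.molecules[i], v, hit_smiles, hit_scaffolds)

        loss = rl_step(agent, prior_f, res.handles, filtered, weights, rl_params,
                       opt, replay=replay, replay_rng=r_replay)
        logp_agent = res.logp
        logp_prior = prior_f.loglik_handles(res.handles)
        if replay is not None:
            for i in labels:
                if res.molecules[i].valid:
                    replay.add(res.molecules[i].canonical_smiles,
                               res.molecules[i].raw_smiles,
                               res.handles[i], float(filtered[i]))

        for i, m in enumerate(res.molecules):
            log.compounds.append({
                "epoch": epoch, "gen_index": m.gen_index, "smiles": m.raw_smiles,
                "canonical": m.canonical_smiles, "valid": bool(m.valid),
                "label_source": sources[i] if m.valid else None,
                "components": comp_log.get(i),
                "oracle_raw": labels.get(i),
                "surrogate_mean": surr_pred.get(i, (None,))[0],
                "surrogate_sd": surr_pred[i][1] if i in surr_pred else None,
                "mpo": float(mpo[i]), "filtered_mpo": float(filtered[i]),
                "weight": float(weights[i]),
                "logp_prior": float(logp_prior[i]),
                "logp_agent": float(logp_agent[i]),
            })
        log.epochs.append(EpochRecord(
            epoch=epoch, oracle_calls=calls_epoch, cumulative_calls=total_calls,
            n_valid=len(valid_idx), mean_mpo=float(mpo.mean()),
            mean_filtered_mpo=float(filtered.mean()), loss=float(loss),
            surrogate_refits=refits, lookahead_mae=look,
            cum_hit_smiles=len(hit_smiles), cum_hit_scaffolds=len(hit_scaffolds)))

        if config.oracle_budget is not None and total_calls >= config.oracle_budget:
            break
        if (config.stop_at_hit_scaffolds is not None
                and len(hit_scaffolds) >= config.stop_at_hit_scaffolds):
            break
    log.total_oracle_calls = total_calls
    return log


def _surrogate_spec(oracle_spec):
    """The oracle component recast as a stochastic surrogate component."""
    from .scoring import ScoreComponentSpec
    return ScoreComponentSpec(name=oracle_spec.name, evaluator="surrogate",
                              is_penalty=oracle_spec.is_penalty,
                              weight=oracle_spec.weight,
                              transform=oracle_spec.transform,
                              params=oracle_spec.params)


def run_vs_al(library: Sequence[Molecule], config: RunConfig,
              oracle: Oracle | None = None) -> RunLog:
    """Iterative active learning over a fixed library (no generator, no RL).

    The first batch is random; later batches follow the configured
    acquisition strategy. Stops when the oracle budget is exhausted or the
    library fully labelled; exhausting the library recovers the brute-force
    hit set.
    """
    library = [m for m in library if m.valid]
    if not library:
        raise ValueError("virtual-screening library is empty")
    oracle = oracle if oracle is not None else config.build_oracle()
    acq_spec = config.acquisition_spec()
    if acq_spec.strategy.startswith("mpo_"):
        raise ValueError("virtual screening ranks raw oracle predictions; "
                         "use random/greedy/ucb")
    streams = np.random.SeedSequence(config.seed).spawn(2)
    r_acq, r_surr = (np.random.default_rng(s) for s in streams)
    for i, m in enumerate(library):
        m.gen_index = i
    X = np.stack([_descriptor_row(m.rdkit_mol(), config.descriptor_set)[0]
                  for m in library])
    pool = TrainingPool(window=config.surrogate.window,
                        selection_mode=config.surrogate.selection_mode)
    budget = config.oracle_budget or len(library)
    model = None
    log = RunLog(config=config.model_dump(), mode="vs-al")
    hit_smiles: set[str] = set()
    hit_scaffolds: set[str] = set()
    labelled: set[int] = set()
    total_calls = 0
    it = 0
    while total_calls < budget and len(labelled) < len(library):
        it += 1
        remaining = [i for i in range(len(library)) if i not in labelled]
        k = min(config.n_acquired, len(remaining), budget - total_calls)
        mols_rem = [library[i] for i in remaining]
        if model is None or acq_spec.strategy == "random":
            prio = priority(mols_rem, None, AcquisitionSpec(strategy="random"),
                            rng=r_acq)
        else:
            mean, sd = model.predict_matrix(X[remaining])
            preds = [Prediction(float(m_), float(s_)) for m_, s_ in zip(mean, sd)]
            prio = priority(mols_rem, preds, acq_spec)
        split = select(mols_rem, prio, k)
        for m in split.acquired:
            i = m.gen_index
            v = float(oracle(m))
            labelled.add(i)
            total_calls += 1
            _hit_update(oracle, m, v, hit_smiles, hit_scaffolds)
            pool.add([PoolEntry(canonical=m.canonical_smiles, descriptors=X[i],
                                label=v, epoch=it)])
            log.compounds.append({
                "epoch": it, "gen_index": i, "smiles": m.raw_smiles,
                "canonical": m.canonical_smiles, "valid": True,
                "label_source": "oracle", "oracle_raw": v,
                "surrogate_mean": None, "surrogate_sd": None,
                "mpo": None, "filtered_mpo": None, "weight": None,
                "logp_prior": None, "logp_agent": None})
        model = fit_surrogate(pool, seed=int(r_surr.integers(2 ** 31)),
                              n_trees=config.surrogate.n_trees,
                              max_depth=config.surrogate.max_depth,
                              min_samples_split=config.surrogate.min_samples_split)
        log.epochs.append(EpochRecord(
            epoch=it, oracle_calls=len(split.acquired),
            cumulative_calls=total_calls, n_valid=len(split.acquired),
            mean_mpo=0.0, mean_filtered_mpo=0.0, loss=0.0,
            surrogate_refits=1, lookahead_mae=None,
            cum_hit_smiles=len(hit_smiles), cum_hit_scaffolds=len(hit_scaffolds)))
    log.total_oracle_calls = total_calls
    return log


@dataclass
class MetricsReport:
    n_oracle_calls: int
    unique_hit_smiles: int
    unique_hit_scaffolds: int
    smiles_efficiency_pct: float
    scaffold_efficiency_pct: float
    mean_hit_similarity: float | None
    mean_hit_mpo: float | None
    calls_to_first: dict[int, int | None]
    mpo_trajectory: list[float]
    al_rl_ratio: float | None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calls_to_first"] = {str(k): v for k, v in d["calls_to_first"].items()}
        return d


def compute_metrics(log: RunLog, oracle: Oracle | None = None,
                    first_n: Sequence[int] = (1, 5, 10, 20, 50, 100)) -> MetricsReport:
    """Hits, oracle-call efficiency (%), and hit diversity from a run log.

    Hits are oracle-labelled compounds passing the hit test, counted unique
    by canonical SMILES and by Murcko scaffold; efficiency is
    hits / total oracle calls × 100.
    """
    if oracle is None:
        from .oracles import make_oracle
        oracle = make_oracle(log.config["oracle"]["name"])
    labelled = [c for c in log.compounds
                if c.get("label_source") == "oracle" and c.get("oracle_raw") is not None]
    n_calls = log.total_oracle_calls or len(labelled)
    if n_calls == 0:
        raise ValueError("metrics are undefined with zero oracle calls")
    hits = [c for c in labelled if oracle.is_hit(c["oracle_raw"])]
    hit_smiles = {c["canonical"] for c in hits}
    from .chem import canonicalize
    hit_mols = [canonicalize(s) for s in sorted(hit_smiles)]
    hit_scaffolds = {murcko_scaffold(m).scaffold_smiles for m in hit_mols}
    similarity = (mean_pairwise_similarity(hit_mols) if len(hit_mols) >= 2 else None)
    hit_mpo_vals = [c["mpo"] for c in hits if c.get("mpo") is not None]
    cfg = log.config
    ratio = (cfg["n_acquired"] / cfg["n_batch"]
             if cfg.get("n_acquired") and cfg.get("n_batch") else None)
    calls_to_first: dict[int, int | None] = {}
    for n in first_n:
        calls_to_first[n] = next((e.cumulative_calls for e in log.epochs
                                  if e.cum_hit_scaffolds >= n), None)
    return MetricsReport(
        n_oracle_calls=n_calls,
        unique_hit_smiles=len(hit_smiles),
        unique_hit_scaffolds=len(hit_scaffolds),
        smiles_efficiency_pct=100.0 * len(hit_smiles) / n_calls,
        scaffold_efficiency_pct=100.0 * len(hit_scaffolds) / n_calls,
        mean_hit_similarity=similarity,
        mean_hit_mpo=(float(np.mean(hit_mpo_vals)) if hit_mpo_vals else None),
        calls_to_first=calls_to_first,
        mpo_trajectory=[e.mean_mpo for e in log.epochs],
        al_rl_ratio=ratio)
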