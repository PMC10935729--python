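"""SMILES sequence policy.

A compact multi-layer GRU language model over SMILES tokens, implemented
directly in numpy (forward, backward-through-time, Adam), small enough that
fixture-scale pretraining finishes in minutes on one CPU. The same network
serves as *prior* (frozen after pretraining) and *agent* (updated by RL).
A categorical :class:`MockPolicy` over a fixed molecule pool satisfies the
same contract and is used as a fast, analytically tractable test double.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import Molecule, canonicalize

__all__ = [
    "Vocabulary",
    "TokenSequence",
    "SampleResult",
    "Adam",
    "GRUPolicy",
    "MockPolicy",
    "pretrain",
]

_TOKEN_RE = re.compile(r"\[[^\]]+\]|Br|Cl|%\d{2}|.")

PAD, BOS, EOS = "<pad>", "^", "$"


class Vocabulary:
    """Token inventory with begin/end/pad specials.

    Multi-character atom tokens (Cl, Br, bracket atoms, ``%NN`` ring
    closures) are single tokens.
    """

    def __init__(self, tokens: Sequence[str]):
        specials = [PAD, BOS, EOS]
        rest = sorted(t for t in tokens if t not in specials)
        self.tokens: list[str] = specials + rest
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}
        self.pad, self.bos, self.eos = 0, 1, 2

    def __len__(self) -> int:
        return len(self.tokens)

    @classmethod
    def from_corpus(cls, smiles: Sequence[str]) -> "Vocabulary":
        seen: set[str] = set()
        for s in smiles:
            seen.update(_split_tokens(s))
        return cls(sorted(seen))

    def encode(self, smiles: str) -> np.ndarray:
        """Token indices with a terminal end token appended."""
        idx = []
        pos = 0
        for tok in _split_tokens(smiles):
            if tok not in self.index:
                raise KeyError(
                    f"unknown token {tok!r} at position {pos} in {smiles!r}")
            idx.append(self.index[tok])
            pos += len(tok)
        idx.append(self.eos)
        return np.asarray(idx, dtype=np.int64)

    def decode(self, indices: np.ndarray) -> str:
        out = []
        for i in indices:
            if i == self.eos:
                break
            if i in (self.pad, self.bos):
                continue
            out.append(self.tokens[int(i)])
        return "".join(out)


def _split_tokens(smiles: str) -> list[str]:
    toks = _TOKEN_RE.findall(smiles)
    if "".join(toks) != smiles:
        raise ValueError(f"untokenizable SMILES: {smiles!r}")
    return toks


@dataclass
class TokenSequence:
    """Indices including the terminal end token."""

    indices: np.ndarray
    max_len: int = 128


def tokenize(smiles: str, vocab: Vocabulary, max_len: int = 128) -> TokenSequence:
    return TokenSequence(indices=vocab.encode(smiles), max_len=max_len)


def detokenize(seq: TokenSequence | np.ndarray, vocab: Vocabulary) -> str:
    idx = seq.indices if isinstance(seq, TokenSequence) else seq
    return vocab.decode(idx)


@dataclass
class SampleResult:
    """One sampled batch: molecules plus the agent's own log-likelihoods.

    ``handles`` are opaque per-sequence identifiers the policy accepts back
    in :meth:`loglik_handles` / :meth:`grad_step` (token arrays for the GRU,
    canonical SMILES for the mock policy).
    """

    molecules: list[Molecule]
    logp: np.ndarray
    handles: list
    truncated: np.ndarray


class Adam:
    """Standard Adam; state keyed per parameter name."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRUPolicy:
    """Multi-layer GRU SMILES language model (numpy, float32).

    Gate layout inside the combined weight matrices is [update | reset | new];
    the reset gate multiplies the hidden-to-new pre-activation (the
    "reset-after" formulation).
    """

    def __init__(self, vocab: Vocabulary, embed_dim: int = 128,
                 hidden_dim: int = 256, n_layers: int = 3,
                 seed: int = 0, role: str = "prior", max_len: int = 128):
        self.vocab = vocab
        self.embed_dim, self.hidden_dim, self.n_layers = embed_dim, hidden_dim, n_layers
        self.role = role
        self.max_len = max_len
        rng = np.random.default_rng(seed)
        V, E, H = len(vocab), embed_dim, hidden_dim
        p: dict[str, np.ndarray] = {}
        p["E"] = (rng.standard_normal((V, E)) * 0.1).astype(np.float32)
        for l in range(n_layers):
            din = E if l == 0 else H
            s_in = 1.0 / np.sqrt(din)
            s_h = 1.0 / np.sqrt(H)
            p[f"Wx{l}"] = (rng.uniform(-s_in, s_in, (din, 3 * H))).astype(np.float32)
            p[f"Wh{l}"] = (rng.uniform(-s_h, s_h, (H, 3 * H))).astype(np.float32)
            p[f"b{l}"] = np.zeros(3 * H, dtype=np.float32)
        p["W_out"] = (rng.uniform(-1, 1, (H, V)) / np.sqrt(H)).astype(np.float32)
        p["b_out"] = np.zeros(V, dtype=np.float32)
        self.params = p

    # -- copies ------------------------------------------------------------
    def _copy(self, role: str) -> "GRUPolicy":
        other = GRUPolicy.__new__(GRUPolicy)
        other.vocab = self.vocab
        other.embed_dim, other.hidden_dim = self.embed_dim, self.hidden_dim
        other.n_layers, other.max_len = self.n_layers, self.max_len
        other.role = role
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other

    def clone_agent(self) -> "GRUPolicy":
        """Exact copy serving as the trainable agent."""
        return self._copy("agent")

    def clone_frozen(self) -> "GRUPolicy":
        """Exact copy serving as the immutable prior."""
        return self._copy("prior")

    def parameters_blob(self) -> bytes:
        return b"".join(self.params[k].tobytes() for k in sorted(self.params))

    # -- core passes -------------------------------------------------------
    def _step_layers(self, x, hs, caches=None):
        H = self.hidden_dim
        for l in range(self.n_layers):
            Wx, Wh, b = (self.params[f"Wx{l}"], self.params[f"Wh{l}"],
                         self.params[f"b{l}"])
            h = hs[l]
            pre_x = x @ Wx + b
            pre_h = h @ Wh
            z = _sigmoid(pre_x[:, :H] + pre_h[:, :H])
            r = _sigmoid(pre_x[:, H:2 * H] + pre_h[:, H:2 * H])
            pre_hn = pre_h[:, 2 * H:]
            n = np.tanh(pre_x[:, 2 * H:] + r * pre_hn)
            h_new = (1.0 - z) * n + z * h
            if caches is not None:
                caches[l].append((x, h, z, r, n, pre_hn))
            hs[l] = h_new
            x = h_new
        return x  # top-layer hidden

    def _pad(self, seqs: Sequence[np.ndarray]):
        if any(len(s) > self.max_len for s in seqs):
            raise ValueError(f"sequence exceeds max length {self.max_len}")
        B = len(seqs)
        T = max(len(s) for s in seqs)
        targets = np.full((B, T), self.vocab.pad, dtype=np.int64)
        inputs = np.full((B, T), self.vocab.pad, dtype=np.int64)
        mask = np.zeros((B, T), dtype=np.float32)
        inputs[:, 0] = self.vocab.bos
        for b, s in enumerate(seqs):
            L = len(s)
            targets[b, :L] = s
            inputs[b, 1:L] = s[:-1]
            mask[b, :L] = 1.0
        return inputs, targets, mask

    def _forward_teacher(self, seqs: Sequence[np.ndarray], need_grads: bool):
        inputs, targets, mask = self._pad(seqs)
        B, T = inputs.shape
        H = self.hidden_dim
        hs = [np.zeros((B, H), dtype=np.float32) for _ in range(self.n_layers)]
        caches = [[] for _ in range(self.n_layers)] if need_grads else None
        logprob = np.zeros(B, dtype=np.float64)
        probs_all = [] if need_grads else None
        tops = []
        for t in range(T):
            x = self.params["E"][inputs[:, t]]
            top = self._step_layers(x, hs, caches)
            logits = top @ self.params["W_out"] + self.params["b_out"]
            logits = logits - logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            probs = expl / expl.sum(axis=1, keepdims=True)
            lp = np.log(np.maximum(probs[np.arange(B), targets[:, t]], 1e-30))
            logprob += mask[:, t] * lp
            if need_grads:
                probs_all.append(probs)
                tops.append(top)
        extras = (inputs, targets, mask, caches, probs_all, tops)
        return logprob, extras

    def loglik_handles(self, seqs: Sequence[np.ndarray]) -> np.ndarray:
        logp, _ = self._forward_teacher([np.asarray(s, dtype=np.int64) for s in seqs],
                                        need_grads=False)
        return logp

    def loglik(self, smiles: Sequence[str]) -> np.ndarray:
        return self.loglik_handles([self.vocab.encode(s) for s in smiles])

    def sequence_loglik(self, seq: TokenSequence | np.ndarray) -> float:
        idx = seq.indices if isinstance(seq, TokenSequence) else np.asarray(seq)
        return float(self.loglik_handles([idx])[0])

    def grad_step(self, seqs: Sequence, coeffs: np.ndarray, optimizer: Adam) -> None:
        """One optimizer step on L with dL/dlogp given per sequence.

        ``coeffs[b]`` is dL/d(logp of sequence b); the method accumulates
        dL/dθ = Σ_b coeffs[b] · ∇θ logp_b and applies the optimizer.
        """
        if self.role == "prior":
            raise RuntimeError("the prior is immutable during RL")
        grads = self.loglik_grads(seqs, np.asarray(coeffs, dtype=np.float64))
        optimizer.step(self.params, grads)

    def grad_step_unchecked(self, seqs: Sequence, coeffs: np.ndarray,
                            optimizer: Adam) -> None:
        """Role-agnostic step; used by pretraining before the prior freezes."""
        grads = self.loglik_grads(seqs, np.asarray(coeffs, dtype=np.float64))
        optimizer.step(self.params, grads)

    def loglik_grads(self, seqs: Sequence, coeffs: np.ndarray) -> dict[str, np.ndarray]:
        seqs = [np.asarray(s, dtype=np.int64) for s in seqs]
        _, (inputs, targets, mask, caches, probs_all, tops) = \
            self._forward_teacher(seqs, need_grads=True)
        B, T = inputs.shape
        H = self.hidden_dim
        V = len(self.vocab)
        c32 = coeffs.astype(np.float32)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dhs = [np.zeros((B, H), dtype=np.float32) for _ in range(self.n_layers)]
        for t in range(T - 1, -1, -1):
            probs = probs_all[t]
            dlogits = -probs * (c32[:, None] * mask[:, t][:, None])
            dlogits[np.arange(B), targets[:, t]] += c32 * mask[:, t]
            grads["W_out"] += tops[t].T @ dlogits
            grads["b_out"] += dlogits.sum(axis=0)
            dtop = dlogits @ self.params["W_out"].T
            for l in range(self.n_layers - 1, -1, -1):
                dh = dhs[l] + dtop
                x, h_prev, z, r, n, pre_hn = caches[l][t]
                dz = dh * (h_prev - n)
                dn = dh * (1.0 - z)
                dh_prev = dh * z
                dan = dn * (1.0 - n * n)
                dr = dan * pre_hn
                daz = dz * z * (1.0 - z)
                dar = dr * r * (1.0 - r)
                dpre_x = np.concatenate([daz, dar, dan], axis=1)
                dpre_h = np.concatenate([daz, dar, dan * r], axis=1)
                grads[f"Wx{l}"] += x.T @ dpre_x
                grads[f"Wh{l}"] += h_prev.T @ dpre_h
                grads[f"b{l}"] += dpre_x.sum(axis=0)
                dhs[l] = dh_prev + dpre_h @ self.params[f"Wh{l}"].T
                dtop = dpre_x @ self.params[f"Wx{l}"].T
            np.add.at(grads["E"], inputs[:, t], dtop)
        return grads

    def sample(self, n: int, rng: np.random.Generator | int,
               max_len: int | None = None) -> SampleResult:
        """Ancestral sampling at temperature 1; reproducible given the rng.

        Sequences that hit ``max_len`` without emitting the end token are
        marked invalid.
        """
        if n < 1:
            raise ValueError("sample size must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        max_len = max_len or self.max_len
        B = n
        H = self.hidden_dim
        hs = [np.zeros((B, H), dtype=np.float32) for _ in range(self.n_layers)]
        cur = np.full(B, self.vocab.bos, dtype=np.int64)
        active = np.ones(B, dtype=bool)
        logp = np.zeros(B, dtype=np.float64)
        seqs: list[list[int]] = [[] for _ in range(B)]
        for _ in range(max_len):
            x = self.params["E"][cur]
            top = self._step_layers(x, hs)
            logits = top @ self.params["W_out"] + self.params["b_out"]
            logits = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(B)
            cum = np.cumsum(probs, axis=1)
            idx = np.minimum((cum < u[:, None]).sum(axis=1), len(self.vocab) - 1)
            lp = np.log(np.maximum(probs[np.arange(B), idx], 1e-30))
            for b in range(B):
                if active[b]:
                    logp[b] += lp[b]
                    seqs[b].append(int(idx[b]))
            active &= idx != self.vocab.eos
            if not active.any():
                break
            cur = idx
        truncated = active.copy()
        molecules, handles = [], []
        for b in range(B):
            arr = np.asarray(seqs[b], dtype=np.int64)
            handles.append(arr)
            smi = self.vocab.decode(arr)
            if truncated[b]:
                molecules.append(Molecule(raw_smiles=smi, canonical_smiles=None,
                                          valid=False))
            else:
                molecules.append(canonicalize(smi))
        return SampleResult(molecules=molecules, logp=logp, handles=handles,
                            truncated=truncated)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {"tokens": self.vocab.tokens, "embed_dim": self.embed_dim,
                "hidden_dim": self.hidden_dim, "n_layers": self.n_layers,
                "max_len": self.max_len, "role": self.role, "format": 1}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "GRUPolicy":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        vocab = Vocabulary(meta["tokens"])
        model = cls(vocab, embed_dim=meta["embed_dim"], hidden_dim=meta["hidden_dim"],
                    n_layers=meta["n_layers"], role=meta["role"],
                    max_len=meta["max_len"])
        with np.load(path.with_suffix(".npz")) as blob:
            model.params = {k: blob[k].copy() for k in blob.files}
        return model


class MockPolicy:
    """Categorical policy over a fixed molecule pool (test double).

    ``sample`` draws pool members with softmax(logits) probabilities; the
    log-likelihood of a pool member is its categorical log-probability, and a
    gradient step nudges the logits. Satisfies the full policy contract.
    """

    def __init__(self, pool: Sequence[Molecule | str], logits: np.ndarray,
                 role: str = "agent"):
        mols = [m if isinstance(m, Molecule) else canonicalize(m) for m in pool]
        if not mols:
            raise ValueError("mock policy pool must be non-empty")
        if len(mols) != len(logits):
            raise ValueError("pool and logits must have equal length")
        self.pool = mols
        self.keys = [m.canonical_smiles if m.valid else m.raw_smiles for m in mols]
        self.key_index = {k: i for i, k in enumerate(self.keys)}
        self.params = {"logits": np.asarray(logits, dtype=np.float64).copy()}
        self.role = role
        self.max_len = 0

    @property
    def logits(self) -> np.ndarray:
        return self.params["logits"]

    def _probs(self) -> np.ndarray:
        z = self.logits - self.logits.max()
        e = np.exp(z)
        return e / e.sum()

    def sample(self, n: int, rng: np.random.Generator | int,
               max_len: int | None = None) -> SampleResult:
        if n < 1:
            raise ValueError("sample size must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        p = self._probs()
        idx = rng.choice(len(self.pool), size=n, p=p)
        molecules = []
        for i in idx:
            src = self.pool[i]
            molecules.append(Molecule(raw_smiles=src.raw_smiles,
                                      canonical_smiles=src.canonical_smiles,
                                      valid=src.valid, _mol=src._mol))
        logp = np.log(p[idx])
        handles = [self.keys[i] for i in idx]
        return SampleResult(molecules=molecules, logp=logp, handles=handles,
                            truncated=np.zeros(n, dtype=bool))

    def loglik_handles(self, handles: Sequence[str]) -> np.ndarray:
        p = np.log(self._probs())
        return np.array([p[self.key_index[h]] for h in handles])

    def loglik(self, smiles: Sequence[str]) -> np.ndarray:
        return self.loglik_handles(list(smiles))

    def grad_step(self, handles: Sequence[str], coeffs: np.ndarray,
                  optimizer: Adam) -> None:
        if self.role == "prior":
            raise RuntimeError("the prior is immutable during RL")
        coeffs = np.asarray(coeffs, dtype=np.float64)
        p = self._probs()
        g = -np.outer(coeffs, p).sum(axis=0)
        for c, h in zip(coeffs, handles):
            g[self.key_index[h]] += c
        optimizer.step(self.params, {"logits": g})

    def clone_agent(self) -> "MockPolicy":
        return MockPolicy(self.pool, self.logits.copy(), role="agent")

    def clone_frozen(self) -> "MockPolicy":
        return MockPolicy(self.pool, self.logits.copy(), role="prior")

    def parameters_blob(self) -> bytes:
        return self.logits.tobytes()


def pretrain(corpus: Sequence[Molecule | str], epochs: int = 5,
             batch_size: int = 128, lr: float = 1e-3, seed: int = 0,
             embed_dim: int = 128, hidden_dim: int = 256, n_layers: int = 3,
             max_len: int = 128, holdout_frac: float = 0.05,
             vocab: Vocabulary | None = None) -> tuple[GRUPolicy, dict]:
    """Teacher-forcing maximum-likelihood pretraining of the prior.

    Returns the trained policy (role "prior") and a history dict with
    per-epoch held-out NLL per token (index 0 = before training).
    """
    smiles = [m.canonical_smiles if isinstance(m, Molecule) else m for m in corpus]
    smiles = [s for s in smiles if s]
    if not smiles:
        raise ValueError("empty pretraining corpus")
    if vocab is None:
        vocab = Vocabulary.from_corpus(smiles)
    model = GRUPolicy(vocab, embed_dim=embed_dim, hidden_dim=hidden_dim,
                      n_layers=n_layers, seed=seed, role="prior",
                      max_len=max_len)
    encoded = [e for e in (vocab.encode(s) for s in smiles) if len(e) <= max_len]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(encoded))
    n_hold = max(1, int(len(encoded) * holdout_frac))
    hold = [encoded[i] for i in order[:n_hold]]
    train = [encoded[i] for i in order[n_hold:]]
    if not train:
        raise ValueError("corpus too small for the requested holdout")
    opt = Adam(lr=lr)

    def holdout_nll() -> float:
        tot_lp, tot_tok = 0.0, 0
        for i in range(0, len(hold), 256):
            chunk = hold[i:i + 256]
            tot_lp += model.loglik_handles(chunk).sum()
            tot_tok += sum(len(s) for s in chunk)
        return -tot_lp / tot_tok

    history = {"holdout_nll_per_token": [holdout_nll()]}
    for _ in range(epochs):
        perm = rng.permutation(len(train))
        for i in range(0, len(train), batch_size):
            batch = [train[j] for j in perm[i:i + batch_size]]
            coeffs = np.full(len(batch), -1.0 / len(batch))
            model.grad_step_unchecked(batch, coeffs, opt)
        history["holdout_nll_per_token"].append(holdout_nll())
    return model, history
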