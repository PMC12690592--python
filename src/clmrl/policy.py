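"""Autoregressive GRU policy over SMILES tokens, in pure numpy.

The policy is a single-layer gated-recurrent-unit network: token embedding,
GRU cell, and a linear output head producing next-token logits. Forward,
sampling, per-step distributions, sequence log-likelihoods, and full
backpropagation through time are implemented here in float64; gradient
correctness is pinned by finite-difference tests.

Two instances play distinct roles during RL: a frozen *prior* produced by
maximum-likelihood pretraining on a corpus, and a trainable *agent*
initialized as an exact copy of the prior.

Gate layout follows the common [reset | update | candidate] convention:

    r_t = sigmoid(x W_xr + b_xr + h W_hr + b_hr)
    z_t = sigmoid(x W_xz + b_xz + h W_hz + b_hz)
    n_t = tanh(x W_xn + b_xn + r_t * (h W_hn + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .vocab import Vocabulary, VocabularyError

CHECKPOINT_VERSION = 1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


@dataclass
class Episode:
    """One generated trajectory: tokens, sample-time log-probs, rewards."""

    tokens: list[int]                 # includes begin marker; end marker if complete
    logprobs: np.ndarray              # one per generated token, recorded at sampling
    smiles: str
    complete: bool
    raw_reward: float = float("nan")
    shaped_reward: float = float("nan")
    valid: bool = False
    canonical: str | None = None
    source: str = "on-policy"         # on-policy | replay

    @property
    def total_logprob(self) -> float:
        return float(self.logprobs.sum())

    @property
    def n_generated(self) -> int:
        return len(self.tokens) - 1


class GRUPolicy:
    """Small recurrent categorical policy; ``role`` is 'prior' or 'agent'."""

    PARAM_NAMES = ("E", "Wx", "Wh", "bx", "bh", "Wo", "bo")

    def __init__(
        self,
        vocab: Vocabulary,
        embedding_size: int = 64,
        hidden_size: int = 128,
        seed: int = 0,
        role: str = "agent",
    ):
        self.vocab = vocab
        self.embedding_size = embedding_size
        self.hidden_size = hidden_size
        self.role = role
        V, De, H = len(vocab), embedding_size, hidden_size
        rng = np.random.default_rng(seed)
        k = 1.0 / np.sqrt(H)
        u = lambda *shape: rng.uniform(-k, k, size=shape)
        self.params: dict[str, np.ndarray] = {
            "E": u(V, De),
            "Wx": u(De, 3 * H),
            "Wh": u(H, 3 * H),
            "bx": u(3 * H),
            "bh": u(3 * H),
            "Wo": u(H, V),
            "bo": u(V),
        }

    # ------------------------------------------------------------------ utils

    def copy(self, role: str | None = None) -> "GRUPolicy":
        clone = GRUPolicy.__new__(GRUPolicy)
        clone.vocab = self.vocab
        clone.embedding_size = self.embedding_size
        clone.hidden_size = self.hidden_size
        clone.role = role or self.role
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def make_uniform(self) -> "GRUPolicy":
        """Zero the output head so every step emits a uniform distribution."""
        self.params["Wo"][:] = 0.0
        self.params["bo"][:] = 0.0
        return self

    def pad_batch(self, sequences: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Teacher-forcing batch: (inputs, targets, mask), each (B, T).

        ``inputs[b, t]`` is fed at step t, ``targets[b, t]`` is the token the
        model should predict there; mask is 1 on real positions.
        """
        if any(len(s) < 2 for s in sequences):
            raise ValueError("sequences must contain at least begin marker + one token")
        B = len(sequences)
        T = max(len(s) for s in sequences) - 1
        pad = self.vocab.pad
        inputs = np.full((B, T), pad, dtype=np.int64)
        targets = np.full((B, T), pad, dtype=np.int64)
        mask = np.zeros((B, T), dtype=np.float64)
        for b, seq in enumerate(sequences):
            L = len(seq) - 1
            inputs[b, :L] = seq[:-1]
            targets[b, :L] = seq[1:]
            mask[b, :L] = 1.0
        return inputs, targets, mask

    # ---------------------------------------------------------------- forward

    def forward(self, inputs: np.ndarray, want_cache: bool = False):
        """Run the network over (B, T) input tokens; return (B, T, V) logits.

        With ``want_cache`` the per-step activations needed by
        :meth:`backward` are retained.
        """
        p = self.params
        B, T = inputs.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        logits = np.empty((B, T, len(self.vocab)))
        cache = {"inputs": inputs, "r": [], "z": [], "n": [], "hun": [], "h_prev": []} if want_cache else None
        for t in range(T):
            x = p["E"][inputs[:, t]]
            ax = x @ p["Wx"] + p["bx"]
            ah = h @ p["Wh"] + p["bh"]
            r = _sigmoid(ax[:, :H] + ah[:, :H])
            z = _sigmoid(ax[:, H : 2 * H] + ah[:, H : 2 * H])
            hun = ah[:, 2 * H :]
            n = np.tanh(ax[:, 2 * H :] + r * hun)
            h_new = (1.0 - z) * n + z * h
            logits[:, t] = h_new @ p["Wo"] + p["bo"]
            if want_cache:
                cache["r"].append(r)
                cache["z"].append(z)
                cache["n"].append(n)
                cache["hun"].append(hun)
                cache["h_prev"].append(h)
            h = h_new
        if want_cache:
            cache["h_last"] = h
            return logits, cache
        return logits

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Backpropagate (B, T, V) logit gradients to parameter gradients.

        Positions the loss does not touch must carry zero ``dlogits``; the
        recurrent carry then stays zero through padded steps automatically.
        """
        p = self.params
        inputs = cache["inputs"]
        B, T = inputs.shape
        H = self.hidden_size
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        WoT = p["Wo"].T
        WhT = p["Wh"].T
        WxT = p["Wx"].T
        carry = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            r, z, n = cache["r"][t], cache["z"][t], cache["n"][t]
            hun, h_prev = cache["hun"][t], cache["h_prev"][t]
            h_t = (1.0 - z) * n + z * h_prev
            dl = dlogits[:, t]
            grads["Wo"] += h_t.T @ dl
            grads["bo"] += dl.sum(axis=0)
            dh = carry + dl @ WoT
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dhp = dh * z
            dan = dn * (1.0 - n * n)
            dr = dan * hun
            dhun = dan * r
            dar = dr * r * (1.0 - r)
            daz = dz * z * (1.0 - z)
            da_x = np.concatenate([dar, daz, dan], axis=1)
            da_h = np.concatenate([dar, daz, dhun], axis=1)
            x = p["E"][inputs[:, t]]
            grads["Wx"] += x.T @ da_x
            grads["bx"] += da_x.sum(axis=0)
            grads["Wh"] += h_prev.T @ da_h
            grads["bh"] += da_h.sum(axis=0)
            dx = da_x @ WxT
            np.add.at(grads["E"], inputs[:, t], dx)
            carry = dhp + da_h @ WhT
        return grads

    # --------------------------------------------------------------- sampling

    def sample(self, n: int, max_len: int = 100, seed: int | np.random.Generator = 0) -> list[Episode]:
        """Draw ``n`` episodes by multinomial sampling at temperature 1.

        Each episode ends at the end marker or at ``max_len`` generated
        tokens (then flagged incomplete). Identical seed and parameters give
        token-identical batches.
        """
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0:
            return []
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        p = self.params
        H = self.hidden_size
        bos, eos = self.vocab.bos, self.vocab.eos
        h = np.zeros((n, H))
        current = np.full(n, bos, dtype=np.int64)
        alive = np.ones(n, dtype=bool)
        tokens: list[list[int]] = [[bos] for _ in range(n)]
        logprobs: list[list[float]] = [[] for _ in range(n)]
        for _ in range(max_len):
            x = p["E"][current]
            ax = x @ p["Wx"] + p["bx"]
            ah = h @ p["Wh"] + p["bh"]
            r = _sigmoid(ax[:, :H] + ah[:, :H])
            z = _sigmoid(ax[:, H : 2 * H] + ah[:, H : 2 * H])
            nn = np.tanh(ax[:, 2 * H :] + r * ah[:, 2 * H :])
            h = (1.0 - z) * nn + z * h
            logp = log_softmax(h @ p["Wo"] + p["bo"])
            probs = np.exp(logp)
            cdf = np.cumsum(probs, axis=1)
            cdf[:, -1] = 1.0
            u = rng.random((n, 1))
            choice = (cdf < u).sum(axis=1)
            for b in range(n):
                if alive[b]:
                    tok = int(choice[b])
                    tokens[b].append(tok)
                    logprobs[b].append(float(logp[b, tok]))
                    if tok == eos:
                        alive[b] = False
            if not alive.any():
                break
            current = choice
        episodes = []
        for b in range(n):
            complete = tokens[b][-1] == eos
            episodes.append(
                Episode(
                    tokens=tokens[b],
                    logprobs=np.asarray(logprobs[b]),
                    smiles=self.vocab.decode(tokens[b]),
                    complete=complete,
                )
            )
        return episodes

    # ------------------------------------------------------------ likelihoods

    def sequence_log_likelihood(self, sequences: Sequence[Sequence[int]]) -> tuple[list[np.ndarray], np.ndarray]:
        """Per-step log-probabilities and totals for encoded sequences."""
        inputs, targets, mask = self.pad_batch(sequences)
        logits = self.forward(inputs)
        logp = log_softmax(logits)
        picked = np.take_along_axis(logp, targets[:, :, None], axis=2)[:, :, 0] * mask
        per_step = [picked[b, : len(seq) - 1].copy() for b, seq in enumerate(sequences)]
        totals = np.array([s.sum() for s in per_step])
        return per_step, totals

    def step_distributions(self, sequence: Sequence[int]) -> np.ndarray:
        """(L, V) action-probability rows along one realized trajectory."""
        inputs, _, _ = self.pad_batch([sequence])
        logits = self.forward(inputs)
        return softmax(logits[0, : len(sequence) - 1])

    def encode_smiles(self, smiles: str) -> list[int]:
        return self.vocab.encode_smiles(smiles)

    # ------------------------------------------------------------- pretraining

    def pretrain(
        self,
        corpus: Sequence[str],
        epochs: int,
        seed: int = 0,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
    ) -> list[float]:
        """Maximum-likelihood next-token training; returns per-epoch mean NLL.

        NLL is per token, averaged over the epoch. Untokenizable corpus lines
        raise with the offending line quoted.
        """
        from .optim import Adam  # local import to avoid a cycle

        if not corpus:
            raise ValueError("corpus is empty")
        encoded = []
        for line in corpus:
            try:
                encoded.append(self.vocab.encode_smiles(line))
            except (VocabularyError, ValueError) as exc:
                raise ValueError(f"cannot encode corpus line {line!r}: {exc}") from exc
        trace: list[float] = []
        if epochs == 0:
            return trace
        rng = np.random.default_rng(seed)
        opt = Adam(self.params)
        order = np.arange(len(encoded))
        for _ in range(epochs):
            rng.shuffle(order)
            total_nll, total_tok = 0.0, 0.0
            for start in range(0, len(order), batch_size):
                batch = [encoded[i] for i in order[start : start + batch_size]]
                inputs, targets, mask = self.pad_batch(batch)
                logits, cache = self.forward(inputs, want_cache=True)
                logp = log_softmax(logits)
                n_tok = mask.sum()
                picked = np.take_along_axis(logp, targets[:, :, None], axis=2)[:, :, 0]
                total_nll += float(-(picked * mask).sum())
                total_tok += n_tok
                dlogits = np.exp(logp)
                B, T = targets.shape
                dlogits[np.arange(B)[:, None], np.arange(T)[None, :], targets] -= 1.0
                dlogits *= mask[:, :, None] / n_tok
                grads = self.backward(dlogits, cache)
                opt.step(self.params, grads, learning_rate)
            trace.append(total_nll / total_tok)
        return trace

    # ------------------------------------------------------------- checkpoints

    def save(self, path: str | Path) -> None:
        """Single-file, versioned checkpoint with the vocabulary embedded."""
        payload = {f"param_{k}": v for k, v in self.params.items()}
        payload["vocab_tokens"] = np.array(self.vocab.tokens, dtype=object)
        payload["meta"] = np.array(
            [CHECKPOINT_VERSION, self.embedding_size, self.hidden_size], dtype=np.int64
        )
        payload["role"] = np.array(self.role, dtype=object)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "GRUPolicy":
        data = np.load(path, allow_pickle=True)
        version, emb, hid = (int(v) for v in data["meta"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        vocab = Vocabulary(tokens=tuple(str(t) for t in data["vocab_tokens"]))
        policy = cls(vocab, embedding_size=emb, hidden_size=hid, role=str(data["role"]))
        for k in cls.PARAM_NAMES:
            policy.params[k] = data[f"param_{k}"].astype(np.float64)
        return policy


def kl_is_zero_at_init(prior: GRUPolicy, agent: GRUPolicy) -> bool:
    """True when agent parameters are an exact copy of the prior's."""
    return all(np.array_equal(prior.params[k], agent.params[k]) for k in prior.params)
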