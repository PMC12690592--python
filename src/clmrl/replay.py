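"""Bounded experience-replay buffer of the best molecules seen so far.

Entries are keyed by canonical SMILES (duplicates keep the highest reward
recorded), only valid molecules are stored, and when the buffer exceeds its
capacity the lowest-reward entries are evicted — so the buffer always holds
the top-N unique molecules by raw reward and its minimum reward never
decreases once full. Sampling for batch augmentation is either uniform or
reward-proportional ("prioritized"), without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .policy import Episode, GRUPolicy

PRIORITY_EPS = 1e-6


@dataclass
class ReplayEntry:
    canonical: str
    tokens: list[int]
    reward: float
    insertion_step: int = 0


@dataclass
class ReplayBuffer:
    capacity: int = 100
    batch_size: int = 20
    mode: Literal["prioritized", "uniform"] = "prioritized"
    entries: dict[str, ReplayEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def min_reward(self) -> float:
        if not self.entries:
            return float("-inf")
        return min(e.reward for e in self.entries.values())

    def insert(self, episodes: Iterable[Episode], step: int = 0) -> int:
        """Insert valid episodes by raw reward; returns the eviction count."""
        for ep in episodes:
            if not ep.valid or ep.canonical is None:
                continue
            if not np.isfinite(ep.raw_reward):
                continue
            existing = self.entries.get(ep.canonical)
            if existing is None:
                self.entries[ep.canonical] = ReplayEntry(
                    canonical=ep.canonical,
                    tokens=list(ep.tokens),
                    reward=float(ep.raw_reward),
                    insertion_step=step,
                )
            elif ep.raw_reward > existing.reward:
                existing.reward = float(ep.raw_reward)
                existing.tokens = list(ep.tokens)
                existing.insertion_step = step
        evicted = 0
        if len(self.entries) > self.capacity:
            ranked = sorted(self.entries.values(), key=lambda e: e.reward, reverse=True)
            keep = ranked[: self.capacity]
            evicted = len(self.entries) - self.capacity
            self.entries = {e.canonical: e for e in keep}
        return evicted

    def sample(self, m: int, seed: int | np.random.Generator = 0) -> list[ReplayEntry]:
        """Draw min(m, len) entries without replacement.

        Prioritized mode draws with probability proportional to reward
        (plus a tiny epsilon so all-zero rewards stay well defined),
        renormalizing after each pick; uniform mode is equiprobable.
        """
        if m < 0:
            raise ValueError("m must be >= 0")
        pool = list(self.entries.values())
        take = min(m, len(pool))
        if take == 0:
            return []
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if self.mode == "uniform":
            idx = rng.choice(len(pool), size=take, replace=False)
            return [pool[i] for i in idx]
        weights = np.array([e.reward for e in pool], dtype=np.float64) + PRIORITY_EPS
        if np.any(weights < 0):
            raise ValueError("prioritized sampling requires non-negative rewards")
        idx = rng.choice(len(pool), size=take, replace=False, p=weights / weights.sum())
        return [pool[i] for i in idx]

    def as_episodes(self, agent: GRUPolicy) -> list[Episode]:
        """All entries as replay-tagged episodes (log-probs left for refresh)."""
        return [self.entry_to_episode(e, agent) for e in self.entries.values()]

    @staticmethod
    def entry_to_episode(entry: ReplayEntry, agent: GRUPolicy) -> Episode:
        per_step, totals = agent.sequence_log_likelihood([entry.tokens])
        return Episode(
            tokens=list(entry.tokens),
            logprobs=per_step[0],
            smiles=agent.vocab.decode(entry.tokens),
            complete=True,
            raw_reward=entry.reward,
            valid=True,
            canonical=entry.canonical,
            source="replay",
        )

    # ------------------------------------------------------------------ I/O

    def dump(self, path: str | Path) -> None:
        """TSV dump: canonical SMILES, reward, insertion step, token indices."""
        with Path(path).open("w") as handle:
            handle.write("canonical\treward\tstep\ttokens\n")
            for e in sorted(self.entries.values(), key=lambda e: -e.reward):
                toks = ",".join(str(t) for t in e.tokens)
                handle.write(f"{e.canonical}\t{e.reward:.10g}\t{e.insertion_step}\t{toks}\n")

    @classmethod
    def load(cls, path: str | Path, capacity: int = 100, batch_size: int = 20,
             mode: str = "prioritized") -> "ReplayBuffer":
        buf = cls(capacity=capacity, batch_size=batch_size, mode=mode)  # type: ignore[arg-type]
        with Path(path).open() as handle:
            header = handle.readline()
            if not header.startswith("canonical"):
                raise ValueError("not a replay-buffer dump")
            for line in handle:
                canonical, reward, step, toks = line.rstrip("\n").split("\t")
                buf.entries[canonical] = ReplayEntry(
                    canonical=canonical,
                    tokens=[int(t) for t in toks.split(",")],
                    reward=float(reward),
                    insertion_step=int(step),
                )
        return buf


def replay_loglik_refresh(agent: GRUPolicy, episodes: list[Episode]) -> None:
    """Recompute each replay episode's log-probs under the current agent."""
    if not episodes:
        return
    for ep in episodes:
        if max(ep.tokens) >= len(agent.vocab):
            raise ValueError("vocabulary mismatch between replay entry and agent")
    per_step, _ = agent.sequence_log_likelihood([ep.tokens for ep in episodes])
    for ep, lp in zip(episodes, per_step):
        ep.logprobs = lp
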