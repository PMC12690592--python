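"""Synthetic SMILES corpus and chemistry-light reward functions.

These stand in for the large pretraining corpus and the external oracle
scoring functions of full-scale molecular-optimization benchmarks, so the
whole RL stack can be exercised on one CPU with no downloads. The corpus
generator enumerates a template family (linear/branched alkanes, ethers,
amines, and simple aromatics) that is valid by construction; the rewards
are deterministic, bounded in [0, 1], and score invalid molecules 0.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from . import chem

_CHAIN_ATOMS = ("C", "C", "C", "N", "O")  # carbon-weighted
_RINGS = ("c1ccccc1", "c1ccncc1", "c1cc[nH]c1", "c1ccco1", "c1cccs1")
_BRANCHES = ("(C)", "(CC)", "(O)", "(N)")

RewardFn = Callable[[str], float]

# Default motif target: inside the template family's alphabet but rare enough
# under the toy prior that the top-10 curve keeps headroom over a toy budget,
# so efficiency differences between algorithms stay visible.
DEFAULT_MOTIF = "NC(C)OC(C)NC(C)O"


def _random_molecule(rng: np.random.Generator) -> str:
    """One valid-by-construction SMILES from the template family."""
    parts: list[str] = []
    length = int(rng.integers(4, 14))
    for pos in range(length):
        atom = _CHAIN_ATOMS[rng.integers(0, len(_CHAIN_ATOMS))]
        parts.append(atom)
        # at most one branch per interior carbon keeps valence safe
        if atom == "C" and 0 < pos < length - 1 and rng.random() < 0.25:
            parts.append(_BRANCHES[rng.integers(0, len(_BRANCHES))])
    if rng.random() < 0.4:
        parts.append(_RINGS[rng.integers(0, len(_RINGS))])
    return "".join(parts)


def make_corpus(seed: int, n: int) -> list[str]:
    """Generate ``n`` parseable SMILES, seed-deterministic.

    Duplicates are possible (the family is finite) but rare: the draw space
    is large enough that well over 90% of a 5,000-molecule corpus is
    distinct.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        smi = _random_molecule(rng)
        if chem.is_valid(smi):  # belt and braces; templates are valid by design
            out.append(smi)
    return out


def _lcs_length(a: str, b: str) -> int:
    """Longest-common-subsequence length, O(len(a)*len(b))."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        curr = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                curr[j] = prev[j - 1] + 1
            else:
                curr[j] = max(prev[j], curr[j - 1])
        prev = curr
    return prev[len(b)]


def motif_reward(text: str, motif: str) -> float:
    """Normalized LCS similarity between a decoded string and a motif.

    Returns ``LCS(text, motif) / max(len(text), len(motif))``: 1 exactly when
    the two strings are identical, 0 when they share no characters. Purely
    string-level, so the RL loop is testable without a chemistry backend.
    """
    if not motif:
        raise ValueError("motif must be nonempty")
    if not text:
        return 0.0
    return _lcs_length(text, motif) / max(len(text), len(motif))


def ring_count_reward(smiles: str, target_rings: int) -> float:
    """``1 - min(1, |rings - target| / target)``; invalid molecules score 0."""
    if target_rings < 1:
        raise ValueError("target_rings must be >= 1")
    rings = chem.ring_count(smiles)
    if rings is None:
        return 0.0
    return 1.0 - min(1.0, abs(rings - target_rings) / target_rings)


def length_window_reward(smiles: str, low: int, high: int) -> float:
    """1 inside the [low, high] character-length window, linear falloff outside."""
    if high < low:
        raise ValueError("window bounds must be ordered")
    if not smiles:
        return 0.0
    n = len(smiles)
    if low <= n <= high:
        return 1.0
    dist = (low - n) if n < low else (n - high)
    span = max(1, high - low)
    return max(0.0, 1.0 - dist / span)


def composite_reward(components: list[tuple[RewardFn, float]]) -> RewardFn:
    """Weighted mean of component rewards; weights normalized to sum 1."""
    total = sum(w for _, w in components)
    if total <= 0:
        raise ValueError("weights must sum to a positive value")

    def _reward(smiles: str) -> float:
        return sum(w * fn(smiles) for fn, w in components) / total

    return _reward


def get_reward(name: str, params: dict | None = None) -> RewardFn:
    """Look up a reward by registry name.

    The plug-in contract: any callable taking a decoded molecule string and
    returning a number in [0, 1] qualifies; built-ins are ``motif``,
    ``ring_count``, and ``length_window``.
    """
    params = dict(params or {})
    if name == "motif":
        motif = params.get("motif", DEFAULT_MOTIF)
        return lambda s: motif_reward(s, motif)
    if name == "ring_count":
        target = int(params.get("target_rings", 1))
        return lambda s: ring_count_reward(s, target)
    if name == "length_window":
        low = int(params.get("low", 10))
        high = int(params.get("high", 30))
        return lambda s: length_window_reward(s, low, high)
    raise KeyError(f"unknown reward {name!r}; available: motif, ring_count, length_window")
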