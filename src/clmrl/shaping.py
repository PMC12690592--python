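"""Reward transformation: prior-coupled reshaping, diversity filters, RND.

Two reshaping formulations are provided. The REINVENT-lineage form couples
the raw reward R to both prior and agent sequence log-likelihoods,

    R_reshaped = (logp_prior - logp_agent + sigma * R)^2 / logp_agent,

which can go negative and entangles regularization strength with the scale
and gradient of the reward landscape. The decoupled clip-power form

    R_reshaped = clip(R + sigma * logp_prior, 0, 1)^alpha

keeps the output in [0, 1]; sigma alone sets the strength of prior
regularization (logp_prior <= 0, so larger sigma only ever lowers the
reshaped reward of prior-unlikely molecules) while the exponent alpha >= 1
independently steepens the reward gradient.

Diversity filters and the random-network-distillation (RND) novelty bonus
act on the raw reward *before* reshaping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import chem


# --------------------------------------------------------------- reshaping

def reinvent_reshape(raw_reward: float, logp_prior: float, logp_agent: float,
                     sigma: float) -> float:
    """REINVENT-style reshaped reward; may be negative by construction."""
    if logp_agent == 0.0:
        raise ZeroDivisionError("agent log-likelihood is exactly 0")
    num = logp_prior - logp_agent + sigma * raw_reward
    return (num * num) / logp_agent


def proposed_reshape(raw_reward: float, logp_prior: float, sigma: float,
                     alpha: float, clip_low: float = 0.0, clip_high: float = 1.0) -> float:
    """Clip-power reshaped reward, bounded in [clip_low, clip_high]^alpha."""
    if alpha < 1.0:
        raise ValueError("alpha must be >= 1")
    if sigma < 0.0:
        raise ValueError("sigma must be >= 0")
    clipped = min(max(raw_reward + sigma * logp_prior, clip_low), clip_high)
    return clipped ** alpha


@dataclass
class ShapingConfig:
    """Which formulation to apply and its coefficients."""

    formulation: Literal["none", "reinvent", "proposed"] = "none"
    sigma: float = 0.0
    alpha: float = 1.0
    # with a per-token option the prior log-likelihood is divided by the
    # number of generated tokens before entering the formula
    per_token_prior: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 1.0:
            raise ValueError("alpha must be >= 1")
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")

    def apply(self, raw_reward: float, logp_prior: float, logp_agent: float,
              n_tokens: int = 0) -> float:
        lp = logp_prior
        if self.per_token_prior and n_tokens > 0:
            lp = logp_prior / n_tokens
        if self.formulation == "none":
            return raw_reward
        if self.formulation == "reinvent":
            return reinvent_reshape(raw_reward, lp, logp_agent, self.sigma)
        if self.formulation == "proposed":
            return proposed_reshape(raw_reward, lp, self.sigma, self.alpha)
        raise ValueError(f"unknown formulation {self.formulation!r}")


# ---------------------------------------------------------- diversity filter

@dataclass
class DiversityFilter:
    """Memory-based penalty zeroing rewards of repeated sampling.

    ``occurrence`` mode zeroes any molecule seen before (by canonical
    SMILES); ``bin`` mode zeroes a molecule once its Bemis-Murcko scaffold
    bin holds more than ``bin_threshold`` members.
    """

    mode: Literal["off", "occurrence", "bin"] = "off"
    bin_threshold: int = 25
    seen_counts: dict[str, int] = field(default_factory=dict)
    bin_counts: dict[str, int] = field(default_factory=dict)

    def penalize(self, canonical: str | None, raw_reward: float) -> float:
        """Return the (possibly zeroed) reward and record the occurrence."""
        if self.mode == "off" or canonical is None:
            return raw_reward
        if self.mode == "occurrence":
            count = self.seen_counts.get(canonical, 0)
            self.seen_counts[canonical] = count + 1
            return 0.0 if count > 0 else raw_reward
        if self.mode == "bin":
            scaffold = chem.murcko_scaffold(canonical)
            key = scaffold if scaffold is not None else ""
            count = self.bin_counts.get(key, 0)
            self.bin_counts[key] = count + 1
            return 0.0 if count >= self.bin_threshold else raw_reward
        raise ValueError(f"unknown diversity-filter mode {self.mode!r}")


# ---------------------------------------------------------------------- RND

class _TwoLayerMLP:
    """Tiny MLP head used for both the frozen target and the predictor."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        s1 = np.sqrt(2.0 / n_in)
        s2 = np.sqrt(2.0 / n_hidden)
        self.W1 = rng.normal(0.0, s1, size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, s2, size=(n_hidden, n_out))
        self.b2 = np.zeros(n_out)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        a = x @ self.W1 + self.b1
        hrelu = np.maximum(a, 0.0)
        out = hrelu @ self.W2 + self.b2
        if want_cache:
            return out, (x, a, hrelu)
        return out


class RNDState:
    """Random network distillation: predictor error against a frozen target.

    The bonus for a molecule is ``lambda_rnd * mean squared error`` between
    the two network outputs on its fingerprint. Inputs seen often are
    predicted well (small bonus); novel inputs carry a large bonus.
    """

    def __init__(self, lambda_rnd: float, n_features: int = 1024,
                 n_hidden: int = 64, n_out: int = 32,
                 learning_rate: float = 1e-3, seed: int = 0):
        if lambda_rnd < 0:
            raise ValueError("lambda_rnd must be >= 0")
        rng = np.random.default_rng(seed)
        self.lambda_rnd = lambda_rnd
        self.n_features = n_features
        self.learning_rate = learning_rate
        self.target = _TwoLayerMLP(n_features, n_hidden, n_out, rng)
        self.predictor = _TwoLayerMLP(n_features, n_hidden, n_out, rng)

    def _check(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"feature length {features.shape[1]} != expected {self.n_features}"
            )
        return features

    def bonus(self, features: np.ndarray) -> np.ndarray:
        """Per-row novelty bonus, always >= 0."""
        x = self._check(features)
        err = self.predictor.forward(x) - self.target.forward(x)
        return self.lambda_rnd * np.mean(err * err, axis=1)

    def train(self, features: np.ndarray, n_steps: int = 1) -> None:
        """Fit the predictor toward the frozen target on this batch (plain SGD)."""
        x = self._check(features)
        y = self.target.forward(x)
        B = x.shape[0]
        for _ in range(n_steps):
            pred, (xc, a, hrelu) = self.predictor.forward(x, want_cache=True)
            dout = 2.0 * (pred - y) / (B * pred.shape[1])
            dW2 = hrelu.T @ dout
            db2 = dout.sum(axis=0)
            dh = dout @ self.predictor.W2.T
            dh[a <= 0.0] = 0.0
            dW1 = xc.T @ dh
            db1 = dh.sum(axis=0)
            lr = self.learning_rate
            self.predictor.W2 -= lr * dW2
            self.predictor.b2 -= lr * db2
            self.predictor.W1 -= lr * dW1
            self.predictor.b1 -= lr * db1


def featurize_for_rnd(smiles: str, n_features: int = 1024) -> np.ndarray | None:
    """Binary hashed circular fingerprint (radius 2); None for invalid input."""
    return chem.morgan_fingerprint(smiles, radius=2, n_bits=n_features)


def apply_rnd_bonus(rnd: RNDState | None, raw_reward: float,
                    features: np.ndarray | None) -> float:
    """Add the RND bonus to a raw reward, clamped so the total stays <= 1."""
    if rnd is None or rnd.lambda_rnd == 0.0 or features is None:
        return raw_reward
    bonus = float(rnd.bonus(features)[0])
    return min(1.0, raw_reward + bonus)


# ------------------------------------------------------------------ landscape

def landscape_grid(formulation: str, sigma: float, alpha: float,
                   reward_grid: np.ndarray, logp_grid: np.ndarray,
                   logp_agent: float | None = None) -> np.ndarray:
    """Reshaped-reward surface over (reward, prior log-likelihood) axes.

    Entry (i, j) applies the formulation at ``(reward_grid[i],
    logp_grid[j])``. For the REINVENT form, ``logp_agent`` fixes the agent
    likelihood slice; it defaults to the prior value at each grid point
    minus zero (i.e. the grid axis itself) when not given.
    """
    R = np.asarray(reward_grid, dtype=np.float64)
    L = np.asarray(logp_grid, dtype=np.float64)
    out = np.empty((R.size, L.size))
    for i, r in enumerate(R):
        for j, lp in enumerate(L):
            if formulation == "proposed":
                out[i, j] = proposed_reshape(float(r), float(lp), sigma, alpha)
            elif formulation == "reinvent":
                la = lp if logp_agent is None else logp_agent
                out[i, j] = reinvent_reshape(float(r), float(lp), float(la), sigma)
            else:
                raise ValueError(f"unknown formulation {formulation!r}")
    return out


def save_landscape(path, grid: np.ndarray, reward_grid: np.ndarray,
                   logp_grid: np.ndarray, render_png: str | None = None) -> None:
    """Write a landscape grid as CSV; optionally render a heat map."""
    import pandas as pd

    frame = pd.DataFrame(grid, index=np.asarray(reward_grid),
                         columns=np.asarray(logp_grid))
    frame.index.name = "reward"
    frame.to_csv(path)
    if render_png:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.pcolormesh(np.asarray(logp_grid), np.asarray(reward_grid), grid,
                           shading="auto", cmap="viridis")
        fig.colorbar(im, ax=ax, label="reshaped reward")
        ax.set_xlabel("prior log-likelihood")
        ax.set_ylabel("raw reward")
        fig.tight_layout()
        fig.savefig(render_png, dpi=120)
        plt.close(fig)
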