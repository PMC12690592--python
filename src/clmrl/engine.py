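"""Policy-gradient core: loss, baselines, hill-climb, schedules, update step.

The REINFORCE estimator maximizes J(theta) = E[ sum_t log pi(a_t|s_t) * R(tau) ];
minimizing

    loss = -(1/n) * sum_i (R_i - b_i) * sum_t log pi(a_t|s_t)_i

ascends the baseline-subtracted gradient. Two variance-reduction baselines
are available: a moving average over batch means (MAB) and a per-episode
leave-one-out mean (LOO). Hill-climb retains only the top-k fraction of the
on-policy batch before the update. Gradients are computed analytically
against the agent's logits and verified elsewhere by finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .optim import Adam
from .policy import Episode, GRUPolicy, log_softmax
from .regularization import (
    RegularizerConfig,
    all_term,
    entropy_term,
    kl_term,
    regularizer_gradients,
)


# ---------------------------------------------------------------- baselines

def loo_baseline(rewards: Sequence[float]) -> np.ndarray:
    """Leave-one-out baseline: b_i = (sum_j R_j - R_i) / (n - 1)."""
    r = np.asarray(rewards, dtype=np.float64)
    n = r.size
    if n < 2:
        raise ValueError("leave-one-out baseline needs at least 2 rewards")
    return (r.sum() - r) / (n - 1)


@dataclass
class BaselineState:
    """Baseline bookkeeping; LOO holds no state."""

    kind: Literal["none", "mab", "loo"] = "none"
    beta: float = 0.1
    value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")

    def mab_update(self, batch_mean: float) -> float:
        """b <- (1 - beta) * b + beta * mean; the first update sets b = mean."""
        if not np.isfinite(batch_mean):
            raise ValueError("batch mean must be finite")
        if self.value is None:
            self.value = float(batch_mean)
        else:
            self.value = (1.0 - self.beta) * self.value + self.beta * float(batch_mean)
        return self.value

    def mab_value(self) -> float:
        return 0.0 if self.value is None else self.value


# --------------------------------------------------------------- hill-climb

def hill_climb_select(episodes: list[Episode], k_ratio: float) -> list[Episode]:
    """Keep the ceil(k * n) highest-reward episodes (ties: original order).

    Ranking uses the shaped reward — the signal actually entering the
    gradient — which equals the raw reward when shaping is disabled.
    k_ratio = 1 is plain REINFORCE (the whole batch survives).
    """
    if not episodes:
        raise ValueError("cannot select from an empty batch")
    if not 0.0 < k_ratio <= 1.0:
        raise ValueError("k_ratio must be in (0, 1]")
    if k_ratio == 1.0:
        return list(episodes)
    keep = int(np.ceil(k_ratio * len(episodes)))
    order = sorted(range(len(episodes)),
                   key=lambda i: (-episodes[i].shaped_reward, i))
    chosen = sorted(order[:keep])
    return [episodes[i] for i in chosen]


# ---------------------------------------------------------------- schedules

@dataclass(frozen=True)
class OptimizerSchedule:
    """Constant learning rate, or half-cosine anneal then hold."""

    kind: Literal["constant", "cosine"] = "constant"
    base_rate: float = 1e-4
    anneal_start: float = 5e-4
    anneal_end: float = 1e-4
    anneal_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.base_rate <= 0 or self.anneal_start <= 0 or self.anneal_end <= 0:
            raise ValueError("learning rates must be positive")
        if self.anneal_end > self.anneal_start:
            raise ValueError("anneal end rate must be <= start rate")
        if not 0.0 < self.anneal_fraction <= 1.0:
            raise ValueError("anneal_fraction must be in (0, 1]")


def lr_at_step(schedule: OptimizerSchedule, step: int, budget: int) -> float:
    """Learning rate at ``step`` of ``budget`` (same units for both)."""
    if not 0 <= step <= budget:
        raise ValueError("step must lie in [0, budget]")
    if schedule.kind == "constant":
        return schedule.base_rate
    horizon = schedule.anneal_fraction * budget
    if horizon <= 0 or step >= horizon:
        return schedule.anneal_end
    span = schedule.anneal_start - schedule.anneal_end
    return schedule.anneal_end + span * 0.5 * (1.0 + np.cos(np.pi * step / horizon))


# --------------------------------------------------------------------- loss

@dataclass
class StepRecord:
    """One row of the training log."""

    step: int
    n_onpolicy: int
    n_replay: int
    loss_total: float
    loss_pg: float
    loss_kl: float
    loss_ent: float
    loss_all: float
    mean_raw_reward: float
    mean_shaped_reward: float
    agent_nll: float
    prior_nll: float
    baseline: float
    learning_rate: float
    molecules_consumed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_loss_and_grads(
    agent: GRUPolicy,
    episodes: list[Episode],
    advantages: np.ndarray,
    reg: RegularizerConfig = RegularizerConfig(),
    prior: GRUPolicy | None = None,
) -> tuple[dict[str, float], dict[str, np.ndarray], np.ndarray]:
    """Scalar loss components, parameter gradients, and agent totals.

    The gradient is assembled at the logit level: the policy-gradient part
    contributes ``-(A_i / n) * (onehot - q)`` per realized step, regularizers
    add their closed-form logit gradients, and one backward pass maps the
    combined (B, T, V) array to parameter space.
    """
    if len(episodes) != len(advantages):
        raise ValueError("episodes and advantages must align")
    if any(not np.isfinite(ep.shaped_reward) for ep in episodes):
        raise ValueError("every episode must carry a finite shaped reward")
    sequences = [ep.tokens for ep in episodes]
    inputs, targets, mask = agent.pad_batch(sequences)
    logits, cache = agent.forward(inputs, want_cache=True)
    logp = log_softmax(logits)
    B, T = targets.shape
    picked = np.take_along_axis(logp, targets[:, :, None], axis=2)[:, :, 0] * mask
    totals = picked.sum(axis=1)
    q = np.exp(logp)

    adv = np.asarray(advantages, dtype=np.float64)
    loss_pg = float(-(adv * totals).mean())
    onehot_minus_q = -q.copy()
    onehot_minus_q[np.arange(B)[:, None], np.arange(T)[None, :], targets] += 1.0
    dlogits = (-(adv / B))[:, None, None] * onehot_minus_q * mask[:, :, None]

    loss_kl = loss_ent = loss_all = 0.0
    prior_probs = None
    if reg.lambda_kl > 0.0:
        if prior is None:
            raise ValueError("KL regularization requires the prior policy")
        prior_logits = prior.forward(inputs)
        prior_probs = np.exp(log_softmax(prior_logits))
    if reg.lambda_kl > 0.0 or reg.lambda_ent > 0.0 or reg.lambda_all > 0.0:
        lengths = [len(s) - 1 for s in sequences]
        agent_rows = [q[b, :L] for b, L in enumerate(lengths)]
        if reg.lambda_kl > 0.0:
            prior_rows = [prior_probs[b, :L] for b, L in enumerate(lengths)]
            loss_kl = kl_term(prior_rows, agent_rows, reg.lambda_kl)
        loss_ent = entropy_term(agent_rows, reg.lambda_ent)
        loss_all = all_term(totals, reg.lambda_all)
        dlogits += regularizer_gradients(q, prior_probs, targets, mask, totals, reg)

    total = loss_pg + loss_kl + loss_ent + loss_all
    if not np.isfinite(total):
        raise FloatingPointError(
            f"non-finite loss (pg={loss_pg}, kl={loss_kl}, ent={loss_ent}, "
            f"all={loss_all}); batch: {[ep.smiles for ep in episodes]!r}"
        )
    grads = agent.backward(dlogits, cache)
    components = {
        "total": total,
        "pg": loss_pg,
        "kl": loss_kl,
        "ent": loss_ent,
        "all": loss_all,
    }
    return components, grads, totals


def compute_advantages(
    rewards: np.ndarray,
    baseline: BaselineState,
    mab_batch_mean: float | None = None,
) -> tuple[np.ndarray, float]:
    """Baseline-subtracted advantages plus the scalar baseline logged.

    The moving average estimates the *policy's* expected reward, so when the
    gradient batch is a selected subset (hill-climb) or augmented with
    replay, the caller supplies ``mab_batch_mean`` — the mean reward of the
    full on-policy batch — to drive the update; otherwise the mean of the
    gradient batch itself is used.
    """
    r = np.asarray(rewards, dtype=np.float64)
    if baseline.kind == "none":
        return r.copy(), 0.0
    if baseline.kind == "loo":
        b = loo_baseline(r)
        return r - b, float(b.mean())
    if baseline.kind == "mab":
        mean = float(r.mean()) if mab_batch_mean is None else float(mab_batch_mean)
        value = baseline.mab_update(mean)
        return r - value, value
    raise ValueError(f"unknown baseline kind {baseline.kind!r}")


def train_step(
    agent: GRUPolicy,
    optimizer: Adam,
    episodes: list[Episode],
    *,
    step: int,
    learning_rate: float,
    baseline: BaselineState,
    reg: RegularizerConfig = RegularizerConfig(),
    prior: GRUPolicy | None = None,
    mab_batch_mean: float | None = None,
) -> StepRecord:
    """One optimizer update on a combined (on-policy + replay) batch."""
    rewards = np.array([ep.shaped_reward for ep in episodes], dtype=np.float64)
    advantages, baseline_value = compute_advantages(rewards, baseline, mab_batch_mean)
    components, grads, totals = compute_loss_and_grads(
        agent, episodes, advantages, reg=reg, prior=prior
    )
    if learning_rate > 0.0:
        optimizer.step(agent.params, grads, learning_rate)
    prior_nll = float("nan")
    if prior is not None:
        _, prior_totals = prior.sequence_log_likelihood([ep.tokens for ep in episodes])
        prior_nll = float(-prior_totals.mean())
    n_replay = sum(1 for ep in episodes if ep.source == "replay")
    return StepRecord(
        step=step,
        n_onpolicy=len(episodes) - n_replay,
        n_replay=n_replay,
        loss_total=components["total"],
        loss_pg=components["pg"],
        loss_kl=components["kl"],
        loss_ent=components["ent"],
        loss_all=components["all"],
        mean_raw_reward=float(np.mean([ep.raw_reward for ep in episodes])),
        mean_shaped_reward=float(rewards.mean()),
        agent_nll=float(-totals.mean()),
        prior_nll=prior_nll,
        baseline=baseline_value,
        learning_rate=learning_rate,
    )
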