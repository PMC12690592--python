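"""Loss-level regularizers keeping the agent close to (or away from) the prior.

Three additive terms, each gated by a non-negative coefficient:

* KL divergence KL(prior || agent), summed over the realized trajectory's
  per-step full-vocabulary action distributions — pulls the agent's
  *distributions* toward the prior's;
* an entropy bonus, ``-lambda_ent * sum_t H_t`` — rewards spread-out
  per-step distributions, encouraging exploration;
* an agent log-likelihood (ALL) penalty, ``-lambda_all / total_logprob`` —
  grows as a sequence becomes more likely, discouraging over-exploitation
  of single sequences.

All terms are summed over generated tokens only and averaged over the
batch. A probability floor of 1e-10 guards every log and ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

PROB_FLOOR = 1e-10


@dataclass(frozen=True)
class RegularizerConfig:
    lambda_kl: float = 0.0
    lambda_ent: float = 0.0
    lambda_all: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_kl", "lambda_ent", "lambda_all"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _as_list(dists) -> list[np.ndarray]:
    if isinstance(dists, np.ndarray) and dists.ndim == 2:
        return [dists]
    return [np.asarray(d) for d in dists]


def kl_term(prior_dists, agent_dists, lambda_kl: float) -> float:
    """KL(prior || agent) summed over steps, averaged over the batch.

    ``prior_dists`` / ``agent_dists`` are matched per-episode arrays of
    shape (T_i, V). Non-negative; zero iff the distributions coincide.
    """
    if lambda_kl == 0.0:
        return 0.0
    priors, agents = _as_list(prior_dists), _as_list(agent_dists)
    if len(priors) != len(agents):
        raise ValueError("mismatched batch sizes")
    total = 0.0
    for p, q in zip(priors, agents):
        if p.shape != q.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {q.shape}")
        pf = np.maximum(p, PROB_FLOOR)
        qf = np.maximum(q, PROB_FLOOR)
        total += float((p * (np.log(pf) - np.log(qf))).sum())
    return lambda_kl * total / len(priors)


def entropy_term(agent_dists, lambda_ent: float) -> float:
    """``-lambda_ent * sum_t H_t`` averaged over the batch (<= 0).

    Magnitude is bounded by ``lambda_ent * T * log V``, attained exactly at
    uniform per-step distributions.
    """
    if lambda_ent == 0.0:
        return 0.0
    agents = _as_list(agent_dists)
    total = 0.0
    for q in agents:
        qf = np.maximum(q, PROB_FLOOR)
        entropy = float(-(q * np.log(qf)).sum())
        total += entropy
    return -lambda_ent * total / len(agents)


def all_term(total_log_likelihood, lambda_all: float) -> float:
    """Agent log-likelihood penalty ``-lambda_all / sum_t log pi`` (> 0).

    Accepts a scalar or a vector of per-episode totals (averaged). Totals
    are floored away from zero: a sequence of probability one would make
    the term blow up.
    """
    if lambda_all == 0.0:
        return 0.0
    totals = np.atleast_1d(np.asarray(total_log_likelihood, dtype=np.float64))
    totals = np.minimum(totals, -PROB_FLOOR)
    return float(np.mean(-lambda_all / totals))


def regularizer_gradients(
    agent_probs: np.ndarray,
    prior_probs: np.ndarray | None,
    targets: np.ndarray,
    mask: np.ndarray,
    totals: np.ndarray,
    config: RegularizerConfig,
) -> np.ndarray:
    """d(regularizer loss)/d(agent logits) for a padded (B, T, V) batch.

    Closed forms (per step, per batch element, before the 1/B average):

    * KL:  ``q - p``            (only the cross term depends on agent logits)
    * ENT: ``q * (log q + H)``  scaled by lambda_ent
    * ALL: ``(onehot - q) * lambda_all / total^2``
    """
    B, T, V = agent_probs.shape
    dlogits = np.zeros_like(agent_probs)
    if config.lambda_kl > 0.0 and prior_probs is not None:
        dlogits += config.lambda_kl * (agent_probs - prior_probs)
    if config.lambda_ent > 0.0:
        logq = np.log(np.maximum(agent_probs, PROB_FLOOR))
        H = -(agent_probs * logq).sum(axis=2, keepdims=True)
        dlogits += config.lambda_ent * agent_probs * (logq + H)
    if config.lambda_all > 0.0:
        onehot_minus_q = -agent_probs.copy()
        onehot_minus_q[np.arange(B)[:, None], np.arange(T)[None, :], targets] += 1.0
        safe_totals = np.minimum(totals, -PROB_FLOOR)
        scale = (config.lambda_all / (safe_totals * safe_totals))[:, None, None]
        dlogits += scale * onehot_minus_q
    dlogits *= mask[:, :, None] / B
    return dlogits
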