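"""Orchestration of the full RL loop, logging, and hyperparameter search.

One run consumes exactly ``budget`` on-policy molecules in batches; replay
molecules are off-policy reuse and do not count against the budget. Per
batch the loop is: sample -> score -> ledger -> diversity penalty -> RND
bonus -> reshape -> hill-climb -> replay insert/sample -> baseline ->
gradient step. Every random draw descends deterministically from the run
seed, so (config, seed) reproduces a run bit for bit on a fixed platform.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, toy
from .config import RunConfig
from .engine import (
    BaselineState,
    OptimizerSchedule,
    StepRecord,
    hill_climb_select,
    lr_at_step,
    train_step,
)
from .metrics import MetricLedger
from .optim import Adam
from .policy import GRUPolicy
from .regularization import RegularizerConfig
from .replay import ReplayBuffer, replay_loglik_refresh
from .shaping import DiversityFilter, RNDState, ShapingConfig, featurize_for_rnd
from .vocab import Vocabulary, read_smi


@dataclass
class RunResult:
    ledger: MetricLedger
    log: pd.DataFrame
    agent: GRUPolicy
    prior: GRUPolicy
    buffer: ReplayBuffer | None


def build_prior(config: RunConfig) -> GRUPolicy:
    """Load a prior checkpoint or pretrain one on the (toy or file) corpus."""
    if config.prior_checkpoint:
        return GRUPolicy.load(config.prior_checkpoint)
    pre = config.pretrain
    if pre.corpus_path:
        corpus = read_smi(pre.corpus_path)
    else:
        corpus = toy.make_corpus(pre.corpus_seed, pre.corpus_size)
    vocab = Vocabulary.from_corpus(corpus)
    prior = GRUPolicy(
        vocab,
        embedding_size=config.policy.embedding_size,
        hidden_size=config.policy.hidden_size,
        seed=config.seed,
        role="prior",
    )
    prior.pretrain(
        corpus,
        epochs=pre.epochs,
        seed=config.seed,
        batch_size=pre.batch_size,
        learning_rate=pre.learning_rate,
    )
    return prior


def run(config: RunConfig, prior: GRUPolicy | None = None) -> RunResult:
    """Execute one full RL run; returns the ledger, log, and trained agent."""
    if prior is None:
        prior = build_prior(config)
    agent = prior.copy(role="agent")

    reward_fn = toy.get_reward(config.reward.name, config.reward.params)
    shaping_cfg = ShapingConfig(
        formulation=config.shaping.formulation,
        sigma=config.shaping.sigma,
        alpha=config.shaping.alpha,
        per_token_prior=config.shaping.per_token_prior,
    )
    reg = RegularizerConfig(
        lambda_kl=config.regularization.lambda_kl,
        lambda_ent=config.regularization.lambda_ent,
        lambda_all=config.regularization.lambda_all,
    )
    baseline = BaselineState(kind=config.baseline.kind, beta=config.baseline.beta)
    schedule = OptimizerSchedule(
        kind=config.schedule.kind,
        base_rate=config.schedule.base_rate,
        anneal_start=config.schedule.anneal_start,
        anneal_end=config.schedule.anneal_end,
        anneal_fraction=config.schedule.anneal_fraction,
    )
    diversity = DiversityFilter(
        mode=config.diversity.mode, bin_threshold=config.diversity.bin_threshold
    )
    rnd = None
    if config.rnd.lambda_rnd > 0.0:
        rnd = RNDState(
            lambda_rnd=config.rnd.lambda_rnd,
            n_features=config.rnd.n_features,
            learning_rate=config.rnd.learning_rate,
            seed=config.seed,
        )
    buffer = None
    if config.replay.enabled:
        buffer = ReplayBuffer(
            capacity=config.replay.capacity,
            batch_size=config.replay.batch_size,
            mode=config.replay.mode,
        )

    root = np.random.SeedSequence(config.seed)
    sample_rng, replay_rng = (np.random.default_rng(s) for s in root.spawn(2))
    optimizer = Adam(agent.params)
    ledger = MetricLedger(budget=config.budget)
    n_steps = config.budget // config.batch_size
    rows: list[StepRecord] = []
    consumed = 0

    for step in range(n_steps):
        episodes = agent.sample(config.batch_size, config.policy.max_len, seed=sample_rng)
        consumed += len(episodes)

        # score and ledger the on-policy batch
        for ep in episodes:
            ep.canonical = chem.canonical_smiles(ep.smiles)
            ep.valid = ep.canonical is not None
            if config.zero_invalid and not ep.valid:
                ep.raw_reward = 0.0
            else:
                ep.raw_reward = float(np.clip(reward_fn(ep.smiles), 0.0, 1.0))
            ledger.record(ep.canonical, ep.raw_reward, step)
        ledger.mark_batch()

        # diversity penalty and RND novelty bonus act before reshaping
        pre_reshape = []
        rnd_features = []
        for ep in episodes:
            r = diversity.penalize(ep.canonical, ep.raw_reward)
            if rnd is not None and ep.valid:
                feats = featurize_for_rnd(ep.canonical, config.rnd.n_features)
                if feats is not None:
                    rnd_features.append(feats)
                    r = min(1.0, r + float(rnd.bonus(feats)[0]))
            pre_reshape.append(r)

        # reshape on-policy rewards against prior/agent sequence likelihoods
        _, prior_totals = prior.sequence_log_likelihood([ep.tokens for ep in episodes])
        for ep, r, lp_prior in zip(episodes, pre_reshape, prior_totals):
            ep.shaped_reward = shaping_cfg.apply(
                r, float(lp_prior), ep.total_logprob, ep.n_generated
            )

        selected = hill_climb_select(episodes, config.hill_climb.k_ratio)

        replay_episodes = []
        if buffer is not None:
            buffer.insert(episodes, step=step)
            for entry in buffer.sample(config.replay.batch_size, seed=replay_rng):
                rep = ReplayBuffer.entry_to_episode(entry, agent)
                _, rep_prior = prior.sequence_log_likelihood([rep.tokens])
                rep.shaped_reward = shaping_cfg.apply(
                    rep.raw_reward, float(rep_prior[0]), rep.total_logprob, rep.n_generated
                )
                replay_episodes.append(rep)

        batch = selected + replay_episodes
        replay_loglik_refresh(agent, replay_episodes)
        lr = lr_at_step(schedule, step, n_steps)
        # the moving-average baseline tracks the full on-policy batch mean —
        # an estimate of the policy's expected shaped reward — not the mean
        # of the selected/augmented gradient batch
        onpolicy_mean = float(np.mean([ep.shaped_reward for ep in episodes]))
        record = train_step(
            agent,
            optimizer,
            batch,
            step=step,
            learning_rate=lr,
            baseline=baseline,
            reg=reg,
            prior=prior,
            mab_batch_mean=onpolicy_mean,
        )
        record.molecules_consumed = consumed
        rows.append(record)
        if rnd is not None and rnd_features:
            rnd.train(np.stack(rnd_features), n_steps=1)

    log = pd.DataFrame([r.as_dict() for r in rows])
    result = RunResult(ledger=ledger, log=log, agent=agent, prior=prior, buffer=buffer)
    if config.output_dir:
        _write_outputs(config, result)
    return result


def _write_outputs(config: RunConfig, result: RunResult) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.log.to_csv(out / "training_log.csv", index=False)
    result.ledger.save_curve(out / "top10_curve.csv")
    result.ledger.save_report(out / "metrics.csv", out / "metrics.json")
    result.agent.save(out / "agent.npz")
    if result.buffer is not None:
        result.buffer.dump(out / "replay_buffer.tsv")
    manifest = {
        "config": config.model_dump(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


# ------------------------------------------------------------ random search

def sample_search_space(space: dict[str, list], n_samples: int, seed: int) -> list[dict]:
    """Uniform sample without replacement from the Cartesian product.

    If ``n_samples`` covers the whole product, every configuration is
    returned exactly once.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    keys = sorted(space)
    if any(not space[k] for k in keys):
        raise ValueError("candidate lists must be nonempty")
    sizes = np.array([len(space[k]) for k in keys], dtype=np.int64)
    total = int(np.prod(sizes))
    take = min(n_samples, total)
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=take, replace=False)
    combos = []
    for f in flat:
        combo = {}
        rem = int(f)
        for k, size in zip(keys, sizes):
            combo[k] = space[k][rem % size]
            rem //= size
        combos.append(combo)
    return combos


def random_search(
    space: dict[str, list],
    n_samples: int,
    seed: int,
    task_configs: list[RunConfig],
    leaderboard_path: str | Path | None = None,
) -> pd.DataFrame:
    """Run sampled configurations on each task; rank by mean Top-10 AUC."""
    combos = sample_search_space(space, n_samples, seed)
    priors: dict[int, GRUPolicy] = {}
    rows = []
    for i, combo in enumerate(combos):
        aucs = []
        for j, task in enumerate(task_configs):
            cfg = task.override(combo)
            if j not in priors:
                priors[j] = build_prior(task)
            result = run(cfg, prior=priors[j])
            aucs.append(result.ledger.top10_auc())
        rows.append({"config_id": i, **combo, "mean_top10_auc": float(np.mean(aucs))})
    board = pd.DataFrame(rows).sort_values(
        "mean_top10_auc", ascending=False, kind="stable"
    ).reset_index(drop=True)
    if leaderboard_path is not None:
        board.to_csv(leaderboard_path, index=False)
    return board
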