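import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clmrl.engine import (
    BaselineState,
    OptimizerSchedule,
    compute_loss_and_grads,
    hill_climb_select,
    loo_baseline,
    lr_at_step,
    train_step,
)
from clmrl.optim import Adam
from clmrl.policy import GRUPolicy
from clmrl.regularization import RegularizerConfig
from clmrl.vocab import Vocabulary


def _episodes(policy, n, seed=3, reward=0.5):
    eps = policy.sample(n, max_len=8, seed=seed)
    for e in eps:
        e.raw_reward = e.shaped_reward = reward
    return eps


# ------------------------------------------------------------------ baselines

def test_loo_direct_formula():
    assert np.allclose(loo_baseline([0.0, 1.0]), [1.0, 0.0])
    r = np.array([0.0, 1.0])
    assert np.allclose(r - loo_baseline(r), [-1.0, 1.0])


def test_loo_symmetry_all_equal():
    b = loo_baseline([1.0, 1.0, 1.0])
    assert np.allclose(b, 1.0)
    assert np.allclose(np.array([1.0, 1.0, 1.0]) - b, 0.0)


def test_loo_requires_two():
    with pytest.raises(ValueError):
        loo_baseline([0.3])


@given(st.lists(st.floats(-10, 10), min_size=2, max_size=20), st.floats(-5, 5))
@settings(max_examples=100, deadline=None)
def test_loo_shift_invariance(rewards, c):
    r = np.asarray(rewards)
    adv1 = r - loo_baseline(r)
    adv2 = (r + c) - loo_baseline(r + c)
    assert np.allclose(adv1, adv2, atol=1e-9)


def test_mab_beta_one_tracks_latest():
    state = BaselineState(kind="mab", beta=1.0)
    state.mab_update(0.3)
    state.mab_update(0.9)
    assert state.mab_value() == pytest.approx(0.9)


def test_mab_first_update_sets_mean_then_recurses():
    state = BaselineState(kind="mab", beta=0.5)
    state.mab_update(0.0)
    assert state.mab_value() == 0.0
    state.mab_update(1.0)
    assert state.mab_value() == pytest.approx(0.5)


def test_mab_converges_to_constant_stream():
    state = BaselineState(kind="mab", beta=0.1)
    for _ in range(200):
        state.mab_update(0.7)
    assert state.mab_value() == pytest.approx(0.7, abs=1e-8)


# ----------------------------------------------------------------- hill-climb

def test_hill_climb_identity(tiny_policy):
    eps = _episodes(tiny_policy, 4)
    assert hill_climb_select(eps, 1.0) == eps


def test_hill_climb_sort_and_cut(tiny_policy):
    eps = _episodes(tiny_policy, 4)
    for e, r in zip(eps, [0.1, 0.9, 0.5, 0.7]):
        e.shaped_reward = r
    kept = hill_climb_select(eps, 0.5)
    assert [e.shaped_reward for e in kept] == [0.9, 0.7]


def test_hill_climb_tie_break_stable(tiny_policy):
    eps = _episodes(tiny_policy, 4, reward=0.5)
    kept = hill_climb_select(eps, 0.25)
    assert kept == [eps[0]]


def test_hill_climb_empty_and_bad_ratio(tiny_policy):
    with pytest.raises(ValueError):
        hill_climb_select([], 0.5)
    with pytest.raises(ValueError):
        hill_climb_select(_episodes(tiny_policy, 2), 0.0)


# ------------------------------------------------------------------ schedules

def test_constant_schedule():
    sched = OptimizerSchedule(kind="constant", base_rate=1e-4)
    for step in (0, 50, 100):
        assert lr_at_step(sched, step, 100) == 1e-4


def test_cosine_schedule_endpoints_and_midpoint():
    sched = OptimizerSchedule(kind="cosine", anneal_start=5e-4, anneal_end=1e-4,
                              anneal_fraction=0.5)
    assert lr_at_step(sched, 0, 100) == pytest.approx(5e-4)
    assert lr_at_step(sched, 50, 100) == pytest.approx(1e-4)
    assert lr_at_step(sched, 100, 100) == pytest.approx(1e-4)
    # half-cosine midpoint of the anneal window
    assert lr_at_step(sched, 25, 100) == pytest.approx(3e-4)


def test_schedule_validation():
    with pytest.raises(ValueError):
        OptimizerSchedule(kind="cosine", anneal_start=1e-4, anneal_end=5e-4)


# ----------------------------------------------------------------------- loss

def test_loss_zero_when_rewards_equal_baseline(tiny_policy):
    eps = _episodes(tiny_policy, 3)
    comp, _, _ = compute_loss_and_grads(tiny_policy, eps, np.zeros(3))
    assert comp["total"] == pytest.approx(0.0)


def test_loss_single_episode_plug_in(tiny_policy):
    eps = _episodes(tiny_policy, 1, reward=1.0)
    comp, _, totals = compute_loss_and_grads(tiny_policy, eps, np.ones(1))
    assert comp["total"] == pytest.approx(-float(totals[0]))
    assert comp["total"] == pytest.approx(-eps[0].total_logprob)


def _finite_difference_check(policy, episodes, advantages, reg, prior, tol):
    comp, grads, _ = compute_loss_and_grads(policy, episodes, advantages, reg=reg, prior=prior)

    def value():
        c, _, _ = compute_loss_and_grads(policy, episodes, advantages, reg=reg, prior=prior)
        return c["total"]

    rng = np.random.default_rng(1)
    worst = 0.0
    for name, grad in grads.items():
        flat = policy.params[name].ravel()
        gflat = grad.ravel()
        for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            h = 1e-6
            orig = flat[i]
            flat[i] = orig + h
            up = value()
            flat[i] = orig - h
            down = value()
            flat[i] = orig
            numeric = (up - down) / (2 * h)
            analytic = gflat[i]
            scale = max(abs(numeric), abs(analytic), 1e-8)
            worst = max(worst, abs(numeric - analytic) / scale)
    assert worst < tol


def test_gradient_matches_finite_differences_plain(vocab):
    """Analytic REINFORCE gradient vs central differences on a toy policy."""
    tiny = Vocabulary.from_corpus(["CCO", "CN"])
    policy = GRUPolicy(tiny, embedding_size=3, hidden_size=4, seed=2)
    eps = policy.sample(3, max_len=4, seed=5)
    for e in eps:
        e.shaped_reward = 0.4
    adv = np.array([0.9, -0.2, 0.5])
    _finite_difference_check(policy, eps, adv, RegularizerConfig(), None, 1e-4)


def test_gradient_matches_finite_differences_with_regularizers(vocab):
    """The combined loss (policy gradient + KL + entropy + ALL) keeps exact
    analytic gradients."""
    tiny = Vocabulary.from_corpus(["CCO", "CN"])
    prior = GRUPolicy(tiny, embedding_size=3, hidden_size=4, seed=8)
    policy = prior.copy()
    policy.params["Wo"] += 0.05  # separate agent from prior
    eps = policy.sample(3, max_len=4, seed=5)
    for e in eps:
        e.shaped_reward = 0.4
    adv = np.array([0.9, -0.2, 0.5])
    reg = RegularizerConfig(lambda_kl=0.3, lambda_ent=0.2, lambda_all=0.1)
    _finite_difference_check(policy, eps, adv, reg, prior, 1e-4)


def test_loo_gradient_shift_invariance(tiny_policy):
    """Adding a constant to all rewards changes no LOO advantage and hence no
    gradient on a fixed batch."""
    eps = _episodes(tiny_policy, 4, seed=13)
    rewards = np.array([0.1, 0.4, 0.9, 0.2])
    adv1 = rewards - loo_baseline(rewards)
    adv2 = (rewards + 3.7) - loo_baseline(rewards + 3.7)
    _, g1, _ = compute_loss_and_grads(tiny_policy, eps, adv1)
    _, g2, _ = compute_loss_and_grads(tiny_policy, eps, adv2)
    for k in g1:
        assert np.allclose(g1[k], g2[k], atol=1e-10)


# ----------------------------------------------------------------- train_step

def test_train_step_zero_learning_rate_freezes_parameters(tiny_policy):
    agent = tiny_policy.copy()
    eps = _episodes(agent, 4)
    before = {k: v.copy() for k, v in agent.params.items()}
    train_step(agent, Adam(agent.params), eps, step=0, learning_rate=0.0,
               baseline=BaselineState(kind="none"))
    for k in before:
        assert np.array_equal(before[k], agent.params[k])


def test_train_step_reduces_to_plain_reinforce(tiny_policy):
    """All coefficients zero, no baseline, k=1: the logged loss is the plain
    REINFORCE loss."""
    agent = tiny_policy.copy()
    eps = _episodes(agent, 4, reward=0.6)
    comp, _, _ = compute_loss_and_grads(agent, eps, np.full(4, 0.6))
    rec = train_step(agent, Adam(agent.params), eps, step=0, learning_rate=1e-4,
                     baseline=BaselineState(kind="none"))
    assert rec.loss_total == pytest.approx(comp["total"])
    assert rec.loss_kl == rec.loss_ent == rec.loss_all == 0.0


def test_train_step_rejects_missing_rewards(tiny_policy):
    agent = tiny_policy.copy()
    eps = agent.sample(3, max_len=6, seed=2)  # rewards never assigned
    with pytest.raises(ValueError):
        train_step(agent, Adam(agent.params), eps, step=0, learning_rate=1e-4,
                   baseline=BaselineState(kind="none"))
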