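import numpy as np
import pytest

from clmrl.shaping import (
    DiversityFilter,
    RNDState,
    ShapingConfig,
    featurize_for_rnd,
    landscape_grid,
    proposed_reshape,
    reinvent_reshape,
    save_landscape,
)


# ------------------------------------------------------------- formulations

@pytest.mark.parametrize(
    "raw, lp_prior, lp_agent, sigma, expected",
    [
        (0.0, -10.0, -10.0, 60.0, 0.0),          # zero numerator
        (0.5, -10.0, -20.0, 60.0, -80.0),        # (10 + 30)^2 / -20
        (0.0, -30.0, -20.0, 0.0, -5.0),          # (-10)^2 / -20
    ],
)
def test_reinvent_reshape_values(raw, lp_prior, lp_agent, sigma, expected):
    assert reinvent_reshape(raw, lp_prior, lp_agent, sigma) == pytest.approx(expected, abs=1e-12)


def test_reinvent_reshape_zero_agent_loglik():
    with pytest.raises(ZeroDivisionError):
        reinvent_reshape(0.5, -10.0, 0.0, 60.0)


@pytest.mark.parametrize(
    "raw, lp_prior, sigma, alpha, expected",
    [
        (0.5, -10.0, 0.0, 1.0, 0.5),     # identity reduction
        (1.0, -5.0, 0.2, 1.0, 0.0),      # clip floor
        (0.8, -2.0, 0.05, 3.0, 0.343),   # 0.7^3
    ],
)
def test_proposed_reshape_values(raw, lp_prior, sigma, alpha, expected):
    assert proposed_reshape(raw, lp_prior, sigma, alpha) == pytest.approx(expected, abs=1e-12)


def test_proposed_reshape_rejects_bad_alpha():
    with pytest.raises(ValueError):
        proposed_reshape(0.5, -1.0, 0.1, 0.5)
    with pytest.raises(ValueError):
        ShapingConfig(formulation="proposed", alpha=0.5)


def test_proposed_reshape_properties_on_random_grid(rng):
    """Bounded in [0,1]; monotone in reward and prior log-likelihood;
    larger sigma never increases the output."""
    n = 10_000
    R = rng.uniform(0, 1, n)
    LP = rng.uniform(-60, 0, n)
    sigma = 0.02
    alpha = 3.0
    vals = np.array([proposed_reshape(r, lp, sigma, alpha) for r, lp in zip(R, LP)])
    assert ((vals >= 0.0) & (vals <= 1.0)).all()
    dr = np.array([proposed_reshape(min(r + 0.05, 1.0), lp, sigma, alpha) for r, lp in zip(R, LP)])
    assert (dr >= vals - 1e-12).all()
    dl = np.array([proposed_reshape(r, lp * 0.9, sigma, alpha) for r, lp in zip(R, LP)])
    assert (dl >= vals - 1e-12).all()  # lp * 0.9 is closer to 0, i.e. larger
    bigger_sigma = np.array([proposed_reshape(r, lp, 2 * sigma, alpha) for r, lp in zip(R, LP)])
    assert (bigger_sigma <= vals + 1e-12).all()


def test_shaping_config_apply_dispatch():
    cfg = ShapingConfig(formulation="none")
    assert cfg.apply(0.42, -10.0, -12.0) == 0.42
    cfg = ShapingConfig(formulation="proposed", sigma=0.05, alpha=3.0)
    assert cfg.apply(0.8, -2.0, -3.0) == pytest.approx(0.343)
    per_tok = ShapingConfig(formulation="proposed", sigma=0.05, alpha=3.0, per_token_prior=True)
    assert per_tok.apply(0.8, -8.0, -3.0, n_tokens=4) == pytest.approx(0.343)


# ---------------------------------------------------------- diversity filter

def test_occurrence_filter_zeroes_repeats():
    df = DiversityFilter(mode="occurrence")
    assert df.penalize("CCO", 0.8) == 0.8
    assert df.penalize("CCO", 0.8) == 0.0
    assert df.penalize("CCN", 0.6) == 0.6


def test_bin_filter_threshold():
    df = DiversityFilter(mode="bin", bin_threshold=2)
    # toluene and ethylbenzene share the benzene scaffold
    assert df.penalize("Cc1ccccc1", 0.9) == 0.9
    assert df.penalize("CCc1ccccc1", 0.9) == 0.9
    assert df.penalize("CCCc1ccccc1", 0.9) == 0.0


def test_filter_off_and_invalid_bypass():
    df = DiversityFilter(mode="off")
    assert df.penalize("CCO", 0.5) == 0.5
    df = DiversityFilter(mode="occurrence")
    assert df.penalize(None, 0.0) == 0.0


# ------------------------------------------------------------------------ RND

def test_rnd_zero_coefficient_gives_zero_bonus(rng):
    state = RNDState(lambda_rnd=0.0, n_features=32, seed=0)
    x = rng.integers(0, 2, 32).astype(float)
    assert state.bonus(x)[0] == 0.0


def test_rnd_feature_length_mismatch():
    state = RNDState(lambda_rnd=1.0, n_features=32, seed=0)
    with pytest.raises(ValueError):
        state.bonus(np.ones(16))


def test_rnd_training_shrinks_error_and_preserves_novelty(rng):
    """A repeatedly trained input's predictor error drops >= 10x while a
    fresh random input keeps a larger bonus in >= 9/10 trials."""
    state = RNDState(lambda_rnd=1.0, n_features=64, learning_rate=5e-2, seed=3)
    x = rng.integers(0, 2, 64).astype(float)
    before = state.bonus(x)[0]
    state.train(x, n_steps=500)
    after = state.bonus(x)[0]
    assert after <= before / 10.0
    wins = 0
    for _ in range(10):
        fresh = rng.integers(0, 2, 64).astype(float)
        wins += state.bonus(fresh)[0] > after
    assert wins >= 9


def test_rnd_featurization_of_molecules():
    feats = featurize_for_rnd("CCO", n_features=128)
    assert feats.shape == (128,)
    assert set(np.unique(feats)) <= {0.0, 1.0}
    assert featurize_for_rnd("not-a-molecule", n_features=128) is None


# -------------------------------------------------------------------- landscape

def test_landscape_sign_structure():
    """The decoupled clip-power surface is never negative; the quadratic
    prior-coupled surface has negative cells in the low-prior region."""
    rewards = np.linspace(0, 1, 11)
    logps = np.linspace(-60, -1, 11)
    proposed = landscape_grid("proposed", 0.01, 2.0, rewards, logps)
    assert (proposed >= 0.0).all() and (proposed <= 1.0).all()
    # rows non-decreasing along increasing reward
    assert (np.diff(proposed, axis=0) >= -1e-12).all()
    reinvent = landscape_grid("reinvent", 5.0, 1.0, rewards, logps, logp_agent=-20.0)
    assert (reinvent < 0.0).any()


def test_landscape_io(tmp_path):
    rewards = np.linspace(0, 1, 5)
    logps = np.linspace(-30, 0, 5)
    grid = landscape_grid("proposed", 0.01, 1.0, rewards, logps)
    csv = tmp_path / "grid.csv"
    png = tmp_path / "grid.png"
    save_landscape(csv, grid, rewards, logps, render_png=str(png))
    assert csv.exists() and png.exists()
    import pandas as pd

    loaded = pd.read_csv(csv, index_col=0)
    assert np.allclose(loaded.to_numpy(), grid)
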