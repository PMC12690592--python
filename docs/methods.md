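# Methods

## Problem setting

Molecule generation with a chemical language model is treated as an MDP:
states are token prefixes, actions are vocabulary tokens, transitions append
the chosen token, and the episode ends at the end-of-sequence marker (or a
length cap). The reward is assigned only to complete generations; there are
no true per-token rewards. This terminal-reward structure, together with a
non-random initialization (the agent starts as a copy of a pretrained
prior), is why the plain REINFORCE estimator — rather than actor-critic or
clipped-ratio methods — is the core algorithm here: the whole generation is
effectively a single action, and large on-policy updates from a good
starting point are the operating regime.

## Policy model

The policy is a single-layer GRU: token embedding → GRU cell → linear head
over the vocabulary. Defaults are embedding 64, hidden 128 — small enough
that pretraining the toy prior takes under a minute on one CPU while still
reaching ≈98% valid samples. Sampling is multinomial at temperature 1; no
nucleus or top-k truncation. Sequences that hit the length cap without an
end marker are flagged incomplete and decoded anyway (almost always invalid,
hence zero reward).

Forward, sampling, sequence log-likelihoods, and full backpropagation
through time are implemented in numpy in float64. This was a deliberate
choice: the model is small, float64 makes log-likelihoods bit-stable across
calls (a tested invariant), and the analytic gradients are verified against
central finite differences to < 1e-4 relative error, including with all
regularizers active. The optimizer is Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) with
the learning rate supplied per step by the schedule.

All loss terms are assembled at the logit level. For a batch of n episodes
with advantages A_i the policy-gradient part contributes
−(A_i/n)·(onehot − softmax) at each realized step; the KL, entropy, and
inverse-likelihood terms add their closed-form logit gradients; one backward
pass maps the combined array to parameter space. Padded positions carry zero
gradient, which keeps the recurrent carry exactly zero through padding.

## Pretraining and the prior

The prior is trained by maximum likelihood (next-token prediction) on a
corpus; the agent starts as an exact parameter copy, so KL(prior‖agent) is
exactly zero at step 0 (tested). The prior is never updated afterwards.

The toy corpus generator emulates the role of a large drug-like pretraining
set at desk scale: 1,000 molecules by default, drawn from a valid-by-
construction template family — carbon-weighted chains of 4–13 heavy atoms
over {C, N, O}, optional single branches on interior carbons, and an
optional terminal aromatic ring (benzene, pyridine, pyrrole, furan,
thiophene). The defaults (corpus 1,000; 30 epochs; batch 64; learning rate
2e-3) were chosen once so that the pretrained prior emits ≥ 95% chemically
valid strings, which is the property the downstream experiments rely on.
What the toy corpus does *not* reproduce: realistic ring-system diversity,
stereochemistry, charged/bracket atom richness, and the heavy-tailed length
distribution of real drug-like sets. Conclusions from the toy system are
therefore directional (which extension helps, which direction a coefficient
pushes), not quantitative predictions for real chemistry.

## Rewards

Rewards are deterministic callables on the decoded SMILES string, bounded in
[0, 1]; invalid molecules always score 0 (validity is a reported metric, not
a shaped signal). The default task is motif similarity: the normalized
longest-common-subsequence between the decoded string and a target motif.
The default motif (`NC(C)OC(C)NC(C)O`) lies inside the template family's
alphabet but is rare under the toy prior, so the running top-10 curve keeps
headroom over a 5,000-molecule budget and efficiency differences between
algorithms remain visible instead of saturating.

## Reward pipeline and shaping

Per on-policy episode the order of operations is: raw reward → diversity
penalty → RND bonus (clamped so the total stays ≤ 1) → reshaping. The order
is a design choice (no canonical ordering exists); it makes the memory- and
novelty-based signals part of the reward the shaping acts on.

Two reshaping formulations are provided. The quadratic prior-coupled form
`(logπ_prior − logπ_agent + σR)²/logπ_agent` is kept for comparison; it can
be negative and entangles the regularization strength with the scale and
gradient of the landscape (the landscape grids in `shaping.landscape_grid`
show its negative region at low prior likelihood). The decoupled clip-power
form `clip(R + σ·logπ_prior, 0, 1)^α` is the recommended one: outputs stay
in [0, 1], σ alone controls prior regularization (log-likelihoods are ≤ 0,
so larger σ can only lower the reward of prior-unlikely molecules), and
α ≥ 1 independently steepens the gradient; the sweep range worth exploring
is α ∈ [1, 5], beyond which gains saturate. Sequence log-likelihoods enter
as totals, not per-token averages (a per-token option exists behind a config
flag).

Replay episodes receive reshaping and baselines identically to on-policy
episodes but bypass the diversity filter and RND bonus: both are
memory/novelty devices and would systematically zero or distort episodes
that are by construction re-used.

## Baselines, hill-climb, replay

The leave-one-out baseline is b_i = (ΣR − R_i)/(n−1), computed over the
post-selection gradient batch including replay episodes. The moving-average
baseline is b ← (1−β)b + βm with β = 0.1 (first update sets b = m), where m
is the mean shaped reward of the **full on-policy batch**, not of the
selected subset. This matters when combined with hill-climb: a baseline
updated from the top-k subset overestimates the policy's expected reward,
assigns negative advantages to good-but-not-best selected episodes, and
destabilizes the combination. The baseline in the estimator approximates
E[R(τ)] under the sampling policy, and the full batch is its unbiased
estimate; with this choice the MAB+hill-climb combination is consistently
better than either alone in the package's own sweeps.

Hill-climb keeps the ceil(k·n) highest-reward episodes of the on-policy
batch (ties broken by original batch order for determinism), ranked by the
shaped reward — the signal actually entering the gradient; with shaping
disabled this is the raw reward. Selection happens before replay episodes
are appended, since replay molecules are already top performers.

The replay buffer stores the top-N unique valid molecules by raw reward,
keyed by RDKit canonical SMILES (duplicates keep the max reward; its
minimum stored reward is non-decreasing once full). Rewards are stored raw
and reshaped at use time, because reshaping depends on the current σ, α and
the current agent likelihood. Sampling is without replacement, uniform or
reward-proportional with successive renormalization; an ε = 1e-6 priority
floor keeps the all-zero-reward case well defined. The default
configuration — capacity 100, replay batch 20, prioritized — is the one
that maximizes performance and efficiency in the explored grid
{100, 500} × {10, 20} × {prioritized, uniform}.

## Regularizers

KL(prior‖agent) is summed over the realized trajectory's per-step
full-vocabulary distributions, averaged over the batch — this direction
(prior as the reference distribution) penalizes the agent for assigning low
probability where the prior assigns high. The entropy term −λΣH_t rewards
spread-out distributions; its magnitude is bounded by λ·T·log V and the
bound is attained exactly at uniform (tested). The inverse-likelihood
penalty −λ/Σlogπ grows as a sequence becomes more likely, discouraging
mode collapse onto single sequences. All per-step sums run over generated
tokens only; a probability floor of 1e-10 guards logs and ratios, and the
likelihood total is floored away from zero. Useful coefficient ranges are
small (1e-2-scale for λ_ENT and λ_ALL); large values visibly destroy
optimization.

## Random network distillation

The novelty bonus is λ·‖f̂(x) − f(x)‖² (mean squared error over a 32-wide
output) between a frozen random target MLP and a trained predictor MLP,
both two-layer over a 1024-bit hashed circular fingerprint (radius 2) of
the molecule — a featurization chosen to be sequence-order invariant. The
predictor takes one SGD pass per RL step on the current batch. Inputs seen
often are predicted well and earn a small bonus; fresh inputs earn a large
one (both directions tested). Invalid molecules get no bonus: their reward
is pinned at 0 and they have no fingerprint.

## Learning-rate schedules

Constant (default 1e-4) or half-cosine annealing from 5e-4 to 1e-4 over the
first half of the run, then holding the end rate. The anneal horizon is a
fraction of the step budget.

## Metrics

The ledger ingests one record per generated molecule and closes a curve
point per batch. Top-10 statistics deduplicate by canonical SMILES (best
reward per molecule) before ranking. Top-10 AUC is the trapezoidal integral
of the running top-10 mean against molecules consumed, normalized by the
budget so a constant curve at r scores exactly r; the curve is extended
flat from zero to the first batch boundary. The streaming value matches an
independent brute-force recomputation to 1e-12 (tested); curve updates
happen at batch boundaries, so step-located features are resolved to one
batch width.

Chemistry-aware metrics: basic filters (substructure alerts, Crippen LogP
range, molecular weight range, rotatable-bond cap), a scaffold-diverse
Top-10 (greedy by descending reward, one molecule per Bemis–Murcko
scaffold), and sphere-exclusion diversity at Tanimoto threshold 0.65 over
2048-bit radius-2 fingerprints (all three config-exposed). Aggregation over
a task suite is the plain sum of per-task metrics, each in [0, 1].

## Budget accounting and determinism

A run consumes exactly `budget` on-policy molecules in `budget //
batch_size` batches; replay samples are off-policy reuse and do not count
against the budget. Every random draw (parameter init, sampling, replay
draws, RND init, corpus generation) descends from the single run seed
through deterministically spawned generators, so (config, seed) reproduces
a run bit for bit on a fixed platform.

## Problem sizes used in the shipped experiments

The learning-behavior checks and the acceptance script use the toy study
conditions: corpus 1,000 / 30 epochs for the prior, budget 5,000 at batch
50 (100 gradient steps), maximum sequence length 48, five seeds for
directional comparisons. These sizes are the package's scaled-down study
system: large enough that the known qualitative effects (hill-climb and
replay improve sample efficiency; σ increases prior likelihood of
generations; α accelerates optimization) are reproducible across seeds,
small enough to run on one CPU in minutes.

## Known limitations

* The toy reward landscape is far smoother than real oracle functions;
  absolute metric values do not transfer.
* The quadratic reshaping is implemented exactly as printed, including its
  negative-reward idiosyncrasy; no attempt is made to "fix" it beyond
  providing the clip-power alternative.
* Off-policy replay gradients carry no importance-weight correction, by
  design (matching common practice in this algorithm family).
* Diversity filters rarely bind at a 5,000-molecule budget with a 100-slot
  memory; their tests exercise the mechanism, not their large-scale effect.
* The hyperparameter search runs full (reduced-budget) trainings serially;
  searching thousands of configurations is out of desk-scale scope, though
  the mechanism is the same.
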