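"""Reversal-learning environment and the two simulated agent families.

The environment is a two-alternative "100-0" task: in each block one side is
rewarded with probability 1 and the other with probability 0; the high-reward
side alternates at block boundaries, with block lengths drawn uniformly from
the closed integer interval [15, 25].  An optional rolling criterion (trailing
15-trial performance >= 0.75 before the side may flip) emulates the animal
task; plain forward simulations do not apply it.

Two agent families are simulated:

* a model-free Q-learner that updates the chosen action's value by
  ``q <- q + gamma * (r - q)`` and acts epsilon-greedily (exploration rate
  ``eps_explore``, distinct from the sigmoid lapse), and
* an inference-based Bayesian observer holding an internal two-state Markov
  model of the world (switch probability ``p_switch``, reward probability
  ``p_rew``) that recursively updates its posterior belief over the hidden
  side from its previous choice and outcome and picks the side with posterior
  above 0.5 (random on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentSpec",
    "QAgentSpec",
    "IBAgentSpec",
    "SimulatedSession",
    "make_environment",
    "q_step",
    "q_policy",
    "ib_update",
    "ib_policy",
    "simulate_agent",
]

LEFT, RIGHT = 0, 1
SIDE_LABELS = np.array(["L", "R"])


@dataclass(frozen=True)
class EnvironmentSpec:
    """Block schedule of the 100-0 reversal task."""

    n_blocks: int = 1000
    block_len_range: tuple[int, int] = (15, 25)
    rolling_criterion: Optional[tuple[int, float]] = None  # (window, threshold)

    def __post_init__(self) -> None:
        lo, hi = self.block_len_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid block length range")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass(frozen=True)
class QAgentSpec:
    """Model-free agent: learning rate gamma, epsilon-greedy exploration.

    ``q_init`` may be a scalar (both actions) or an (q_L, q_R) pair.
    """

    learning_rate: float
    eps_explore: float
    q_init: object = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if not 0 <= self.eps_explore <= 1:
            raise ValueError("eps_explore must lie in [0, 1]")

    def initial_values(self) -> tuple[float, float]:
        if np.isscalar(self.q_init):
            return float(self.q_init), float(self.q_init)
        q_l, q_r = self.q_init
        return float(q_l), float(q_r)


@dataclass(frozen=True)
class IBAgentSpec:
    """Inference-based observer: internal model (p_switch, p_rew)."""

    p_switch: float
    p_rew: float

    def __post_init__(self) -> None:
        if not 0 < self.p_switch < 1:
            raise ValueError("p_switch must lie in (0, 1)")
        if not 0 < self.p_rew < 1:
            raise ValueError("p_rew must lie in (0, 1)")


@dataclass
class SimulatedSession:
    """Per-trial records of one simulated session plus its provenance."""

    trials: pd.DataFrame  # block, trial_in_block, world_state, choice, reward
    agent: object
    env: EnvironmentSpec
    seed: object = None
    extras: dict = field(default_factory=dict)

    def to_session_frame(self, session: int = 1) -> pd.DataFrame:
        """Convert to the session-CSV schema (world_state -> target_side)."""
        df = self.trials.rename(columns={"world_state": "target_side"}).copy()
        df.insert(0, "session", session)
        df["block"] = df["block"] + 1  # session schema is 1-based
        return df.loc[:, ["session", "block", "trial_in_block", "target_side", "choice", "reward"]]


def make_environment(spec: EnvironmentSpec, random_state=None):
    """Draw the alternating block schedule: (side per block, length per block).

    Sides are 0 (left) / 1 (right); the first side is random and subsequent
    blocks alternate deterministically.  With a rolling criterion the lengths
    are minimum lengths only — the block additionally runs until the trailing
    performance gate is met (see :func:`simulate_agent`).
    """
    rng = np.random.default_rng(random_state)
    lo, hi = spec.block_len_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_blocks)
    first = int(rng.integers(2))
    sides = (first + np.arange(spec.n_blocks)) % 2
    return sides, lengths


def q_step(q: float, r: int, gamma: float) -> float:
    """Delta-rule value update of the chosen action: q + gamma * (r - q)."""
    return q + gamma * (r - q)


def q_policy(q_l: float, q_r: float, eps_explore: float, rng) -> int:
    """Epsilon-greedy choice: exploit argmax (uniform on exact ties)."""
    if rng.random() < eps_explore:
        return int(rng.integers(2))
    if q_l > q_r:
        return LEFT
    if q_r > q_l:
        return RIGHT
    return int(rng.integers(2))


def ib_update(p_l: float, choice: int, r: int, p_switch: float, p_rew: float) -> float:
    """Recursive Bayes update of the belief that the world is in the L state.

    The reward likelihood is conditioned on the previous choice (reward
    probability p_rew when choice matches the hidden side, 1 - p_rew
    otherwise); the Markov world transition with switch probability p_switch
    is then applied and the posterior renormalized.
    """
    if not 0 <= p_l <= 1:
        raise ValueError("belief must lie in [0, 1]")
    if choice == LEFT:
        like_l = p_rew if r == 1 else 1.0 - p_rew
        like_r = 1.0 - p_rew if r == 1 else p_rew
    else:
        like_l = 1.0 - p_rew if r == 1 else p_rew
        like_r = p_rew if r == 1 else 1.0 - p_rew
    m_l = p_l * like_l
    m_r = (1.0 - p_l) * like_r
    new_l = m_l * (1.0 - p_switch) + m_r * p_switch
    new_r = m_l * p_switch + m_r * (1.0 - p_switch)
    omega = new_l + new_r
    if omega <= 0:
        raise ZeroDivisionError("degenerate belief normalizer")
    return new_l / omega


def ib_policy(p_l: float, rng) -> int:
    """Choose left if P_L > 0.5, right if < 0.5, random on the exact tie."""
    if p_l > 0.5:
        return LEFT
    if p_l < 0.5:
        return RIGHT
    return int(rng.integers(2))


def _simulate_arrays(agent, spec: EnvironmentSpec, rng):
    """Tight simulation loop returning flat per-trial arrays.

    Returns (block, trial_in_block, world_state, choice, reward) int arrays.
    The rolling criterion, when set, keeps a block open until both its drawn
    length has elapsed and the trailing-window performance clears the gate.
    """
    sides, lengths = make_environment(spec, rng)
    window, threshold = spec.rolling_criterion or (0, 0.0)
    gated = spec.rolling_criterion is not None

    is_q = isinstance(agent, QAgentSpec)
    if is_q:
        q_l, q_r = agent.initial_values()
        gamma = agent.learning_rate
        eps = agent.eps_explore
    else:
        p_l = 0.5
        p_sw, p_rw = agent.p_switch, agent.p_rew

    blocks, pos_list, states, choices, rewards = [], [], [], [], []
    recent: list[int] = []  # trailing outcomes for the rolling gate
    # cap total trials so a hopeless agent cannot loop forever under the gate
    max_trials = int(lengths.sum() * 20 + 1000)
    total = 0
    for b in range(spec.n_blocks):
        side = sides[b]
        need = int(lengths[b])
        pos = 0
        recent = []
        while True:
            pos += 1
            total += 1
            if is_q:
                u = rng.random()
                if u < eps:
                    c = int(rng.integers(2))
                elif q_l > q_r:
                    c = LEFT
                elif q_r > q_l:
                    c = RIGHT
                else:
                    c = int(rng.integers(2))
            else:
                if p_l > 0.5:
                    c = LEFT
                elif p_l < 0.5:
                    c = RIGHT
                else:
                    c = int(rng.integers(2))
            r = 1 if c == side else 0
            if is_q:
                if c == LEFT:
                    q_l += gamma * (r - q_l)
                else:
                    q_r += gamma * (r - q_r)
            else:
                # inline Bayes update (see ib_update) — hot loop
                if (c == LEFT) == (r == 1):
                    like_l, like_r = p_rw, 1.0 - p_rw
                else:
                    like_l, like_r = 1.0 - p_rw, p_rw
                m_l = p_l * like_l
                m_r = (1.0 - p_l) * like_r
                new_l = m_l * (1.0 - p_sw) + m_r * p_sw
                p_l = new_l / (new_l + m_l * p_sw + m_r * (1.0 - p_sw))
            blocks.append(b)
            pos_list.append(pos)
            states.append(side)
            choices.append(c)
            rewards.append(r)
            if gated:
                recent.append(r)
                if len(recent) > window:
                    recent.pop(0)
            done = pos >= need
            if gated and done:
                done = len(recent) >= window and (sum(recent) / window) >= threshold
            if done or total >= max_trials:
                break
        if total >= max_trials:
            break
    return (
        np.asarray(blocks),
        np.asarray(pos_list),
        np.asarray(states),
        np.asarray(choices),
        np.asarray(rewards),
    )


def simulate_agent(agent, env: EnvironmentSpec, random_state=None) -> SimulatedSession:
    """Forward-simulate one agent in the reversal environment.

    Interleaves policy, environment feedback and learning / belief updates
    per trial.  Reproducible: the same seed yields an identical session.
    """
    rng = np.random.default_rng(random_state)
    block, pos, state, choice, reward = _simulate_arrays(agent, env, rng)
    trials = pd.DataFrame(
        {
            "block": block,
            "trial_in_block": pos,
            "world_state": SIDE_LABELS[state],
            "choice": SIDE_LABELS[choice],
            "reward": reward,
        }
    )
    return SimulatedSession(trials=trials, agent=agent, env=env, seed=random_state)


def simulate_signed_outcomes(agent, n_blocks: int, rng, block_len_range=(15, 25)):
    """Fast path for feature extraction: (trial position, signed correct).

    Simulates ``n_blocks`` with plain alternation (no rolling gate) and
    returns the within-block position and the signed-correct indicator per
    trial, skipping DataFrame construction.
    """
    spec = EnvironmentSpec(n_blocks=n_blocks, block_len_range=tuple(block_len_range))
    _, pos, state, choice, _ = _simulate_arrays(agent, spec, rng)
    return pos, (choice == state).astype(np.int8)
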