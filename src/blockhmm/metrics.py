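"""Session- and block-level behavioral benchmarks.

Covers the standard descriptive measures of reversal-learning behavior
(overall performance, initial errors per block, late performance, side
bias), the win-stay-lose-shift benchmark agent, per-block constrained
maximum-likelihood sigmoid fits, the bootstrap test for non-uniform
block-to-block performance, and the early-switch refit that allows negative
switch offsets by prepending pre-reversal trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .hmm import BlockHMM, select_num_modes
from .io import SESSION_COLUMNS, sessions_to_shifted_blocks, validate_sessions
from .regimes import fit_transition_curve
from .transitions import (
    ModeTaxonomy,
    TransitionParams,
    classify_mode,
    foraging_efficiency,
    sigmoid_transition,
)

__all__ = [
    "SessionMetrics",
    "VariabilityTestResult",
    "session_metrics",
    "wsls_benchmark",
    "per_block_mle_fit",
    "uniform_strategy_test",
    "early_switch_refit",
]


@dataclass(frozen=True)
class SessionMetrics:
    """Descriptive benchmarks of one session (or pooled sessions)."""

    performance: float        # fraction of rewarded trials
    initial_errors: float     # mean errors before the first correct, per block
    late_performance: float   # mean accuracy over the last 10 trials per block
    side_bias: float          # left-block accuracy minus right-block accuracy


@dataclass(frozen=True)
class VariabilityTestResult:
    """Bootstrap comparison of observed vs uniform-strategy variability."""

    s_observed: float
    s_simulated: np.ndarray
    p_value: float  # fraction of bootstrap runs with s_simulated >= s_observed


def session_metrics(df: pd.DataFrame) -> SessionMetrics:
    """Compute the four descriptive benchmarks from trial records."""
    df = validate_sessions(df)
    if df.empty:
        raise ValueError("need at least one block of trials")
    correct = (df["choice"] == df["target_side"]).to_numpy(int)
    performance = float(df["reward"].mean())

    init_errors = []
    late = []
    short_blocks = 0
    for _, g in df.assign(correct=correct).groupby(["session", "block"], sort=True):
        c = g["correct"].to_numpy()
        hits = np.flatnonzero(c)
        # a block with no correct response contributes its full length
        init_errors.append(int(hits[0]) if hits.size else len(c))
        if len(c) >= 10:
            late.append(c[-10:].mean())
        else:
            short_blocks += 1
    if short_blocks:
        warnings.warn(
            f"{short_blocks} blocks shorter than 10 trials excluded from late performance"
        )
    left = df["target_side"] == "L"
    bias = float(correct[left].mean() - correct[~left].mean()) if left.any() and (~left).any() else 0.0
    return SessionMetrics(
        performance=performance,
        initial_errors=float(np.mean(init_errors)),
        late_performance=float(np.mean(late)) if late else float("nan"),
        side_bias=bias,
    )


def wsls_benchmark(
    n_blocks: int = 25, block_len_range=(15, 25), random_state=None
) -> tuple[SessionMetrics, np.ndarray]:
    """Ideal win-stay-lose-shift agent: one error at each block start.

    Returns the session metrics and the per-block accuracy, which is exactly
    (len - 1) / len for each sampled block length (93-96% over lengths
    15-25); initial errors are exactly 1 and late performance 100%.
    """
    rng = np.random.default_rng(random_state)
    lo, hi = block_len_range
    lengths = rng.integers(lo, hi + 1, size=n_blocks)
    first = int(rng.integers(2))
    side_labels = np.array(["L", "R"])
    recs = []
    for b, n in enumerate(lengths):
        target = side_labels[(first + b) % 2]
        other = side_labels[1 - (first + b) % 2]
        for t in range(1, int(n) + 1):
            choice = other if t == 1 else target
            recs.append((1, b + 1, t, target, choice, int(choice == target)))
    df = pd.DataFrame(recs, columns=SESSION_COLUMNS)
    per_block = (lengths - 1) / lengths
    return session_metrics(df), per_block


def per_block_mle_fit(
    y, offset_shift: float = 0.0
) -> tuple[TransitionParams, bool]:
    """Constrained Bernoulli MLE of (offset, slope, lapse) for one block.

    With ``offset_shift`` > 0 (early-switch mode: the block vector was built
    on a prepended trial axis) the reported offset is the fitted offset minus
    the shift, and may be negative.  Returns ``(params, degenerate)`` where
    the flag marks flat-likelihood blocks (all responses identical) whose
    estimates sit on the constraint boundary.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("block must be binary")
    t = np.arange(1, y.size + 1, dtype=float)

    def nll(theta):
        s, a, eps = theta
        g = expit(a * (t - s))
        p = np.clip(eps + (1 - 2 * eps) * g, 1e-9, 1 - 1e-9)
        return -(y @ np.log(p) + (1 - y) @ np.log1p(-p))

    bounds = [(0.01, 2 * y.size), (0.01, 100.0), (0.01, 0.5)]
    best = None
    for x0 in ([2.0, 1.0, 0.1], [8.0, 0.5, 0.3], [0.5, 4.0, 0.05]):
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    s, a, eps = best.x
    degenerate = bool(len(np.unique(y)) == 1)
    return TransitionParams(s - offset_shift, a, eps), degenerate


def uniform_strategy_test(
    df: pd.DataFrame, n_boot: int = 100, random_state=None
) -> VariabilityTestResult:
    """Bootstrap test of block-performance variability against one strategy.

    Fits a single sigmoid to the pooled average transition curve and
    simulates an agent that on trial n of each block responds correctly with
    probability sigma(n), with block lengths matched to the data.  The
    p-value is the bootstrap fraction of simulated standard deviations at or
    above the observed one; small p means the observed block-to-block
    variability exceeds what a uniform strategy produces.
    """
    df = validate_sessions(df)
    rng = np.random.default_rng(random_state)
    correct = (df["choice"] == df["target_side"]).to_numpy(int)
    grouped = df.assign(correct=correct).groupby(["session", "block"], sort=True)
    block_perf = grouped["correct"].mean().to_numpy()
    lengths = grouped.size().to_numpy()
    if len(block_perf) < 2:
        raise ValueError("need at least two blocks")
    s_observed = float(np.std(block_perf))

    pos = df["trial_in_block"].to_numpy()
    n_max = int(lengths.min())
    counts = np.bincount(pos, minlength=n_max + 1)[1 : n_max + 1]
    sums = np.bincount(pos, weights=correct, minlength=n_max + 1)[1 : n_max + 1]
    a_n = sums / counts
    params = fit_transition_curve(a_n)
    p_by_pos = sigmoid_transition(params, np.arange(1, lengths.max() + 1, dtype=float))

    s_sim = np.empty(n_boot)
    for i in range(n_boot):
        perfs = [
            (rng.random(n) < p_by_pos[:n]).mean() for n in lengths
        ]
        s_sim[i] = np.std(perfs)
    p_value = float(np.mean(s_sim >= s_observed))
    return VariabilityTestResult(s_observed, s_sim, p_value)


@dataclass
class EarlySwitchResult:
    """Outcome of the early-switch (prepended-axis) refit."""

    model: BlockHMM
    K: int
    offsets: np.ndarray            # true-axis offsets (fitted minus the shift)
    labels: list[ModeTaxonomy]
    efficiencies: np.ndarray


def early_switch_refit(
    df: pd.DataFrame,
    *,
    pre: int = 3,
    post: int = 15,
    K: int | None = None,
    K_range=range(1, 7),
    random_state=None,
    **fit_config,
) -> EarlySwitchResult:
    """Re-fit the blockHMM on the prepended axis to expose early switches.

    Builds the B x (pre + post) signed-choice matrix (pre-reversal trials
    signed against the new block's correct side), selects K by cross
    validation unless given, fits, and reports offsets shifted back to the
    true axis; high-performing modes with negative offsets are labeled
    ``high_early``.
    """
    Y = sessions_to_shifted_blocks(df, pre=pre, post=post)
    if K is None:
        K = select_num_modes(Y, K_range, random_state=random_state, **fit_config)
    model = BlockHMM(n_modes=K, random_state=random_state, **fit_config).fit(Y)
    offsets = model.offsets_ - pre
    true_modes = [
        TransitionParams(s, a, e)
        for s, a, e in zip(offsets, model.slopes_, model.lapses_)
    ]
    effs = np.array([foraging_efficiency(m) for m in true_modes])
    labels = [classify_mode(m, e) for m, e in zip(true_modes, effs)]
    return EarlySwitchResult(model=model, K=K, offsets=offsets, labels=labels, efficiencies=effs)
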