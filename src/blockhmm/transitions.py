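"""Sigmoidal block-transition functions and the performance-based mode taxonomy.

In a two-alternative reversal-learning task the high-reward side flips at
unsignaled block boundaries.  Within a block, the probability that the subject
chooses the (new) high-reward side typically rises along a sigmoid in the
within-block trial index t:

    sigma(t) = eps + (1 - 2*eps) / (1 + exp(-alpha * (t - s)))

with switch offset ``s`` (trials), slope ``alpha`` (1/trials) and lapse ``eps``
(the asymptotic error rate, bounding sigma in [eps, 1 - eps]).  A block of
"signed" choices y_t (1 if the choice matched the block's high-reward side) is
modeled as independent Bernoulli draws with rate sigma(t).

The foraging efficiency of a mode is the normalized area under sigma over
trials 1..25, a per-mode expected fraction of rewarded trials; modes are
classified into a low / intermediate (high-lapse or high-offset) / high
performance taxonomy from that efficiency, with an extra "high, early" label
for high-performing modes that switch before the reversal (s < 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import expit

__all__ = [
    "TransitionParams",
    "ModeTaxonomy",
    "sigmoid_transition",
    "block_loglik",
    "foraging_efficiency",
    "classify_mode",
]


@dataclass(frozen=True)
class TransitionParams:
    """Parameters of one mode's sigmoidal choice-transition function.

    Parameters
    ----------
    offset : float
        Switch offset ``s`` in trials; the midpoint of the transition.  May be
        negative for anticipatory ("early") switches fit on a shifted axis.
    slope : float
        Switch slope ``alpha`` in 1/trials; must be non-negative.
    lapse : float
        Asymptotic error rate ``eps`` in [0, 0.5].
    """

    offset: float
    slope: float
    lapse: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.offset, self.slope, self.lapse]).all():
            raise ValueError("transition parameters must be finite")
        if self.slope < 0:
            raise ValueError(f"slope must be >= 0, got {self.slope}")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError(f"lapse must lie in [0, 0.5], got {self.lapse}")

    def as_array(self) -> np.ndarray:
        return np.array([self.offset, self.slope, self.lapse])


class ModeTaxonomy(str, Enum):
    """Performance-based classification of a transition mode."""

    LOW = "low"
    INTERMEDIATE_HIGH_LAPSE = "intermediate_high_lapse"
    INTERMEDIATE_HIGH_OFFSET = "intermediate_high_offset"
    HIGH = "high"
    HIGH_EARLY = "high_early"


def sigmoid_transition(params: TransitionParams, t):
    """Evaluate the transition function sigma(t).

    ``t`` is the 1-based trial index within the block; real values are allowed
    (the efficiency integral evaluates sigma on a fine grid).  Returns values
    in [lapse, 1 - lapse].
    """
    t = np.asarray(t, dtype=float)
    s, a, eps = params.offset, params.slope, params.lapse
    # logistic in increasing convention: rises from eps toward 1 - eps
    g = expit(a * (t - s))
    out = eps + (1.0 - 2.0 * eps) * g
    if out.ndim == 0:
        return float(out)
    return out


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.size and not np.isin(y, (0, 1)).all():
        raise ValueError("signed choices must be binary (0/1)")
    return y.astype(float)


def block_loglik(params: TransitionParams, y) -> float:
    """Bernoulli log-likelihood of one block of signed choices.

    y_t ~ Bernoulli(sigma(t)) independently for t = 1..T, so the block
    log-likelihood is sum_t [y_t log sigma(t) + (1 - y_t) log(1 - sigma(t))].
    Always <= 0.
    """
    y = _check_binary(np.atleast_1d(y))
    t = np.arange(1, y.shape[-1] + 1, dtype=float)
    sig = sigmoid_transition(params, t)
    # lapse can be 0, so clip away exact 0/1 rates before taking logs
    sig = np.clip(sig, 1e-12, 1.0 - 1e-12)
    return float(y @ np.log(sig) + (1.0 - y) @ np.log1p(-sig))


def mode_log_prob_table(offsets, slopes, lapses, n_trials: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial log sigma / log(1 - sigma) tables for a bank of K modes.

    Returns two (n_trials, K) arrays; a B x T binary matrix Y then yields the
    B x K block emission log-likelihoods as ``Y @ logp + (1 - Y) @ logq``.
    """
    t = np.arange(1, n_trials + 1, dtype=float)[:, None]
    s = np.asarray(offsets, dtype=float)[None, :]
    a = np.asarray(slopes, dtype=float)[None, :]
    eps = np.asarray(lapses, dtype=float)[None, :]
    g = expit(a * (t - s))
    sig = np.clip(eps + (1.0 - 2.0 * eps) * g, 1e-12, 1.0 - 1e-12)
    return np.log(sig), np.log1p(-sig)


def foraging_efficiency(params: TransitionParams, *, step: float = 0.1) -> float:
    """Normalized area under the transition curve over trials 1..25.

    The integral of sigma over t in [1, 25] is evaluated by the composite
    trapezoid rule on a grid with the given step and divided by the interval
    length 24, giving an expected fraction of signed-correct trials in
    [lapse, 1 - lapse].  Rectangle-rule vs trapezoid differences on the 0.1
    grid are below 1e-3, far from the taxonomy thresholds.
    """
    lo, hi = 1.0, 25.0
    n = int(round((hi - lo) / step))
    grid = np.linspace(lo, hi, n + 1)
    vals = sigmoid_transition(params, grid)
    return float(np.trapezoid(vals, grid) / (hi - lo))


def classify_mode(params: TransitionParams, efficiency: float) -> ModeTaxonomy:
    """Classify a mode by its foraging efficiency (and lapse / offset).

    efficiency < 0.65 -> low; 0.65..0.84 -> intermediate, split at lapse 0.1
    into high-lapse vs high-offset; > 0.84 -> high, or high_early when the
    fitted offset is negative (switch before the reversal).
    """
    e = float(efficiency)
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"efficiency must lie in [0, 1], got {e}")
    if e < 0.65:
        return ModeTaxonomy.LOW
    if e <= 0.84:
        if params.lapse > 0.1:
            return ModeTaxonomy.INTERMEDIATE_HIGH_LAPSE
        return ModeTaxonomy.INTERMEDIATE_HIGH_OFFSET
    if params.offset < 0:
        return ModeTaxonomy.HIGH_EARLY
    return ModeTaxonomy.HIGH
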