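"""Synthetic-data generators and fixtures.

Everything the other modules need for testing and demonstration is generated
here programmatically: the three-mode reference mixture agent used throughout
the documentation, blockHMM mixture datasets in the session-CSV schema (with
a ground-truth state sidecar), and sessions with anticipatory (early) switches
generated on the prepended trial axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import BlockHMM
from .io import SESSION_COLUMNS, write_sessions
from .transitions import TransitionParams, sigmoid_transition

__all__ = [
    "REFERENCE_MIXTURE",
    "make_reference_agent",
    "mixture_sessions",
    "generate_mixture_dataset",
    "anticipatory_sessions",
]

# Three-mode reference mixture: a flat/high-lapse mode, a fast low-lapse mode
# and a sharp but delayed mode, with strongly sticky block-to-block dynamics.
REFERENCE_MIXTURE = {
    "offsets": (4.0, 1.0, 9.0),
    "slopes": (0.2, 0.8, 1.5),
    "lapses": (0.3, 0.15, 0.05),
    "transmat": (
        (0.966, 0.003, 0.031),
        (0.007, 0.954, 0.039),
        (0.025, 0.020, 0.955),
    ),
    "n_blocks": 1000,
    "block_len": 30,
}


def make_reference_agent() -> BlockHMM:
    """The K=3 reference mixture agent with a uniform initial distribution."""
    m = REFERENCE_MIXTURE
    modes = [
        TransitionParams(s, a, e)
        for s, a, e in zip(m["offsets"], m["slopes"], m["lapses"])
    ]
    return BlockHMM.from_params(modes, np.asarray(m["transmat"]))


def mixture_sessions(
    model: BlockHMM,
    n_blocks: int,
    block_len: int,
    random_state=None,
    *,
    blocks_per_session: int = 20,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample a mixture dataset as session records plus ground-truth states.

    Blocks are grouped into sessions of ``blocks_per_session`` with target
    sides alternating within each session (first side random per session).
    Returns ``(sessions, states)`` with one state index per block.
    """
    rng = np.random.default_rng(random_state)
    if n_blocks == 0:
        return pd.DataFrame(columns=SESSION_COLUMNS), np.empty(0, dtype=int)
    states, Y = model.sample(n_blocks, block_len, random_state=rng.integers(2**31 - 1))
    sides = np.empty(n_blocks, dtype=int)
    for start in range(0, n_blocks, blocks_per_session):
        first = int(rng.integers(2))
        idx = np.arange(start, min(start + blocks_per_session, n_blocks))
        sides[idx] = (first + idx - start) % 2
    side_labels = np.array(["L", "R"])
    recs = []
    for b in range(n_blocks):
        target = side_labels[sides[b]]
        other = side_labels[1 - sides[b]]
        for t in range(block_len):
            correct = Y[b, t] == 1
            recs.append(
                (
                    b // blocks_per_session + 1,
                    b + 1,
                    t + 1,
                    target,
                    target if correct else other,
                    int(correct),
                )
            )
    sessions = pd.DataFrame(recs, columns=SESSION_COLUMNS)
    return sessions, states


def generate_mixture_dataset(
    model: BlockHMM,
    n_blocks: int,
    block_len: int,
    random_state,
    path,
    states_path=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Write a sampled mixture dataset to CSV plus a ground-truth sidecar."""
    sessions, states = mixture_sessions(model, n_blocks, block_len, random_state)
    write_sessions(sessions, path)
    if states_path is not None:
        pd.DataFrame({"block": np.arange(1, len(states) + 1), "state": states}).to_csv(
            states_path, index=False
        )
    return sessions, states


def anticipatory_sessions(
    params_true: TransitionParams,
    n_blocks: int,
    random_state=None,
    *,
    block_len: int = 18,
    pre: int = 3,
) -> pd.DataFrame:
    """Sessions from an agent whose switches may precede the reversal.

    The generating sigmoid is defined on the true axis (t = 0 at the
    reversal; ``params_true.offset`` may be negative).  Within each block the
    last ``pre`` trials are drawn against the NEXT block's target from the
    pre-reversal portion of the curve, so re-fitting on the prepended axis
    recovers ``offset + pre``.
    """
    rng = np.random.default_rng(random_state)
    first = int(rng.integers(2))
    sides = (first + np.arange(n_blocks)) % 2
    side_labels = np.array(["L", "R"])
    # probability (relative to a block's own target) of matching it at trial
    # j = 1..block_len; trials past block_len - pre anticipate the next block
    t_own = np.arange(1, block_len + 1, dtype=float)
    p_own = sigmoid_transition(params_true, t_own)
    t_pre = np.arange(-pre + 1, 1, dtype=float)  # -2, -1, 0 relative to next reversal
    p_next = sigmoid_transition(params_true, t_pre)  # next-target match prob
    recs = []
    for b in range(n_blocks):
        target = side_labels[sides[b]]
        other = side_labels[1 - sides[b]]
        for j in range(1, block_len + 1):
            tail = j > block_len - pre and b < n_blocks - 1
            if tail:
                # anticipatory tail: Bernoulli toward the NEXT block's target
                p_match_next = p_next[j - (block_len - pre) - 1]
                match_next = rng.random() < p_match_next
                choice = other if match_next else target
            else:
                match = rng.random() < p_own[j - 1]
                choice = target if match else other
            recs.append((1, b + 1, j, target, choice, int(choice == target)))
    return pd.DataFrame(recs, columns=SESSION_COLUMNS)
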