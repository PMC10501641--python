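"""Session-file schema and conversion to block matrices.

Sessions are stored as delimited text with one row per trial and columns

    session, block, trial_in_block, target_side, choice, reward

where sides are 'L'/'R', reward is 0/1 and ``trial_in_block`` is 1-based.
The signed choice of a trial is 1 when the choice matched the block's
high-reward (target) side, which is the binary emission the blockHMM models.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SESSION_COLUMNS",
    "read_sessions",
    "write_sessions",
    "validate_sessions",
    "sessions_to_blocks",
    "sessions_to_shifted_blocks",
]

SESSION_COLUMNS = ["session", "block", "trial_in_block", "target_side", "choice", "reward"]


def validate_sessions(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and domains; re-sort out-of-order rows with a warning."""
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in SESSION_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"wrong column set: missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    df = df.loc[:, SESSION_COLUMNS].copy()
    for col, domain in (("target_side", {"L", "R"}), ("choice", {"L", "R"})):
        bad = ~df[col].isin(domain)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(f"invalid {col} value at row {row}: {df[col][bad].iloc[0]!r}")
    bad = ~df["reward"].isin((0, 1))
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"invalid reward value at row {row}: {df['reward'][bad].iloc[0]!r}")
    if (df["trial_in_block"] < 1).any():
        raise ValueError("trial_in_block must be 1-based")
    order_cols = ["session", "block", "trial_in_block"]
    if not df[order_cols].equals(df.sort_values(order_cols)[order_cols].reset_index(drop=True)):
        sorted_df = df.sort_values(order_cols, kind="stable").reset_index(drop=True)
        if not df.equals(sorted_df):
            warnings.warn("session rows out of order; re-sorting by (session, block, trial)")
        df = sorted_df
    return df


def read_sessions(path) -> pd.DataFrame:
    """Read and validate a session CSV."""
    df = pd.read_csv(path)
    if df.empty and set(df.columns) == set(SESSION_COLUMNS):
        return df.loc[:, SESSION_COLUMNS]
    return validate_sessions(df)


def write_sessions(df: pd.DataFrame, path) -> None:
    """Write a session table (validating first); lossless round trip."""
    if not df.empty:
        df = validate_sessions(df)
    else:
        df = df.loc[:, SESSION_COLUMNS] if len(df.columns) else pd.DataFrame(
            columns=SESSION_COLUMNS
        )
    df.to_csv(path, index=False)


def sessions_to_blocks(df: pd.DataFrame, T: int = 15) -> np.ndarray:
    """Signed-choice block matrix: first T trials of each block, 0/1 entries.

    Blocks with fewer than T trials are dropped.  Entry (b, t) is 1 when the
    choice on trial t of block b matched the block's high-reward side.
    """
    df = validate_sessions(df)
    signed = (df["choice"] == df["target_side"]).astype(int)
    rows = []
    for _, g in df.assign(signed=signed).groupby(["session", "block"], sort=True):
        if len(g) >= T:
            rows.append(g["signed"].to_numpy()[:T])
    if not rows:
        raise ValueError(f"no blocks with at least {T} trials")
    return np.vstack(rows)


def sessions_to_shifted_blocks(
    df: pd.DataFrame, pre: int = 3, post: int = 15
) -> np.ndarray:
    """Block matrix with trials prepended from before each reversal.

    For every block after the first within a session, the last ``pre``
    trials of the preceding block are prepended and signed against the NEW
    block's high-reward side, so a correct anticipation scores 1; the first
    ``post`` trials of the block itself follow.  The resulting rows have
    T = pre + post entries, and fitted offsets on this axis exceed the true
    offsets by ``pre`` trials.  Blocks lacking enough context are skipped.
    """
    df = validate_sessions(df)
    rows = []
    skipped = 0
    for _, sess in df.groupby("session", sort=True):
        block_ids = sess["block"].unique()
        for prev_id, cur_id in zip(block_ids[:-1], block_ids[1:]):
            prev = sess[sess["block"] == prev_id]
            cur = sess[sess["block"] == cur_id]
            if len(prev) < pre or len(cur) < post:
                skipped += 1
                continue
            target = cur["target_side"].iloc[0]
            pre_signed = (prev["choice"].to_numpy()[-pre:] == target).astype(int)
            post_signed = (
                cur["choice"].to_numpy()[:post] == cur["target_side"].to_numpy()[:post]
            ).astype(int)
            rows.append(np.concatenate([pre_signed, post_signed]))
    if skipped:
        warnings.warn(f"skipped {skipped} blocks without full pre-reversal context")
    if not rows:
        raise ValueError("no blocks with sufficient pre-reversal context")
    return np.vstack(rows)
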