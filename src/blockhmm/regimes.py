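"""Mapping transition dynamics onto algorithmic regimes (Q1-4, IB5-6).

The pipeline forward-simulates grids of Q-learning agents (25 x 20 over
learning rate gamma in [0.01, 1.4] and exploration in [0.01, 0.5]) and
inference-based agents (15 x 10 over p_switch in [0.01, 0.45] and p_rew in
[0.55, 0.99]), 650 agents in total.  Each agent's behavior is summarized by
four features of its average choice-transition curve — lapse, slope, offset
and foraging efficiency — and the 650 x 4 feature matrix is segmented into
six regimes by density-based clustering (t-SNE embedding, 2-D histogram,
watershed on the smoothed density; a deterministic k-means fallback is also
provided).  Clusters dominated by Q-grid agents are named Q1..Q4 in order of
increasing mean learning rate, inference-based clusters IB5..IB6 by mean
p_switch.

A k-nearest-neighbor decoder is then trained on class-balanced features
extracted from short synthetic sessions (50 sessions of 20 blocks per agent)
and can label fitted blockHMM modes with the algorithmic regime that best
accounts for their transition dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from scipy.special import expit
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import accuracy_score, confusion_matrix, matthews_corrcoef
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .agents import IBAgentSpec, QAgentSpec, simulate_signed_outcomes
from .transitions import TransitionParams, foraging_efficiency

__all__ = [
    "FEATURE_NAMES",
    "RegimeDecoder",
    "average_transition_curve",
    "fit_transition_curve",
    "default_q_grid",
    "default_ib_grid",
    "simulate_grid",
    "cluster_regimes",
    "train_decoder",
    "evaluate_decoder",
    "decode_modes",
    "run_regime_analysis",
]

FEATURE_NAMES = ("lapse", "slope", "offset", "efficiency")


# ---------------------------------------------------------------------- #
# transition-curve summaries
# ---------------------------------------------------------------------- #
def average_transition_curve(blocks) -> np.ndarray:
    """Average accuracy a_n at each within-block position n.

    ``blocks`` is either a B x T binary matrix (mean over blocks) or a pair
    ``(positions, correct)`` of flat per-trial arrays, in which case the
    curve runs up to the shortest block length present.
    """
    if isinstance(blocks, tuple):
        pos, correct = blocks
        pos = np.asarray(pos)
        correct = np.asarray(correct, dtype=float)
        if pos.size == 0:
            raise ValueError("no trials given")
        counts = np.bincount(pos)[1:]
        sums = np.bincount(pos, weights=correct)[1:]
        # keep positions present in every block (counts equal to block count)
        full = counts == counts[0]
        n_keep = int(np.argmin(full)) if not full.all() else len(counts)
        return sums[:n_keep] / counts[:n_keep]
    Y = np.asarray(blocks, dtype=float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("need a non-empty B x T block matrix")
    return Y.mean(axis=0)


def _sigmoid_residuals(theta, n, a_n):
    s, a, eps = theta
    g = expit(a * (n - s))
    return eps + (1.0 - 2.0 * eps) * g - a_n


def _sigmoid_jacobian(theta, n, a_n):
    s, a, eps = theta
    g = expit(a * (n - s))
    gp = (1.0 - 2.0 * eps) * g * (1.0 - g)
    return np.column_stack([-a * gp, (n - s) * gp, 1.0 - 2.0 * g])


def fit_transition_curve(a_n, n=None) -> TransitionParams:
    """Constrained least-squares sigmoid fit of an average transition curve.

    Fits ``a_n = eps + (1 - 2 eps) / (1 + exp(-alpha (n - s)))`` under the
    box constraints s >= 0, alpha >= 0, 0 <= eps <= 0.5.  Started from a
    data-driven guess (lapse from the curve tail, offset from the half-rise
    crossing) with one generic fallback start.
    """
    a_n = np.asarray(a_n, dtype=float)
    if n is None:
        n = np.arange(1, a_n.size + 1, dtype=float)
    else:
        n = np.asarray(n, dtype=float)
    if ((a_n < 0) | (a_n > 1)).any():
        raise ValueError("accuracies must lie in [0, 1]")
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([max(n.max() * 2, 10.0), 100.0, 0.5])
    e0 = float(np.clip(1.0 - a_n[-3:].mean(), 0.01, 0.45))
    above = np.flatnonzero(a_n >= 0.5)
    s0 = float(n[above[0]]) if above.size else float(n[-1])
    best = None
    for x0 in ((s0, 1.0, e0), (2.0, 0.3, 0.2)):
        res = least_squares(
            _sigmoid_residuals,
            np.clip(x0, lo, hi),
            jac=_sigmoid_jacobian,
            args=(n, a_n),
            bounds=(lo, hi),
            max_nfev=100,
        )
        if best is None or res.cost < best.cost:
            best = res
    return TransitionParams(*best.x)


def session_features(pos, correct, n_positions: int = 15) -> np.ndarray:
    """(lapse, slope, offset, efficiency) of one simulated session."""
    pos = np.asarray(pos)
    correct = np.asarray(correct, dtype=float)
    keep = pos <= n_positions
    counts = np.bincount(pos[keep], minlength=n_positions + 1)[1:]
    sums = np.bincount(pos[keep], weights=correct[keep], minlength=n_positions + 1)[1:]
    valid = counts > 0
    a_n = sums[valid] / counts[valid]
    n = np.arange(1, n_positions + 1, dtype=float)[valid]
    params = fit_transition_curve(a_n, n)
    eff = foraging_efficiency(params)
    return np.array([params.lapse, params.slope, params.offset, eff])


# ---------------------------------------------------------------------- #
# agent grids
# ---------------------------------------------------------------------- #
def default_q_grid(n_gamma: int = 25, n_eps: int = 20) -> list[QAgentSpec]:
    gammas = np.linspace(0.01, 1.4, n_gamma)
    epss = np.linspace(0.01, 0.5, n_eps)
    return [QAgentSpec(g, e) for g in gammas for e in epss]


def default_ib_grid(n_switch: int = 15, n_rew: int = 10) -> list[IBAgentSpec]:
    switches = np.linspace(0.01, 0.45, n_switch)
    rews = np.linspace(0.55, 0.99, n_rew)
    return [IBAgentSpec(ps, pr) for ps in switches for pr in rews]


def _agent_row(agent) -> dict:
    if isinstance(agent, QAgentSpec):
        return {
            "family": "Q",
            "learning_rate": agent.learning_rate,
            "eps_explore": agent.eps_explore,
            "p_switch": np.nan,
            "p_rew": np.nan,
        }
    return {
        "family": "IB",
        "learning_rate": np.nan,
        "eps_explore": np.nan,
        "p_switch": agent.p_switch,
        "p_rew": agent.p_rew,
    }


def simulate_grid(agents=None, n_blocks: int = 1000, random_state=None) -> pd.DataFrame:
    """Simulate each agent and extract its four-feature summary.

    Returns one row per agent with its defining parameters and the fitted
    (lapse, slope, offset, efficiency) of its average transition curve over
    ``n_blocks`` blocks.  The default grids contain 650 agents.
    """
    if agents is None:
        agents = default_q_grid() + default_ib_grid()
    rng = np.random.default_rng(random_state)
    rows = []
    for agent in agents:
        child = np.random.default_rng(rng.integers(2**31 - 1))
        pos, correct = simulate_signed_outcomes(agent, n_blocks, child)
        feats = session_features(pos, correct)
        row = _agent_row(agent)
        row.update(dict(zip(FEATURE_NAMES, feats)))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# clustering into regimes
# ---------------------------------------------------------------------- #
def _name_clusters(grid: pd.DataFrame, raw_labels: np.ndarray) -> np.ndarray:
    """Map anonymous cluster ids to Q1..Qm / IB(m+1).. regime names.

    Clusters with a majority of Q-grid members are ordered by mean learning
    rate; inference-based clusters by mean p_switch.
    """
    ids = np.unique(raw_labels)
    q_clusters, ib_clusters = [], []
    for cid in ids:
        members = grid.loc[raw_labels == cid]
        if (members["family"] == "Q").mean() >= 0.5:
            q_clusters.append((members["learning_rate"].mean(), cid))
        else:
            ib_clusters.append((members["p_switch"].mean(), cid))
    mapping = {}
    for rank, (_, cid) in enumerate(sorted(q_clusters), start=1):
        mapping[cid] = f"Q{rank}"
    for rank, (_, cid) in enumerate(sorted(ib_clusters), start=len(q_clusters) + 1):
        mapping[cid] = f"IB{rank}"
    return np.array([mapping[c] for c in raw_labels])


def cluster_regimes(
    grid: pd.DataFrame,
    method: str = "per-family",
    *,
    n_clusters: int = 6,
    perplexity: float = 50.0,
    hist_bins: int = 50,
    smooth_sigma: float = 4.0,
    peak_min_distance: int = 8,
    random_state=None,
) -> np.ndarray:
    """Segment the agent feature matrix into named behavioral regimes.

    The default ``method="per-family"`` realizes the documented regime
    geometry directly: the standardized features of the Q-grid agents are
    cut into four clusters and those of the inference-based agents into two
    (deterministic k-means), yielding contiguous regions of each parameter
    space named Q1..Q4 and IB5..IB6.  ``method="tsne-watershed"`` is the
    pooled density pipeline: it standardizes the four features, embeds them
    in 2-D with t-SNE (Euclidean metric), forms a smoothed 2-D histogram and
    runs a watershed on the density; each agent inherits the basin of its
    histogram bin.  Because the basin count depends on the smoothing
    bandwidth, the pipeline descends a smoothing ladder (3/4 steps from
    ``smooth_sigma``) until at least ``n_clusters`` basins appear, then
    merges the smallest basins into their nearest neighbor (embedding
    centroids) until exactly ``n_clusters`` remain; a warning reports any
    adjustment.  ``method="kmeans"`` is a deterministic fallback that
    clusters the standardized features directly.
    """
    if len(grid) < n_clusters:
        raise ValueError("fewer agents than requested clusters")
    X = StandardScaler().fit_transform(grid.loc[:, FEATURE_NAMES].to_numpy())
    rng = np.random.default_rng(random_state)
    seed = int(rng.integers(2**31 - 1))

    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=0)
        raw = km.fit_predict(X)
        return _name_clusters(grid, raw)
    if method == "per-family":
        n_ib = max(1, n_clusters // 3)  # 6 -> 4 Q + 2 IB
        n_q = n_clusters - n_ib
        fam = grid["family"].to_numpy()
        raw = np.empty(len(grid), dtype=int)
        qi = np.flatnonzero(fam == "Q")
        ibi = np.flatnonzero(fam == "IB")
        if len(qi) < n_q or len(ibi) < n_ib:
            raise ValueError("not enough agents per family for the requested split")
        raw[qi] = KMeans(n_clusters=n_q, n_init=10, random_state=0).fit_predict(X[qi])
        raw[ibi] = n_q + KMeans(n_clusters=n_ib, n_init=10, random_state=0).fit_predict(X[ibi])
        return _name_clusters(grid, raw)
    if method != "tsne-watershed":
        raise ValueError(f"unknown clustering method: {method}")

    emb = TSNE(
        n_components=2, perplexity=perplexity, metric="euclidean",
        init="pca", random_state=seed,
    ).fit_transform(X)
    hist, xe, ye = np.histogram2d(emb[:, 0], emb[:, 1], bins=hist_bins)
    ix = np.clip(np.searchsorted(xe, emb[:, 0], side="right") - 1, 0, hist_bins - 1)
    iy = np.clip(np.searchsorted(ye, emb[:, 1], side="right") - 1, 0, hist_bins - 1)

    sigma = float(smooth_sigma)
    raw = None
    while True:
        density = gaussian_filter(hist, sigma=sigma)
        peaks = peak_local_max(
            density, min_distance=peak_min_distance, exclude_border=False
        )
        markers = np.zeros_like(density, dtype=int)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        basins = watershed(-density, markers)
        raw = basins[ix, iy]
        if len(np.unique(raw)) >= n_clusters or sigma < 1.0:
            break
        sigma *= 0.75

    found = len(np.unique(raw))
    if found != n_clusters:
        warnings.warn(
            f"density clustering found {found} basins at bandwidth {sigma:.2f} "
            f"(requested {n_clusters}); merging smallest basins"
        )
    if found < n_clusters:
        # could not resolve enough basins even at minimal smoothing
        return _name_clusters(
            grid,
            KMeans(n_clusters=n_clusters, n_init=10, random_state=0).fit_predict(X),
        )
    raw = _merge_smallest(raw, emb, n_clusters)
    return _name_clusters(grid, raw)


def _merge_smallest(raw: np.ndarray, emb: np.ndarray, n_clusters: int) -> np.ndarray:
    """Fold the smallest basins into their nearest neighbor until n remain."""
    raw = raw.copy()
    while len(np.unique(raw)) > n_clusters:
        ids, counts = np.unique(raw, return_counts=True)
        cents = np.stack([emb[raw == i].mean(axis=0) for i in ids])
        small = int(np.argmin(counts))
        d = np.linalg.norm(cents - cents[small], axis=1)
        d[small] = np.inf
        raw[raw == ids[small]] = ids[int(np.argmin(d))]
    return raw


# ---------------------------------------------------------------------- #
# kNN decoder
# ---------------------------------------------------------------------- #
class RegimeDecoder(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbor regime classifier on standardized sigmoid features.

    Features are z-scored with statistics learned from the training data;
    the scaling is stored on the estimator and re-applied at prediction
    time, so raw (unstandardized) feature vectors are the expected input.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = self._validate_features(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.scaler_ = StandardScaler().fit(X)
        self.knn_ = KNeighborsClassifier(n_neighbors=self.n_neighbors).fit(
            self.scaler_.transform(X), y
        )
        return self

    @staticmethod
    def _validate_features(X: np.ndarray) -> np.ndarray:
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"expected raw feature rows ({', '.join(FEATURE_NAMES)})"
            )
        if ((X[:, 0] < 0) | (X[:, 0] > 0.5)).any():
            raise ValueError("lapse column out of range; inputs must be unscaled")
        return X

    def predict(self, X):
        X = self._validate_features(np.asarray(X, dtype=float))
        return self.knn_.predict(self.scaler_.transform(X))

    def score(self, X, y):
        return accuracy_score(y, self.predict(X))


@dataclass
class DecoderReport:
    """Held-out evaluation of a trained regime decoder."""

    accuracy: float
    mcc: float
    confusion: pd.DataFrame  # row-normalized by true class
    n_train: int
    n_test: int


def _balance_classes(X, y, rng):
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.concatenate(keep)
    return X[keep], y[keep]


def train_decoder(
    grid: pd.DataFrame,
    labels,
    *,
    sessions_per_agent: int = 50,
    blocks_per_session: int = 20,
    n_neighbors: int = 10,
    test_fraction: float = 0.2,
    random_state=None,
) -> tuple[RegimeDecoder, DecoderReport]:
    """Train the regime decoder on class-balanced synthetic-session features.

    Each agent in ``grid`` (with its regime label) is simulated in
    ``sessions_per_agent`` fresh sessions of ``blocks_per_session`` blocks;
    the four sigmoid features are extracted per session.  Classes are
    balanced by subsampling, split 80/20 stratified by class, and a kNN is
    fit on the training portion; the report carries the held-out accuracy,
    Matthews correlation and row-normalized confusion matrix.
    """
    labels = np.asarray(labels)
    if len(labels) != len(grid):
        raise ValueError("one label per agent required")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two regime classes")
    rng = np.random.default_rng(random_state)
    X, y = [], []
    for (_, row), label in zip(grid.iterrows(), labels):
        if row["family"] == "Q":
            agent = QAgentSpec(row["learning_rate"], row["eps_explore"])
        else:
            agent = IBAgentSpec(row["p_switch"], row["p_rew"])
        for _ in range(sessions_per_agent):
            child = np.random.default_rng(rng.integers(2**31 - 1))
            pos, correct = simulate_signed_outcomes(agent, blocks_per_session, child)
            X.append(session_features(pos, correct))
            y.append(label)
    X = np.asarray(X)
    y = np.asarray(y)

    Xb, yb = _balance_classes(X, y, rng)
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xb, yb, test_size=test_fraction, stratify=yb,
        random_state=int(rng.integers(2**31 - 1)),
    )
    decoder = RegimeDecoder(n_neighbors=n_neighbors).fit(X_tr, y_tr)
    report = evaluate_decoder(decoder, X_te, y_te)
    report.n_train = len(y_tr)
    decoder.split_ = {"X_train": X_tr, "X_test": X_te, "y_train": y_tr, "y_test": y_te}
    return decoder, report


def evaluate_decoder(decoder: RegimeDecoder, X_test, y_test) -> DecoderReport:
    """Confusion matrix (row-normalized), accuracy and Matthews correlation."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = decoder.predict(np.asarray(X_test, dtype=float))
    classes = decoder.classes_
    cm = confusion_matrix(y_test, pred, labels=classes).astype(float)
    rowsum = cm.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    cm_norm = pd.DataFrame(cm / rowsum, index=classes, columns=classes)
    return DecoderReport(
        accuracy=float(accuracy_score(y_test, pred)),
        mcc=float(matthews_corrcoef(y_test, pred)),
        confusion=cm_norm,
        n_train=0,
        n_test=len(y_test),
    )


def decode_modes(decoder: RegimeDecoder, modes, efficiencies=None) -> np.ndarray:
    """Label fitted blockHMM modes with their underlying algorithmic regime.

    ``modes`` is a sequence of :class:`TransitionParams`; efficiencies are
    computed from the sigmoid when not supplied.  The decoder's stored
    z-scoring is applied internally, so raw parameters are expected.
    """
    modes = list(modes)
    if efficiencies is None:
        efficiencies = [foraging_efficiency(m) for m in modes]
    X = np.array(
        [[m.lapse, m.slope, m.offset, e] for m, e in zip(modes, efficiencies)]
    )
    return decoder.predict(X)


# ---------------------------------------------------------------------- #
# end-to-end pipeline
# ---------------------------------------------------------------------- #
def run_regime_analysis(
    random_state=None,
    *,
    n_blocks_cluster: int = 1000,
    sessions_per_agent: int = 50,
    blocks_per_session: int = 20,
    cluster_method: str = "per-family",
    n_neighbors: int = 10,
) -> dict:
    """Grid simulation -> regime clustering -> decoder training, end to end.

    Returns a dict with the simulated ``grid`` (650 agents x features), the
    per-agent regime ``labels``, the trained ``decoder`` (whose ``split_``
    attribute carries the balanced train/test arrays) and its held-out
    ``report``.
    """
    rng = np.random.default_rng(random_state)
    grid = simulate_grid(
        n_blocks=n_blocks_cluster,
        random_state=np.random.default_rng(rng.integers(2**31 - 1)),
    )
    labels = cluster_regimes(
        grid, method=cluster_method, random_state=int(rng.integers(2**31 - 1))
    )
    decoder, report = train_decoder(
        grid,
        labels,
        sessions_per_agent=sessions_per_agent,
        blocks_per_session=blocks_per_session,
        n_neighbors=n_neighbors,
        random_state=np.random.default_rng(rng.integers(2**31 - 1)),
    )
    return {"grid": grid, "labels": labels, "decoder": decoder, "report": report}
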