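"""Hidden Markov model over blocks with sigmoid-emission likelihoods.

Each hidden mode k carries one sigmoidal transition function (offset s_k,
slope alpha_k, lapse eps_k); the emission probability of a whole block of T
signed choices under mode k is the product of the per-trial Bernoulli
likelihoods with rate sigma_k(t).  Modes evolve block-to-block as a Markov
chain with a K x K row-stochastic transition matrix.

Fitting is by expectation-maximization: the E-step is exact forward-backward
over the block chain (in log space, because block emissions can be e^-20 or
smaller); the M-step updates the transition matrix and the initial
distribution in closed form from expected counts and maximizes the expected
complete-data log-likelihood over (s, alpha, eps) per mode with L-BFGS-B
under the box constraints s >= 0.01, alpha >= 0.01, 0.01 <= eps <= 0.5.

Model selection compares the normalized cross-validated log-likelihood

    L_norm = (L_test - L_0) / (n_test * log 2)

across candidate K, where L_0 is the held-out log-likelihood of a Bernoulli
null model with rate estimated on the training trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils import check_random_state

from .transitions import TransitionParams, mode_log_prob_table

__all__ = [
    "BlockHMM",
    "CVResult",
    "forward_backward",
    "fit_em",
    "most_likely_states",
    "normalized_cv_loglik",
    "select_num_modes",
    "sample_blockhmm",
]

# box constraints on the emission parameters used by the M-step
OFFSET_BOUNDS = (0.01, 60.0)
SLOPE_BOUNDS = (0.01, 100.0)
LAPSE_BOUNDS = (0.01, 0.5)


def _validate_blocks(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("block data must be a 2-D (blocks x trials) array")
    if Y.size and not np.isin(Y, (0, 1)).all():
        raise ValueError("block data must be binary (0/1)")
    return Y.astype(float)


def _forward_backward_core(log_emit: np.ndarray, T: np.ndarray, pi: np.ndarray):
    """Exact E-step quantities for one chain of block-level emissions.

    Parameters are the B x K emission log-likelihood matrix, the K x K
    transition matrix and the initial distribution.  Returns the total
    log-likelihood, the B x K posterior marginals and the K x K matrix of
    expected transition counts summed over block pairs.

    Block emissions can be e^-20 or far smaller, so each block's emission row
    is max-normalized in log space and the recursion runs in scaled linear
    space (per-step normalization); the log-likelihood is reassembled from
    the scaling constants, which keeps the computation exact to machine
    precision without per-step logsumexp calls.
    """
    B, K = log_emit.shape
    emax = log_emit.max(axis=1)
    Bn = np.exp(log_emit - emax[:, None])  # row max is exactly 1

    alpha = np.empty((B, K))
    c = np.empty(B)
    a = pi * Bn[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for b in range(1, B):
        a = (alpha[b - 1] @ T) * Bn[b]
        cb = a.sum()
        c[b] = cb
        alpha[b] = a / cb
    loglik = float(np.log(c).sum() + emax.sum())

    beta = np.empty((B, K))
    beta[B - 1] = 1.0
    for b in range(B - 2, -1, -1):
        beta[b] = (T @ (Bn[b + 1] * beta[b + 1])) / c[b + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    if B > 1:
        u = (Bn[1:] * beta[1:]) / c[1:, None]
        xi_sum = T * (alpha[:-1].T @ u)
    else:
        xi_sum = np.zeros((K, K))
    return loglik, gamma, xi_sum


def _split_segments(idx: np.ndarray) -> list[slice]:
    """Runs of consecutive original block indices, as slices into the subset.

    A random train/test split removes blocks from the middle of the session
    chain; the retained blocks form contiguous segments and the Markov chain
    must be evaluated per segment rather than across the gaps.
    """
    idx = np.asarray(idx)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) != 1) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [idx.size]])
    return [slice(int(s), int(e)) for s, e in zip(starts, ends)]


def _fb_segments(log_emit, T, pi, segments):
    """Forward-backward over a list of independent contiguous segments.

    Each segment starts from the initial distribution; log-likelihoods and
    expected transition counts are summed, posteriors concatenated.
    """
    total = 0.0
    gammas = np.empty_like(log_emit)
    xi_sum = np.zeros_like(T)
    for seg in segments:
        ll, g, xi = _forward_backward_core(log_emit[seg], T, pi)
        total += ll
        gammas[seg] = g
        xi_sum += xi
    return total, gammas, xi_sum


def _emission_loglik_matrix(Y, offsets, slopes, lapses) -> np.ndarray:
    logp, logq = mode_log_prob_table(offsets, slopes, lapses, Y.shape[1])
    return Y @ logp + (1.0 - Y) @ logq


def _weighted_counts(Y: np.ndarray, resp_k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-weighted per-trial success / failure counts for one mode."""
    n1 = resp_k @ Y
    n0 = resp_k @ (1.0 - Y)
    return n1, n0


def _mode_objective(theta, t, n1, n0):
    s, a, eps = theta
    g = expit(a * (t - s))
    sig = np.clip(eps + (1.0 - 2.0 * eps) * g, 1e-12, 1.0 - 1e-12)
    f = -(n1 @ np.log(sig) + n0 @ np.log1p(-sig))
    # gradient of sigma wrt (s, alpha, eps)
    w = n1 / sig - n0 / (1.0 - sig)
    gp = (1.0 - 2.0 * eps) * g * (1.0 - g)
    grad = -np.array([
        w @ (gp * (-a)),
        w @ (gp * (t - s)),
        w @ (1.0 - 2.0 * g),
    ])
    return f, grad


def _maximize_mode(Y, resp_k, start: np.ndarray) -> np.ndarray:
    """Bounded quasi-Newton update of one mode's (s, alpha, eps).

    Falls back to the previous iterate when the optimizer fails to improve,
    preserving EM monotonicity.
    """
    t = np.arange(1, Y.shape[1] + 1, dtype=float)
    n1, n0 = _weighted_counts(Y, resp_k)
    f0, _ = _mode_objective(start, t, n1, n0)
    try:
        res = minimize(
            _mode_objective,
            start,
            args=(t, n1, n0),
            jac=True,
            method="L-BFGS-B",
            bounds=[OFFSET_BOUNDS, SLOPE_BOUNDS, LAPSE_BOUNDS],
        )
    except Exception:  # pragma: no cover - defensive
        return start
    if np.isfinite(res.fun) and res.fun <= f0:
        return res.x
    return start


@dataclass(frozen=True)
class CVResult:
    """Cross-validated model-selection score for one candidate K."""

    K: int
    L_test: float
    L_0: float
    n_test: int
    L_norm: float


class BlockHMM(BaseEstimator):
    """Block-level hidden Markov model with sigmoidal transition emissions.

    Parameters
    ----------
    n_modes : int
        Number of hidden modes K.
    n_iter : int
        Maximum EM iterations per restart.
    tol : float
        Absolute convergence tolerance on the joint log-likelihood.
    n_restarts : int
        Number of random restarts; the run with the highest cross-validated
        (held-out) log-likelihood is kept.
    cv_fraction : float
        Fraction of blocks held out to score restarts and compute the
        normalized cross-validated log-likelihood.  With 0, restarts are
        trained on all blocks and scored by the training log-likelihood.
    init_offset, init_slope, init_lapse : float
        Emission-parameter initialization shared by all modes (s=0.2,
        alpha=4, eps=0.3 by default).
    refit_full : bool
        After restart selection on the held-out split, continue EM on the
        full block matrix from the winning parameters (default).  Model
        selection turns this off, as only the held-out score is needed.
    random_state : int, RandomState or None
        Controls k-means initialization, restart seeds and the CV split.

    Attributes
    ----------
    offsets_, slopes_, lapses_ : (K,) arrays of fitted mode parameters.
    transmat_ : (K, K) row-stochastic block-to-block transition matrix.
    startprob_ : (K,) initial mode distribution.
    loglik_trace_ : per-iteration joint log-likelihood of the winning restart.
    loglik_ : joint log-likelihood of the full data under the fitted model.
    posteriors_ : (B, K) posterior mode probabilities for the full data.
    states_ : (B,) marginal-MAP mode index per block.
    cv_result_ : CVResult for the winning restart (None when cv_fraction=0).
    """

    def __init__(
        self,
        n_modes: int = 3,
        *,
        n_iter: int = 3000,
        tol: float = 1e-4,
        n_restarts: int = 5,
        cv_fraction: float = 0.2,
        init_offset: float = 0.2,
        init_slope: float = 4.0,
        init_lapse: float = 0.3,
        refit_full: bool = True,
        random_state=None,
    ):
        self.n_modes = n_modes
        self.n_iter = n_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.cv_fraction = cv_fraction
        self.init_offset = init_offset
        self.init_slope = init_slope
        self.init_lapse = init_lapse
        self.refit_full = refit_full
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    # construction from known parameters (e.g. the reference mixture)
    # ------------------------------------------------------------------ #
    @classmethod
    def from_params(cls, modes, transmat, startprob=None) -> "BlockHMM":
        """Build a ready-to-use model from explicit mode parameters.

        ``modes`` is a sequence of :class:`TransitionParams` (or (s, alpha,
        eps) triples); ``startprob`` defaults to uniform.
        """
        modes = [m if isinstance(m, TransitionParams) else TransitionParams(*m) for m in modes]
        K = len(modes)
        transmat = np.asarray(transmat, dtype=float)
        if transmat.shape != (K, K):
            raise ValueError("transition matrix shape must be (K, K)")
        if (transmat < 0).any() or not np.allclose(transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        startprob = (
            np.full(K, 1.0 / K) if startprob is None else np.asarray(startprob, dtype=float)
        )
        if startprob.shape != (K,) or not np.isclose(startprob.sum(), 1.0, atol=1e-8):
            raise ValueError("startprob must be a length-K probability vector")
        model = cls(n_modes=K)
        model.offsets_ = np.array([m.offset for m in modes])
        model.slopes_ = np.array([m.slope for m in modes])
        model.lapses_ = np.array([m.lapse for m in modes])
        model.transmat_ = transmat
        model.startprob_ = startprob
        return model

    @property
    def modes_(self) -> list[TransitionParams]:
        return [
            TransitionParams(s, a, e)
            for s, a, e in zip(self.offsets_, self.slopes_, self.lapses_)
        ]

    # ------------------------------------------------------------------ #
    # inference
    # ------------------------------------------------------------------ #
    def emission_loglik(self, Y) -> np.ndarray:
        """B x K matrix of block emission log-likelihoods."""
        Y = _validate_blocks(Y)
        out = _emission_loglik_matrix(Y, self.offsets_, self.slopes_, self.lapses_)
        if not np.isfinite(out).all():
            raise ValueError("non-finite emission log-likelihoods; corrupted data?")
        return out

    def score(self, Y) -> float:
        """Total log-likelihood of the block chain."""
        return forward_backward(self, Y)[0]

    def predict_proba(self, Y) -> np.ndarray:
        """Posterior mode probabilities per block."""
        return forward_backward(self, Y)[1]

    def predict(self, Y) -> np.ndarray:
        """Marginal-MAP mode index per block (ties break to the lower index)."""
        return np.argmax(self.predict_proba(Y), axis=1)

    def sample(self, n_blocks: int, block_len: int, random_state=None):
        """Sample a mode sequence and a block matrix from the model.

        Returns ``(states, Y)`` with states drawn from the initial
        distribution and the Markov chain, and y_t ~ Bernoulli(sigma_z(t))
        independently within each block.
        """
        if n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        rng = check_random_state(random_state)
        K = len(self.startprob_)
        states = np.empty(n_blocks, dtype=int)
        states[0] = rng.choice(K, p=self.startprob_)
        for b in range(1, n_blocks):
            states[b] = rng.choice(K, p=self.transmat_[states[b - 1]])
        t = np.arange(1, block_len + 1, dtype=float)
        probs = np.stack(
            [
                self.lapses_[k]
                + (1 - 2 * self.lapses_[k]) * expit(self.slopes_[k] * (t - self.offsets_[k]))
                for k in range(K)
            ]
        )
        Y = (rng.random_sample((n_blocks, block_len)) < probs[states]).astype(int)
        return states, Y

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #
    def fit(self, Y, y=None) -> "BlockHMM":
        Y = _validate_blocks(Y)
        B = Y.shape[0]
        K = self.n_modes
        if K > B:
            raise ValueError(f"need at least K={K} blocks, got {B}")
        rng = check_random_state(self.random_state)

        n_test = int(round(B * self.cv_fraction)) if self.cv_fraction > 0 else 0
        if self.cv_fraction > 0 and n_test == 0:
            n_test = 1
        if n_test >= B:
            raise ValueError("cv_fraction leaves no training blocks")
        perm = rng.permutation(B)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
        Y_train = Y[train_idx]
        Y_test = Y[test_idx]
        train_segments = _split_segments(train_idx)
        test_segments = _split_segments(test_idx)

        best = None
        for _ in range(max(1, self.n_restarts)):
            seed = rng.randint(0, 2**31 - 1)
            params, transmat, pi, trace, n_done = self._em(Y_train, seed, train_segments)
            if n_test:
                log_emit = _emission_loglik_matrix(
                    Y_test, params[:, 0], params[:, 1], params[:, 2]
                )
                seg_lls = np.array(
                    [
                        _forward_backward_core(log_emit[seg], transmat, pi)[0]
                        for seg in test_segments
                    ]
                )
                sel_score = float(seg_lls.sum())
            else:
                seg_lls = np.empty(0)
                sel_score = trace[-1]
            if best is None or sel_score > best[0]:
                best = (sel_score, params, transmat, pi, trace, n_done, seg_lls)

        sel_score, params, transmat, pi, trace, n_done, seg_lls = best
        self.cv_segment_logliks_ = seg_lls
        if n_test and self.refit_full:
            # continue EM on the full block set from the winning restart, so
            # the final parameters use all data and the trace refers to the
            # full chain
            params, transmat, pi, trace, n_done = self._em(
                Y, 0, None, start=(params, transmat, pi)
            )
        self.offsets_ = params[:, 0].copy()
        self.slopes_ = params[:, 1].copy()
        self.lapses_ = params[:, 2].copy()
        self.transmat_ = transmat
        self.startprob_ = pi
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = n_done
        self.train_idx_ = train_idx
        self.test_idx_ = test_idx

        if n_test:
            p_hat = float(np.clip(Y_train.mean(), 1e-6, 1 - 1e-6))
            n_trials_test = Y_test.size
            n1 = Y_test.sum()
            L0 = float(n1 * np.log(p_hat) + (n_trials_test - n1) * np.log1p(-p_hat))
            L_norm = (sel_score - L0) / (n_trials_test * np.log(2.0))
            self.cv_result_ = CVResult(K, float(sel_score), L0, int(n_trials_test), float(L_norm))
        else:
            self.cv_result_ = None

        self.loglik_, self.posteriors_, _ = forward_backward(self, Y)
        self.states_ = np.argmax(self.posteriors_, axis=1)
        return self

    def _em(self, Y: np.ndarray, seed: int, segments=None, start=None):
        B, T = Y.shape
        K = self.n_modes
        if segments is None:
            segments = [slice(0, B)]
        seg_starts = np.array([s.start for s in segments])

        if start is not None:
            # warm start: E-step at the supplied parameters
            params, transmat, pi = (np.array(a, dtype=float) for a in start)
            log_emit = _emission_loglik_matrix(Y, params[:, 0], params[:, 1], params[:, 2])
            _, resp, xi_sum = _fb_segments(log_emit, transmat, pi, segments)
        else:
            # hard initial state assignments from k-means on the raw binary rows
            if K == 1:
                hard = np.zeros(B, dtype=int)
            else:
                km = KMeans(n_clusters=K, n_init=5, random_state=seed % (2**31 - 1))
                hard = km.fit_predict(Y)
            resp = np.full((B, K), 0.05 / max(K - 1, 1))
            resp[np.arange(B), hard] = 0.95
            if K == 1:
                resp = np.ones((B, 1))
            resp /= resp.sum(axis=1, keepdims=True)
            xi_sum = np.ones((K, K))  # flat prior counts for the very first M-step
            for seg in segments:
                h = hard[seg]
                for a, b in zip(h[:-1], h[1:]):
                    xi_sum[a, b] += 1.0

            params = np.tile(
                np.array([self.init_offset, self.init_slope, self.init_lapse]), (K, 1)
            )
            params[:, 0] = np.clip(params[:, 0], *OFFSET_BOUNDS)
            params[:, 1] = np.clip(params[:, 1], *SLOPE_BOUNDS)
            params[:, 2] = np.clip(params[:, 2], *LAPSE_BOUNDS)
            transmat = xi_sum / xi_sum.sum(axis=1, keepdims=True)
            pi = resp[0] / resp[0].sum()

        trace: list[float] = []
        n_done = 0
        for it in range(self.n_iter):
            # M-step
            for k in range(K):
                params[k] = _maximize_mode(Y, resp[:, k], params[k])
            if B > 1:
                row = xi_sum.sum(axis=1, keepdims=True)
                ok = row[:, 0] > 1e-12
                new_T = transmat.copy()
                new_T[ok] = xi_sum[ok] / row[ok]
                # floor entries so sampled chains never hit an exact-zero path
                new_T = np.clip(new_T, 1e-10, None)
                transmat = new_T / new_T.sum(axis=1, keepdims=True)
            pi = np.clip(resp[seg_starts].mean(axis=0), 1e-12, None)
            pi = pi / pi.sum()

            # E-step
            log_emit = _emission_loglik_matrix(Y, params[:, 0], params[:, 1], params[:, 2])
            ll, resp, xi_sum = _fb_segments(log_emit, transmat, pi, segments)
            trace.append(ll)
            n_done = it + 1
            if it > 0 and abs(trace[-1] - trace[-2]) < self.tol:
                break
        return params, transmat, pi, trace, n_done

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_json(self) -> str:
        payload = {
            "n_modes": int(len(self.offsets_)),
            "modes": [
                {"offset": float(s), "slope": float(a), "lapse": float(e)}
                for s, a, e in zip(self.offsets_, self.slopes_, self.lapses_)
            ],
            "transmat": np.asarray(self.transmat_).tolist(),
            "startprob": np.asarray(self.startprob_).tolist(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BlockHMM":
        payload = json.loads(text)
        modes = [(m["offset"], m["slope"], m["lapse"]) for m in payload["modes"]]
        return cls.from_params(modes, payload["transmat"], payload["startprob"])


# ---------------------------------------------------------------------- #
# module-level thin wrappers
# ---------------------------------------------------------------------- #
def forward_backward(model: BlockHMM, Y):
    """Exact marginal log-likelihood, posteriors and expected transitions.

    Returns ``(loglik, posteriors, xi_sum)`` where posteriors is B x K with
    rows summing to 1 and xi_sum is the K x K matrix of expected transition
    counts.  Computed in log space throughout.
    """
    log_emit = model.emission_loglik(Y)
    return _forward_backward_core(log_emit, model.transmat_, model.startprob_)


def sample_blockhmm(model: BlockHMM, n_blocks: int, block_len: int, random_state=None):
    return model.sample(n_blocks, block_len, random_state=random_state)


def fit_em(Y, K: int, **config) -> BlockHMM:
    """Fit a K-mode blockHMM; keyword arguments mirror BlockHMM's parameters."""
    return BlockHMM(n_modes=K, **config).fit(Y)


def most_likely_states(fit: BlockHMM) -> np.ndarray:
    """Marginal-MAP state sequence of a fitted model (ties -> lower index)."""
    return np.argmax(fit.posteriors_, axis=1)


def normalized_cv_loglik(Y, K: int, **config) -> CVResult:
    """Fit on a random 80% of blocks and score the held-out 20%.

    Returns the normalized score L_norm = (L_test - L_0) / (n_test log 2)
    where the null model is Bernoulli with the training-set rate.
    """
    config.setdefault("cv_fraction", 0.2)
    config.setdefault("refit_full", False)
    if config["cv_fraction"] <= 0:
        raise ValueError("normalized_cv_loglik requires a nonempty test split")
    model = BlockHMM(n_modes=K, **config).fit(Y)
    return model.cv_result_


def select_num_modes(Y, K_range=range(1, 7), *, se_rule: float = 1.0, **config) -> int:
    """Choose K maximizing the normalized cross-validated log-likelihood.

    The train/test split is held fixed across K (the same random_state seeds
    every candidate's fit, so the permutation is identical) and ties resolve
    to the smaller K.  Because the held-out log-likelihood plateaus once the
    true number of modes is reached, near-ties are resolved by the standard
    cross-validation one-standard-error rule: the smallest K whose held-out
    score is within ``se_rule`` standard errors of the maximum (paired SE
    over held-out segments) is selected.  ``se_rule=0`` recovers the strict
    float argmax.
    """
    K_range = sorted(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    config.setdefault("cv_fraction", 0.2)
    config.setdefault("refit_full", False)
    seed = config.pop("random_state", None)
    if seed is None:
        seed = 0
    scores = {}
    seg_lls = {}
    for K in K_range:
        model = BlockHMM(n_modes=K, random_state=seed, **config).fit(Y)
        scores[K] = model.cv_result_.L_norm
        seg_lls[K] = model.cv_segment_logliks_
    k_star = max(K_range, key=lambda k: (scores[k], -k))
    if se_rule > 0:
        for K in K_range:
            if K == k_star:
                return K
            d = seg_lls[k_star] - seg_lls[K]
            n = len(d)
            se = float(d.std(ddof=1)) * np.sqrt(n) if n > 1 else 0.0
            if d.sum() <= se_rule * se:
                return K
    return k_star
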