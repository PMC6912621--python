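"""Population hidden Markov model over daily drink-count sequences.

Each student contributes one sequence of 28 daily drink counts (7 days at
each of 4 diary waves, concatenated Monday-first).  A single parameter set
(initial distribution pi, transition matrix A, per-state emissions) is
shared across all students; sequences are independent realizations.

Emission families
-----------------
``hurdle`` (default): state k emits zero with probability ``1 - p_k`` and,
with probability ``p_k``, a zero-truncated Poisson count with rate
``lam_k``.  This represents the dominant zero mass of diary data
explicitly and keeps the BIC parameter count well defined:
``(K-1) + K(K-1) + 2K`` free parameters.

``bernoulli``: drinking indicator only (``(K-1) + K(K-1) + K`` free
parameters); available for sensitivity checks.

Missing days (NaN) are marginalized exactly: their emission term is
probability one, so the chain passes through them under the transition
model alone.

Estimation is Baum-Welch EM from random restarts with per-step scaling
(equivalent to log-space up to round-off, and vectorized across
sequences); decoding offers smoothed posteriors (forward-backward) and
Viterbi paths with ties broken toward the lower state index.  The number
of states is chosen by minimizing BIC, with n equal to the total count of
observed (non-missing) daily observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = ["HmmParameters", "HurdleHMM", "HurdleHMMResults",
           "emission_logprob", "forward_backward", "viterbi",
           "em_fit", "select_states", "bic"]

P_FLOOR = 1e-6           # emission probabilities kept off the simplex boundary
LAM_FLOOR = 1e-3


@dataclass
class HmmParameters:
    """HMM parameter set: K states, pi (K,), A (K, K), hurdle emissions."""

    initial: np.ndarray
    transition: np.ndarray
    p: np.ndarray                      # per-state daily drinking probability
    lam: np.ndarray | None = None      # per-state ZTP rate (None => bernoulli)

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.lam is not None:
            self.lam = np.asarray(self.lam, dtype=float)
        self.validate()

    @property
    def k_states(self) -> int:
        return self.initial.size

    @property
    def emission(self) -> str:
        return "bernoulli" if self.lam is None else "hurdle"

    @property
    def n_free_params(self) -> int:
        K = self.k_states
        per_state = 2 if self.lam is not None else 1
        return (K - 1) + K * (K - 1) + per_state * K

    def validate(self, atol: float = 1e-9) -> None:
        K = self.k_states
        if self.transition.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if abs(self.initial.sum() - 1.0) > atol:
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > atol):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("emission p outside [0, 1]")
        if self.lam is not None and np.any(self.lam <= 0):
            raise ValueError("emission rates must be positive")

    def to_dict(self) -> dict:
        return {"k_states": self.k_states,
                "initial": self.initial.tolist(),
                "transition": self.transition.tolist(),
                "p": self.p.tolist(),
                "lam": None if self.lam is None else self.lam.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParameters":
        return cls(np.array(d["initial"]), np.array(d["transition"]),
                   np.array(d["p"]),
                   None if d.get("lam") is None else np.array(d["lam"]))


def _ztp_logpmf(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log pmf of the zero-truncated Poisson, broadcasting y against lam."""
    y = np.asarray(y, dtype=float)
    return (y * np.log(lam) - lam - gammaln(y + 1.0)
            - np.log1p(-np.exp(-lam)))


def emission_logprob(obs, p, lam=None):
    """Log emission probability of one observation under one state.

    ``obs`` may be a nonnegative count or missing (None / NaN), in which
    case the observation is marginalized and the log-probability is
    exactly 0.  With ``lam`` given, the emission is the hurdle
    Bernoulli x zero-truncated-Poisson; without it, the Bernoulli drinking
    indicator (any positive count counts as drinking).
    """
    if obs is None or (np.isscalar(obs) and np.isnan(obs)):
        return 0.0
    if obs < 0:
        raise ValueError("drink counts must be nonnegative")
    p = float(np.clip(p, P_FLOOR, 1.0 - P_FLOOR))
    if obs == 0:
        return float(np.log1p(-p))
    if lam is None:
        return float(np.log(p))
    return float(np.log(p) + _ztp_logpmf(obs, max(float(lam), LAM_FLOOR)))


def _emission_matrix(seqs: np.ndarray, params: HmmParameters) -> np.ndarray:
    """Emission probabilities e[n, t, k]; exactly 1 for missing days.

    Drink counts repeat heavily, so emissions are evaluated once per
    distinct observed value and gathered, which keeps the E step cheap.
    """
    p = np.clip(params.p, P_FLOOR, 1.0 - P_FLOOR)
    miss = np.isnan(seqs)
    vals = np.where(miss, 0.0, seqs)
    uniq, inv = np.unique(vals, return_inverse=True)       # small table
    if params.lam is None:
        logdrink = np.broadcast_to(np.log(p), (uniq.size, p.size)).copy()
    else:
        lam = np.maximum(params.lam, LAM_FLOOR)
        logdrink = np.log(p) + _ztp_logpmf(uniq[:, None], lam)
    table = np.where(uniq[:, None] == 0, np.log1p(-p), logdrink)
    e = np.exp(table)[inv].reshape(seqs.shape + (p.size,))
    e[miss] = 1.0
    return e


def _forward_backward_batch(seqs: np.ndarray, params: HmmParameters):
    """Scaled forward-backward over a batch of sequences.

    Returns (logliks (N,), gamma (N,T,K), xi_sum (K,K), e (N,T,K)).
    """
    N, T = seqs.shape
    K = params.k_states
    e = _emission_matrix(seqs, params)
    A = params.transition
    alpha = np.empty((N, T, K))
    c = np.empty((N, T))
    a = params.initial[None, :] * e[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ A) * e[:, t, :]
        c[:, t] = a.sum(axis=1)
        alpha[:, t, :] = a / c[:, t, None]
    logliks = np.log(c).sum(axis=1)

    beta = np.empty((N, T, K))
    beta[:, T - 1, :] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bec = beta[:, t + 1, :] * e[:, t + 1, :] / c[:, t + 1, None]
        # xi[n, i, j] ~ alpha[n,t,i] A[i,j] e[n,t+1,j] beta[n,t+1,j] / c[n,t+1]
        xi_sum += (alpha[:, t, :].T @ bec) * A
        beta[:, t, :] = bec @ A.T
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return logliks, gamma, xi_sum, e


def forward_backward(seq, params: HmmParameters):
    """Log-likelihood and smoothed posteriors for one sequence.

    The log-likelihood equals the log of the sum over all state paths of
    the joint path probability; posteriors are the smoothed marginals
    P(state_t | all observations), whose rows sum to one.
    """
    seq = np.asarray(seq, dtype=float).reshape(1, -1)
    if seq.size == 0:
        raise ValueError("sequence must be nonempty")
    logliks, gamma, _, _ = _forward_backward_batch(seq, params)
    return float(logliks[0]), gamma[0]


def viterbi(seq, params: HmmParameters) -> np.ndarray:
    """Most probable state path; ties broken toward the lower state index."""
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        raise ValueError("sequence must be nonempty")
    return _viterbi_batch(seq.reshape(1, -1), params)[0]


def _viterbi_batch(seqs: np.ndarray, params: HmmParameters) -> np.ndarray:
    N, T = seqs.shape
    K = params.k_states
    with np.errstate(divide="ignore"):
        loge = np.log(_emission_matrix(seqs, params))
        logA = np.log(params.transition)
        logpi = np.log(params.initial)
    delta = logpi[None, :] + loge[:, 0, :]
    psi = np.empty((N, T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, :, None] + logA[None, :, :]     # (N, prev, cur)
        psi[:, t, :] = cand.argmax(axis=1)              # first max = low index
        delta = cand.max(axis=1) + loge[:, t, :]
    paths = np.empty((N, T), dtype=int)
    paths[:, T - 1] = delta.argmax(axis=1)
    for t in range(T - 2, -1, -1):
        paths[:, t] = psi[np.arange(N), t + 1, paths[:, t + 1]]
    return paths


def _ztp_rate_from_mean(mean: float) -> float:
    if mean <= 1.0 + 1e-9:
        return LAM_FLOOR
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return brentq(f, max(mean - 1.0, 1e-12), mean, xtol=1e-12)


def bic(total_loglik: float, n_free_params: int, n_observations: int) -> float:
    """Bayesian information criterion: -2 loglik + params * ln(n)."""
    return -2.0 * total_loglik + n_free_params * np.log(n_observations)


@dataclass
class HurdleHMMResults:
    """Fit results: parameters, likelihood, BIC, and decoding methods."""

    model: "HurdleHMM"
    params: HmmParameters
    total_loglik: float
    converged: bool
    n_iter: int
    n_restarts_used: int
    seed: int | None
    loglik_trace: list = field(default_factory=list, repr=False)

    @property
    def k_states(self) -> int:
        return self.params.k_states

    @property
    def llf(self) -> float:
        return self.total_loglik

    @property
    def n_free_params(self) -> int:
        return self.params.n_free_params

    @property
    def bic(self) -> float:
        return bic(self.total_loglik, self.n_free_params,
                   self.model.n_observations)

    def posteriors(self) -> np.ndarray:
        """Smoothed state posteriors, shape (n_sequences, T, K)."""
        _, gamma, _, _ = _forward_backward_batch(self.model.sequences,
                                                 self.params)
        return gamma

    def viterbi_paths(self) -> np.ndarray:
        """Viterbi state paths, shape (n_sequences, T)."""
        return _viterbi_batch(self.model.sequences, self.params)

    def logliks(self) -> np.ndarray:
        """Per-sequence log-likelihoods."""
        ll, _, _, _ = _forward_backward_batch(self.model.sequences,
                                              self.params)
        return ll

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Hurdle HMM fit: K={self.k_states} states, "
            f"emission={p.emission}",
            f"  sequences: {self.model.n_sequences}, observed days: "
            f"{self.model.n_observations}",
            f"  log-likelihood: {self.total_loglik:.3f}   "
            f"BIC: {self.bic:.3f}   free params: {self.n_free_params}",
            f"  converged: {self.converged} after {self.n_iter} iterations "
            f"({self.n_restarts_used} restarts, seed={self.seed})",
            "  state   pi      p(drink)  E[drinks|drink]  self-transition",
        ]
        for k in range(self.k_states):
            lam = p.lam[k] if p.lam is not None else float("nan")
            mean_q = lam / (1 - np.exp(-lam)) if p.lam is not None else float("nan")
            lines.append(f"  {k:>5d}  {p.initial[k]:.3f}   {p.p[k]:.3f}     "
                         f"{mean_q:>7.2f}          {p.transition[k, k]:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(),
                "total_loglik": self.total_loglik,
                "n_free_params": self.n_free_params,
                "bic": self.bic,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "n_restarts_used": self.n_restarts_used,
                "seed": self.seed}


class HurdleHMM:
    """Shared-parameter HMM for a batch of daily drink-count sequences.

    Parameters
    ----------
    sequences : array-like, shape (n_sequences, T)
        Daily drink counts; NaN marks missing days.
    k_states : int
        Number of hidden states.
    emission : {"hurdle", "bernoulli"}
        Emission family (see module docstring).
    """

    def __init__(self, sequences, k_states: int, emission: str = "hurdle"):
        seqs = np.asarray(sequences, dtype=float)
        if seqs.ndim == 1:
            seqs = seqs[None, :]
        if seqs.ndim != 2 or seqs.shape[0] < 1 or seqs.shape[1] < 1:
            raise ValueError("sequences must be a nonempty (N, T) array")
        if np.any(seqs[~np.isnan(seqs)] < 0):
            raise ValueError("drink counts must be nonnegative")
        if k_states < 1:
            raise ValueError("k_states must be >= 1")
        if emission not in ("hurdle", "bernoulli"):
            raise ValueError(f"unknown emission family {emission!r}")
        self.sequences = seqs
        self.k_states = int(k_states)
        self.emission = emission
        self.observed = ~np.isnan(seqs)
        self.n_sequences, self.n_obs_per_seq = seqs.shape
        self.n_observations = int(self.observed.sum())
        n_distinct = len(np.unique(seqs[self.observed])) if self.n_observations else 0
        if k_states > max(n_distinct ** 2, 1) and k_states > 1:
            warnings.warn(f"k_states={k_states} is large for "
                          f"{n_distinct} distinct observed values; "
                          "degenerate states are likely")

    # ------------------------------------------------------------------ EM
    def loglike(self, params: HmmParameters) -> float:
        """Total observed-data log-likelihood across all sequences."""
        ll, _, _, _ = _forward_backward_batch(self.sequences, params)
        return float(ll.sum())

    def _init_params(self, rng: np.random.Generator) -> HmmParameters:
        K = self.k_states
        pi = rng.dirichlet(np.ones(K))
        A = rng.dirichlet(np.ones(K), size=K)
        p = rng.uniform(0.05, 0.95, size=K)
        lam = rng.uniform(0.5, 8.0, size=K) if self.emission == "hurdle" else None
        return HmmParameters(pi, A, p, lam)

    def _m_step(self, gamma: np.ndarray, xi_sum: np.ndarray) -> HmmParameters:
        seqs, obs = self.sequences, self.observed
        K = self.k_states
        pi = gamma[:, 0, :].mean(axis=0)
        pi = pi / pi.sum()
        rows = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xi_sum / np.where(rows == 0, 1.0, rows),
                     1.0 / K)
        A = A / A.sum(axis=1, keepdims=True)

        g_obs = np.where(obs[..., None], gamma, 0.0)        # (N, T, K)
        drink = np.where(obs & (seqs > 0), 1.0, 0.0)
        denom = g_obs.sum(axis=(0, 1))
        num = np.einsum("ntk,nt->k", g_obs, drink)
        p = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), 0.0)
        p = np.clip(p, 0.0, 1.0)

        lam = None
        if self.emission == "hurdle":
            y = np.where(obs & (seqs > 0), seqs, 0.0)
            wsum = np.einsum("ntk,nt->k", g_obs, drink)
            ysum = np.einsum("ntk,nt->k", g_obs, y)
            lam = np.empty(K)
            for k in range(K):
                if wsum[k] <= 0:
                    lam[k] = LAM_FLOOR
                else:
                    lam[k] = _ztp_rate_from_mean(ysum[k] / wsum[k])
            lam = np.maximum(lam, LAM_FLOOR)
        return HmmParameters(pi, A, p, lam)

    def _fit_once(self, rng: np.random.Generator, tol: float, maxiter: int,
                  init: HmmParameters | None = None):
        params = init if init is not None else self._init_params(rng)
        trace = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            ll_vec, gamma, xi_sum, _ = _forward_backward_batch(
                self.sequences, params)
            ll = float(ll_vec.sum())
            trace.append(ll)
            if ll < prev - 1e-8:
                warnings.warn(f"EM log-likelihood decreased by {prev - ll:.3g}")
            if np.isfinite(prev) and abs(ll - prev) < tol * max(1.0, abs(ll)):
                converged = True
                break
            prev = ll
            params = self._m_step(gamma, xi_sum)
        # guard the simplex boundary on p (spec'd floor)
        params = HmmParameters(params.initial, params.transition,
                               np.clip(params.p, 0.0, 1.0), params.lam)
        return params, trace[-1], converged, it, trace

    def fit(self, n_restarts: int = 20, seed: int | None = None,
            tol: float = 1e-6, maxiter: int = 500,
            short_run_iter: int | None = 25,
            n_final: int = 3) -> HurdleHMMResults:
        """Baum-Welch EM from ``n_restarts`` random initializations.

        Restarts use a short-run strategy: every initialization is run for
        ``short_run_iter`` EM iterations, then only the ``n_final`` most
        promising (by log-likelihood) continue to full convergence.  This
        buys the local-optimum protection of many restarts at a fraction
        of the cost; set ``short_run_iter=None`` to run every restart to
        convergence.  Returns the restart with the highest final
        log-likelihood; deterministic given ``seed``.  ``tol`` is the
        relative log-likelihood change declaring convergence.
        """
        if tol <= 0:
            raise ValueError("tol must be positive")
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        rng = np.random.default_rng(seed)
        best = None
        if short_run_iter is None or n_restarts <= n_final:
            for _ in range(n_restarts):
                params, ll, conv, it, trace = self._fit_once(rng, tol, maxiter)
                if best is None or ll > best[1]:
                    best = (params, ll, conv, it, trace)
        else:
            short = []
            for _ in range(n_restarts):
                short.append(self._fit_once(rng, tol, short_run_iter))
            short.sort(key=lambda r: r[1], reverse=True)
            for params0, _, conv0, it0, trace0 in short[:n_final]:
                if conv0:
                    cand = (params0, trace0[-1], conv0, it0, trace0)
                else:
                    params, ll, conv, it, trace = self._fit_once(
                        rng, tol, maxiter, init=params0)
                    cand = (params, ll, conv, it0 + it, trace0[:-1] + trace)
                if best is None or cand[1] > best[1]:
                    best = cand
        params, ll, conv, it, trace = best
        return HurdleHMMResults(self, params, ll, conv, it, n_restarts, seed,
                                trace)


def em_fit(sequences, k_states: int, n_restarts: int = 20,
           seed: int | None = None, tol: float = 1e-6,
           maxiter: int = 500, emission: str = "hurdle",
           short_run_iter: int | None = 25,
           n_final: int = 3) -> HurdleHMMResults:
    """Convenience wrapper: build a :class:`HurdleHMM` and fit it."""
    return HurdleHMM(sequences, k_states, emission).fit(
        n_restarts=n_restarts, seed=seed, tol=tol, maxiter=maxiter,
        short_run_iter=short_run_iter, n_final=n_final)


def select_states(sequences, k_range, n_restarts: int = 20,
                  seed: int | None = None, tol: float = 1e-6,
                  maxiter: int = 500, emission: str = "hurdle",
                  short_run_iter: int | None = 25, n_final: int = 3):
    """Fit every K in ``k_range`` and return the BIC minimizer.

    Returns ``(best_results, results_by_k)``.  Ties in BIC go to the
    smaller K; a failure at one K is recorded (``None`` in the dict) and
    only fatal if every K fails.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    results: dict[int, HurdleHMMResults | None] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(len(k_range))]
    for k, s in zip(k_range, child_seeds):
        try:
            results[k] = em_fit(sequences, k, n_restarts=n_restarts, seed=s,
                                tol=tol, maxiter=maxiter, emission=emission,
                                short_run_iter=short_run_iter, n_final=n_final)
        except Exception as exc:   # pragma: no cover - defensive
            warnings.warn(f"fit failed for K={k}: {exc}")
            results[k] = None
    ok = {k: r for k, r in results.items() if r is not None}
    if not ok:
        raise RuntimeError("state selection failed for every K")
    best_k = min(sorted(ok), key=lambda k: ok[k].bic)
    return ok[best_k], results
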