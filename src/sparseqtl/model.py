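"""Integrated posterior score for sparse Bayesian (multi-)regression.

The model: expression Y (n x q, columns centered) regressed on the included
genotype columns X_gamma,

    Y = X_gamma B_gamma + E,   rows of E ~ N_q(0, Sigma),

with a conjugate prior stack that can be integrated analytically:

* B_gamma | Sigma, tau  ~ matrix-normal, row covariance tau (X'X)^{-1}
  (Zellner g-prior) and column covariance Sigma;
* Sigma ~ Inverse-Wishart with shape delta and scale Q = k I_q, in the
  convention where E(Sigma) = Q / (delta - 2);
* gamma ~ exchangeable Bernoulli with Beta-integrated inclusion rate
  (Beta-Binomial model-size prior);
* tau ~ hyper-g style shrinkage prior, truncated to (0, max(n, p^2)].

Integrating B and Sigma leaves a closed-form score over (gamma, tau):

    log f(Y | gamma, tau) = -(q p_g / 2) log(1 + tau)
        - (n + delta + q - 1)/2 * log det(Q + Y'Y - tau/(1+tau) Y'P_g Y)

up to a gamma- and tau-free constant, with P_g the orthogonal projector on
the column space of X_gamma.  For q = 1 this is the usual single-response
g-prior marginal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, logsumexp

from .datatypes import ExpressionPanel, GenotypePanel, ModelIndicator

__all__ = [
    "Hyperparameters",
    "solve_beta_binomial",
    "log_model_size_prior",
    "log_tau_prior",
    "tau_grid_log_prior",
    "ScoreWorkspace",
    "log_score",
    "enumerate_posterior",
]

_RANK_TOL = 1e-10


def solve_beta_binomial(e_size: float, v_size: float, p: int) -> tuple[float, float]:
    """Beta-Binomial hyperparameters (a, b) from a target model-size mean
    and variance with p trials.

    The moment equations invert in closed form: with pi = E/p and
    R = V / (p pi (1 - pi)) the overdispersion ratio, the Beta total
    concentration is s = a + b = (p - R) / (R - 1).

    Raises ValueError when (e_size, v_size) is infeasible: the variance
    must exceed the Binomial variance e(1 - e/p) (overdispersion) and stay
    below the two-point-mass bound e(p - e).
    """
    if not 0 < e_size < p:
        raise ValueError(f"e_size must lie in (0, {p}); got {e_size}")
    pi = e_size / p
    binom_var = p * pi * (1.0 - pi)
    if v_size <= binom_var:
        raise ValueError(
            "infeasible Beta-Binomial moments: v_size must exceed the "
            f"Binomial variance e(1 - e/p) = {binom_var:.6g}; got {v_size}"
        )
    R = v_size / binom_var
    if R >= p:
        raise ValueError(
            "infeasible Beta-Binomial moments: v_size must be below "
            f"e_size (p - e_size) = {e_size * (p - e_size):.6g}"
        )
    s = (p - R) / (R - 1.0)
    return pi * s, (1.0 - pi) * s


@dataclass
class Hyperparameters:
    """Model hyperparameters with the defaults used throughout.

    delta is the Inverse-Wishart shape (>= 3 so the prior mean of Sigma
    exists); k_scale sets Q = k I_q; (e_size, v_size) are the prior mean
    and variance of the number of genetic control points, fixed at (2, 2)
    so the prior model size ranges roughly over 0..12 with larger models
    increasingly penalised.
    """

    p: int
    n: int
    delta: float = 3.0
    k_scale: float = 0.1
    e_size: float = 2.0
    v_size: float = 2.0
    max_model_size: int = 15
    tau_grid_size: int = 100
    a_bb: float = field(init=False)
    b_bb: float = field(init=False)
    tau_grid: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.delta <= 2:
            raise ValueError("delta must exceed 2 (finite Inverse-Wishart mean)")
        if self.k_scale <= 0:
            raise ValueError("k_scale must be positive")
        self.a_bb, self.b_bb = solve_beta_binomial(self.e_size, self.v_size, self.p)
        upper = self.tau_upper
        self.tau_grid = np.geomspace(1.0, upper, self.tau_grid_size)

    @property
    def tau_upper(self) -> float:
        """Upper truncation of the shrinkage prior: max(n, p^2)."""
        return float(max(self.n, self.p**2))

    @classmethod
    def from_data(cls, Y: np.ndarray, p: int, **kw) -> "Hyperparameters":
        """Build hyperparameters for a given expression matrix.

        k_scale defaults to 0.1 x the mean per-tissue sample variance,
        a weakly informative, scale-matched error-variance prior.
        """
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] == 1:
            Y = Y.T
        n = Y.shape[0]
        if "k_scale" not in kw:
            kw["k_scale"] = 0.1 * float(np.mean(np.var(Y, axis=0, ddof=1)))
        return cls(p=p, n=n, **kw)


def log_model_size_prior(gamma: ModelIndicator | int, hyper: Hyperparameters) -> float:
    """Log prior mass of one model configuration of the given size.

    Exchangeable per-configuration form: p(gamma) = B(a + k, b + p - k)/B(a, b)
    with k = |gamma|.  Summing over the C(p, k) configurations of each size
    recovers the Beta-Binomial size distribution.
    """
    k = gamma.size if isinstance(gamma, ModelIndicator) else int(gamma)
    if not 0 <= k <= hyper.p:
        raise ValueError("model size out of range")
    a, b = hyper.a_bb, hyper.b_bb
    return float(betaln(a + k, b + hyper.p - k) - betaln(a, b))


def log_tau_prior(tau: float, n: int, p: int) -> float:
    """Log density of the truncated shrinkage prior on tau.

    p(tau) proportional to (1 + tau)^(-3/2) on (0, U], U = max(n, p^2):
    a hyper-g style density with mode at 0 and finite mean, normalised in
    closed form over the truncated support.
    """
    upper = float(max(n, p**2))
    if not 0.0 < tau <= upper:
        raise ValueError(f"tau must lie in (0, {upper}]; got {tau}")
    log_norm = math.log(2.0 * (1.0 - (1.0 + upper) ** -0.5))
    return -1.5 * math.log1p(tau) - log_norm


def tau_grid_log_prior(hyper: Hyperparameters) -> np.ndarray:
    """Log probabilities of the discretised tau prior over hyper.tau_grid.

    The continuous prior is discretised by assigning each grid point mass
    proportional to density x geometric cell width (log-space trapezoid),
    so the discrete measure approximates the continuous prior integral
    over the grid range rather than over-weighting small tau.  The same
    measure is used consistently by the Gibbs update, the model-evidence
    grid summation and the enumeration oracle.
    """
    grid = hyper.tau_grid
    dens = -1.5 * np.log1p(grid)
    if grid.size > 1:
        logt = np.log(grid)
        width = np.empty_like(grid)
        width[1:-1] = 0.5 * (logt[2:] - logt[:-2])
        width[0] = 0.5 * (logt[1] - logt[0])
        width[-1] = 0.5 * (logt[-1] - logt[-2])
        dens = dens + logt + np.log(width)
    return dens - logsumexp(dens)


class ScoreWorkspace:
    """Caches per-model sufficient statistics for fast repeated scoring.

    For each visited gamma the q x q matrix Y' P_gamma Y and the model size
    are stored; every (gamma, tau) score is then an O(q^3) determinant.
    """

    def __init__(
        self,
        Y: ExpressionPanel | np.ndarray,
        X: GenotypePanel | np.ndarray,
        hyper: Hyperparameters | None = None,
        max_cache: int = 200_000,
    ):
        if isinstance(Y, ExpressionPanel):
            if not Y.is_centered:
                Y = Y.center()
            Ymat = Y.values
        else:
            Ymat = np.atleast_2d(np.asarray(Y, dtype=float))
            if Ymat.shape[0] == 1:
                Ymat = Ymat.T
            Ymat = Ymat - Ymat.mean(axis=0, keepdims=True)
        Xmat = X.codes if isinstance(X, GenotypePanel) else np.asarray(X, float)
        if Xmat.shape[0] != Ymat.shape[0]:
            raise ValueError("Y and X strain counts differ")
        if np.isnan(Xmat).any():
            raise ValueError("genotypes contain missing values; impute first")
        self.Y = Ymat
        self.X = Xmat
        self.n, self.q = Ymat.shape
        self.p = Xmat.shape[1]
        self.hyper = hyper if hyper is not None else Hyperparameters.from_data(Ymat, self.p)
        self.YtY = Ymat.T @ Ymat
        self.Q = self.hyper.k_scale * np.eye(self.q)
        self.A = self.Q + self.YtY  # constant part of the determinant matrix
        self._sign, self._logdet_A = np.linalg.slogdet(self.A)
        self.size_cap = min(self.hyper.max_model_size, self.n - 1, self.p)
        self._cache: dict[tuple, tuple[int, np.ndarray] | None] = {}
        self._grid_cache: dict[tuple, np.ndarray] = {}
        self._max_cache = max_cache
        self.log_size_prior = np.array(
            [log_model_size_prior(k, self.hyper) for k in range(self.size_cap + 1)]
        )
        self.tau_grid = self.hyper.tau_grid
        self._tau_pos = {float(t): i for i, t in enumerate(self.tau_grid)}
        self.log_tau_grid_prior = tau_grid_log_prior(self.hyper)
        self._exponent = 0.5 * (self.n + self.hyper.delta + self.q - 1)

    # -- sufficient statistics -------------------------------------------------

    def stats(self, included: tuple) -> tuple[int, np.ndarray] | None:
        """(model size, Y' P_gamma Y) for the model, or None if the reduced
        design is rank deficient at tolerance 1e-10 x leading singular value."""
        got = self._cache.get(included, False)
        if got is not False:
            return got
        k = len(included)
        if k == 0:
            out = (0, np.zeros((self.q, self.q)))
        else:
            Xg = self.X[:, list(included)]
            u, s, _ = np.linalg.svd(Xg, full_matrices=False)
            if s[0] <= 0 or s[-1] <= _RANK_TOL * s[0]:
                out = None
            else:
                UtY = u.T @ self.Y
                out = (k, UtY.T @ UtY)
        if len(self._cache) >= self._max_cache:
            self._cache.clear()
        self._cache[included] = out
        return out

    def collinear_members(self, included: tuple) -> list[int]:
        """Identify a minimal set of included markers causing rank deficiency."""
        bad = []
        kept: list[int] = []
        for j in included:
            cand = kept + [j]
            s = np.linalg.svd(self.X[:, cand], compute_uv=False)
            if s[-1] <= _RANK_TOL * s[0]:
                bad.append(j)
            else:
                kept.append(j)
        return bad

    # -- scores ----------------------------------------------------------------

    def log_lik(self, included: tuple, tau: float) -> float:
        """Integrated log marginal likelihood part of the score (no priors).

        Returns -inf for rank-deficient designs (used as an automatic
        Metropolis rejection inside the sampler).  Evaluations at tau grid
        points go through the cached per-model grid vector.
        """
        pos = self._tau_pos.get(float(tau))
        if pos is not None:
            return float(self.log_lik_grid(included)[pos])
        st = self.stats(included)
        if st is None:
            return -np.inf
        k, YtPY = st
        if k == 0:
            return -self._exponent * self._logdet_A
        c = tau / (1.0 + tau)
        sign, logdet = np.linalg.slogdet(self.A - c * YtPY)
        if sign <= 0:
            return -np.inf
        return -0.5 * self.q * k * math.log1p(tau) - self._exponent * logdet

    def log_lik_grid(self, included: tuple) -> np.ndarray:
        """Integrated log likelihood at every tau grid point (vectorised,
        cached per model)."""
        cached = self._grid_cache.get(included)
        if cached is not None:
            return cached
        st = self.stats(included)
        if st is None:
            out = np.full(self.tau_grid.size, -np.inf)
        else:
            k, YtPY = st
            if k == 0:
                out = np.full(self.tau_grid.size, -self._exponent * self._logdet_A)
            else:
                c = self.tau_grid / (1.0 + self.tau_grid)
                mats = self.A[None, :, :] - c[:, None, None] * YtPY[None, :, :]
                sign, logdet = np.linalg.slogdet(mats)
                out = -0.5 * self.q * k * np.log1p(self.tau_grid) - self._exponent * logdet
                out[sign <= 0] = -np.inf
        if len(self._grid_cache) >= self._max_cache:
            self._grid_cache.clear()
        self._grid_cache[included] = out
        return out

    def log_posterior(self, included: tuple, tau: float) -> float:
        """log p(gamma, tau | Y) up to a constant (likelihood + both priors)."""
        k = len(included)
        if k > self.size_cap:
            return -np.inf
        return (
            self.log_lik(included, tau)
            + self.log_size_prior[k]
            + log_tau_prior(tau, self.n, self.p)
        )

    def log_evidence(self, included: tuple) -> float:
        """Tau-integrated (grid summation) log marginal likelihood of a model."""
        return float(logsumexp(self.log_lik_grid(included) + self.log_tau_grid_prior))

    def log_model_posterior(self, included: tuple) -> float:
        """Tau-integrated unnormalised log posterior (evidence x size prior)."""
        k = len(included)
        if k > self.size_cap:
            return -np.inf
        return self.log_evidence(included) + self.log_size_prior[k]


def log_score(
    Y: ExpressionPanel | np.ndarray,
    X: GenotypePanel | np.ndarray,
    gamma: ModelIndicator,
    tau: float,
    hyper: Hyperparameters | None = None,
) -> float:
    """Log unnormalised joint posterior density of (gamma, tau) given data.

    Convenience wrapper over ScoreWorkspace for one-off evaluations.
    Raises on rank-deficient included designs and on models larger than
    min(n - 1, max_model_size).
    """
    ws = ScoreWorkspace(Y, X, hyper)
    if gamma.size > ws.size_cap:
        raise ValueError(
            f"model size {gamma.size} exceeds cap {ws.size_cap} "
            "(min of max_model_size and n - 1)"
        )
    if ws.stats(gamma.included) is None:
        bad = ws.collinear_members(gamma.included)
        raise np.linalg.LinAlgError(
            f"reduced design is rank deficient; collinear markers: {bad}"
        )
    return ws.log_posterior(gamma.included, tau)


def enumerate_posterior(ws: ScoreWorkspace) -> dict:
    """Exact posterior over (gamma, tau_grid) by full enumeration.

    Feasible for p <= ~12.  Returns marginal inclusion probabilities, the
    model-size posterior, per-model probabilities and the argmax model,
    all under the same discretised tau measure the sampler uses.
    """
    from itertools import combinations

    p = ws.p
    models = []
    scores = []
    for k in range(min(ws.size_cap, p) + 1):
        for combo in combinations(range(p), k):
            s = ws.log_model_posterior(combo)
            if np.isfinite(s):
                models.append(combo)
                scores.append(s)
    scores = np.asarray(scores)
    probs = np.exp(scores - logsumexp(scores))
    mppi = np.zeros(p)
    size_post = np.zeros(ws.size_cap + 1)
    for combo, pr in zip(models, probs):
        size_post[len(combo)] += pr
        for j in combo:
            mppi[j] += pr
    best = models[int(np.argmax(scores))]
    return {
        "models": models,
        "probs": probs,
        "mppi": mppi,
        "size_posterior": size_post,
        "best": ModelIndicator(best, p),
    }
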