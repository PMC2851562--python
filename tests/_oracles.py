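"""Independent oracle implementations used to verify the package.

Everything here is deliberately written through a different algebraic or
numerical path than the library code (QR residual sums, brute-force grid
search, direct Monte-Carlo integration) so agreement is evidence of
correctness rather than of shared bugs.
"""

import numpy as np
from scipy.special import logsumexp
from scipy.stats import invwishart


def q1_g_prior_log_marginal(y, X, included, tau, delta, k_scale):
    """Single-response g-prior integrated log marginal (up to a model- and
    tau-free constant) via QR-based residual sums.

    With sigma^2 ~ scaled inverse-chi-square carrying shape delta and scale
    k_scale, and beta | sigma^2 ~ N(0, tau sigma^2 (X'X)^{-1}):

        log p(y | gamma, tau) = -(k_gamma/2) log(1+tau)
            - (n+delta)/2 * log( k_scale + RSS + y'P y / (1+tau) )

    where RSS is the residual sum of squares of the least-squares fit and
    y'P y the fitted sum of squares (RSS + y'P y = y'y).
    """
    y = np.asarray(y, float).ravel()
    y = y - y.mean()
    n = y.size
    if included:
        Q, _ = np.linalg.qr(np.asarray(X, float)[:, list(included)])
        fitted = Q @ (Q.T @ y)
        ypy = float(fitted @ fitted)
        rss = float((y - fitted) @ (y - fitted))
    else:
        ypy = 0.0
        rss = float(y @ y)
    S = k_scale + rss + ypy / (1.0 + tau)
    return -0.5 * len(included) * np.log1p(tau) - 0.5 * (n + delta) * np.log(S)


def q1_log_evidence(y, X, included, ws):
    """Grid tau-integrated q=1 log evidence via the oracle formula and the
    workspace's discretised tau measure."""
    liks = np.array(
        [
            q1_g_prior_log_marginal(
                y, X, included, t, ws.hyper.delta, ws.hyper.k_scale
            )
            for t in ws.tau_grid
        ]
    )
    return float(logsumexp(liks + ws.log_tau_grid_prior))


def beta_binomial_moments(a, b, p):
    """Exact Beta-Binomial mean and variance by summation over sizes 0..p."""
    from scipy.stats import betabinom

    ks = np.arange(p + 1)
    pmf = betabinom.pmf(ks, p, a, b)
    mean = float((ks * pmf).sum())
    var = float(((ks - mean) ** 2 * pmf).sum())
    return mean, var


def brute_force_beta_binomial(e, v, p, grid=None):
    """Grid search over (a, b) minimising the squared moment error."""
    if grid is None:
        grid = np.geomspace(0.05, 50, 220)
    best = None
    best_err = np.inf
    for a in grid:
        for b in grid:
            m, s2 = beta_binomial_moments(a, b, p)
            err = (m - e) ** 2 + (s2 - v) ** 2
            if err < best_err:
                best_err = err
                best = (a, b)
    return best


def mc_log_marginal(Y, X, included, tau, delta, k_scale, n_draws, rng, n_batches=10):
    """Direct Monte-Carlo estimate of log p(Y | gamma, tau) including all
    constants, by averaging the exact matrix-normal likelihood over prior
    draws of (Sigma, B).  Returns (estimate, standard error) with the SE
    from batch means.
    """
    Y = np.asarray(Y, float)
    Y = Y - Y.mean(axis=0, keepdims=True)
    n, q = Y.shape
    k = len(included)
    Q = k_scale * np.eye(q)
    df = delta + q - 1  # scipy df for the Dawid-convention shape delta
    if k:
        Xg = np.asarray(X, float)[:, list(included)]
        Lx = np.linalg.cholesky(tau * np.linalg.inv(Xg.T @ Xg))
    batch = n_draws // n_batches
    batch_lse = np.empty(n_batches)
    for bi in range(n_batches):
        Sig = invwishart.rvs(df=df, scale=Q, size=batch, random_state=rng)
        Sig = Sig.reshape(batch, q, q)
        Ls = np.linalg.cholesky(Sig)
        if k:
            Z = rng.standard_normal((batch, k, q))
            B = np.einsum("ij,bjq->biq", Lx, Z) @ np.transpose(Ls, (0, 2, 1))
            R = Y[None, :, :] - np.einsum("nk,bkq->bnq", Xg, B)
        else:
            R = np.broadcast_to(Y, (batch, n, q))
        # log N(R_i; 0, Sigma) summed over rows, batched via cholesky solves
        V = np.linalg.solve(Ls, np.transpose(R, (0, 2, 1)))  # (b, q, n)
        quad = np.einsum("bqn,bqn->b", V, V)
        logdet = 2.0 * np.log(np.einsum("bii->bi", Ls)).sum(axis=1)
        loglik = -0.5 * (n * q * np.log(2 * np.pi) + n * logdet + quad)
        batch_lse[bi] = logsumexp(loglik) - np.log(batch)
    est = logsumexp(batch_lse) - np.log(n_batches)
    se = float(np.std(batch_lse, ddof=1) / np.sqrt(n_batches))
    return float(est), se


def mc_score_constant(n, q, delta, k_scale, tau_unused=None):
    """The gamma- and tau-free constant connecting the library's truncated
    score to the full log marginal: log p = const + library_score."""
    from scipy.special import multigammaln

    Q = k_scale * np.eye(q)
    _, logdet_Q = np.linalg.slogdet(Q)
    a = 0.5 * (delta + q - 1)
    return (
        -0.5 * n * q * np.log(np.pi)
        + multigammaln(a + 0.5 * n, q)
        - multigammaln(a, q)
        + a * logdet_Q
    )
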