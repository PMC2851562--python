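"""Classical single-marker comparators for the Bayesian multi-locus model.

Per-marker scans: a two-sample Hotelling T^2 scan across tissues (with a
Box's M covariance-homogeneity check), a univariate marker-regression scan
with permutation genome-wide p-values, and the two-stage sequential search
for up to two additive eQTLs.  Multiple testing over markers or traits is
handled with Storey's q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ScanResult",
    "hotelling_scan",
    "boxs_m_test",
    "marginal_scan",
    "ssm_two_stage",
    "storey_qvalues",
]


@dataclass
class ScanResult:
    statistic: np.ndarray
    pvalue: np.ndarray
    qvalue: np.ndarray | None = None
    skipped: np.ndarray = field(default=None)
    flags: dict = field(default_factory=dict)

    def peak(self) -> int:
        stat = np.where(self.skipped, -np.inf, self.statistic)
        return int(np.nanargmax(stat))


def _groups(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split strains by founder allele (sign of the genotype code);
    exactly-zero imputed calls are assigned to neither group."""
    return np.flatnonzero(x < 0), np.flatnonzero(x > 0)


def boxs_m_test(Y1: np.ndarray, Y2: np.ndarray) -> float:
    """Box's M test p-value for equality of two group covariance matrices
    (chi-square approximation)."""
    n1, q = Y1.shape
    n2 = Y2.shape[0]
    S1 = np.cov(Y1, rowvar=False, ddof=1)
    S2 = np.cov(Y2, rowvar=False, ddof=1)
    v1, v2 = n1 - 1, n2 - 1
    Sp = (v1 * S1 + v2 * S2) / (v1 + v2)
    sign, logdet_p = np.linalg.slogdet(Sp)
    s1, l1 = np.linalg.slogdet(np.atleast_2d(S1))
    s2, l2 = np.linalg.slogdet(np.atleast_2d(S2))
    if sign <= 0 or s1 <= 0 or s2 <= 0:
        return np.nan
    M = (v1 + v2) * logdet_p - v1 * l1 - v2 * l2
    c = (
        (1 / v1 + 1 / v2 - 1 / (v1 + v2))
        * (2 * q**2 + 3 * q - 1)
        / (6 * (q + 1))
    )
    dof = q * (q + 1) / 2
    return float(stats.chi2.sf(M * (1 - c), dof))


def hotelling_scan(Y: np.ndarray, X: np.ndarray, box_alpha: float = 0.05) -> ScanResult:
    """Two-sample Hotelling T^2 scan over markers, all tissues jointly.

    Strains are grouped by founder allele at each marker; the T^2
    statistic is F-transformed for the p-value.  Markers whose groups are
    smaller than q + 1 are skipped with a flag.  Box's M covariance
    homogeneity is checked per marker at box_alpha; failures are flagged
    but the T^2 p-value is still reported.  For q = 1 use marginal_scan.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] == 1:
        Y = Y.T
    n, q = Y.shape
    if q < 2:
        raise ValueError("hotelling_scan needs q >= 2; use marginal_scan for q = 1")
    p = X.shape[1]
    stat = np.full(p, np.nan)
    pval = np.full(p, np.nan)
    skipped = np.zeros(p, dtype=bool)
    box_fail = np.zeros(p, dtype=bool)
    for j in range(p):
        g1, g2 = _groups(X[:, j])
        n1, n2 = len(g1), len(g2)
        if n1 < q + 1 or n2 < q + 1:
            skipped[j] = True
            continue
        Y1, Y2 = Y[g1], Y[g2]
        d = Y1.mean(axis=0) - Y2.mean(axis=0)
        Sp = ((n1 - 1) * np.cov(Y1, rowvar=False) + (n2 - 1) * np.cov(Y2, rowvar=False)) / (
            n1 + n2 - 2
        )
        try:
            sol = np.linalg.solve(Sp, d)
        except np.linalg.LinAlgError:
            skipped[j] = True
            continue
        t2 = (n1 * n2) / (n1 + n2) * float(d @ sol)
        dof2 = n1 + n2 - q - 1
        f = t2 * dof2 / ((n1 + n2 - 2) * q)
        stat[j] = t2
        pval[j] = stats.f.sf(f, q, dof2)
        bp = boxs_m_test(Y1, Y2)
        box_fail[j] = np.isfinite(bp) and bp < box_alpha
    return ScanResult(
        statistic=stat, pvalue=pval, skipped=skipped, flags={"box_m_fail": box_fail}
    )


def _marker_f_stats(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-marker simple-regression F statistics.

    Returns (F, valid); constant genotype columns are invalid.
    """
    n = y.shape[0]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    valid = sxx > 1e-12
    syy = float(yc @ yc)
    sxy = yc @ Xc
    F = np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(valid, sxy**2 / np.maximum(sxx * syy, 1e-300), 0.0)
        F = np.where(valid, (n - 2) * r2 / np.maximum(1.0 - r2, 1e-12), 0.0)
    return F, valid


def marginal_scan(
    y: np.ndarray,
    X: np.ndarray,
    n_perms: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ScanResult:
    """Single-tissue marker-regression scan with permutation genome-wide
    p-values.

    Expression is regressed on the genotype code marker by marker (imputed
    fractional codes enter as-is); the genome-wide p-value of a marker is
    the fraction of permutations whose maximum F statistic reaches the
    marker's observed F (add-one corrected).
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    y = np.asarray(y, float).ravel()
    F, valid = _marker_f_stats(y, X)
    null_max = np.empty(n_perms)
    for b in range(n_perms):
        Fb, _ = _marker_f_stats(rng.permutation(y), X)
        null_max[b] = Fb.max()
    exceed = (null_max[None, :] >= F[:, None]).sum(axis=1)
    p_gw = (1.0 + exceed) / (1.0 + n_perms)
    p_gw = np.where(valid, p_gw, np.nan)
    n = y.size
    p_nom = np.where(valid, stats.f.sf(F, 1, n - 2), np.nan)
    return ScanResult(
        statistic=np.where(valid, F, np.nan),
        pvalue=p_gw,
        skipped=~valid,
        flags={"nominal_pvalue": p_nom},
    )


def _conditional_f_stats(y: np.ndarray, X: np.ndarray, primary: int) -> np.ndarray:
    """F statistics for each marker added to an additive model that already
    contains the primary locus (the primary's own entry is 0)."""
    n = y.size
    x0 = X[:, primary] - X[:, primary].mean()
    nrm = x0 @ x0
    yc = y - y.mean()
    r = yc - x0 * (x0 @ yc) / nrm
    Xc = X - X.mean(axis=0, keepdims=True)
    Xr = Xc - np.outer(x0, (x0 @ Xc) / nrm)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    valid = sxx > 1e-12
    srr = float(r @ r)
    sxy = r @ Xr
    with np.errstate(divide="ignore", invalid="ignore"):
        ess = np.where(valid, sxy**2 / np.maximum(sxx, 1e-300), 0.0)
        rss = np.maximum(srr - ess, 1e-300)
        F = np.where(valid, ess / (rss / (n - 3)), 0.0)
    F[primary] = 0.0
    return F


def ssm_two_stage(
    y: np.ndarray,
    X: np.ndarray,
    fdr_level: float = 0.05,
    rng: np.random.Generator | int | None = None,
    use_permutation_stage1: bool = False,
    n_perms: int = 1000,
) -> list[int]:
    """Two-stage sequential search for up to two additive eQTLs.

    Stage 1: marginal scan; the peak marker is the primary locus if its
    q-value (over nominal per-marker p-values; optionally its permutation
    genome-wide p-value) is <= fdr_level.  Stage 2: every remaining marker
    is tested in an additive two-locus model containing the primary, with
    the same q-value machinery on the conditional p-values.  Purely
    additive: no gene-by-gene interaction term.
    """
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must be in (0, 1)")
    y = np.asarray(y, float).ravel()
    n = y.size
    F, valid = _marker_f_stats(y, X)
    if not valid.any():
        return []
    p_nom = np.where(valid, stats.f.sf(F, 1, n - 2), np.nan)
    if use_permutation_stage1:
        res = marginal_scan(y, X, n_perms=n_perms, rng=rng)
        peak = res.peak()
        if not res.pvalue[peak] <= fdr_level:
            return []
        primary = peak
    else:
        q1 = storey_qvalues(p_nom[valid])
        qfull = np.full(X.shape[1], np.nan)
        qfull[valid] = q1
        primary = int(np.nanargmax(np.where(valid, F, -np.inf)))
        if not qfull[primary] <= fdr_level:
            return []
    F2 = _conditional_f_stats(y, X, primary)
    ok = (F2 > 0) & valid
    ok[primary] = False
    if not ok.any():
        return [primary]
    p2 = stats.f.sf(F2[ok], 1, n - 3)
    q2 = storey_qvalues(p2)
    idx_ok = np.flatnonzero(ok)
    best = int(np.argmax(F2[ok]))
    if q2[best] <= fdr_level:
        return [primary, int(idx_ok[best])]
    return [primary]


def storey_qvalues(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with the cubic-smoother pi0 estimate.

    pi0 is estimated on the grid lambda = 0.05, 0.10, ..., 0.90 by a cubic
    polynomial fit to pi0(lambda) evaluated at the largest lambda (a
    conventional smoother choice), clipped to (0, 1]; q-values are the
    usual step-up transform of pi0 * p * m / rank.
    """
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.901, 0.05)
    if m < 8:
        pi0 = 1.0
    else:
        pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
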