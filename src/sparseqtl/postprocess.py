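"""Post-processing of significant models into interpretable eQTL reports.

Linked markers that enter a best model together are collapsed into genetic
control points (5 cM single-linkage windows); control points are labelled
cis or trans against the probe's genomic location (10 Mbp window); markers
that recur across the well-supported visited models are flagged as having
a noticeable effect; and effect sizes / residual correlations are drawn
from their exact conditional posterior given the filtered model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import invwishart

from .datatypes import MarkerMap, ModelIndicator
from .model import ScoreWorkspace
from .sampler import VisitedModelTrace
from .summaries import ThresholdRule

__all__ = [
    "FilteredModel",
    "EffectDraws",
    "ResidualCorrelation",
    "collapse_linked_markers",
    "count_distinct_eqtls",
    "classify_cis_trans",
    "noticeable_markers",
    "tau_posterior_given_model",
    "sample_effect_sizes",
    "residual_correlation",
]


@dataclass
class FilteredModel:
    """Best model after collapsing linked markers.

    One representative per linked cluster; clusters maps representative
    index -> list of member indices (including the representative).
    """

    representatives: list[int]
    clusters: dict[int, list[int]]
    source: ModelIndicator

    @property
    def size(self) -> int:
        return len(self.representatives)


@dataclass
class EffectDraws:
    """Posterior draws of the tissues x markers effect matrix."""

    draws: np.ndarray  # (n_draws, n_markers, n_tissues)
    markers: list[int]
    mean: np.ndarray  # (n_markers, n_tissues)
    quantiles: dict[float, np.ndarray]


@dataclass
class ResidualCorrelation:
    posterior_mean: np.ndarray  # q x q
    raw_empirical: np.ndarray  # q x q


def collapse_linked_markers(
    model: ModelIndicator,
    marker_map: MarkerMap,
    window_cm: float = 5.0,
    mppi: np.ndarray | None = None,
) -> FilteredModel:
    """Collapse included markers within a cM window into single control points.

    Single-linkage clustering per chromosome (adjacent markers join a
    cluster when their cM gap is <= window_cm, boundary inclusive).  The
    representative is the member with the highest marginal inclusion
    probability (ties: smaller cM position).
    """
    if model.size and max(model.included) >= len(marker_map):
        raise KeyError("model markers missing from marker map")
    chrom = marker_map.chrom
    cm = marker_map.cm
    clusters: dict[int, list[int]] = {}
    reps: list[int] = []
    by_chr: dict[str, list[int]] = {}
    for j in model.included:
        by_chr.setdefault(chrom[j], []).append(j)
    for c in sorted(by_chr):
        members = sorted(by_chr[c], key=lambda j: (cm[j], j))
        groups: list[list[int]] = [[members[0]]]
        for j in members[1:]:
            if cm[j] - cm[groups[-1][-1]] <= window_cm:
                groups[-1].append(j)
            else:
                groups.append([j])
        for g in groups:
            if mppi is not None:
                rep = max(g, key=lambda j: (mppi[j], -cm[j], -j))
            else:
                rep = min(g, key=lambda j: (cm[j], j))
            reps.append(rep)
            clusters[rep] = g
    reps.sort()
    return FilteredModel(representatives=reps, clusters=clusters, source=model)


def count_distinct_eqtls(
    model: ModelIndicator, marker_map: MarkerMap, distinct_cm: float = 10.0
) -> int:
    """Number of distinct control points under the wider separation rule
    (clusters at least distinct_cm apart count as separate eQTLs)."""
    if model.size == 0:
        return 0
    return collapse_linked_markers(model, marker_map, window_cm=distinct_cm).size


def classify_cis_trans(
    filtered: FilteredModel,
    probe_chr: str | None,
    probe_mbp: float | None,
    marker_map: MarkerMap,
    window_mbp: float = 10.0,
) -> dict[int, str]:
    """Label each representative cis or trans.

    cis iff on the probe's chromosome and within window_mbp of the probe
    (inclusive window); unknown probe location labels everything unknown.
    """
    if probe_chr is None or probe_mbp is None:
        return {j: "unknown" for j in filtered.representatives}
    labels = {}
    for j in filtered.representatives:
        same = str(marker_map.chrom[j]) == str(probe_chr)
        near = abs(marker_map.mbp[j] - probe_mbp) <= window_mbp
        labels[j] = "cis" if (same and near) else "trans"
    return labels


def _per_model_bfs(trace: VisitedModelTrace, ws: ScoreWorkspace) -> np.ndarray:
    null_ev = ws.log_evidence(())
    return (trace.log_evidence - null_ev) / np.log(10.0)


def noticeable_markers(
    trace: VisitedModelTrace,
    filtered: FilteredModel,
    rule: ThresholdRule,
    ws: ScoreWorkspace,
    kappa: float = 0.5,
    weighting: str = "frequency",
) -> list[int]:
    """Representatives that recur across the well-supported models.

    For each representative, the fraction of above-threshold visited
    models containing it (or a member of its cluster) is computed; those
    with fraction >= kappa are kept (boundary inclusive, so kappa = 1
    keeps exactly the markers present in every supported model).  Raising
    kappa gives a more parsimonious list.  Fractions are visit-count
    weighted by default; probability weighting is available.
    """
    bfs = _per_model_bfs(trace, ws)
    keep = np.array(
        [rule.passes(bf, len(m)) for m, bf in zip(trace.models, bfs)]
    )
    if not keep.any():
        warnings.warn("no visited model clears the threshold rule", UserWarning)
        return []
    if weighting == "frequency":
        w = trace.counts.astype(float)
    elif weighting == "probability":
        w = trace.probs.copy()
    else:
        raise ValueError("weighting must be 'frequency' or 'probability'")
    w = np.where(keep, w, 0.0)
    w /= w.sum()
    out = []
    for rep in filtered.representatives:
        members = set(filtered.clusters[rep])
        frac = sum(
            wi for m, wi in zip(trace.models, w) if members.intersection(m)
        )
        if frac >= kappa:
            out.append(rep)
    return out


def tau_posterior_given_model(ws: ScoreWorkspace, included: tuple) -> np.ndarray:
    """Posterior over the tau grid conditional on one model."""
    logw = ws.log_lik_grid(tuple(included)) + ws.log_tau_grid_prior
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _conditional_draw(ws, idx, tau_post, rng):
    """One (Sigma, B) draw from the exact conditional posterior given the
    model, with tau marginalised over its grid posterior."""
    q, n = ws.q, ws.n
    tau = float(ws.tau_grid[rng.choice(tau_post.size, p=tau_post)])
    c = tau / (1.0 + tau)
    Xg = ws.X[:, idx]
    XtX = Xg.T @ Xg
    XtX_inv = np.linalg.inv(XtX)
    M = c * XtX_inv @ (Xg.T @ ws.Y)
    k, YtPY = ws.stats(tuple(idx))
    S = ws.A - c * YtPY
    S = 0.5 * (S + S.T)
    df = ws.hyper.delta + n + q - 1  # scipy convention for Dawid shape delta + n
    Sigma = np.atleast_2d(invwishart.rvs(df=df, scale=S, random_state=rng))
    Lv = np.linalg.cholesky(c * XtX_inv)
    Ls = np.linalg.cholesky(Sigma)
    Z = rng.standard_normal((k, q))
    B = M + Lv @ Z @ Ls.T
    return Sigma, B


def sample_effect_sizes(
    ws: ScoreWorkspace,
    filtered: FilteredModel,
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = None,
    tau_posterior: np.ndarray | None = None,
) -> EffectDraws:
    """Posterior draws of per-tissue effect sizes for the filtered model.

    (Sigma, B) are drawn from their exact conjugate conditional posterior
    given the filtered design (Inverse-Wishart, then matrix-normal), with
    tau marginalised over its grid posterior.  Empty models return an
    empty draw set.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    idx = list(filtered.representatives)
    if not idx:
        empty = np.zeros((0, 0, ws.q))
        return EffectDraws(empty, [], np.zeros((0, ws.q)), {})
    s = np.linalg.svd(ws.X[:, idx], compute_uv=False)
    if s[-1] <= 1e-10 * s[0]:
        raise np.linalg.LinAlgError("filtered design is rank deficient")
    if tau_posterior is None:
        tau_posterior = tau_posterior_given_model(ws, tuple(idx))
    draws = np.empty((n_draws, len(idx), ws.q))
    for d in range(n_draws):
        _, B = _conditional_draw(ws, idx, tau_posterior, rng)
        draws[d] = B
    qs = {0.05: np.quantile(draws, 0.05, axis=0), 0.5: np.quantile(draws, 0.5, axis=0), 0.95: np.quantile(draws, 0.95, axis=0)}
    return EffectDraws(draws=draws, markers=idx, mean=draws.mean(axis=0), quantiles=qs)


def residual_correlation(
    ws: ScoreWorkspace,
    filtered: FilteredModel,
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = None,
    tau_posterior: np.ndarray | None = None,
) -> ResidualCorrelation:
    """Posterior mean residual cross-tissue correlation given the model,
    next to the raw empirical correlation of expression.

    Requires q >= 2; the null (empty) model conditions on no markers, so
    its residual correlation reflects the full cross-tissue dependence.
    """
    if ws.q < 2:
        raise ValueError("residual correlation needs at least two tissues")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    idx = list(filtered.representatives)
    if tau_posterior is None:
        tau_posterior = tau_posterior_given_model(ws, tuple(idx))
    acc = np.zeros((ws.q, ws.q))
    for _ in range(n_draws):
        if idx:
            Sigma, _ = _conditional_draw(ws, idx, tau_posterior, rng)
        else:
            S = 0.5 * (ws.A + ws.A.T)
            df = ws.hyper.delta + ws.n + ws.q - 1
            Sigma = np.atleast_2d(invwishart.rvs(df=df, scale=S, random_state=rng))
        d = np.sqrt(np.diag(Sigma))
        acc += Sigma / np.outer(d, d)
    post = acc / n_draws
    np.fill_diagonal(post, 1.0)
    raw = np.corrcoef(ws.Y.T)
    return ResidualCorrelation(posterior_mean=post, raw_empirical=np.atleast_2d(raw))
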