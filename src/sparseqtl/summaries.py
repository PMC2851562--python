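"""Posterior summaries and permutation-calibrated Bayes-factor thresholds.

From a visited-model trace we compute marker-level marginal posterior
inclusion probabilities (MPPI), the model-size posterior, the best visited
model and log10 Bayes factors.  The Jeffreys scale is calibrated to a
target FDR by reshuffling strain order (breaking genotype-phenotype
linkage while preserving the cross-tissue correlation), rerunning the
sampler, and choosing the weakest dimension-linear Bayes-factor cutoff
whose null/real positive ratio stays below the target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .datatypes import ExpressionPanel, GenotypePanel, ModelIndicator
from .model import Hyperparameters, ScoreWorkspace
from .sampler import SamplerConfig, VisitedModelTrace, run_ess

__all__ = [
    "PosteriorSummary",
    "ThresholdRule",
    "marginal_inclusion",
    "model_size_posterior",
    "best_model",
    "log10_bayes_factor",
    "summarize_trace",
    "calibrate_threshold",
    "declare_significant",
]


@dataclass
class PosteriorSummary:
    """Per-probe posterior report."""

    probe_id: str
    mppi: np.ndarray
    size_posterior: np.ndarray
    best_model: ModelIndicator
    log10_bf_best_vs_null: float
    trace: VisitedModelTrace | None = None


@dataclass
class ThresholdRule:
    """Dimension-linear log10 Bayes-factor cutoff tied to an FDR level.

    A best model of size k is called positive when its log10 BF is at
    least base_cutoff + per_dimension_increment * (k - 1); ties at the
    cutoff are positive (>= convention).
    """

    fdr_level: float
    base_cutoff: float
    per_dimension_increment: float = 0.0
    n_shuffles: int = 1

    def __post_init__(self):
        if self.per_dimension_increment < 0:
            raise ValueError("per_dimension_increment must be >= 0")

    def cutoff(self, size: int) -> float:
        return self.base_cutoff + self.per_dimension_increment * max(size - 1, 0)

    def passes(self, log10_bf: float, size: int) -> bool:
        return size > 0 and log10_bf >= self.cutoff(size)


def _check_trace(trace: VisitedModelTrace):
    if len(trace) == 0:
        raise ValueError("empty visited-model trace")


def _weights(trace: VisitedModelTrace, weighting: str) -> np.ndarray:
    if weighting == "probability":
        return trace.probs
    if weighting == "frequency":
        return trace.counts / trace.counts.sum()
    raise ValueError("weighting must be 'probability' or 'frequency'")


def marginal_inclusion(
    trace: VisitedModelTrace,
    rule: ThresholdRule | None = None,
    log10_bfs: np.ndarray | None = None,
    weighting: str = "probability",
) -> np.ndarray:
    """Marginal posterior probability of inclusion per marker.

    mppi_j = sum over unique visited models of weight * gamma_j; optionally
    conditioned on the models whose log10 Bayes factor clears a calibrated
    threshold rule (pass per-model log10_bfs alongside the rule).
    """
    _check_trace(trace)
    w = _weights(trace, weighting).copy()
    if rule is not None:
        if log10_bfs is None:
            raise ValueError("rule filtering requires per-model log10_bfs")
        keep = np.array(
            [rule.passes(bf, len(m)) for m, bf in zip(trace.models, log10_bfs)]
        )
        w = np.where(keep, w, 0.0)
        tot = w.sum()
        if tot == 0:
            return np.zeros(trace.p)
        w = w / tot
    mppi = np.zeros(trace.p)
    for m, wi in zip(trace.models, w):
        for j in m:
            mppi[j] += wi
    # guard against float accumulation pushing a probability past the bounds
    return np.clip(mppi, 0.0, 1.0)


def model_size_posterior(
    trace: VisitedModelTrace, weighting: str = "probability"
) -> np.ndarray:
    """Posterior distribution over model sizes (index = size)."""
    _check_trace(trace)
    w = _weights(trace, weighting)
    kmax = max(len(m) for m in trace.models)
    out = np.zeros(kmax + 1)
    for m, wi in zip(trace.models, w):
        out[len(m)] += wi
    return out


def best_model(trace: VisitedModelTrace) -> ModelIndicator:
    """Visited model maximising the tau-integrated posterior score.

    Ties broken toward smaller models, then lexicographic marker order.
    """
    _check_trace(trace)
    order = sorted(
        range(len(trace)),
        key=lambda i: (-trace.log_model_posterior[i], len(trace.models[i]), trace.models[i]),
    )
    return ModelIndicator(trace.models[order[0]], trace.p)


def log10_bayes_factor(
    model_a: ModelIndicator | tuple,
    model_b: ModelIndicator | tuple,
    ws: ScoreWorkspace,
    include_size_prior: bool = False,
) -> float:
    """log10 Bayes factor of model_a versus model_b.

    Ratio of tau-integrated marginal likelihoods (grid summation); by
    default the model-size prior is excluded so the factor measures data
    support only.
    """
    a = model_a.included if isinstance(model_a, ModelIndicator) else tuple(model_a)
    b = model_b.included if isinstance(model_b, ModelIndicator) else tuple(model_b)
    if include_size_prior:
        la = ws.log_model_posterior(a)
        lb = ws.log_model_posterior(b)
    else:
        la = ws.log_evidence(a)
        lb = ws.log_evidence(b)
    return (la - lb) / math.log(10.0)


def summarize_trace(
    trace: VisitedModelTrace, ws: ScoreWorkspace, probe_id: str = "probe"
) -> PosteriorSummary:
    """Bundle the standard posterior quantities for one probe set."""
    bm = best_model(trace)
    bf = log10_bayes_factor(bm, ModelIndicator.null(trace.p), ws)
    return PosteriorSummary(
        probe_id=probe_id,
        mppi=marginal_inclusion(trace),
        size_posterior=model_size_posterior(trace),
        best_model=bm,
        log10_bf_best_vs_null=bf,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# FDR calibration by strain-order reshuffling


def _fit_probe(panel, X, config, hyper_kw, rng):
    ws = ScoreWorkspace(panel, X, Hyperparameters.from_data(
        panel.values if isinstance(panel, ExpressionPanel) else panel,
        X.codes.shape[1] if isinstance(X, GenotypePanel) else np.asarray(X).shape[1],
        **hyper_kw,
    ))
    trace = run_ess(None, None, config, rng=rng, workspace=ws)
    bm = best_model(trace)
    bf = log10_bayes_factor(bm, ModelIndicator.null(trace.p), ws)
    return bm, bf


def calibrate_threshold(
    panels: list[ExpressionPanel],
    X: GenotypePanel | np.ndarray,
    config: SamplerConfig,
    fdr_level: float = 0.05,
    n_shuffles: int = 1,
    rng: np.random.Generator | int | None = None,
    hyper_kw: dict | None = None,
    increments: tuple[float, ...] = (0.0, 0.5, 1.0),
    real_results: list[tuple[ModelIndicator, float]] | None = None,
) -> ThresholdRule:
    """Calibrate the Jeffreys-scale cutoff to a target FDR.

    For each probe the strain order of Y is reshuffled jointly across
    tissues (severing the genotype-phenotype link but keeping the
    cross-tissue covariance), the sampler rerun, and the best-vs-null
    log10 Bayes factor recorded.  Among dimension-linear cutoff families
    base + increment * (size - 1), the rule declaring the most real-data
    positives subject to (#null positives / #real positives) <= fdr_level
    is returned (ties: smaller base, then smaller increment).

    Passing ``real_results`` (per-probe (best model, log10 BF) pairs from
    an already completed real-data run) skips recomputing them.
    """
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must be in (0, 1)")
    if len(panels) < 20:
        warnings.warn(
            f"calibrating on only {len(panels)} probe sets; >= 20 recommended",
            UserWarning,
        )
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    hyper_kw = dict(hyper_kw or {})
    Xmat = X.codes if isinstance(X, GenotypePanel) else np.asarray(X, float)

    if real_results is None:
        real_results = []
        for panel in panels:
            real_results.append(_fit_probe(panel, Xmat, config, hyper_kw, rng))
    real = [(bm.size, bf) for bm, bf in real_results]

    null = []
    for panel in panels:
        vals = panel.values if isinstance(panel, ExpressionPanel) else np.asarray(panel)
        for _ in range(n_shuffles):
            perm = rng.permutation(vals.shape[0])
            shuffled = vals[perm]
            bm, bf = _fit_probe(shuffled, Xmat, config, hyper_kw, rng)
            null.append((bm.size, bf))

    best_rule = None
    best_key = None
    for inc in increments:
        # statistic per probe: BF minus the size-dependent part of the cutoff;
        # null models can never be positive
        r = np.array([bf - inc * (k - 1) if k > 0 else -np.inf for k, bf in real])
        z = np.array([bf - inc * (k - 1) if k > 0 else -np.inf for k, bf in null])
        candidates = np.unique(r[np.isfinite(r)])
        for base in candidates:
            n_real = int((r >= base).sum())
            n_null = float((z >= base).sum()) / max(n_shuffles, 1)
            if n_real == 0:
                continue
            if n_null / n_real <= fdr_level:
                key = (-n_real, base, inc)
                if best_key is None or key < best_key:
                    best_key = key
                    best_rule = ThresholdRule(fdr_level, float(base), float(inc), n_shuffles)
                # n_real is non-increasing in base, so the smallest feasible
                # base maximises the declared positives for this increment
                break
    if best_rule is None:
        finite = [bf for k, bf in real + null if k > 0]
        top = max(finite) + 1.0 if finite else 1.0
        warnings.warn(
            "no cutoff satisfied the FDR constraint with real positives; "
            "returning a maximal cutoff",
            UserWarning,
        )
        return ThresholdRule(fdr_level, float(top), 0.0, n_shuffles)
    return best_rule


def declare_significant(
    results: list[PosteriorSummary], rule: ThresholdRule
) -> dict:
    """Apply a calibrated rule and tabulate probes by eQTL count.

    A probe is under genetic control iff its best model is nonempty and its
    log10 BF clears the size-dependent cutoff.  Counts are reported in the
    classes {no eQTL, 1, 2, >=3} of the best-model size.
    """
    decisions = []
    counts = {"no_eqtl": 0, "1": 0, "2": 0, "3+": 0}
    for res in results:
        k = res.best_model.size
        sig = rule.passes(res.log10_bf_best_vs_null, k)
        decisions.append(sig)
        if not sig or k == 0:
            counts["no_eqtl"] += 1
        elif k == 1:
            counts["1"] += 1
        elif k == 2:
            counts["2"] += 1
        else:
            counts["3+"] += 1
    return {"decisions": decisions, "counts": counts}
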