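"""Evolutionary Stochastic Search over marker-inclusion indicators.

A population of L parallel-tempered chains explores the space of binary
inclusion vectors.  Each sweep applies, per chain, one local
add/delete/swap Metropolis move; with configured probabilities a genetic
crossover between two chains and temperature-adjacent exchange moves; and
finally a Gibbs draw of the shared shrinkage weight tau from its
discretised full conditional.  The temperature ladder is tuned during
burn-in toward a target exchange acceptance rate and frozen afterwards so
the post-burn-in kernel is a valid MCMC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .datatypes import ExpressionPanel, GenotypePanel, ModelIndicator
from .model import Hyperparameters, ScoreWorkspace

__all__ = [
    "SamplerConfig",
    "ChainState",
    "ChainPopulation",
    "VisitedModelTrace",
    "stepwise_screen",
    "init_chains",
    "local_move",
    "crossover_move",
    "exchange_move",
    "gibbs_update_tau",
    "adapt_temperature_ladder",
    "run_ess",
]


@dataclass
class SamplerConfig:
    """Run-time knobs of the evolutionary sampler."""

    n_chains: int = 4
    n_sweeps: int = 25_000
    burn_in: int = 5_000
    move_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # add, delete, swap
    crossover_prob: float = 0.25
    exchange_prob: float = 1.0
    crossover_kind: str = "uniform"  # or "one_point"
    target_exchange_rate: float = 0.5
    adapt_window: int = 100
    adapt_step: float = 0.5
    initial_ladder_ratio: float = 2.0
    initial_tau: float | None = None  # default: grid point nearest n
    stepwise_f_enter: float = 4.0
    stepwise_max_per_tissue: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.burn_in < self.n_sweeps:
            raise ValueError("require 0 < burn_in < n_sweeps")
        if abs(sum(self.move_probs) - 1.0) > 1e-9:
            raise ValueError("move_probs must sum to 1")


@dataclass
class ChainState:
    """One chain: its model, temperature and the cached integrated
    log likelihood at the population's current tau."""

    included: tuple
    temperature: float
    cached_log_lik: float


@dataclass
class ChainPopulation:
    chains: list[ChainState]
    tau: float
    tau_index: int
    move_stats: dict = field(default_factory=dict)
    ladder_ratio: float = 2.0

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def count(self, move: str, accepted: bool):
        prop, acc = self.move_stats.get(move, (0, 0))
        self.move_stats[move] = (prop + 1, acc + int(accepted))


@dataclass
class VisitedModelTrace:
    """Unique models visited by the cold chain after burn-in.

    probs are renormalised tau-integrated posterior probabilities over the
    visited set (the substrate for inclusion probabilities, the size
    posterior and the best model); counts are raw visit frequencies.
    """

    p: int
    models: list[tuple]
    counts: np.ndarray
    log_model_posterior: np.ndarray
    log_evidence: np.ndarray
    probs: np.ndarray
    best_joint_score: np.ndarray
    n_sweeps: int
    burn_in: int
    seed: int

    def __len__(self) -> int:
        return len(self.models)

    def as_indicators(self) -> list[ModelIndicator]:
        return [ModelIndicator(m, self.p) for m in self.models]


# ---------------------------------------------------------------------------
# initialisation


def stepwise_screen(
    y: np.ndarray, X: np.ndarray, f_enter: float = 4.0, max_terms: int = 5
) -> list[int]:
    """Forward stepwise screening of markers for one response vector.

    Greedy residual-sum-of-squares forward selection; a marker enters while
    its partial F statistic exceeds ``f_enter`` and fewer than ``max_terms``
    markers are included.  Used only to seed the sampler.
    """
    n, p = X.shape
    y = y - y.mean()
    resid = y.copy()
    chosen: list[int] = []
    Qcols = np.empty((n, 0))
    Xc = X - X.mean(axis=0, keepdims=True)
    for _ in range(max_terms):
        # orthogonalise candidates against current design
        R = Xc - Qcols @ (Qcols.T @ Xc)
        norms = np.einsum("ij,ij->j", R, R)
        ok = norms > 1e-12
        if not ok.any():
            break
        proj = np.zeros(p)
        proj[ok] = (R[:, ok].T @ resid) ** 2 / norms[ok]
        j = int(np.argmax(proj))
        rss0 = resid @ resid
        rss1 = rss0 - proj[j]
        dof = n - 2 - len(chosen)
        if dof <= 0 or rss1 <= 0:
            break
        f = proj[j] / (rss1 / dof)
        if f < f_enter:
            break
        qj = R[:, j] / math.sqrt(norms[j])
        Qcols = np.column_stack([Qcols, qj])
        resid = resid - qj * (qj @ resid)
        chosen.append(j)
    return chosen


def init_chains(
    ws: ScoreWorkspace, config: SamplerConfig, rng: np.random.Generator
) -> ChainPopulation:
    """Build the initial population.

    The cold chain starts from the union, over tissues, of forward stepwise
    screens (capped at the model-size cap); hotter chains start from
    independently thinned copies.  tau starts at the grid point nearest n
    and the ladder is geometric.
    """
    if ws.n < 3:
        raise ValueError("need at least 3 strains")
    if ws.p < 1:
        raise ValueError("empty marker set")
    union: list[int] = []
    for h in range(ws.q):
        for j in stepwise_screen(
            ws.Y[:, h], ws.X, config.stepwise_f_enter, config.stepwise_max_per_tissue
        ):
            if j not in union:
                union.append(j)
    union = union[: ws.size_cap]
    # drop collinear members so the seed model is scoreable
    seed_model = tuple(sorted(union))
    if seed_model and ws.stats(seed_model) is None:
        bad = set(ws.collinear_members(seed_model))
        seed_model = tuple(j for j in seed_model if j not in bad)

    tau0 = config.initial_tau if config.initial_tau is not None else float(ws.n)
    tau_index = int(np.argmin(np.abs(ws.tau_grid - tau0)))
    tau = float(ws.tau_grid[tau_index])

    ratio = config.initial_ladder_ratio
    chains = []
    for l in range(config.n_chains):
        if l == 0:
            inc = seed_model
        else:
            keep = [j for j in seed_model if rng.random() < 0.5]
            inc = tuple(sorted(keep))
            if inc and ws.stats(inc) is None:
                inc = ()
        chains.append(
            ChainState(
                included=inc,
                temperature=ratio**l,
                cached_log_lik=ws.log_lik(inc, tau),
            )
        )
    return ChainPopulation(chains=chains, tau=tau, tau_index=tau_index, ladder_ratio=ratio)


# ---------------------------------------------------------------------------
# moves


def _log_target(ws: ScoreWorkspace, lik: float, size: int) -> float:
    return lik + ws.log_size_prior[size]


def local_move(
    state: ChainState,
    ws: ScoreWorkspace,
    tau: float,
    rng: np.random.Generator,
    move_probs: tuple[float, float, float] = (0.4, 0.4, 0.2),
    stats_sink: ChainPopulation | None = None,
) -> ChainState:
    """One add/delete/swap Metropolis–Hastings update of a single chain.

    Infeasible move types at the size boundaries (delete from the null
    model, add at the cap) are treated as null proposals; the Hastings
    correction for the add/delete asymmetry is exact.  Rank-deficient
    proposals score -inf and are rejected.
    """
    pa, pd, ps = move_probs
    p, cap = ws.p, ws.size_cap
    inc = state.included
    k = len(inc)
    u = rng.random()
    new = None
    log_q_fwd = log_q_rev = 0.0
    if u < pa:  # add
        kind = "add"
        if k < cap and k < p:
            j = int(rng.integers(p))
            while j in inc:
                j = int(rng.integers(p))
            new = tuple(sorted(inc + (j,)))
            log_q_fwd = math.log(pa) - math.log(p - k)
            log_q_rev = math.log(pd) - math.log(k + 1)
    elif u < pa + pd:  # delete
        kind = "delete"
        if k > 0:
            j = inc[int(rng.integers(k))]
            new = tuple(x for x in inc if x != j)
            log_q_fwd = math.log(pd) - math.log(k)
            log_q_rev = math.log(pa) - math.log(p - k + 1)
    else:  # swap (symmetric proposal)
        kind = "swap"
        if 0 < k < p:
            j_out = inc[int(rng.integers(k))]
            j_in = int(rng.integers(p))
            while j_in in inc:
                j_in = int(rng.integers(p))
            new = tuple(sorted([x for x in inc if x != j_out] + [j_in]))
    if new is None:
        if stats_sink is not None:
            stats_sink.count(kind, False)
        return state
    new_lik = ws.log_lik(new, tau)
    log_alpha = (
        _log_target(ws, new_lik, len(new)) - _log_target(ws, state.cached_log_lik, k)
    ) / state.temperature + log_q_rev - log_q_fwd
    accept = np.isfinite(new_lik) and math.log(rng.random()) < log_alpha
    if stats_sink is not None:
        stats_sink.count(kind, accept)
    if accept:
        state.included = new
        state.cached_log_lik = new_lik
    return state


def _crossover_children(
    a: tuple, b: tuple, p: int, kind: str, rng: np.random.Generator
) -> tuple[tuple, tuple]:
    if kind == "uniform":
        both = sorted(set(a) & set(b))
        diff = sorted(set(a) ^ set(b))
        mask = rng.random(len(diff)) < 0.5
        c1 = list(both) + [j for j, m in zip(diff, mask) if m]
        c2 = list(both) + [j for j, m in zip(diff, mask) if not m]
        return tuple(sorted(c1)), tuple(sorted(c2))
    if kind == "one_point":
        cut = int(rng.integers(p + 1))
        c1 = [j for j in a if j < cut] + [j for j in b if j >= cut]
        c2 = [j for j in b if j < cut] + [j for j in a if j >= cut]
        return tuple(sorted(c1)), tuple(sorted(c2))
    raise ValueError(f"unknown crossover kind {kind!r}")


def crossover_move(
    pop: ChainPopulation,
    ws: ScoreWorkspace,
    rng: np.random.Generator,
    kind: str = "uniform",
) -> ChainPopulation:
    """Genetic crossover between two randomly chosen chains.

    Both offspring replace their parents on joint Metropolis acceptance
    under the product of the two tempered targets; the uniform and
    one-point recombination proposals are symmetric, so no Hastings
    correction is needed.
    """
    L = pop.n_chains
    if L < 2:
        return pop
    i = int(rng.integers(L))
    j = int(rng.integers(L - 1))
    if j >= i:
        j += 1
    si, sj = pop.chains[i], pop.chains[j]
    c1, c2 = _crossover_children(si.included, sj.included, ws.p, kind, rng)
    if len(c1) > ws.size_cap or len(c2) > ws.size_cap:
        pop.count("crossover", False)
        return pop
    lik1 = ws.log_lik(c1, pop.tau)
    lik2 = ws.log_lik(c2, pop.tau)
    log_alpha = (
        (_log_target(ws, lik1, len(c1)) - _log_target(ws, si.cached_log_lik, len(si.included)))
        / si.temperature
        + (_log_target(ws, lik2, len(c2)) - _log_target(ws, sj.cached_log_lik, len(sj.included)))
        / sj.temperature
    )
    accept = (
        np.isfinite(lik1) and np.isfinite(lik2) and math.log(rng.random()) < log_alpha
    )
    pop.count("crossover", accept)
    if accept:
        si.included, si.cached_log_lik = c1, lik1
        sj.included, sj.cached_log_lik = c2, lik2
    return pop


def exchange_move(
    pop: ChainPopulation, ws: ScoreWorkspace, rng: np.random.Generator
) -> ChainPopulation:
    """Adjacent-temperature state exchanges over the whole ladder.

    Standard parallel-tempering acceptance computed from the cached
    log scores at the shared tau.
    """
    for l in range(pop.n_chains - 1):
        a, b = pop.chains[l], pop.chains[l + 1]
        sa = _log_target(ws, a.cached_log_lik, len(a.included))
        sb = _log_target(ws, b.cached_log_lik, len(b.included))
        log_alpha = (sa - sb) * (1.0 / b.temperature - 1.0 / a.temperature)
        accept = math.log(rng.random()) < log_alpha
        pop.count(f"exchange_{l}", accept)
        if accept:
            a.included, b.included = b.included, a.included
            a.cached_log_lik, b.cached_log_lik = b.cached_log_lik, a.cached_log_lik
    return pop


def gibbs_update_tau(
    pop: ChainPopulation, ws: ScoreWorkspace, rng: np.random.Generator
) -> ChainPopulation:
    """Gibbs draw of the shared tau from its discretised full conditional.

    Grid mass at tau_g is proportional to the product over chains of the
    tempered integrated likelihoods times the (untempered) discretised
    prior, normalised by log-sum-exp.
    """
    grids = [ws.log_lik_grid(c.included) for c in pop.chains]
    logw = ws.log_tau_grid_prior.copy()
    for c, g in zip(pop.chains, grids):
        logw += g / c.temperature
    logw -= logw.max()
    w = np.exp(logw)
    cdf = np.cumsum(w)
    idx = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
    idx = min(idx, logw.size - 1)
    pop.tau_index = idx
    pop.tau = float(ws.tau_grid[idx])
    for c, g in zip(pop.chains, grids):
        c.cached_log_lik = float(g[idx])
    return pop


def adapt_temperature_ladder(
    pop: ChainPopulation,
    target_rate: float = 0.5,
    step: float = 0.5,
) -> ChainPopulation:
    """Stochastic-approximation update of the geometric ladder ratio.

    Exchange acceptance above target spreads the ladder (ratio grows);
    below target contracts it.  The cold chain stays at temperature 1.
    Call only during burn-in; exchange counters are consumed and reset.
    """
    props, accs = 0, 0
    for key in list(pop.move_stats):
        if key.startswith("exchange_"):
            prop, acc = pop.move_stats.pop(key)
            props += prop
            accs += acc
    if props == 0:
        return pop
    rate = accs / props
    log_ratio = math.log(pop.ladder_ratio) + step * (rate - target_rate)
    pop.ladder_ratio = max(1.001, math.exp(log_ratio))
    for l, c in enumerate(pop.chains):
        c.temperature = pop.ladder_ratio**l
    return pop


# ---------------------------------------------------------------------------
# driver


def run_ess(
    Y: ExpressionPanel | np.ndarray,
    X: GenotypePanel | np.ndarray,
    config: SamplerConfig | None = None,
    rng: np.random.Generator | int | None = None,
    hyper: Hyperparameters | None = None,
    workspace: ScoreWorkspace | None = None,
) -> VisitedModelTrace:
    """Run the evolutionary sampler and collect the cold chain's trace.

    Per sweep: one local move per chain, crossover with configured
    probability, adjacent exchanges, then the tau Gibbs draw; during
    burn-in the temperature ladder adapts every ``adapt_window`` sweeps.
    Emits a convergence warning (never an error) if the cold chain's best
    score is still improving in the final 10% of sweeps.
    """
    config = config or SamplerConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    ws = workspace if workspace is not None else ScoreWorkspace(Y, X, hyper)
    pop = init_chains(ws, config, rng)

    counts: dict[tuple, int] = {}
    best_joint: dict[tuple, float] = {}
    best_score = -np.inf
    best_score_at_90 = None
    last_improve = 0
    mark = config.n_sweeps - max(1, config.n_sweeps // 10)

    for sweep in range(config.n_sweeps):
        in_burn = sweep < config.burn_in
        for l in range(pop.n_chains):
            pop.chains[l] = local_move(
                pop.chains[l], ws, pop.tau, rng, config.move_probs, stats_sink=pop
            )
        if pop.n_chains >= 2 and rng.random() < config.crossover_prob:
            crossover_move(pop, ws, rng, config.crossover_kind)
        if pop.n_chains >= 2 and rng.random() < config.exchange_prob:
            exchange_move(pop, ws, rng)
        gibbs_update_tau(pop, ws, rng)
        if in_burn and (sweep + 1) % config.adapt_window == 0:
            adapt_temperature_ladder(pop, config.target_exchange_rate, config.adapt_step)
        if not in_burn:
            cold = pop.chains[0]
            inc = cold.included
            counts[inc] = counts.get(inc, 0) + 1
            joint = ws.log_posterior(inc, pop.tau)
            prev = best_joint.get(inc)
            if prev is None or joint > prev:
                best_joint[inc] = joint
            if joint > best_score:
                best_score = joint
                last_improve = sweep
        if sweep == mark:
            best_score_at_90 = best_score

    if best_score_at_90 is not None and best_score > best_score_at_90 + 1e-9:
        warnings.warn(
            "cold chain best score still improving in the final 10% of "
            "sweeps; consider more sweeps",
            RuntimeWarning,
        )

    # Rao-Blackwellisation of the trace: the null and every feasible
    # single-marker model always enter with their exact posterior weight
    # (zero visit count), so marginal inclusion probabilities resolve
    # markers the chains never visited instead of tying them at zero
    for m in [()] + [(j,) for j in range(ws.p)]:
        if m in counts:
            continue
        try:
            ws.log_evidence(m)
        except np.linalg.LinAlgError:
            continue  # collinear (e.g. constant) genotype column
        counts[m] = 0
        best_joint[m] = float(
            np.max(ws.log_lik_grid(m) + ws.log_tau_grid_prior)
            + ws.log_size_prior[len(m)]
        )

    models = sorted(counts)
    cnt = np.array([counts[m] for m in models], dtype=int)
    log_ev = np.array([ws.log_evidence(m) for m in models])
    log_post = np.array(
        [le + ws.log_size_prior[len(m)] for m, le in zip(models, log_ev)]
    )
    probs = np.exp(log_post - logsumexp(log_post))
    probs /= probs.sum()
    return VisitedModelTrace(
        p=ws.p,
        models=models,
        counts=cnt,
        log_model_posterior=log_post,
        log_evidence=log_ev,
        probs=probs,
        best_joint_score=np.array([best_joint[m] for m in models]),
        n_sweeps=config.n_sweeps,
        burn_in=config.burn_in,
        seed=config.seed,
    )
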