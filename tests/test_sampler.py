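"""Evolutionary stochastic search: moves, tempering, Gibbs tau, driver."""

import numpy as np
import pytest

from conftest import make_instance
from sparseqtl.model import Hyperparameters, ScoreWorkspace, enumerate_posterior
from sparseqtl.sampler import (
    ChainPopulation,
    ChainState,
    SamplerConfig,
    adapt_temperature_ladder,
    _crossover_children,
    crossover_move,
    exchange_move,
    gibbs_update_tau,
    init_chains,
    local_move,
    run_ess,
    stepwise_screen,
)
from sparseqtl.summaries import marginal_inclusion, model_size_posterior


def small_config(**kw):
    base = dict(n_chains=2, n_sweeps=600, burn_in=150, seed=0)
    base.update(kw)
    return SamplerConfig(**base)


class _FixedInts:
    """Minimal rng stub driving deterministic proposals where needed."""

    def __init__(self, ints=(), floats=()):
        self._ints = list(ints)
        self._floats = list(floats)

    def integers(self, *a, **kw):
        return self._ints.pop(0)

    def random(self, *a, **kw):
        if self._floats:
            return self._floats.pop(0)
        return 0.5


# ---------------------------------------------------------------------------
# initialisation


class TestInit:
    def test_deterministic(self):
        Y, X, hyper = make_instance(1, signal={1: 1.4})
        ws = ScoreWorkspace(Y, X, hyper)
        cfg = small_config(n_chains=4)
        p1 = init_chains(ws, cfg, np.random.default_rng(7))
        p2 = init_chains(ws, cfg, np.random.default_rng(7))
        assert [c.included for c in p1.chains] == [c.included for c in p2.chains]
        assert p1.tau == p2.tau

    def test_huge_effect_marker_seeds_cold_chain(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            X = rng.choice([-0.5, 0.5], size=(29, 40))
            Y = 10.0 * X[:, [17]] + rng.standard_normal((29, 2))  # 5 sd effect
            ws = ScoreWorkspace(Y, X)
            pop = init_chains(ws, small_config(), np.random.default_rng(s))
            hits += 17 in pop.chains[0].included
        assert hits == 20

    def test_noise_screen_stays_small(self):
        rng = np.random.default_rng(2)
        X = rng.choice([-0.5, 0.5], size=(20, 50))
        Y = rng.standard_normal((20, 3))
        ws = ScoreWorkspace(Y, X)
        pop = init_chains(ws, small_config(), np.random.default_rng(0))
        assert len(pop.chains[0].included) <= ws.size_cap

    def test_ladder_geometric_cold_at_one(self):
        Y, X, hyper = make_instance(1)
        ws = ScoreWorkspace(Y, X, hyper)
        pop = init_chains(ws, small_config(n_chains=4), np.random.default_rng(0))
        temps = [c.temperature for c in pop.chains]
        assert temps[0] == 1.0
        ratios = np.diff(np.log(temps))
        assert np.allclose(ratios, ratios[0])

    def test_stepwise_screen_finds_planted(self):
        rng = np.random.default_rng(3)
        X = rng.choice([-0.5, 0.5], size=(29, 30))
        y = 3.0 * X[:, 4] + 0.5 * rng.standard_normal(29)
        assert 4 in stepwise_screen(y, X)


# ---------------------------------------------------------------------------
# local move


class TestLocalMove:
    def test_add_rejected_at_cap(self):
        Y, X, hyper = make_instance(1, n=12, p=6, q=2)
        hyper.max_model_size = 2
        ws = ScoreWorkspace(Y, X, hyper)
        state = ChainState((0, 1), 1.0, ws.log_lik((0, 1), 4.0))
        pop = ChainPopulation([state], 4.0, 0)
        out = local_move(state, ws, 4.0, _FixedInts(), (1.0, 0.0, 0.0), pop)
        assert out.included == (0, 1)  # null proposal, state unchanged
        assert pop.move_stats["add"] == (1, 0)

    def test_delete_from_null_is_null_proposal(self):
        Y, X, hyper = make_instance(1)
        ws = ScoreWorkspace(Y, X, hyper)
        state = ChainState((), 1.0, ws.log_lik((), 4.0))
        pop = ChainPopulation([state], 4.0, 0)
        out = local_move(state, ws, 4.0, _FixedInts(floats=[0.5]), (0.0, 1.0, 0.0), pop)
        assert out.included == ()
        assert pop.move_stats["delete"] == (1, 0)

    def test_flat_target_accepts_symmetric_swaps(self):
        # at a huge temperature the tempered target is flat, so the
        # symmetric swap proposal is accepted (numerically) always
        Y, X, hyper = make_instance(4, n=20, p=15, q=2, signal={3: 2.0})
        ws = ScoreWorkspace(Y, X, hyper)
        rng = np.random.default_rng(0)
        pop = ChainPopulation([ChainState((3,), 1e12, ws.log_lik((3,), 4.0))], 4.0, 0)
        for _ in range(300):
            local_move(pop.chains[0], ws, 4.0, rng, (0.0, 0.0, 1.0), pop)
        prop, acc = pop.move_stats["swap"]
        assert prop == 300
        assert acc / prop > 0.99

    def test_bookkeeping_conserved(self):
        Y, X, hyper = make_instance(5, signal={1: 1.2})
        ws = ScoreWorkspace(Y, X, hyper)
        rng = np.random.default_rng(1)
        state = ChainState((), 1.0, ws.log_lik((), 4.0))
        pop = ChainPopulation([state], 4.0, 0)
        for _ in range(500):
            state = local_move(state, ws, 4.0, rng, (0.4, 0.4, 0.2), pop)
        total = sum(prop for prop, _ in pop.move_stats.values())
        assert total == 500
        for prop, acc in pop.move_stats.values():
            assert 0 <= acc <= prop

    def test_local_moves_alone_reach_exact_posterior(self):
        Y, X, hyper = make_instance(6, n=16, p=5, q=2, signal={2: 1.5},
                                    tau_grid_size=20)
        ws = ScoreWorkspace(Y, X, hyper)
        exact = enumerate_posterior(ws)
        rng = np.random.default_rng(0)
        tau = float(ws.tau_grid[10])
        state = ChainState((), 1.0, ws.log_lik((), tau))
        pop = ChainPopulation([state], tau, 10)
        counts = {}
        for sweep in range(30_000):
            state = local_move(state, ws, pop.tau, rng, (0.4, 0.4, 0.2), pop)
            pop.chains[0] = state
            gibbs_update_tau(pop, ws, rng)
            state = pop.chains[0]
            if sweep >= 2_000:
                counts[state.included] = counts.get(state.included, 0) + 1
        tot = sum(counts.values())
        exact_map = {m: pr for m, pr in zip(exact["models"], exact["probs"])}
        tv = 0.5 * sum(
            abs(counts.get(m, 0) / tot - exact_map.get(m, 0.0))
            for m in set(counts) | set(exact_map)
        )
        assert tv < 0.05


# ---------------------------------------------------------------------------
# crossover / exchange


class TestCrossoverExchange:
    def test_identical_parents_noop_accepted(self):
        Y, X, hyper = make_instance(1, signal={1: 1.4})
        ws = ScoreWorkspace(Y, X, hyper)
        tau = 4.0
        s = lambda: ChainState((1, 3), 1.0, ws.log_lik((1, 3), tau))
        pop = ChainPopulation([s(), s()], tau, 0)
        crossover_move(pop, ws, np.random.default_rng(0))
        assert pop.chains[0].included == (1, 3)
        assert pop.chains[1].included == (1, 3)
        assert pop.move_stats["crossover"] == (1, 1)

    def test_one_point_boundary_cut_reproduces_parents(self):
        a, b = (0, 2), (1, 4)
        c1, c2 = _crossover_children(a, b, 6, "one_point", _FixedInts(ints=[0]))
        assert {c1, c2} == {a, b}
        c1, c2 = _crossover_children(a, b, 6, "one_point", _FixedInts(ints=[6]))
        assert {c1, c2} == {a, b}

    def test_uniform_crossover_partitions_symmetric_difference(self):
        rng = np.random.default_rng(0)
        a, b = (0, 1, 4), (1, 2, 5)
        for _ in range(20):
            c1, c2 = _crossover_children(a, b, 8, "uniform", rng)
            assert set(c1) & set(c2) >= {1}
            assert set(c1) ^ set(c2) == {0, 2, 4, 5}
            assert sorted(set(c1) | set(c2)) == [0, 1, 2, 4, 5]

    def test_exchange_equal_scores_always_accepts(self):
        Y, X, hyper = make_instance(1, signal={1: 1.4})
        ws = ScoreWorkspace(Y, X, hyper)
        tau = 4.0
        lik = ws.log_lik((1,), tau)
        pop = ChainPopulation(
            [ChainState((1,), 1.0, lik), ChainState((1,), 3.0, lik)], tau, 0
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            exchange_move(pop, ws, rng)
        assert pop.move_stats["exchange_0"] == (50, 50)

    def test_exchange_equal_temperatures_always_accepts(self):
        Y, X, hyper = make_instance(1, signal={1: 1.4})
        ws = ScoreWorkspace(Y, X, hyper)
        tau = 4.0
        pop = ChainPopulation(
            [
                ChainState((1,), 2.0, ws.log_lik((1,), tau)),
                ChainState((0, 2), 2.0, ws.log_lik((0, 2), tau)),
            ],
            tau,
            0,
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            exchange_move(pop, ws, rng)
        assert pop.move_stats["exchange_0"] == (50, 50)


# ---------------------------------------------------------------------------
# Gibbs tau


class TestGibbsTau:
    def _empirical_tau_freq(self, pop_builder, ws, n=6000, seed=0):
        rng = np.random.default_rng(seed)
        freq = np.zeros(ws.tau_grid.size)
        for _ in range(n):
            pop = pop_builder()
            gibbs_update_tau(pop, ws, rng)
            freq[pop.tau_index] += 1
        return freq / n

    def test_null_chains_sample_from_prior(self):
        Y, X, hyper = make_instance(1, tau_grid_size=15)
        ws = ScoreWorkspace(Y, X, hyper)
        build = lambda: ChainPopulation(
            [ChainState((), 1.0, ws.log_lik((), 1.0)),
             ChainState((), 2.0, ws.log_lik((), 1.0))],
            1.0, 0,
        )
        freq = self._empirical_tau_freq(build, ws)
        prior = np.exp(ws.log_tau_grid_prior)
        assert 0.5 * np.abs(freq - prior).sum() < 0.03

    def test_single_chain_single_marker_matches_direct_evaluation(self):
        Y, X, hyper = make_instance(2, signal={1: 1.4}, tau_grid_size=15)
        ws = ScoreWorkspace(Y, X, hyper)
        logw = ws.log_lik_grid((1,)) + ws.log_tau_grid_prior
        expect = np.exp(logw - logw.max())
        expect /= expect.sum()
        build = lambda: ChainPopulation(
            [ChainState((1,), 1.0, ws.log_lik((1,), 1.0))], 1.0, 0
        )
        freq = self._empirical_tau_freq(build, ws)
        assert 0.5 * np.abs(freq - expect).sum() < 0.03

    def test_updates_cached_likelihoods_coherently(self):
        Y, X, hyper = make_instance(3, signal={0: 1.2})
        ws = ScoreWorkspace(Y, X, hyper)
        rng = np.random.default_rng(5)
        pop = ChainPopulation(
            [ChainState((0,), 1.0, ws.log_lik((0,), 1.0)),
             ChainState((0, 2), 2.0, ws.log_lik((0, 2), 1.0))],
            1.0, 0,
        )
        gibbs_update_tau(pop, ws, rng)
        assert pop.tau == ws.tau_grid[pop.tau_index]
        for c in pop.chains:
            assert c.cached_log_lik == pytest.approx(
                ws.log_lik(c.included, pop.tau), abs=1e-10
            )


# ---------------------------------------------------------------------------
# ladder adaptation


class TestLadderAdaptation:
    def _pop(self, ratio=2.0):
        chains = [ChainState((), ratio**l, 0.0) for l in range(3)]
        return ChainPopulation(chains, 1.0, 0, ladder_ratio=ratio)

    def test_high_acceptance_spreads_ladder(self):
        pop = self._pop()
        pop.move_stats["exchange_0"] = (100, 95)
        pop.move_stats["exchange_1"] = (100, 95)
        adapt_temperature_ladder(pop, target_rate=0.5)
        assert pop.ladder_ratio > 2.0
        assert pop.chains[0].temperature == 1.0
        assert pop.chains[2].temperature == pytest.approx(pop.ladder_ratio**2)

    def test_low_acceptance_contracts_ladder(self):
        pop = self._pop()
        pop.move_stats["exchange_0"] = (100, 2)
        adapt_temperature_ladder(pop, target_rate=0.5)
        assert pop.ladder_ratio < 2.0
        assert pop.ladder_ratio >= 1.001

    def test_counters_consumed(self):
        pop = self._pop()
        pop.move_stats["exchange_0"] = (10, 5)
        pop.move_stats["add"] = (7, 3)
        adapt_temperature_ladder(pop)
        assert "exchange_0" not in pop.move_stats
        assert pop.move_stats["add"] == (7, 3)

    def test_no_data_is_noop(self):
        pop = self._pop()
        adapt_temperature_ladder(pop)
        assert pop.ladder_ratio == 2.0


# ---------------------------------------------------------------------------
# full driver


class TestRunEss:
    def test_determinism(self):
        Y, X, hyper = make_instance(1, signal={1: 1.4})
        cfg = small_config(n_sweeps=800, burn_in=200)
        t1 = run_ess(Y, X, cfg, rng=3, hyper=hyper)
        t2 = run_ess(Y, X, cfg, rng=3, hyper=hyper)
        assert t1.models == t2.models
        assert np.array_equal(t1.counts, t2.counts)
        assert np.allclose(t1.probs, t2.probs)

    def test_trace_invariants(self):
        Y, X, hyper = make_instance(2, signal={1: 1.4})
        cfg = small_config(n_sweeps=800, burn_in=200)
        trace = run_ess(Y, X, cfg, rng=0, hyper=hyper)
        assert trace.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert trace.counts.sum() == cfg.n_sweeps - cfg.burn_in
        assert len(trace.models) == len(set(trace.models))

    def test_matches_enumeration_on_small_instance(self):
        Y, X, hyper = make_instance(9, n=16, p=6, q=2, signal={2: 1.5},
                                    tau_grid_size=25)
        ws = ScoreWorkspace(Y, X, hyper)
        exact = enumerate_posterior(ws)
        cfg = SamplerConfig(n_chains=3, n_sweeps=8000, burn_in=1500, seed=0)
        trace = run_ess(None, None, cfg, rng=0, workspace=ws)
        mppi = marginal_inclusion(trace)
        assert np.max(np.abs(mppi - exact["mppi"])) < 0.02
        sp = model_size_posterior(trace)
        ex = exact["size_posterior"]
        m = max(sp.size, ex.size)
        sp = np.pad(sp, (0, m - sp.size))
        ex = np.pad(ex, (0, m - ex.size))
        assert 0.5 * np.abs(sp - ex).sum() < 0.02

    def test_tempering_off_vs_on_agree(self):
        Y, X, hyper = make_instance(10, n=16, p=6, q=2, signal={1: 1.3},
                                    tau_grid_size=25)
        ws = ScoreWorkspace(Y, X, hyper)
        t1 = run_ess(None, None, SamplerConfig(n_chains=1, n_sweeps=8000,
                                               burn_in=1500, seed=1),
                     rng=1, workspace=ws)
        t4 = run_ess(None, None, SamplerConfig(n_chains=4, n_sweeps=8000,
                                               burn_in=1500, seed=2),
                     rng=2, workspace=ws)
        assert np.max(np.abs(marginal_inclusion(t1) - marginal_inclusion(t4))) < 0.03

    def test_pure_noise_prefers_null_model(self):
        from sparseqtl.summaries import best_model

        # at the ~hundreds-of-markers operating scale the exchangeable size
        # prior concentrates near the null, so noise data rarely beat it
        nulls = 0
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            X = rng.choice([-0.5, 0.5], size=(29, 200))
            Y = rng.standard_normal((29, 2))
            hyper = Hyperparameters.from_data(Y, 200)
            ws = ScoreWorkspace(Y, X, hyper)
            trace = run_ess(None, None,
                            small_config(seed=s, n_sweeps=800, burn_in=200),
                            rng=s, workspace=ws)
            bm = best_model(trace)
            nulls += bm.size == 0
            # whenever the sampler prefers a non-null model on noise, that
            # preference must be genuine: its exact score beats the null
            if bm.size > 0:
                assert (ws.log_model_posterior(bm.included)
                        > ws.log_model_posterior(()))
        # exact enumeration over sizes 0-1 prefers the null on 18/20 of
        # these datasets; one further dataset carries a genuine two-marker
        # mode, so a correct sampler reports the null at most 17 times
        assert nulls >= 16

    def test_adapted_exchange_rate_near_target(self):
        # drive the population manually after an adaptive burn-in and check
        # the frozen ladder yields an exchange rate near the target
        Y, X, hyper = make_instance(12, n=29, p=40, q=4, signal={5: 2.0, 22: 1.0})
        ws = ScoreWorkspace(Y, X, hyper)
        rng = np.random.default_rng(0)
        cfg = SamplerConfig(n_chains=4, n_sweeps=3000, burn_in=1500, seed=0)
        pop = init_chains(ws, cfg, rng)
        for sweep in range(cfg.n_sweeps):
            for l in range(pop.n_chains):
                pop.chains[l] = local_move(
                    pop.chains[l], ws, pop.tau, rng, cfg.move_probs, pop
                )
            exchange_move(pop, ws, rng)
            gibbs_update_tau(pop, ws, rng)
            if sweep < cfg.burn_in and (sweep + 1) % cfg.adapt_window == 0:
                adapt_temperature_ladder(pop, cfg.target_exchange_rate, cfg.adapt_step)
            if sweep == cfg.burn_in - 1:
                for key in list(pop.move_stats):
                    if key.startswith("exchange_"):
                        pop.move_stats.pop(key)
        props = accs = 0
        for key, (prop, acc) in pop.move_stats.items():
            if key.startswith("exchange_"):
                props += prop
                accs += acc
        assert abs(accs / props - cfg.target_exchange_rate) < 0.15

    def test_cache_coherence_after_moves(self):
        Y, X, hyper = make_instance(13, signal={1: 1.4})
        ws = ScoreWorkspace(Y, X, hyper)
        rng = np.random.default_rng(0)
        pop = init_chains(ws, small_config(n_chains=3), rng)
        for _ in range(200):
            for l in range(pop.n_chains):
                pop.chains[l] = local_move(pop.chains[l], ws, pop.tau, rng,
                                           (0.4, 0.4, 0.2), pop)
            crossover_move(pop, ws, rng)
            exchange_move(pop, ws, rng)
            gibbs_update_tau(pop, ws, rng)
        for c in pop.chains:
            assert c.cached_log_lik == pytest.approx(
                ws.log_lik(c.included, pop.tau), abs=1e-10
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_chains=0)
        with pytest.raises(ValueError):
            SamplerConfig(burn_in=100, n_sweeps=100)
        with pytest.raises(ValueError):
            SamplerConfig(move_probs=(0.5, 0.5, 0.5))
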