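"""Gibbs/Metropolis updates, label-switching moves, adaptation and the
full run contract."""

import numpy as np
import pytest
from scipy import stats

from prmix.adapt import AdaptiveScales, SamplerConfig, adapt_step
from prmix.cohort import CohortArrays, DAYS_PER_YEAR
from prmix.mixture import log_joint, stick_breaking
from prmix.priors import PriorSpec
from prmix.sampler import (
    init_state,
    move1,
    move2,
    move3,
    run_prm,
    run_rprm,
    update_allocations,
    update_cluster_scalars,
    update_sticks,
)
from prmix.survival import gibbs_update_lambda
from prmix.synthetic import simulate_cohort, toy_truth
from .conftest import make_state


class TestUpdateSticks:
    def test_empty_counts_draw_from_prior(self, small_arrays, prior):
        state = make_state(small_arrays, 4, seed=1, prior=prior)
        state.alloc = np.full(small_arrays.m, 3)  # components 0-2 empty
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(3000):
            update_sticks(state, rng)
            draws.append(state.V[0])  # n_0 = 0, no tail mass beyond it? no: tail>0
        # V_2 has empty component but non-zero tail; V_0's conditional is
        # Beta(1, alpha + m) -- check against that closed form instead
        d = stats.kstest(draws, stats.beta(1, state.alpha + small_arrays.m).cdf)
        assert d.pvalue > 0.01

    def test_posterior_mean_matches_beta_formula(self, small_arrays, prior):
        state = make_state(small_arrays, 3, seed=2, prior=prior)
        rng = np.random.default_rng(1)
        n = state.counts()
        tail = n[1] + n[2]
        vs = []
        for _ in range(4000):
            alloc = state.alloc.copy()
            update_sticks(state, rng)
            state.alloc = alloc  # keep counts fixed
            vs.append(state.V[0])
        expect = (1 + n[0]) / (1 + n[0] + state.alpha + tail)
        se = np.std(vs) / np.sqrt(len(vs))
        assert abs(np.mean(vs) - expect) < 4 * se

    def test_weights_always_renormalised(self, small_arrays, prior):
        state = make_state(small_arrays, 5, seed=3, prior=prior)
        rng = np.random.default_rng(2)
        for _ in range(50):
            update_sticks(state, rng)
            assert state.phi.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(state.phi >= 0)


class TestConjugateLambda:
    def test_matches_closed_form_posterior(self, prior):
        # one-interval toy cohort: subjects live entirely inside 41-54y,
        # so only lambda_2 sees data; sufficient statistics by hand
        from prmix.cohort import Cohort
        import pandas as pd

        rows = []
        rng = np.random.default_rng(3)
        for i in range(40):
            entry = (41 + rng.uniform(0, 5)) * DAYS_PER_YEAR
            y = entry + rng.uniform(1, 8) * DAYS_PER_YEAR
            rows.append(dict(y=min(y, 54 * DAYS_PER_YEAR), delta=int(rng.uniform() < 0.4),
                             entry_age=entry, x_radon=1.0, x_gamma=1.0, x_dust=1.0,
                             age_first_exposure=20.0, job=1, mine=1, duration_class=1))
        cohort = Cohort(pd.DataFrame(rows))
        arrays = CohortArrays(cohort)
        d2 = sum(r["delta"] for r in rows)
        e2 = sum(r["y"] - r["entry_age"] for r in rows)
        rng = np.random.default_rng(4)
        draws = np.array([
            gibbs_update_lambda(arrays, np.ones(arrays.n), prior, rng) for _ in range(4000)
        ])
        a2, b2 = prior.lam[1]
        ks = stats.kstest(draws[:, 1], stats.gamma(a2 + d2, scale=1 / (b2 + e2)).cdf)
        assert ks.pvalue > 0.01
        # intervals without data reproduce their prior
        a1, b1 = prior.lam[0]
        ks0 = stats.kstest(draws[:, 0], stats.gamma(a1, scale=1 / b1).cdf)
        assert ks0.pvalue > 0.01


class TestUpdateAllocations:
    def test_identical_components_follow_weights(self, small_arrays, prior):
        state = make_state(small_arrays, 3, seed=5, prior=prior)
        for arr in (state.beta, state.mu, state.sigma, state.p_job, state.p_mine,
                    state.p_dur):
            arr[1:] = arr[0]
        rng = np.random.default_rng(6)
        counts = np.zeros(3)
        for _ in range(100):
            update_allocations(state, small_arrays, rng)
            counts += np.bincount(state.alloc, minlength=3)
        expected = state.phi * counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2(df=2).sf(chi2) > 1e-3

    def test_unsupported_component_never_selected(self, small_arrays, prior):
        state = make_state(small_arrays, 3, seed=7, prior=prior)
        state.beta[1] = -1.0 - 1e-9  # survival likelihood -inf
        rng = np.random.default_rng(8)
        update_allocations(state, small_arrays, rng)
        assert not np.any(state.alloc == 1)

    def test_deterministic_under_fixed_stream(self, small_arrays, prior):
        state1 = make_state(small_arrays, 3, seed=9, prior=prior)
        state2 = state1.copy()
        update_allocations(state1, small_arrays, np.random.default_rng(10))
        update_allocations(state2, small_arrays, np.random.default_rng(10))
        assert np.array_equal(state1.alloc, state2.alloc)


class TestMetropolisBlocks:
    def test_local_log_ratios_equal_log_joint_differences(self, small_arrays, prior):
        """The per-block conditional log-ratios the sampler accepts on are
        exactly differences of the full joint density."""
        state = make_state(small_arrays, 3, seed=11, prior=prior)
        base = log_joint(state, small_arrays, prior)
        # beta block
        d = np.bincount(state.alloc, weights=small_arrays.delta[small_arrays.exposed_idx],
                        minlength=3)
        h0 = small_arrays.e @ state.lam
        E = np.bincount(state.alloc, weights=h0[small_arrays.exposed_idx], minlength=3)
        bm, bv = prior.beta
        new_beta = state.beta[1] + 0.37
        local = (
            d[1] * (np.log1p(new_beta) - np.log1p(state.beta[1]))
            - (new_beta - state.beta[1]) * E[1]
            - ((new_beta - bm) ** 2 - (state.beta[1] - bm) ** 2) / (2 * bv)
        )
        prop = state.copy()
        prop.beta[1] = new_beta
        assert log_joint(prop, small_arrays, prior) - base == pytest.approx(local, abs=1e-7)
        # sigma block (radon scale of component 0)
        members = state.alloc == 0
        lx = small_arrays.logx[members, 0]
        mcount, mu = len(lx), state.mu[0, 0]
        ss = np.sum((lx - mu) ** 2)
        new_sigma = state.sigma[0, 0] * 1.21
        local = (
            -mcount * (np.log(new_sigma) - np.log(state.sigma[0, 0]))
            - ss / 2 * (1 / new_sigma ** 2 - 1 / state.sigma[0, 0] ** 2)
        )
        prop = state.copy()
        prop.sigma[0, 0] = new_sigma
        assert log_joint(prop, small_arrays, prior) - base == pytest.approx(local, abs=1e-7)
        # alpha block
        new_alpha = state.alpha + 0.8
        t = np.log1p(-state.V).sum()
        local = 2 * (np.log(new_alpha) - np.log(state.alpha)) + (new_alpha - state.alpha) * t
        prop = state.copy()
        prop.alpha = new_alpha
        assert log_joint(prop, small_arrays, prior) - base == pytest.approx(local, abs=1e-7)

    def test_dirichlet_update_with_no_members_draws_prior(self, small_arrays, prior):
        state = make_state(small_arrays, 3, seed=12, prior=prior)
        state.alloc = np.zeros(small_arrays.m, dtype=int)  # components 1, 2 empty
        scales = AdaptiveScales()
        scales.register("beta", 3, 0.1, 0.4)
        scales.register("sigma", 12, 0.1, 0.4)
        scales.register("alpha", 1, 0.5, 0.4)
        rng = np.random.default_rng(13)
        first = []
        for _ in range(3000):
            update_cluster_scalars(state, small_arrays, prior, scales, rng)
            first.append(state.p_mine[2, 0])
        # marginal of a Dirichlet(0.5, 0.5) coordinate is Beta(0.5, 0.5)
        ks = stats.kstest(first, stats.beta(0.5, 0.5).cdf)
        assert ks.pvalue > 0.01


class TestMoves:
    def test_move1_equal_counts_always_accept(self, small_arrays, prior):
        # equal cluster sizes: exponent 0 -> r = 1 whatever the weights
        state = make_state(small_arrays, 4, seed=14, prior=prior)
        half = small_arrays.m // 2 * 2
        state.alloc[:] = 3
        state.alloc[: half // 2] = 0
        state.alloc[half // 2: half] = 1
        assert move1(state, 0, 1, np.random.default_rng(15))

    def test_move1_equal_weights_always_accept(self, small_arrays, prior):
        state = make_state(small_arrays, 3, seed=15, prior=prior)
        state.phi = np.array([0.4, 0.4, 0.2])
        assert move1(state, 0, 1, np.random.default_rng(16))

    def test_move1_table_example_accepts_surely(self, small_arrays, prior):
        # phi_j = 0.2, phi_k = 0.1, n_j = 5, n_k = 7 -> r = 2^2 = 4 >= 1
        state = make_state(small_arrays, 3, seed=16, prior=prior)
        state.phi = np.array([0.2, 0.1, 0.7])
        state.alloc = np.concatenate([
            np.zeros(5, int), np.ones(7, int),
            np.full(small_arrays.m - 12, 2, int),
        ])
        before = state.beta.copy()
        assert move1(state, 0, 1, np.random.default_rng(17))
        assert state.beta[0] == before[1] and state.beta[1] == before[0]

    def test_move2_acceptance_matches_log_joint_ratio(self, small_arrays, prior):
        for seed in range(4):
            state = make_state(small_arrays, 4, seed=20 + seed, prior=prior)
            state.phi = stick_breaking(state.V, 4)
            j = 1
            n = state.counts()
            expect = n[j] * np.log1p(-state.V[j + 1]) - n[j + 1] * np.log1p(-state.V[j])
            before = log_joint(state, small_arrays, prior)
            prop = state.copy()
            prop.V[[j, j + 1]] = prop.V[[j + 1, j]]
            prop.swap_components(j, j + 1)
            prop.phi = stick_breaking(prop.V, 4)
            after = log_joint(prop, small_arrays, prior)
            assert after - before == pytest.approx(expect, abs=1e-8)

    def test_move2_symmetric_state_accepts(self, small_arrays, prior):
        # V_j = V_{j+1} and n_j = n_{j+1} -> r = 1
        state = make_state(small_arrays, 4, seed=24, prior=prior)
        state.V[:] = 0.4
        state.phi = stick_breaking(state.V, 4)
        half = small_arrays.m // 2 * 2
        state.alloc[:] = 3
        state.alloc[: half // 2] = 0
        state.alloc[half // 2: half] = 1
        assert move2(state, 0, np.random.default_rng(25))

    def test_move_range_errors(self, small_arrays, prior):
        state = make_state(small_arrays, 3, seed=26, prior=prior)
        with pytest.raises(ValueError):
            move2(state, 1, np.random.default_rng(0))  # j+1 has no stick fraction
        with pytest.raises(ValueError):
            move3(state, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            move1(state, 1, 1, np.random.default_rng(0))

    def test_rejection_leaves_state_identical(self, small_arrays, prior):
        state = make_state(small_arrays, 3, seed=27, prior=prior)
        # huge count imbalance with adverse weights -> r astronomically small
        state.alloc = np.zeros(small_arrays.m, dtype=int)
        state.V = np.array([0.98, 0.5])
        state.phi = stick_breaking(state.V, 3)
        snap = state.copy()
        rng = np.random.default_rng(28)
        accepted = move1(state, 1, 0, rng)  # r = (phi_1/phi_0)^{n_0} ~ 0
        assert not accepted
        for attr in ("beta", "mu", "sigma", "V", "phi", "alloc"):
            assert np.array_equal(getattr(state, attr), getattr(snap, attr))


class TestAdaptation:
    def test_tie_is_a_noop_and_direction_correct(self):
        ls = np.array([0.0, 0.0, 0.0])
        rates = np.array([0.40, 0.60, 0.10])
        out = adapt_step(ls, rates, 0.40, batch=1)
        assert out[0] == 0.0 and out[1] > 0 and out[2] < 0

    def test_step_size_decays(self):
        assert adapt_step(np.zeros(1), np.ones(1), 0.4, batch=1)[0] == pytest.approx(0.05)
        assert adapt_step(np.zeros(1), np.ones(1), 0.4, batch=900)[0] == pytest.approx(1 / 30)

    @pytest.mark.parametrize("dim,target,band", [(1, 0.40, (0.30, 0.50)), (4, 0.20, (0.10, 0.30))])
    def test_settles_near_target_on_gaussian(self, dim, target, band):
        """Random-walk MH on a standard normal adapts to the requested rate."""
        rng = np.random.default_rng(dim)
        scales = AdaptiveScales()
        scales.register("x", 1, 1.0, target)
        x = np.zeros(dim)
        lp = -0.5 * x @ x
        for it in range(60 * 100):
            s = scales.scales("x")[0]
            prop = x + s * rng.standard_normal(dim)
            lp_prop = -0.5 * prop @ prop
            acc = np.log(rng.uniform()) < lp_prop - lp
            if acc:
                x, lp = prop, lp_prop
            scales.record("x", np.array([acc]))
            if (it + 1) % 100 == 0:
                scales.end_batch()
                if scales.batch >= 50:
                    scales.freeze()
        rate = scales.acceptance_rates()["x"][0]
        assert band[0] < rate < band[1]


class TestRunContract:
    def test_stored_draw_count_follows_schedule(self):
        cfg = SamplerConfig()
        assert cfg.n_stored == 7500  # 150,000 / 20
        cfg = SamplerConfig.smoke()
        assert cfg.n_stored == 500

    def test_same_seed_bit_identical(self, small_cohort, prior):
        _, cohort, _ = small_cohort
        cfg = SamplerConfig(adapt_batches=2, batch_size=20, burnin=40, n_iter=200,
                            thin=10, c_max=4, seed=123)
        t1 = run_prm(cohort, prior, cfg)
        t2 = run_prm(cohort, prior, cfg)
        for attr in ("beta", "mu", "sigma", "phi", "alpha", "lam", "alloc"):
            assert np.array_equal(getattr(t1, attr), getattr(t2, attr))

    def test_modal_occupancy_matches_truth(self, prior):
        truth = toy_truth(n=300, n_clusters=3, seed=31)
        cohort, _ = simulate_cohort(truth)
        cfg = SamplerConfig.smoke(seed=32, c_max=8)
        trace = run_prm(cohort, prior, cfg)
        occupancy = trace.n_nonempty()
        values, counts = np.unique(occupancy, return_counts=True)
        assert values[np.argmax(counts)] == 3

    def test_rprm_truncates_components(self, small_cohort, prior):
        _, cohort, _ = small_cohort
        cfg = SamplerConfig(adapt_batches=2, batch_size=20, burnin=20, n_iter=100,
                            thin=10, mode="RPRM", K=3, seed=33)
        trace = run_rprm(cohort, prior, cfg)
        assert trace.n_components == 2
        assert trace.beta.shape == (10, 2)

    def test_invalid_rprm_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(mode="RPRM")
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=100, thin=7)
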