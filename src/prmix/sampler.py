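"""Adaptive Metropolis-within-Gibbs sampler for the profile regression
mixture, with three label-switching moves.

Update cycle per sweep: latent allocations (exact categorical full
conditional), stick fractions V (conjugate Beta), lognormal locations mu
(conjugate normal), lognormal scales sigma (random walk within uniform
bounds), per-cluster excess risks beta (random walk on beta > -1),
baseline rates lambda (conjugate gamma), multinomial probability vectors
(conjugate Dirichlet), concentration alpha (random walk within its
uniform support), then one attempt of each label-switching move.

The label-switching moves exchange the identities of two mixture
components to help the chain traverse the permutation modes of the
posterior: move 1 swaps the parameters and allocations of an arbitrary
pair leaving the weights in place; move 2 additionally swaps the stick
fractions of an adjacent pair; move 3 proposes fresh stick fractions for
an adjacent pair from their full conditionals under the swapped
allocation counts, so the implied weights land near their conditional
expectations given the new labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln

from .adapt import AdaptiveScales, SamplerConfig
from .cohort import Cohort, CohortArrays, N_INTERVALS
from .mixture import (
    MixtureState,
    allocation_log_probabilities,
    exposure_loglik_matrix,
    log_joint,
    stick_breaking,
)
from .priors import PriorSpec
from .survival import cohort_loglik_terms, gibbs_update_lambda


# ---------------------------------------------------------------------------
# Gibbs / Metropolis updates


def update_allocations(
    state: MixtureState, arrays: CohortArrays, rng: np.random.Generator
) -> MixtureState:
    """Redraw every exposed subject's component label from its exact
    categorical full conditional (Gumbel-max sampling)."""
    if state.n_components == 1:
        return state
    logits = allocation_log_probabilities(arrays, state)
    g = rng.gumbel(size=logits.shape)
    state.alloc = np.argmax(logits + g, axis=1)
    return state


def update_sticks(
    state: MixtureState, rng: np.random.Generator
) -> MixtureState:
    """Conjugate update V_c ~ Beta(1 + n_c, alpha + sum_{l>c} n_l)."""
    C = state.n_components
    if C == 1:
        state.phi = np.ones(1)
        return state
    n = state.counts()
    tail = np.concatenate((np.cumsum(n[::-1])[::-1][1:], [0]))[: C - 1]
    state.V = rng.beta(1.0 + n[: C - 1], state.alpha + tail)
    state.V = np.clip(state.V, 1e-12, 1.0 - 1e-12)
    state.phi = stick_breaking(state.V, C)
    return state


def _cluster_moments(state: MixtureState, arrays: CohortArrays):
    """Per-component member count and sums / sums of squares of the four
    log covariates, shapes (C,), (C, 4), (C, 4)."""
    C = state.n_components
    n = np.bincount(state.alloc, minlength=C).astype(float)
    S = np.zeros((C, 4))
    Q = np.zeros((C, 4))
    np.add.at(S, state.alloc, arrays.logx)
    np.add.at(Q, state.alloc, arrays.logx ** 2)
    return n, S, Q


def update_cluster_scalars(
    state: MixtureState,
    arrays: CohortArrays,
    prior: PriorSpec,
    proposals: AdaptiveScales,
    rng: np.random.Generator,
) -> MixtureState:
    """One sweep over mu (conjugate), sigma (MH), beta (MH), lambda
    (conjugate), multinomial p (conjugate Dirichlet) and alpha (MH)."""
    C = state.n_components
    n, S, Q = _cluster_moments(state, arrays)

    # --- mu: conjugate normal given sigma
    m0 = prior.mu_priors[:, 0][None, :]
    v0 = prior.mu_priors[:, 1][None, :]
    prec = 1.0 / v0 + n[:, None] / state.sigma ** 2
    mean = (m0 / v0 + S / state.sigma ** 2) / prec
    state.mu = mean + rng.standard_normal((C, 4)) / np.sqrt(prec)

    # --- sigma: random walk within the uniform prior bounds
    SS = Q - 2.0 * state.mu * S + n[:, None] * state.mu ** 2
    lo, hi = prior.sigma_bounds
    cur = state.sigma
    prop = cur + proposals.scales("sigma").reshape(C, 4) * rng.standard_normal((C, 4))
    ok = (prop > max(lo, 0.0)) & (prop <= hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp_cur = -n[:, None] * np.log(cur) - SS / (2.0 * cur ** 2)
        lp_prop = np.where(ok, -n[:, None] * np.log(prop) - SS / (2.0 * prop ** 2), -np.inf)
    acc = np.log(rng.uniform(size=(C, 4))) < lp_prop - lp_cur
    state.sigma = np.where(acc, prop, cur)
    proposals.record("sigma", acc.ravel())

    # --- beta: random walk on the admissible region beta > -1
    d = np.bincount(state.alloc, weights=arrays.delta[arrays.exposed_idx], minlength=C)
    _, h0 = cohort_loglik_terms(arrays, state.lam)
    E = np.bincount(state.alloc, weights=h0[arrays.exposed_idx], minlength=C)
    bm, bv = prior.beta
    cur_b = state.beta
    prop_b = cur_b + proposals.scales("beta") * rng.standard_normal(C)
    okb = prop_b > -1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dlp = (
            d * (np.where(okb, np.log1p(prop_b), -np.inf) - np.log1p(cur_b))
            - (prop_b - cur_b) * E
            - ((prop_b - bm) ** 2 - (cur_b - bm) ** 2) / (2.0 * bv)
        )
    accb = np.log(rng.uniform(size=C)) < dlp
    state.beta = np.where(accb, prop_b, cur_b)
    proposals.record("beta", accb)

    # --- lambda: conjugate gamma given the per-subject multipliers
    mult = np.ones(arrays.n)
    mult[arrays.exposed_idx] = 1.0 + state.beta[state.alloc]
    state.lam = gibbs_update_lambda(arrays, mult, prior, rng)

    # --- multinomial p vectors: conjugate Dirichlet(conc + counts)
    for attr, codes, L in (
        ("p_job", arrays.job0, 5),
        ("p_mine", arrays.mine0, 2),
        ("p_dur", arrays.dur0, 4),
    ):
        counts = np.bincount(state.alloc * L + codes, minlength=C * L).reshape(C, L)
        g = rng.gamma(prior.dirichlet_conc + counts)
        setattr(state, attr, g / g.sum(axis=1, keepdims=True))

    # --- alpha: random walk within its uniform support
    lo_a, hi_a = prior.alpha_bounds
    cur_a = state.alpha
    prop_a = cur_a + proposals.scales("alpha")[0] * rng.standard_normal()
    if lo_a <= prop_a <= hi_a:
        if C > 1:
            t = float(np.log1p(-state.V).sum())
            dlp_a = (C - 1) * (np.log(prop_a) - np.log(cur_a)) + (prop_a - cur_a) * t
        else:
            dlp_a = 0.0
        acc_a = np.log(rng.uniform()) < dlp_a
    else:
        acc_a = False
    if acc_a:
        state.alpha = float(prop_a)
    proposals.record("alpha", np.array([acc_a]))
    return state


# ---------------------------------------------------------------------------
# label-switching moves


def move1(state: MixtureState, j: int, k: int, rng: np.random.Generator) -> bool:
    """Swap components j and k (parameters + allocations, weights kept)
    with probability min(1, (phi_j/phi_k)^(n_k - n_j))."""
    if j == k:
        raise ValueError("move 1 needs two distinct components")
    n = state.counts()
    if n[k] == n[j]:
        log_r = 0.0  # exponent zero: accept regardless of the weights
    else:
        with np.errstate(divide="ignore"):
            log_r = (n[k] - n[j]) * (np.log(state.phi[j]) - np.log(state.phi[k]))
    if np.log(rng.uniform()) < log_r:
        state.swap_components(j, k)
        return True
    return False


def move2(state: MixtureState, j: int, rng: np.random.Generator) -> bool:
    """Swap the adjacent pair (j, j+1) together with their stick
    fractions, with probability min(1, (1-V_{j+1})^{n_j} / (1-V_j)^{n_{j+1}})."""
    C = state.n_components
    if not 0 <= j <= C - 3:
        raise ValueError("move 2 needs an adjacent pair with stick fractions")
    n = state.counts()
    log_r = n[j] * np.log1p(-state.V[j + 1]) - n[j + 1] * np.log1p(-state.V[j])
    if np.log(rng.uniform()) < log_r:
        state.V[[j, j + 1]] = state.V[[j + 1, j]]
        state.swap_components(j, j + 1)
        state.phi = stick_breaking(state.V, C)
        return True
    return False


def move3(state: MixtureState, j: int, rng: np.random.Generator) -> bool:
    """Swap the adjacent pair (j, j+1) proposing fresh stick fractions
    from their full conditionals under the swapped allocation counts.

    Because the proposal is the exact conditional of the V pair, the MH
    ratio reduces to a ratio of Beta normalising constants and does not
    depend on the drawn fractions (derivation in the methods note).
    """
    C = state.n_components
    if not 0 <= j <= C - 2:
        raise ValueError("move 3 needs an adjacent pair")
    n = state.counts()
    S = int(n[j + 2:].sum())
    a = state.alpha
    nj, nk = int(n[j]), int(n[j + 1])
    # log normalising constants of the V full conditionals
    log_z_cur = betaln(1 + nj, a + nk + S)
    log_z_prop = betaln(1 + nk, a + nj + S)
    has_second = j + 1 <= C - 2
    if has_second:
        log_z_cur += betaln(1 + nk, a + S)
        log_z_prop += betaln(1 + nj, a + S)
    v_j = rng.beta(1 + nk, a + nj + S)
    v_k = rng.beta(1 + nj, a + S) if has_second else None
    if not (0 < v_j < 1) or (has_second and not (0 < v_k < 1)):
        return False
    if np.log(rng.uniform()) < log_z_prop - log_z_cur:
        state.swap_components(j, j + 1)
        state.V[j] = v_j
        if has_second:
            state.V[j + 1] = v_k
        state.phi = stick_breaking(state.V, C)
        return True
    return False


# ---------------------------------------------------------------------------
# initialisation, trace container, and the full run


def init_state(
    arrays: CohortArrays, prior: PriorSpec, config: SamplerConfig, rng: np.random.Generator
) -> MixtureState:
    """Reproducible starting point: k-means on standardised log
    covariates for the allocations; occupied components start at their
    empirical moments, empty ones at weakly informative defaults."""
    from sklearn.cluster import KMeans

    C = config.n_exposed_components
    m = arrays.m
    k = max(1, min(config.init_clusters, C, m))
    if k > 1:
        z = (arrays.logx - arrays.logx.mean(axis=0)) / np.maximum(arrays.logx.std(axis=0), 1e-9)
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2 ** 31)))
        alloc = km.fit_predict(z)
    else:
        alloc = np.zeros(m, dtype=int)

    mu = np.tile(prior.mu_priors[:, 0], (C, 1))
    sigma = np.ones((C, 4))
    p_job = np.full((C, 5), 0.2)
    p_mine = np.full((C, 2), 0.5)
    p_dur = np.full((C, 4), 0.25)
    for c in range(k):
        sel = alloc == c
        if sel.sum() >= 2:
            mu[c] = arrays.logx[sel].mean(axis=0)
            sigma[c] = np.clip(arrays.logx[sel].std(axis=0), 0.05, 10.0)
        for arr, codes, L in ((p_job, arrays.job0, 5), (p_mine, arrays.mine0, 2),
                              (p_dur, arrays.dur0, 4)):
            cnt = np.bincount(codes[sel], minlength=L) + prior.dirichlet_conc
            arr[c] = cnt / cnt.sum()

    alpha = float(np.clip(config.alpha_init, *prior.alpha_bounds))
    n = np.bincount(alloc, minlength=C).astype(float)
    if C > 1:
        tail = np.concatenate((np.cumsum(n[::-1])[::-1][1:], [0]))[: C - 1]
        V = (1.0 + n[: C - 1]) / (1.0 + n[: C - 1] + alpha + tail)
        V = np.clip(V, 1e-6, 1 - 1e-6)
        phi = stick_breaking(V, C)
    else:
        V = np.empty(0)
        phi = np.ones(1)
    lam = prior.lam_shapes / prior.lam_rates
    return MixtureState(
        beta=np.zeros(C), mu=mu, sigma=sigma, p_job=p_job, p_mine=p_mine,
        p_dur=p_dur, V=V, phi=phi, alpha=alpha, lam=lam, alloc=alloc,
    )


@dataclass
class Trace:
    """Retained posterior draws of a (R)PRM run."""

    beta: np.ndarray      # (D, C)
    mu: np.ndarray        # (D, C, 4)
    sigma: np.ndarray     # (D, C, 4)
    p_job: np.ndarray     # (D, C, 5)
    p_mine: np.ndarray    # (D, C, 2)
    p_dur: np.ndarray     # (D, C, 4)
    phi: np.ndarray       # (D, C)
    alpha: np.ndarray     # (D,)
    lam: np.ndarray       # (D, 4)
    alloc: np.ndarray     # (D, m) int
    exposed_idx: np.ndarray
    n_subjects: int
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_components(self) -> int:
        return self.beta.shape[1]

    def full_labels(self) -> np.ndarray:
        """(D, n) partition matrix over the whole cohort: reference
        subjects carry the reserved label 0, exposed subjects 1..C."""
        D = self.n_draws
        out = np.zeros((D, self.n_subjects), dtype=int)
        out[:, self.exposed_idx] = self.alloc + 1
        return out

    def n_nonempty(self) -> np.ndarray:
        """Number of occupied exposed components at each retained draw."""
        return np.array([len(np.unique(row)) for row in self.alloc])


def _run(cohort: Cohort, prior: PriorSpec, config: SamplerConfig) -> Trace:
    arrays = CohortArrays(cohort, config.zero_policy, config.delayed_entry)
    if arrays.m == 0:
        raise ValueError("cohort has no exposed subjects to cluster")
    rng = np.random.default_rng(config.seed)
    state = init_state(arrays, prior, config, rng)
    lj = log_joint(state, arrays, prior)
    if not np.isfinite(lj):
        raise RuntimeError(f"non-finite log joint at initialisation (log_joint={lj})")

    C = state.n_components
    proposals = AdaptiveScales()
    # start random-walk scales near 2.4 x the local posterior curvature
    # (Gamma-approximation sd sqrt(d)/E for beta, sigma/sqrt(2 m) for sigma),
    # so the short adaptive phase only has to fine-tune them
    d0 = np.bincount(state.alloc, weights=arrays.delta[arrays.exposed_idx], minlength=C)
    _, h0_init = cohort_loglik_terms(arrays, state.lam)
    E0 = np.bincount(state.alloc, weights=h0_init[arrays.exposed_idx], minlength=C)
    beta_sd = np.sqrt(np.maximum(d0, 1.0)) / np.maximum(E0, 1e-12)
    beta_init_scale = float(np.clip(np.median(beta_sd), 0.05, 10.0)) * 2.4
    m0 = np.maximum(np.bincount(state.alloc, minlength=C), 1)
    sig_sd = state.sigma / np.sqrt(2.0 * m0)[:, None]
    sigma_init_scale = float(np.clip(np.median(sig_sd), 0.01, 5.0)) * 2.4
    proposals.register("beta", C, beta_init_scale, config.target_scalar)
    proposals.register("sigma", C * 4, sigma_init_scale, config.target_scalar)
    proposals.register("alpha", 1, 0.5, config.target_scalar)

    adapt_end = config.adapt_batches * config.batch_size
    keep_start = adapt_end + config.burnin
    n_total = keep_start + config.n_iter
    D = config.n_stored
    trace = Trace(
        beta=np.empty((D, C)), mu=np.empty((D, C, 4)), sigma=np.empty((D, C, 4)),
        p_job=np.empty((D, C, 5)), p_mine=np.empty((D, C, 2)), p_dur=np.empty((D, C, 4)),
        phi=np.empty((D, C)), alpha=np.empty(D), lam=np.empty((D, 4)),
        alloc=np.empty((D, arrays.m), dtype=np.int32),
        exposed_idx=arrays.exposed_idx, n_subjects=arrays.n,
    )
    if adapt_end == 0:
        proposals.freeze()
    move_attempts = np.zeros(3)
    move_accepts = np.zeros(3)
    nonempty = np.empty(n_total, dtype=np.int16)
    stored = 0
    for it in range(n_total):
        update_allocations(state, arrays, rng)
        update_sticks(state, rng)
        update_cluster_scalars(state, arrays, prior, proposals, rng)
        if config.do_label_moves and C >= 2:
            j, k = rng.choice(C, size=2, replace=False)
            move_attempts[0] += 1
            move_accepts[0] += move1(state, int(j), int(k), rng)
            if C >= 3:
                j2 = int(rng.integers(C - 2))
                move_attempts[1] += 1
                move_accepts[1] += move2(state, j2, rng)
            j3 = int(rng.integers(C - 1))
            move_attempts[2] += 1
            move_accepts[2] += move3(state, j3, rng)
        nonempty[it] = len(np.unique(state.alloc))
        if not proposals.frozen and (it + 1) % config.batch_size == 0:
            proposals.end_batch()
            if it + 1 >= adapt_end:
                proposals.freeze()
        if it >= keep_start and (it - keep_start + 1) % config.thin == 0:
            trace.beta[stored] = state.beta
            trace.mu[stored] = state.mu
            trace.sigma[stored] = state.sigma
            trace.p_job[stored] = state.p_job
            trace.p_mine[stored] = state.p_mine
            trace.p_dur[stored] = state.p_dur
            trace.phi[stored] = state.phi
            trace.alpha[stored] = state.alpha
            trace.lam[stored] = state.lam
            trace.alloc[stored] = state.alloc
            stored += 1

    with np.errstate(invalid="ignore"):
        move_rates = np.where(move_attempts > 0, move_accepts / np.maximum(move_attempts, 1), np.nan)
    trace.meta = {
        "config": config.to_dict(),
        "seed": config.seed,
        "acceptance_rates": proposals.acceptance_rates(),
        "move_acceptance": [float(r) for r in move_rates],
        "n_nonempty_trace": nonempty.tolist(),
        "n": arrays.n,
        "m_exposed": int(arrays.m),
        "events": int(arrays.delta.sum()),
    }
    return trace


def run_prm(cohort: Cohort, prior: PriorSpec, config: SamplerConfig) -> Trace:
    """Fit the full profile regression mixture (truncation c_max)."""
    if config.mode != "PRM":
        raise ValueError("config.mode must be 'PRM'")
    return _run(cohort, prior, config)


def run_rprm(cohort: Cohort, prior: PriorSpec, config: SamplerConfig) -> Trace:
    """Fit the restricted variant with K clusters including the
    reference, i.e. K-1 exposed mixture components."""
    if config.mode != "RPRM":
        raise ValueError("config.mode must be 'RPRM' with K set")
    return _run(cohort, prior, config)
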