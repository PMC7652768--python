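"""Exposure sub-model, stick-breaking attribution sub-model, and the
joint posterior density of the profile regression mixture.

Each exposed subject belongs to a latent cluster ``c`` with probability
``phi_c``.  Given the cluster, the three cumulative exposures and the
age at first exposure are independent lognormals and the three
categorical covariates (job type, mine district, exposure-duration
class) are multinomial.  The cluster also carries the excess hazard
``beta_c`` of the survival sub-model, so the outcome informs the
clustering.  The weights ``phi`` follow a truncated stick-breaking
construction: V_c ~ Beta(1, alpha) and

    phi_c = V_c * prod_{k<c} (1 - V_k),   phi_Cmax = remainder.

Subjects with all exposures zero are the reference group, outside the
mixture, with the reserved label 0 and beta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .cohort import CohortArrays, MinerRecord
from .priors import PriorSpec
from .survival import BaselineHazard, cohort_loglik_terms, loglik_record_cluster

LOG_2PI = np.log(2.0 * np.pi)

#: Column order of the four lognormal covariates everywhere in the package.
CONTINUOUS_VARS = ("radon", "gamma", "dust", "age")
CATEGORICAL_SIZES = {"job": 5, "mine": 2, "duration": 4}


@dataclass
class ClusterParams:
    """Risk and exposure-distribution parameters of one cluster."""

    beta: float
    mu_radon: float
    sigma_radon: float
    mu_gamma: float
    sigma_gamma: float
    mu_dust: float
    sigma_dust: float
    mu_age: float
    sigma_age: float
    p_job: np.ndarray
    p_mine: np.ndarray
    p_duration: np.ndarray

    def __post_init__(self) -> None:
        if self.beta <= -1:
            raise ValueError("beta must exceed -1")
        for name in ("sigma_radon", "sigma_gamma", "sigma_dust", "sigma_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name, size in (("p_job", 5), ("p_mine", 2), ("p_duration", 4)):
            p = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, p)
            if p.shape != (size,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a probability vector of length {size}")

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.mu_radon, self.mu_gamma, self.mu_dust, self.mu_age])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([self.sigma_radon, self.sigma_gamma, self.sigma_dust, self.sigma_age])


def stick_breaking(V: np.ndarray, c_max: int) -> np.ndarray:
    """Weights from stick-breaking fractions; the last component takes
    the unbroken remainder of the stick."""
    V = np.asarray(V, dtype=float)
    if V.shape != (c_max - 1,):
        raise ValueError(f"need {c_max - 1} fractions for c_max={c_max}")
    if ((V < 0) | (V > 1)).any():
        raise ValueError("stick fractions must lie in [0, 1]")
    phi = np.empty(c_max)
    remaining = np.concatenate(([1.0], np.cumprod(1.0 - V)))
    phi[:-1] = V * remaining[:-1]
    # the remainder; clip tiny negative round-off
    phi[-1] = max(1.0 - phi[:-1].sum(), 0.0)
    return phi


@dataclass
class MixtureState:
    """Full parameter state of the (R)PRM sampler.

    Arrays are stacked over the ``C`` exposed mixture components; the
    reference cluster is implicit (label 0 in user-facing partitions,
    beta fixed at 0).  ``alloc`` holds 0-based component labels for the
    exposed subjects only.
    """

    beta: np.ndarray          # (C,)
    mu: np.ndarray            # (C, 4) lognormal locations, order CONTINUOUS_VARS
    sigma: np.ndarray         # (C, 4) lognormal scales
    p_job: np.ndarray         # (C, 5)
    p_mine: np.ndarray        # (C, 2)
    p_dur: np.ndarray         # (C, 4)
    V: np.ndarray             # (C-1,)
    phi: np.ndarray           # (C,)
    alpha: float
    lam: np.ndarray           # (4,)
    alloc: np.ndarray         # (m,) int

    def __post_init__(self) -> None:
        C = len(self.beta)
        shapes = {
            "mu": (C, 4), "sigma": (C, 4), "p_job": (C, 5),
            "p_mine": (C, 2), "p_dur": (C, 4), "V": (max(C - 1, 0),), "phi": (C,),
        }
        for name, shape in shapes.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        self.beta = np.asarray(self.beta, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.shape != (4,):
            raise ValueError("lam must have shape (4,)")
        self.alloc = np.asarray(self.alloc, dtype=int)
        if self.alloc.size and (self.alloc.min() < 0 or self.alloc.max() >= C):
            raise ValueError("allocations out of component range")

    @property
    def n_components(self) -> int:
        return len(self.beta)

    def counts(self) -> np.ndarray:
        return np.bincount(self.alloc, minlength=self.n_components)

    def cluster(self, c: int) -> ClusterParams:
        return ClusterParams(
            beta=float(self.beta[c]),
            mu_radon=float(self.mu[c, 0]), sigma_radon=float(self.sigma[c, 0]),
            mu_gamma=float(self.mu[c, 1]), sigma_gamma=float(self.sigma[c, 1]),
            mu_dust=float(self.mu[c, 2]), sigma_dust=float(self.sigma[c, 2]),
            mu_age=float(self.mu[c, 3]), sigma_age=float(self.sigma[c, 3]),
            p_job=self.p_job[c], p_mine=self.p_mine[c], p_duration=self.p_dur[c],
        )

    def copy(self) -> "MixtureState":
        return MixtureState(
            beta=self.beta.copy(), mu=self.mu.copy(), sigma=self.sigma.copy(),
            p_job=self.p_job.copy(), p_mine=self.p_mine.copy(), p_dur=self.p_dur.copy(),
            V=self.V.copy(), phi=self.phi.copy(), alpha=self.alpha,
            lam=self.lam.copy(), alloc=self.alloc.copy(),
        )

    def swap_components(self, j: int, k: int) -> None:
        """Exchange all cluster-specific parameters and relabel the
        allocations of components ``j`` and ``k`` (weights untouched)."""
        for arr in (self.beta, self.mu, self.sigma, self.p_job, self.p_mine, self.p_dur):
            arr[[j, k]] = arr[[k, j]]
        sel_j = self.alloc == j
        sel_k = self.alloc == k
        self.alloc[sel_j] = k
        self.alloc[sel_k] = j


def loglik_exposure(record: MinerRecord, params: ClusterParams) -> float:
    """Log-density of one exposed subject's covariate profile."""
    if not record.is_exposed or min(record.x_radon, record.x_gamma, record.x_dust) <= 0:
        raise ValueError(
            "subject has non-positive exposures; route it to the reference cluster"
        )
    xs = np.array([record.x_radon, record.x_gamma, record.x_dust, record.age_first_exposure])
    logx = np.log(xs)
    ll = float(
        np.sum(
            -logx - np.log(params.sigma) - 0.5 * LOG_2PI
            - 0.5 * ((logx - params.mu) / params.sigma) ** 2
        )
    )
    ll += float(np.log(params.p_job[record.job - 1]))
    ll += float(np.log(params.p_mine[record.mine - 1]))
    ll += float(np.log(params.p_duration[record.duration_class - 1]))
    return ll


def exposure_loglik_matrix(arrays: CohortArrays, state: MixtureState) -> np.ndarray:
    """(m, C) matrix of exposure log-densities for the exposed subjects."""
    logx = arrays.logx  # (m, 4)
    mu, sigma = state.mu, state.sigma  # (C, 4)
    with np.errstate(divide="ignore"):
        z = (logx[:, None, :] - mu[None, :, :]) / sigma[None, :, :]
        ll = np.sum(
            -0.5 * z * z - np.log(sigma)[None, :, :] - 0.5 * LOG_2PI - logx[:, None, :],
            axis=2,
        )
        ll += np.log(state.p_job).T[arrays.job0]
        ll += np.log(state.p_mine).T[arrays.mine0]
        ll += np.log(state.p_dur).T[arrays.dur0]
    return ll


def survival_loglik_matrix(arrays: CohortArrays, state: MixtureState) -> np.ndarray:
    """(m, C) survival log-likelihood of each exposed subject under each
    component's beta (the baseline part is included)."""
    base, h0 = cohort_loglik_terms(arrays, state.lam)
    sub = arrays.exposed_idx
    b = state.beta
    ok = b > -1
    with np.errstate(divide="ignore", invalid="ignore"):
        log1pb = np.where(ok, np.log1p(np.where(ok, b, 0.0)), 0.0)
    out = (
        base[sub, None]
        + arrays.delta[sub, None] * log1pb[None, :]
        - h0[sub, None] * (1.0 + b)[None, :]
    )
    # a component with beta <= -1 is inadmissible for every record
    out[:, ~ok] = -np.inf
    return out


def allocation_log_probabilities(arrays: CohortArrays, state: MixtureState) -> np.ndarray:
    """(m, C) unnormalised allocation log-probabilities."""
    with np.errstate(divide="ignore"):
        logphi = np.log(state.phi)
    return (
        logphi[None, :]
        + exposure_loglik_matrix(arrays, state)
        + survival_loglik_matrix(arrays, state)
    )


def allocation_probabilities(record: MinerRecord, state: MixtureState) -> np.ndarray:
    """Posterior component membership probabilities of one exposed
    subject, computed through log-sum-exp."""
    hazard = BaselineHazard(state.lam)
    C = state.n_components
    logp = np.full(C, -np.inf)
    for c in range(C):
        if state.beta[c] <= -1 or state.phi[c] <= 0:
            continue
        logp[c] = (
            np.log(state.phi[c])
            + loglik_exposure(record, state.cluster(c))
            + loglik_record_cluster(record, float(state.beta[c]), hazard)
        )
    top = logp.max()
    if not np.isfinite(top):
        raise ValueError("all components are inadmissible for this record")
    p = np.exp(logp - top)
    return p / p.sum()


def _dirichlet_logpdf(p: np.ndarray, conc: float) -> float:
    k = p.shape[-1]
    logB = k * gammaln(conc) - gammaln(k * conc)
    with np.errstate(divide="ignore"):
        return float(np.sum((conc - 1.0) * np.log(p)) - p.shape[0] * logB) if p.ndim == 2 \
            else float(np.sum((conc - 1.0) * np.log(p)) - logB)


def log_joint(state: MixtureState, arrays: CohortArrays, prior: PriorSpec) -> float:
    """Unnormalised log posterior density of a full state.

    Returns ``-inf`` (rather than raising) for parameter values outside
    their support, which is what the Metropolis steps rely on.
    """
    C = state.n_components
    # --- support checks -> -inf
    if np.any(state.beta <= -1) or np.any(state.lam <= 0):
        return -np.inf
    lo_s, hi_s = prior.sigma_bounds
    if np.any(state.sigma <= max(lo_s, 0.0)) or np.any(state.sigma > hi_s):
        return -np.inf
    lo_a, hi_a = prior.alpha_bounds
    if not (lo_a <= state.alpha <= hi_a):
        return -np.inf
    if C > 1 and (np.any(state.V <= 0) or np.any(state.V >= 1)):
        return -np.inf
    if np.any(state.phi < 0):
        return -np.inf

    # survival likelihood of the whole cohort
    base, h0 = cohort_loglik_terms(arrays, state.lam)
    mult = np.ones(arrays.n)
    mult[arrays.exposed_idx] = 1.0 + state.beta[state.alloc]
    with np.errstate(divide="ignore"):
        ll = float(np.sum(base + arrays.delta * np.log(mult) - mult * h0))

    # exposure likelihood and allocation probabilities of exposed subjects
    expo = exposure_loglik_matrix(arrays, state)
    m = arrays.m
    ll += float(expo[np.arange(m), state.alloc].sum())
    with np.errstate(divide="ignore"):
        logphi = np.log(state.phi)
    if np.any(~np.isfinite(logphi[state.alloc])):
        return -np.inf
    ll += float(logphi[state.alloc].sum())

    # stick-breaking prior Beta(1, alpha) on each V
    if C > 1:
        ll += (C - 1) * np.log(state.alpha) + (state.alpha - 1.0) * float(
            np.log1p(-state.V).sum()
        )

    # parameter priors (identical across components)
    bm, bv = prior.beta
    ll += float(np.sum(-0.5 * (state.beta - bm) ** 2 / bv - 0.5 * np.log(2 * np.pi * bv)))
    mp = prior.mu_priors  # (4, 2)
    ll += float(
        np.sum(
            -0.5 * (state.mu - mp[:, 0]) ** 2 / mp[:, 1]
            - 0.5 * np.log(2 * np.pi * mp[:, 1])
        )
    )
    ll += -C * 4 * np.log(hi_s - lo_s)  # uniform sigma priors
    for p in (state.p_job, state.p_mine, state.p_dur):
        ll += _dirichlet_logpdf(p, prior.dirichlet_conc)
    a, b = prior.lam_shapes, prior.lam_rates
    ll += float(
        np.sum(a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(state.lam) - b * state.lam)
    )
    ll += -np.log(hi_a - lo_a)  # uniform alpha prior
    return ll
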