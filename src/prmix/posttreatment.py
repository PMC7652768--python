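"""Post-processing of (R)PRM traces.

The retained allocation draws define, for every pair of subjects, the
posterior probability of being clustered together (the similarity
matrix).  The reported partition is the *sampled* partition closest to
that matrix in least squares, which avoids the label-switching problem
entirely.  Cluster-conditional posterior distributions are then built by
averaging, at each retained draw, the parameter of the component each
member currently belongs to.  DIC and WAIC are computed from the
per-subject mixture likelihood for model comparison across fixed K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import Cohort, CohortArrays, DAYS_PER_YEAR
from .mixture import (
    MixtureState,
    allocation_log_probabilities,
    stick_breaking,
)
from .sampler import Trace
from .survival import cohort_loglik_terms

#: trace attributes that are indexed by cluster, hence eligible for
#: partition-conditional averaging (the weights phi included).
CLUSTER_PARAMS = ("beta", "mu", "sigma", "p_job", "p_mine", "p_dur", "phi")


@dataclass
class SimilarityMatrix:
    """Posterior co-clustering proportions of all subject pairs."""

    S: np.ndarray
    K_draws: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        self.S = S


def _as_label_matrix(allocation_trace: np.ndarray) -> np.ndarray:
    labels = np.asarray(allocation_trace)
    if labels.ndim != 2:
        raise ValueError("allocation trace must be a (draws, subjects) matrix")
    return labels.astype(int)


def similarity_matrix(allocation_trace: np.ndarray) -> SimilarityMatrix:
    """Mean over draws of the pairwise same-cluster indicator matrices.

    Accepts the (draws, n) integer label matrix (e.g.
    ``Trace.full_labels()``); the n x n binaries are accumulated one
    draw at a time via one-hot products, never materialised together.
    """
    labels = _as_label_matrix(allocation_trace)
    D, n = labels.shape
    if D == 0:
        raise ValueError("empty allocation trace")
    L = labels.max() + 1
    S = np.zeros((n, n))
    eye = np.eye(L)
    for row in labels:
        Z = eye[row]
        S += Z @ Z.T
    S /= D
    return SimilarityMatrix(S=S, K_draws=D)


def best_partition(allocation_trace: np.ndarray, sim: SimilarityMatrix) -> np.ndarray:
    """The sampled partition minimising the least-squares distance
    (over unordered pairs i<j) to the similarity matrix.

    Ties are broken by the earliest draw index; the result is always one
    of the sampled partitions, never an invented one.
    """
    labels = _as_label_matrix(allocation_trace)
    D, n = labels.shape
    if D == 0:
        raise ValueError("empty allocation trace")
    if sim.S.shape[0] != n:
        raise ValueError("similarity matrix and trace disagree on n")
    # dist_k = sum_{i<j} (I_k - S)^2 = const + sum_{i<j} I_k (1 - 2 S)
    W = 1.0 - 2.0 * sim.S
    np.fill_diagonal(W, 0.0)
    L = labels.max() + 1
    eye = np.eye(L)
    scores = np.empty(D)
    for k, row in enumerate(labels):
        Z = eye[row]
        scores[k] = 0.5 * np.sum(Z * (W @ Z))
    return labels[int(np.argmin(scores))].copy()


def conditional_posteriors(trace: Trace, c_best: np.ndarray, param: str) -> dict[int, np.ndarray]:
    """Partition-conditional posterior samples of a cluster parameter.

    For each retained draw k and each exposed cluster c of the best
    partition, averages the draw-k parameter value of the component each
    member of c belongs to at draw k.  Returns ``{cluster label: array
    of shape (draws, ...)}``.
    """
    if param not in CLUSTER_PARAMS:
        raise ValueError(f"{param!r} is not a cluster-indexed parameter")
    c_best = np.asarray(c_best, dtype=int)
    values = getattr(trace, param)  # (D, C, ...)
    pos_of_subject = {int(s): p for p, s in enumerate(trace.exposed_idx)}
    out: dict[int, np.ndarray] = {}
    for c in np.unique(c_best):
        if c == 0:
            continue  # reference cluster carries no mixture parameters
        members = np.flatnonzero(c_best == c)
        pos = np.array([pos_of_subject[int(i)] for i in members])
        if pos.size == 0:
            raise ValueError(f"cluster {c} of the best partition is empty")
        member_alloc = trace.alloc[:, pos]  # (D, n_c)
        draw_idx = np.arange(trace.n_draws)[:, None]
        gathered = values[draw_idx, member_alloc]  # (D, n_c, ...)
        out[int(c)] = gathered.mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# information criteria


def pointwise_loglik(trace: Trace, arrays: CohortArrays) -> np.ndarray:
    """(draws, n) per-subject log mixture likelihood at each draw.

    Exposed subjects: log sum_c phi_c f_exposure(x_i | c) f_surv(i | beta_c);
    reference subjects: survival likelihood with beta = 0.
    """
    D, n = trace.n_draws, trace.n_subjects
    out = np.empty((D, n))
    state = _state_from_draw(trace, 0)
    for k in range(D):
        _fill_state_from_draw(state, trace, k)
        base, h0 = cohort_loglik_terms(arrays, state.lam)
        ref = base - h0  # multiplier 1
        out[k] = ref
        logits = allocation_log_probabilities(arrays, state)
        out[k, arrays.exposed_idx] = logsumexp(logits, axis=1)
    if not np.isfinite(out).all():
        bad = np.argwhere(~np.isfinite(out))[0]
        raise ValueError(f"non-finite pointwise likelihood at draw {bad[0]}, subject {bad[1]}")
    return out


def _state_from_draw(trace: Trace, k: int) -> MixtureState:
    C = trace.n_components
    return MixtureState(
        beta=trace.beta[k].copy(), mu=trace.mu[k].copy(), sigma=trace.sigma[k].copy(),
        p_job=trace.p_job[k].copy(), p_mine=trace.p_mine[k].copy(),
        p_dur=trace.p_dur[k].copy(),
        V=np.full(max(C - 1, 0), 0.5), phi=trace.phi[k].copy(),
        alpha=float(trace.alpha[k]), lam=trace.lam[k].copy(),
        alloc=trace.alloc[k].copy(),
    )


def _fill_state_from_draw(state: MixtureState, trace: Trace, k: int) -> None:
    state.beta = trace.beta[k]
    state.mu = trace.mu[k]
    state.sigma = trace.sigma[k]
    state.p_job = trace.p_job[k]
    state.p_mine = trace.p_mine[k]
    state.p_dur = trace.p_dur[k]
    state.phi = trace.phi[k]
    state.alpha = float(trace.alpha[k])
    state.lam = trace.lam[k]
    state.alloc = trace.alloc[k]


def _relabelling_permutations(trace: Trace) -> np.ndarray:
    """(D, C) array mapping each draw's component labels onto the first
    draw's, by maximum allocation overlap (Hungarian assignment).

    The posterior is symmetric under label permutation and the sampler's
    label-switching moves exploit that, so raw component-wise averages
    mix permutation modes; aligning draws to a common reference first
    makes the posterior-mean plug-in meaningful.
    """
    from scipy.optimize import linear_sum_assignment

    D, C = trace.n_draws, trace.n_components
    ref = trace.alloc[0]
    perms = np.empty((D, C), dtype=int)
    for k in range(D):
        M = np.zeros((C, C))
        np.add.at(M, (ref, trace.alloc[k]), 1.0)
        rows, cols = linear_sum_assignment(-M)
        inv = np.empty(C, dtype=int)
        inv[cols] = rows  # draw-k label -> reference label
        perms[k] = inv
    return perms


def _posterior_mean_state(trace: Trace) -> MixtureState:
    C = trace.n_components
    perms = _relabelling_permutations(trace)
    order = np.argsort(perms, axis=1)  # reference label -> draw-k label
    draw_idx = np.arange(trace.n_draws)[:, None]

    def aligned_mean(arr: np.ndarray) -> np.ndarray:
        return arr[draw_idx, order].mean(axis=0)

    def norm(rows: np.ndarray) -> np.ndarray:
        return rows / rows.sum(axis=-1, keepdims=True)

    return MixtureState(
        beta=aligned_mean(trace.beta), mu=aligned_mean(trace.mu),
        sigma=aligned_mean(trace.sigma), p_job=norm(aligned_mean(trace.p_job)),
        p_mine=norm(aligned_mean(trace.p_mine)), p_dur=norm(aligned_mean(trace.p_dur)),
        V=np.full(max(C - 1, 0), 0.5), phi=norm(aligned_mean(trace.phi)[None, :])[0],
        alpha=float(trace.alpha.mean()), lam=trace.lam.mean(axis=0),
        alloc=trace.alloc[0].copy(),
    )


def dic_from_loglik(logp: np.ndarray, logp_at_point: np.ndarray) -> float:
    """DIC = mean deviance + pD, pD = mean deviance - deviance at the
    plug-in point; ``logp`` has shape (draws, subjects)."""
    dev = -2.0 * logp.sum(axis=1)
    d_bar = float(dev.mean())
    d_hat = float(-2.0 * np.sum(logp_at_point))
    return d_bar + (d_bar - d_hat)


def waic_from_loglik(logp: np.ndarray) -> float:
    """WAIC = -2 (lppd - p_waic) with p_waic the per-subject posterior
    variance of the log likelihood."""
    D = logp.shape[0]
    lppd = float(np.sum(logsumexp(logp, axis=0) - np.log(D)))
    p_waic = float(np.sum(np.var(logp, axis=0)))
    return -2.0 * (lppd - p_waic)


def _arrays_for_trace(trace: Trace, cohort: Cohort) -> CohortArrays:
    cfg = trace.meta.get("config", {})
    return CohortArrays(
        cohort,
        cfg.get("zero_policy", "impute_half_min"),
        cfg.get("delayed_entry", True),
    )


def compute_dic(trace: Trace, cohort: Cohort) -> float:
    """Deviance information criterion; the plug-in deviance uses the
    posterior means of the continuous parameters with the allocations
    marginalised through the mixture likelihood."""
    arrays = _arrays_for_trace(trace, cohort)
    logp = pointwise_loglik(trace, arrays)
    mean_state = _posterior_mean_state(trace)
    base, h0 = cohort_loglik_terms(arrays, mean_state.lam)
    point = base - h0
    logits = allocation_log_probabilities(arrays, mean_state)
    point = point.copy()
    point[arrays.exposed_idx] = logsumexp(logits, axis=1)
    return dic_from_loglik(logp, point)


def compute_waic(trace: Trace, cohort: Cohort) -> float:
    arrays = _arrays_for_trace(trace, cohort)
    return waic_from_loglik(pointwise_loglik(trace, arrays))


# ---------------------------------------------------------------------------
# partition summary and cluster characterisation report


@dataclass
class PartitionSummary:
    """Best partition with cluster-conditional posterior samples."""

    c_best: np.ndarray
    sizes: dict[int, int]
    events: dict[int, int]
    cond: dict[str, dict[int, np.ndarray]]
    beta_ci: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def clusters(self) -> list[int]:
        return sorted(self.sizes)


def summarize_partition(trace: Trace, cohort: Cohort, c_best: np.ndarray | None = None) -> PartitionSummary:
    labels = trace.full_labels()
    if c_best is None:
        sim = similarity_matrix(labels)
        c_best = best_partition(labels, sim)
    c_best = np.asarray(c_best, dtype=int)
    delta = cohort.frame["delta"].to_numpy()
    sizes, events = {}, {}
    for c in np.unique(c_best):
        sel = c_best == c
        sizes[int(c)] = int(sel.sum())
        events[int(c)] = int(delta[sel].sum())
    cond = {p: conditional_posteriors(trace, c_best, p) for p in CLUSTER_PARAMS}
    beta_ci = {
        c: tuple(np.quantile(s, [0.025, 0.975])) for c, s in cond["beta"].items()
    }
    return PartitionSummary(c_best=c_best, sizes=sizes, events=events, cond=cond,
                            beta_ci=beta_ci)


def _interval_flag(lo: float, hi: float, ref: float, above: str, below: str,
                   neutral: str = "overlapping") -> str:
    if lo > ref:
        return above
    if hi < ref:
        return below
    return neutral


def cluster_report(summary: PartitionSummary, cohort: Cohort) -> pd.DataFrame:
    """Per-cluster characterisation table.

    Rows are the exposed clusters of the best partition ordered by
    posterior median excess risk.  The risk flag declares a cluster
    significant when the 95% interval of beta excludes zero; covariate
    flags compare the 95% interval of the cluster-conditional posterior
    (medians exp(mu) for the lognormal covariates, category
    probabilities for the categorical ones) to the corresponding
    all-subject reference value.
    """
    f = cohort.frame
    exposed = cohort.exposed_mask
    global_median = {
        "radon": float(np.median(f.loc[exposed, "x_radon"])),
        "gamma": float(np.median(f.loc[exposed, "x_gamma"])),
        "dust": float(np.median(f.loc[exposed, "x_dust"])),
        "age": float(np.median(f.loc[exposed, "age_first_exposure"])),
    }
    cat_global = {
        ("job", lvl): float((f.loc[exposed, "job"] == lvl + 1).mean()) for lvl in range(5)
    }
    cat_global.update(
        {("mine", lvl): float((f.loc[exposed, "mine"] == lvl + 1).mean()) for lvl in range(2)}
    )
    cat_global.update(
        {("duration", lvl): float((f.loc[exposed, "duration_class"] == lvl + 1).mean())
         for lvl in range(4)}
    )

    rows = []
    exposed_clusters = [c for c in summary.clusters if c != 0]
    for c in exposed_clusters:
        beta_s = summary.cond["beta"][c]
        q = np.quantile(beta_s, [0.025, 0.25, 0.5, 0.75, 0.975])
        row = {
            "cluster": c,
            "size": summary.sizes[c],
            "events": summary.events[c],
            "beta_lo": q[0], "beta_q1": q[1], "beta_median": q[2],
            "beta_q3": q[3], "beta_hi": q[4],
            "risk_flag": _interval_flag(
                q[0], q[4], 0.0, "significant high risk", "significant low risk",
                "no significant risk",
            ),
        }
        mu_s = summary.cond["mu"][c]  # (D, 4)
        for v, name in enumerate(("radon", "gamma", "dust", "age")):
            med = np.exp(mu_s[:, v])
            lo, hi = np.quantile(med, [0.025, 0.975])
            row[f"{name}_flag"] = _interval_flag(lo, hi, global_median[name], "above", "below")
        for attr, name, L in (("p_job", "job", 5), ("p_mine", "mine", 2),
                              ("p_dur", "duration", 4)):
            p_s = summary.cond[attr][c]
            for lvl in range(L):
                lo, hi = np.quantile(p_s[:, lvl], [0.025, 0.975])
                row[f"{name}{lvl + 1}_flag"] = _interval_flag(
                    lo, hi, cat_global[(name, lvl)], "above", "below"
                )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("beta_median").reset_index(drop=True)
    return table
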