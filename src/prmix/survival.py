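"""Excess hazard ratio (EHR) survival model with a piecewise baseline.

The hazard of death by lung cancer at age ``t`` is

    h_i(t) = h0(t) * (1 + excess_i)

where ``h0`` is piecewise constant on four age intervals (<40, 40-55,
55-70, >=70 years) and the excess term is either a per-cluster constant
``beta_c`` (profile regression) or a linear function of cumulative
exposures ``beta . x_i`` (the classical EHR regression).  The excess is
constrained so that ``1 + excess > 0``.

Subjects enter follow-up at their hire age (delayed entry): the
likelihood conditions on survival to the entry age, so person-time
accrues only from entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adapt import AdaptiveScales, SamplerConfig
from .cohort import (
    CUTPOINTS_DAYS,
    Cohort,
    CohortArrays,
    MinerRecord,
    N_INTERVALS,
    interval_index,
    person_time_by_interval,
)
from .priors import PriorSpec

EXPOSURE_NAMES = ("radon", "gamma", "dust")
#: Default covariate scalings for the regression form: radon enters per
#: 100 WLM, gamma-rays and uranium dust in their raw cumulative units.
DEFAULT_SCALES = {"radon": 100.0, "gamma": 1.0, "dust": 1.0}


@dataclass
class BaselineHazard:
    """Piecewise-constant baseline hazard, rates in events per day."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_INTERVALS,):
            raise ValueError(f"need {N_INTERVALS} rates, got shape {self.rates.shape}")
        if not (self.rates > 0).all():
            raise ValueError("baseline rates must be positive")

    @property
    def cutpoints(self) -> np.ndarray:
        return np.asarray(CUTPOINTS_DAYS)


@dataclass
class EHRCoefficients:
    """Coefficients of the regression-form EHR model on scaled exposures."""

    values: np.ndarray
    exposures: tuple[str, ...] = EXPOSURE_NAMES
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if len(self.values) != len(self.exposures):
            raise ValueError("one coefficient per exposure required")
        if self.scales is None:
            self.scales = np.array([DEFAULT_SCALES[e] for e in self.exposures])
        else:
            self.scales = np.asarray(self.scales, dtype=float)

    def multiplier(self, exposures: np.ndarray) -> np.ndarray:
        """1 + beta . x_scaled for raw exposure rows."""
        x = np.atleast_2d(np.asarray(exposures, dtype=float)) / self.scales
        return 1.0 + x @ self.values


def cumulative_baseline_hazard(hazard: BaselineHazard, t_entry: float, t_exit: float) -> float:
    """Integral of h0 over [t_entry, t_exit] (ages in days)."""
    if t_exit < t_entry:
        raise ValueError("t_exit must be >= t_entry")
    if t_entry < 0:
        raise ValueError("ages must be non-negative")
    e = person_time_by_interval(np.array([t_entry]), np.array([t_exit]))
    return float(e[0] @ hazard.rates)


def _record_loglik(record: MinerRecord, multiplier: float, hazard: BaselineHazard,
                   delayed_entry: bool) -> float:
    entry = record.entry_age if delayed_entry else 0.0
    h0 = cumulative_baseline_hazard(hazard, entry, record.y)
    ll = -multiplier * h0
    if record.delta == 1:
        j = int(interval_index(record.y))
        ll += np.log(hazard.rates[j] * multiplier)
    return float(ll)


def loglik_record_cluster(
    record: MinerRecord, beta: float, hazard: BaselineHazard, delayed_entry: bool = True
) -> float:
    """Censored log-likelihood of one subject under h = h0 (1 + beta)."""
    if beta <= -1:
        raise ValueError("beta must exceed -1 to keep the hazard positive")
    return _record_loglik(record, 1.0 + beta, hazard, delayed_entry)


def loglik_record_regression(
    record: MinerRecord,
    coefs: EHRCoefficients,
    hazard: BaselineHazard,
    delayed_entry: bool = True,
) -> float:
    """Censored log-likelihood under h = h0 (1 + beta . x_scaled)."""
    name_to_field = {"radon": record.x_radon, "gamma": record.x_gamma, "dust": record.x_dust}
    x = np.array([name_to_field[e] for e in coefs.exposures])
    mult = float(coefs.multiplier(x)[0])
    if mult <= 0:
        raise ValueError("inadmissible parameter point: hazard multiplier <= 0")
    return _record_loglik(record, mult, hazard, delayed_entry)


# ---------------------------------------------------------------------------
# vectorised kernels used by the samplers


def cohort_loglik_terms(arrays: CohortArrays, lam: np.ndarray):
    """Per-subject pieces reused across parameter updates.

    Returns ``(base, h0)`` with ``base_i = delta_i log lam_{j(y_i)}`` and
    ``h0_i`` the cumulative baseline hazard over the observation window;
    the per-subject log-likelihood for hazard multiplier ``m_i`` is then
    ``base_i + delta_i log m_i - m_i h0_i``.
    """
    base = arrays.delta * np.log(lam[arrays.ev_int])
    h0 = arrays.e @ lam
    return base, h0


def cohort_survival_loglik(arrays: CohortArrays, lam: np.ndarray, mult: np.ndarray) -> float:
    """Total survival log-likelihood for per-subject multipliers ``mult``."""
    if np.any(mult <= 0) or np.any(lam <= 0):
        return -np.inf
    base, h0 = cohort_loglik_terms(arrays, lam)
    return float(np.sum(base + arrays.delta * np.log(mult) - mult * h0))


def gibbs_update_lambda(
    arrays: CohortArrays, mult: np.ndarray, prior: PriorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate gamma draw of the four baseline rates.

    Posterior is Gamma(shape + events_j, rate + sum_i mult_i * e_ij).
    """
    d = np.bincount(arrays.ev_int, weights=arrays.delta, minlength=N_INTERVALS)
    exposure = arrays.e.T @ mult
    shape = prior.lam_shapes + d
    rate = prior.lam_rates + exposure
    return rng.gamma(shape, 1.0 / rate)


# ---------------------------------------------------------------------------
# classical EHR regression (no clustering)


class EHRTrace:
    """Posterior draws of the regression-form EHR model."""

    def __init__(self, lam: np.ndarray, coefs: np.ndarray, exposures: tuple[str, ...],
                 scales: np.ndarray, meta: dict):
        self.lam = lam              # (draws, 4)
        self.coefs = coefs          # (draws, k)
        self.exposures = exposures
        self.scales = scales
        self.meta = meta

    def summary(self) -> dict:
        """Posterior medians and equal-tailed 95% credible intervals."""
        out = {}
        for i, name in enumerate(self.exposures):
            q = np.quantile(self.coefs[:, i], [0.025, 0.5, 0.975])
            out[f"beta_{name}"] = {"median": q[1], "ci95": (q[0], q[2])}
        for j in range(N_INTERVALS):
            q = np.quantile(self.lam[:, j], [0.025, 0.5, 0.975])
            out[f"lambda_{j + 1}"] = {"median": q[1], "ci95": (q[0], q[2])}
        return out


def fit_ehr_regression(
    cohort: Cohort,
    prior: PriorSpec,
    config: SamplerConfig,
    exposures: tuple[str, ...] = EXPOSURE_NAMES,
    scales: dict[str, float] | None = None,
) -> EHRTrace:
    """Adaptive MH-within-Gibbs fit of the no-clustering EHR model.

    The baseline rates are updated by conjugate gamma draws; the
    coefficient block is a random-walk Metropolis step, tuned to 40%
    acceptance when a single exposure enters and to 20% when several
    coefficients are updated jointly as a vector.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    unknown = [e for e in exposures if e not in EXPOSURE_NAMES]
    if unknown:
        raise ValueError(f"unknown exposures {unknown}")
    scale_map = dict(DEFAULT_SCALES)
    if scales:
        scale_map.update(scales)
    sc = np.array([scale_map[e] for e in exposures])
    arrays = CohortArrays(cohort, config.zero_policy, config.delayed_entry)
    col = {"radon": 0, "gamma": 1, "dust": 2}
    x = arrays.x_raw[:, [col[e] for e in exposures]] / sc
    k = len(exposures)

    rng = np.random.default_rng(config.seed)
    lam = prior.lam_shapes / prior.lam_rates
    beta = np.zeros(k)
    if not np.all(1.0 + x @ beta > 0):
        raise RuntimeError("no admissible starting point found")

    b_mean, b_var = prior.beta

    def beta_logpost(b: np.ndarray) -> float:
        mult = 1.0 + x @ b
        if np.any(mult <= 0):
            return -np.inf
        ll = np.sum(arrays.delta * np.log(mult) - mult * h0)
        lp = -0.5 * np.sum((b - b_mean) ** 2) / b_var
        return float(ll + lp)

    scales_mgr = AdaptiveScales()
    target = config.target_scalar if k == 1 else config.target_vector
    scales_mgr.register("coefs", 1, 0.1, target)

    n_total = config.adapt_batches * config.batch_size + config.burnin + config.n_iter
    adapt_end = config.adapt_batches * config.batch_size
    keep_start = adapt_end + config.burnin
    lam_store = np.empty((config.n_stored, N_INTERVALS))
    coef_store = np.empty((config.n_stored, k))

    _, h0 = cohort_loglik_terms(arrays, lam)
    lp_beta = beta_logpost(beta)
    stored = 0
    if adapt_end == 0:
        scales_mgr.freeze()
    for it in range(n_total):
        mult = 1.0 + x @ beta
        lam = gibbs_update_lambda(arrays, mult, prior, rng)
        _, h0 = cohort_loglik_terms(arrays, lam)
        lp_beta = beta_logpost(beta)

        step = scales_mgr.scales("coefs")[0]
        prop = beta + step * rng.standard_normal(k)
        lp_prop = beta_logpost(prop)
        accept = np.log(rng.uniform()) < lp_prop - lp_beta
        if accept:
            beta, lp_beta = prop, lp_prop
        scales_mgr.record("coefs", np.array([accept]))

        if not scales_mgr.frozen and (it + 1) % config.batch_size == 0:
            scales_mgr.end_batch()
            if it + 1 >= adapt_end:
                scales_mgr.freeze()
        if it >= keep_start and (it - keep_start + 1) % config.thin == 0:
            lam_store[stored] = lam
            coef_store[stored] = beta
            stored += 1

    meta = {
        "acceptance_rates": scales_mgr.acceptance_rates(),
        "config": config.to_dict(),
        "exposures": list(exposures),
        "scales": sc.tolist(),
        "n": arrays.n,
        "events": int(arrays.delta.sum()),
    }
    return EHRTrace(lam_store[:stored], coef_store[:stored], tuple(exposures), sc, meta)
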