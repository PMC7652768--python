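"""Synthetic uranium-miner cohorts with the structure the model assumes.

The generator emulates an occupational cohort followed on the age
scale: delayed entry at the hire age, a small lung-cancer event
fraction, right censoring by competing mortality and an administrative
age cutoff, and three positive cumulative exposures whose strong
pairwise correlation is induced by shared cluster membership (clusters
are ordered from lightly to heavily exposed on all three sources at
once, mirroring how co-exposure arises from a common underground
source).  A configurable fraction of subjects is unexposed on all three
sources; these form the reference group and are simulated with zero
excess risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, DAYS_PER_YEAR, MinerRecord
from .survival import BaselineHazard
from .cohort import CUTPOINTS_DAYS


@dataclass
class SimTruth:
    """Ground-truth generating parameters of a synthetic cohort."""

    n: int
    weights: np.ndarray            # (K,) cluster weights among exposed subjects
    beta: np.ndarray               # (K,) excess hazards, all > -1
    mu: np.ndarray                 # (K, 4) lognormal locations: radon, gamma, dust, age-first
    sigma: np.ndarray              # (K, 4) lognormal scales
    p_job: np.ndarray              # (K, 5)
    p_mine: np.ndarray             # (K, 2)
    p_dur: np.ndarray              # (K, 4)
    lam: np.ndarray                # (4,) baseline rates per day
    entry_age_logmean: float = np.log(27.0)   # entry age lognormal, years
    entry_age_logsd: float = 0.18
    admin_censor_age_years: float = 80.0
    max_age_years: float = 85.0
    competing_rate: float = 2.2e-5  # competing mortality, per day
    reference_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        for name in ("beta", "mu", "sigma", "p_job", "p_mine", "p_dur", "lam"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        K = len(self.weights)
        if abs(self.weights.sum() - 1.0) > 1e-8 or (self.weights < 0).any():
            raise ValueError("weights must be a probability vector")
        if self.beta.shape != (K,) or np.any(self.beta <= -1):
            raise ValueError("need one beta > -1 per cluster")
        if self.mu.shape != (K, 4) or self.sigma.shape != (K, 4):
            raise ValueError("mu and sigma must have shape (K, 4)")
        if np.any(self.sigma <= 0):
            raise ValueError("lognormal scales must be positive")
        for name, L in (("p_job", 5), ("p_mine", 2), ("p_dur", 4)):
            p = getattr(self, name)
            if p.shape != (K, L) or np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1) > 1e-8):
                raise ValueError(f"{name} rows must be probability vectors of length {L}")
        if self.lam.shape != (4,) or np.any(self.lam <= 0):
            raise ValueError("baseline rates must be positive")
        if not 0 <= self.reference_fraction <= 1:
            raise ValueError("reference_fraction must lie in [0, 1]")
        if self.competing_rate < 0:
            raise ValueError("competing_rate must be non-negative")

    @property
    def n_clusters(self) -> int:
        return len(self.weights)

    @property
    def censor_age_days(self) -> float:
        return min(self.admin_censor_age_years, self.max_age_years) * DAYS_PER_YEAR


def default_truth(n: int = 3377, seed: int = 0) -> SimTruth:
    """Study-scale conditions: five exposure profiles ordered from light
    to heavy co-exposure on all three sources (inducing the strong
    pooled correlations), ~3% lung-cancer deaths, ~23% competing
    deaths, and a small fully unexposed reference group."""
    return SimTruth(
        n=n,
        weights=np.array([0.25, 0.24, 0.20, 0.17, 0.14]),
        beta=np.array([0.0, 0.1, 0.3, 0.6, 1.2]),
        mu=np.array([
            [0.3, 1.6, -1.7, 3.35],
            [1.3, 2.6, -0.8, 3.30],
            [2.2, 3.4, -0.1, 3.28],
            [3.0, 4.1, 0.5, 3.30],
            [3.7, 4.7, 1.1, 3.40],
        ]),
        sigma=np.column_stack([np.full(5, 0.7)] * 3 + [np.full(5, 0.15)]),
        p_job=np.array([
            [0.05, 0.15, 0.15, 0.25, 0.40],
            [0.10, 0.25, 0.15, 0.30, 0.20],
            [0.15, 0.30, 0.20, 0.25, 0.10],
            [0.25, 0.30, 0.25, 0.15, 0.05],
            [0.40, 0.25, 0.25, 0.08, 0.02],
        ]),
        p_mine=np.array([[0.5, 0.5], [0.35, 0.65], [0.2, 0.8], [0.1, 0.9], [0.05, 0.95]]),
        p_dur=np.array([
            [0.55, 0.30, 0.10, 0.05],
            [0.35, 0.35, 0.20, 0.10],
            [0.20, 0.30, 0.30, 0.20],
            [0.10, 0.25, 0.30, 0.35],
            [0.05, 0.15, 0.30, 0.50],
        ]),
        lam=np.array([23.7 / 4.9e8, 35.5 / 2.6e7, 88.1 / 1.6e7, 29.7 / 3.2e6]),
        seed=seed,
    )


def toy_truth(n: int = 400, n_clusters: int = 3, seed: int = 0,
              reference_fraction: float = 0.05) -> SimTruth:
    """Small, well-separated clusters with strong risk contrast
    (excess hazards spread from 0 to 4), used for sampler validation at
    desk scale."""
    K = n_clusters
    base = default_truth()
    idx = np.linspace(0, 4, K).round().astype(int)
    mu = base.mu[idx].copy()
    mu[:, :3] = np.linspace(-1.0, 4.0, K)[:, None] + np.array([0.0, 0.6, -1.2])
    return SimTruth(
        n=n,
        weights=np.full(K, 1.0 / K),
        beta=np.linspace(0.0, 4.0, K),
        mu=mu,
        sigma=np.column_stack([np.full(K, 0.35)] * 3 + [np.full(K, 0.12)]),
        p_job=base.p_job[idx],
        p_mine=base.p_mine[idx],
        p_dur=base.p_dur[idx],
        lam=base.lam,
        reference_fraction=reference_fraction,
        seed=seed,
    )


def simulate_survival_time(
    entry_age: float,
    beta: float,
    hazard: BaselineHazard,
    censor_age: float,
    competing_rate: float,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Draw (exit age in days, event indicator) for one subject.

    The lung-cancer age is drawn by inverse-CDF of the
    piecewise-exponential distribution with rates ``lam_j (1 + beta)``,
    conditioned on survival past the entry age; it competes with an
    exponential other-cause death time and the administrative cutoff.
    """
    if beta <= -1:
        raise ValueError("beta must exceed -1")
    if competing_rate < 0:
        raise ValueError("competing_rate must be non-negative")
    if not entry_age < censor_age:
        raise ValueError("entry_age must precede censor_age")
    rates = hazard.rates * (1.0 + beta)
    target = -np.log(rng.uniform())  # Exp(1) cumulative-hazard target
    bounds = np.concatenate(([0.0], CUTPOINTS_DAYS, [np.inf]))
    t_event = np.inf
    acc = 0.0
    t = entry_age
    for j in range(4):
        hi = bounds[j + 1]
        if hi <= entry_age:
            continue
        seg = hi - t
        inc = rates[j] * seg
        if acc + inc >= target:
            t_event = t + (target - acc) / rates[j]
            break
        acc += inc
        t = hi
    t_comp = (
        entry_age + rng.exponential(1.0 / competing_rate)
        if competing_rate > 0
        else np.inf
    )
    y = min(t_event, t_comp, censor_age)
    delta = int(t_event <= min(t_comp, censor_age))
    return float(y), delta


def simulate_cohort(truth: SimTruth) -> tuple[Cohort, np.ndarray]:
    """Generate a cohort and its true labels (0 = reference group,
    1..K = exposure clusters); byte-identical under a fixed seed."""
    rng = np.random.default_rng(truth.seed)
    hazard = BaselineHazard(truth.lam)
    K = truth.n_clusters
    labels = np.zeros(truth.n, dtype=int)
    exposed = rng.uniform(size=truth.n) >= truth.reference_fraction
    labels[exposed] = rng.choice(K, size=int(exposed.sum()), p=truth.weights) + 1

    records = []
    for i in range(truth.n):
        entry = float(
            np.exp(truth.entry_age_logmean + truth.entry_age_logsd * rng.standard_normal())
            * DAYS_PER_YEAR
        )
        entry = min(entry, truth.censor_age_days - 1.0)
        lab = labels[i]
        if lab == 0:
            x = np.zeros(3)
            age_first = 0.0
            c = int(rng.choice(K, p=truth.weights))  # covariates only
            beta = 0.0
        else:
            c = lab - 1
            draws = np.exp(truth.mu[c] + truth.sigma[c] * rng.standard_normal(4))
            x, age_first = draws[:3], float(draws[3])
            beta = float(truth.beta[c])
        job = int(rng.choice(5, p=truth.p_job[c])) + 1
        mine = int(rng.choice(2, p=truth.p_mine[c])) + 1
        dur = int(rng.choice(4, p=truth.p_dur[c])) + 1
        y, delta = simulate_survival_time(
            entry, beta, hazard, truth.censor_age_days, truth.competing_rate, rng
        )
        records.append(
            MinerRecord(
                y=y, delta=delta, entry_age=entry,
                x_radon=float(x[0]), x_gamma=float(x[1]), x_dust=float(x[2]),
                age_first_exposure=age_first, job=job, mine=mine, duration_class=dur,
            )
        )
    return Cohort.from_records(records, labels), labels
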