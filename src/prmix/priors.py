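"""Prior specification for the profile regression mixture.

Defaults encode weakly informative choices for the risk and exposure
parameters, informative gamma priors on the piecewise baseline lung
cancer mortality rates (external French male mortality data), normal
priors on log-scale exposure means informed by the German uranium miner
cohort, and a uniform prior on the Dirichlet-process concentration.

Normal priors are parametrised as (mean, variance); gamma priors as
(shape, rate) with time in days, so e.g. G(23.7, 4.9e8) has mean
4.8e-8 events/day, a plausible pre-40 lung-cancer mortality rate.  A
``normal_dialect="sd"`` switch reads the normal entries as (mean, sd).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class PriorSpec:
    beta: tuple[float, float] = (0.0, 1e6)  # normal (mean, variance)
    mu_radon: tuple[float, float] = (-2.3, 8.08)
    mu_gamma: tuple[float, float] = (0.10, 2.25)
    mu_dust: tuple[float, float] = (1.01, 11.79)
    mu_age: tuple[float, float] = (0.0, 1e6)
    sigma_bounds: tuple[float, float] = (0.0, 100.0)  # uniform on all sigmas
    dirichlet_conc: float = 0.5  # per cell, for p_job / p_mine / p_duration
    # gamma (shape, rate), rates per day
    lam: tuple[tuple[float, float], ...] = (
        (23.7, 4.9e8),
        (35.5, 2.6e7),
        (88.1, 1.6e7),
        (29.7, 3.2e6),
    )
    alpha_bounds: tuple[float, float] = (0.3, 10.0)
    normal_dialect: str = "variance"

    def __post_init__(self) -> None:
        if self.normal_dialect not in ("variance", "sd"):
            raise ValueError("normal_dialect must be 'variance' or 'sd'")
        if self.normal_dialect == "sd":
            conv = lambda p: (p[0], p[1] ** 2)
            self.beta = conv(self.beta)
            self.mu_radon = conv(self.mu_radon)
            self.mu_gamma = conv(self.mu_gamma)
            self.mu_dust = conv(self.mu_dust)
            self.mu_age = conv(self.mu_age)
            self.normal_dialect = "variance"
        for name in ("beta", "mu_radon", "mu_gamma", "mu_dust", "mu_age"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} prior variance must be positive")
        for a, b in self.lam:
            if a <= 0 or b <= 0:
                raise ValueError("gamma prior shape and rate must be positive")
        if not self.sigma_bounds[0] < self.sigma_bounds[1]:
            raise ValueError("sigma_bounds must be ordered")
        if not self.alpha_bounds[0] < self.alpha_bounds[1]:
            raise ValueError("alpha_bounds must be ordered")
        if self.dirichlet_conc <= 0:
            raise ValueError("dirichlet_conc must be positive")

    @property
    def mu_priors(self) -> np.ndarray:
        """(4, 2) array of (mean, variance) for mu of radon/gamma/dust/age."""
        return np.array([self.mu_radon, self.mu_gamma, self.mu_dust, self.mu_age])

    @property
    def lam_shapes(self) -> np.ndarray:
        return np.array([a for a, _ in self.lam])

    @property
    def lam_rates(self) -> np.ndarray:
        return np.array([b for _, b in self.lam])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        d = dict(d)
        if "lam" in d:
            d["lam"] = tuple(tuple(p) for p in d["lam"])
        for k in ("beta", "mu_radon", "mu_gamma", "mu_dust", "mu_age",
                  "sigma_bounds", "alpha_bounds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)
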