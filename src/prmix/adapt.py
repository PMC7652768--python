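"""Adaptive random-walk proposal scaling and the MCMC schedule.

During the adaptive phase the sampler runs ``adapt_batches`` batches of
``batch_size`` iterations; after each batch every proposal block moves
its log proposal scale by ``min(0.05, batch**-0.5)`` toward its target
acceptance rate (0.40 for scalar blocks, 0.20 for vector blocks).
Scales are frozen afterwards, so the post-adaptation chain is a plain
Metropolis-within-Gibbs sampler with a fixed kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

TARGET_SCALAR = 0.40
TARGET_VECTOR = 0.20


@dataclass
class SamplerConfig:
    """Schedule and tuning knobs shared by all MCMC fitters.

    The default schedule is the full production one (100x100 adaptive
    iterations, 10,000 burn-in, 150,000 retained thinned by 20, hence
    7,500 stored draws); :meth:`smoke` gives a reduced schedule for
    quick validation runs.
    """

    adapt_batches: int = 100
    batch_size: int = 100
    burnin: int = 10_000
    n_iter: int = 150_000
    thin: int = 20
    target_scalar: float = TARGET_SCALAR
    target_vector: float = TARGET_VECTOR
    seed: int = 0
    mode: str = "PRM"  # or "RPRM"
    K: int | None = None  # RPRM only: clusters including the reference
    c_max: int = 50
    init_clusters: int = 10
    zero_policy: str = "impute_half_min"
    delayed_entry: bool = True
    alpha_init: float = 1.0
    do_label_moves: bool = True

    def __post_init__(self) -> None:
        for name in ("adapt_batches", "burnin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("batch_size", "n_iter", "thin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for t in (self.target_scalar, self.target_vector):
            if not 0 < t < 1:
                raise ValueError("acceptance targets must lie in (0, 1)")
        if self.n_iter % self.thin != 0:
            raise ValueError("thin must divide n_iter evenly")
        if self.mode not in ("PRM", "RPRM"):
            raise ValueError("mode must be 'PRM' or 'RPRM'")
        if self.mode == "RPRM":
            if self.K is None or self.K < 2:
                raise ValueError("RPRM mode needs K >= 2 (including the reference)")

    @property
    def n_exposed_components(self) -> int:
        return (self.K - 1) if self.mode == "RPRM" else self.c_max

    @property
    def n_stored(self) -> int:
        return self.n_iter // self.thin

    @classmethod
    def smoke(cls, **kw) -> "SamplerConfig":
        """Reduced schedule for tests and pilot runs."""
        base = dict(adapt_batches=10, batch_size=50, burnin=500, n_iter=5_000, thin=10)
        base.update(kw)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


def adapt_step(
    log_scales: np.ndarray, rates: np.ndarray, target: float, batch: int
) -> np.ndarray:
    """One adaptation update after a finished batch (1-based index).

    Moves each log scale by ``min(0.05, batch**-0.5)`` up when the
    empirical acceptance rate exceeds the target, down when below, and
    leaves it unchanged on an exact tie.
    """
    step = min(0.05, batch ** -0.5)
    return log_scales + step * np.sign(rates - target)


class AdaptiveScales:
    """Book-keeping for named blocks of random-walk proposal scales."""

    def __init__(self) -> None:
        self._blocks: dict[str, dict] = {}
        self.frozen = False
        self.batch = 0

    def register(self, name: str, size: int, init_scale: float, target: float) -> None:
        self._blocks[name] = {
            "log_scale": np.full(size, np.log(init_scale)),
            "target": target,
            "acc": np.zeros(size),
            "n": np.zeros(size),
            "post_acc": np.zeros(size),
            "post_n": np.zeros(size),
        }

    def __contains__(self, name: str) -> bool:
        return name in self._blocks

    def scales(self, name: str) -> np.ndarray:
        return np.exp(self._blocks[name]["log_scale"])

    def record(self, name: str, accepted: np.ndarray, attempted: np.ndarray | None = None) -> None:
        b = self._blocks[name]
        acc = np.asarray(accepted, dtype=float)
        att = np.ones_like(acc) if attempted is None else np.asarray(attempted, dtype=float)
        if self.frozen:
            b["post_acc"] += acc
            b["post_n"] += att
        else:
            b["acc"] += acc
            b["n"] += att

    def end_batch(self) -> None:
        if self.frozen:
            return
        self.batch += 1
        for b in self._blocks.values():
            with np.errstate(invalid="ignore"):
                rates = np.where(b["n"] > 0, b["acc"] / np.maximum(b["n"], 1), b["target"])
            b["log_scale"] = adapt_step(b["log_scale"], rates, b["target"], self.batch)
            b["acc"][:] = 0.0
            b["n"][:] = 0.0

    def freeze(self) -> None:
        self.frozen = True

    def acceptance_rates(self) -> dict[str, list[float]]:
        """Post-adaptation empirical acceptance rate per block element."""
        out = {}
        for name, b in self._blocks.items():
            with np.errstate(invalid="ignore"):
                r = np.where(b["post_n"] > 0, b["post_acc"] / np.maximum(b["post_n"], 1), np.nan)
            out[name] = [float(v) for v in r]
        return out
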