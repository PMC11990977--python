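"""Learning-rate policies: plain step decay, MultiStep+Warmup, Cosine+Warmup.

All policies share an optional linear warmup segment: for step ``t < W``
the rate rises linearly from ``f * base_lr`` to ``base_lr``.  After
warmup:

* ``cosine_warmup`` — single-cycle cosine annealing,
  ``eta_min + 0.5 * (base_lr - eta_min) * (1 + cos(pi * (t - W) / (T - W)))``;
* ``multistep_warmup`` — ``base_lr * g^(number of milestones <= t)``;
* ``plain`` — same step-decay formula without the warmup convention being
  assumed; with early milestones and a small decay factor it reproduces
  the failure mode where the rate collapses toward zero long before
  training ends (set ``warmup_steps=0`` for the classic configuration).

Stepping is per-iteration by default; epoch-granular schedules are just a
matter of passing epoch counts as steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ScheduleConfig", "ScheduleState", "lr_at", "schedule_trace"]

POLICIES = ("plain", "multistep_warmup", "cosine_warmup")


@dataclass
class ScheduleConfig:
    total_steps: int
    base_lr: float = 0.01
    warmup_steps: int = 500
    warmup_start_factor: float = 0.001
    eta_min: float = 0.0
    milestones: tuple[int, ...] | None = None  # default: (2T/3, 7T/8)
    decay_factor: float = 0.1
    policy: str = "cosine_warmup"

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; one of {POLICIES}")
        if not (0 < self.warmup_start_factor <= 1):
            raise ValueError("warmup_start_factor must be in (0, 1]")
        if not (0 < self.decay_factor < 1):
            raise ValueError("decay_factor must be in (0, 1)")
        if self.eta_min < 0:
            raise ValueError("eta_min must be >= 0")
        if self.warmup_steps >= self.total_steps:
            raise ValueError("warmup must end before total_steps")
        if self.milestones is None:
            # default milestones; deduplicated and kept past warmup so the
            # config stays valid for arbitrarily short runs
            candidates = {2 * self.total_steps // 3, 7 * self.total_steps // 8}
            self.milestones = tuple(sorted(
                m for m in candidates if m > self.warmup_steps))
        self.milestones = tuple(sorted(int(m) for m in self.milestones))
        if any(b <= a for a, b in zip(self.milestones, self.milestones[1:])):
            raise ValueError("milestones must be strictly increasing")
        if self.milestones and self.warmup_steps > 0 \
                and self.milestones[0] <= self.warmup_steps:
            raise ValueError("milestones must lie after warmup")


@dataclass
class ScheduleState:
    """Step counter for incremental use inside a training loop."""

    config: ScheduleConfig
    t: int = 0

    def current_lr(self) -> float:
        return lr_at(self.t, self.config)

    def step(self) -> float:
        lr = self.current_lr()
        if self.t < self.config.total_steps:
            self.t += 1
        return lr


def lr_at(t: int, cfg: ScheduleConfig) -> float:
    """Learning rate at integer step ``t`` in [0, total_steps]."""
    if t < 0 or t > cfg.total_steps:
        raise ValueError(f"step {t} outside [0, {cfg.total_steps}]")
    w = cfg.warmup_steps
    if t < w:
        frac = t / w
        return cfg.base_lr * (cfg.warmup_start_factor
                              + (1.0 - cfg.warmup_start_factor) * frac)
    if cfg.policy == "cosine_warmup":
        span = cfg.total_steps - w
        phase = (t - w) / span
        return cfg.eta_min + 0.5 * (cfg.base_lr - cfg.eta_min) \
            * (1.0 + math.cos(math.pi * phase))
    # plain and multistep share the step-decay form
    n_passed = sum(1 for m in cfg.milestones if m <= t)
    return cfg.base_lr * cfg.decay_factor ** n_passed


def schedule_trace(cfg: ScheduleConfig) -> np.ndarray:
    """The full lr series, one value per step from 0 to total_steps inclusive."""
    return np.array([lr_at(t, cfg) for t in range(cfg.total_steps + 1)])
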