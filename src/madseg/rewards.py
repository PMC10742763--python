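"""Gestalt-law reward system.

Five indicator rewards encode perceptual grouping: two continuity terms
(low trajectory curvature; shallow collision angle between opposite-sense
agents), proximity (little time spent off the edge), closure (returning
to the departure point), and local edge density. Each component
contributes either 0 or the increment ``delta_r`` per step; the total is
their weighted sum. The shipped default weights are the trained values
(0.31, 0.23, 0.15, 0.19, 0.12 for continuity-1, continuity-2, proximity,
density, closure), under which the two continuity terms account for 54%
of a fully rewarded step.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RewardConfig:
    w_c1: float = 0.31          # continuity by curvature
    w_c2: float = 0.23          # continuity by collision angle
    w_pr: float = 0.15          # proximity
    w_d: float = 0.19           # density
    w_cl: float = 0.12          # closure
    delta_r: float = 1.0        # reward increment per satisfied criterion
    s_prime: float = 0.15       # curvature threshold (1/px)
    theta_min: float = 118.0    # min collision angle (degrees)
    # a 1-px edge curve crossing an r x r window has density ~ 1/r
    # (0.04 at r = 24), so the threshold sits below that but above the
    # empty-window value 0
    d_prime: float = 0.03       # edge-density threshold
    t_cont: int = 12            # proximity horizon (steps off edge)

    def __post_init__(self):
        for name in ("w_c1", "w_c2", "w_pr", "w_d", "w_cl", "delta_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def weight_sum(self) -> float:
        return self.w_c1 + self.w_c2 + self.w_pr + self.w_d + self.w_cl


@dataclass
class RewardBreakdown:
    r_cont1: float = 0.0
    r_cont2: float = 0.0
    r_prox: float = 0.0
    r_closure: float = 0.0
    r_density: float = 0.0

    def total(self, cfg: RewardConfig) -> float:
        return (cfg.w_c1 * self.r_cont1 + cfg.w_c2 * self.r_cont2
                + cfg.w_pr * self.r_prox + cfg.w_cl * self.r_closure
                + cfg.w_d * self.r_density)


def continuity1(s_ic: float, cfg: RewardConfig) -> float:
    """Curvature continuity: reward when the windowed average absolute
    curvature does not exceed the threshold (inclusive)."""
    if s_ic < 0:
        raise ValueError("average curvature must be nonnegative")
    return cfg.delta_r if s_ic <= cfg.s_prime else 0.0


def continuity2(theta_ik: float, cfg: RewardConfig) -> float:
    """Collision continuity: reward shallow meeting angles, from the
    minimum angle (inclusive) up to head-on (180 degrees)."""
    if not (0.0 <= theta_ik <= 180.0):
        raise ValueError("collision angle must lie in [0, 180] degrees")
    return cfg.delta_r if cfg.theta_min <= theta_ik <= 180.0 else 0.0


def proximity(t_free: int, cfg: RewardConfig) -> float:
    """Proximity: reward while time off the edge stays within the
    horizon (inclusive)."""
    if t_free < 0:
        raise ValueError("t_free must be nonnegative")
    return cfg.delta_r if t_free <= cfg.t_cont else 0.0


def closure(position, departure, cfg: RewardConfig,
            closure_radius: float, traveled: float,
            already_fired: bool = False) -> float:
    """Closure: reward (once per episode) when the agent returns to a
    neighborhood of its departure point after meaningful travel."""
    import numpy as np

    if already_fired or traveled < 4.0 * closure_radius:
        return 0.0
    dist = float(np.linalg.norm(np.asarray(position, float)
                                - np.asarray(departure, float)))
    return cfg.delta_r if dist <= closure_radius else 0.0


def density(d_i: float, cfg: RewardConfig) -> float:
    """Density: reward when local edge density strictly exceeds the
    threshold."""
    if not (0.0 <= d_i <= 1.0):
        raise ValueError("edge density must lie in [0, 1]")
    return cfg.delta_r if d_i > cfg.d_prime else 0.0


def total_reward(breakdown: RewardBreakdown, cfg: RewardConfig) -> float:
    """Weighted sum of the five components."""
    return breakdown.total(cfg)
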