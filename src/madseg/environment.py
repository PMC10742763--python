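"""The partially observable multi-agent world on the edge map.

Agents are points with a heading that advance a fixed step length per
tick; the discrete action set rotates the heading by one of five
increments (0, +-22.5, +-45 degrees). An agent is in ``edge`` mode when
an edge pixel lies within the snap tolerance of its position, otherwise
``free``; time spent free beyond ``t_live`` kills it. Each agent keeps
its full path (for curvature), a memory of the last three receptive-field
crops (edge map, grayscale, agent occupancy), and can collide with
opposite-sense agents, which links the edge fragments they trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .aggregation import AggregatedFeatures, aggregate, neighbors
from .offsets import OffsetField, tangent_at_nearest
from .rewards import (RewardBreakdown, RewardConfig, closure, continuity1,
                      density, proximity)

ACTION_DELTAS_DEG = (-45.0, -22.5, 0.0, 22.5, 45.0)
N_ACTIONS = len(ACTION_DELTAS_DEG)

#: observation vector layout: mode flag, body-frame offset tangent (2),
#: windowed average curvature, normalized time free, local edge density
OBS_DIM = 6


@dataclass(frozen=True)
class EnvConfig:
    t2: int = 21                    # curvature averaging window (steps)
    t_live: int = 30                # max consecutive steps off the edge
    t_cont: int = 12                # proximity reward horizon (steps)
    collision_radius: float = 3.0   # px (2 x edge_snap_tol: catches
                                    # near-miss passes of noisy paths)
    closure_radius: float = 3.0     # px
    step_length: float = 1.0        # px per step
    edge_snap_tol: float = 1.5      # px: edge-mode distance
    receptive_field: int = 24       # r: crop size (px)
    neighbor_radius: float = 12.0   # aggregation radius (4 x collision)

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Observation:
    mode_edge: bool
    v_offset: np.ndarray        # unit offset tangent, agent body frame
    s_curvature: float          # mean |kappa| over the last t2 steps
    t_free: int
    edge_density: float

    def vector(self, t_live: int) -> np.ndarray:
        return np.array([
            1.0 if self.mode_edge else 0.0,
            self.v_offset[0], self.v_offset[1],
            self.s_curvature,
            self.t_free / max(t_live, 1),
            self.edge_density,
        ])


@dataclass
class GridMapStack:
    """Last three receptive-field crops, each with 3 channels."""

    frames: list        # three arrays of shape (3, r, r)

    def array(self) -> np.ndarray:
        return np.concatenate(self.frames, axis=0)    # (9, r, r)


@dataclass
class CollisionEvent:
    i: int
    k: int
    point: np.ndarray
    theta_ik: float             # degrees in [0, 180]
    step: int


@dataclass
class AgentState:
    position: np.ndarray
    heading: np.ndarray
    sense: str                  # "CW" or "CCW"
    mode: str = "free"
    t_free: int = 0
    departure: np.ndarray = None
    path: list = field(default_factory=list)
    alive: bool = True
    closed: bool = False
    closure_fired: bool = False
    frames: list = field(default_factory=list)
    reward_prev: float = 0.0
    reward_sum: float = 0.0
    step_rewards: list = field(default_factory=list)
    collided_with: set = field(default_factory=set)

    def traveled(self) -> float:
        return float(max(len(self.path) - 1, 0))


def average_curvature(path, t2: int) -> float:
    """Mean absolute Menger curvature over the last ``t2`` steps.

    Paths shorter than three points have no curvature sample and
    return 0; shorter histories than ``t2`` average what exists.
    """
    p = np.asarray(path, dtype=float)
    if len(p) < 3:
        return 0.0
    window = p[-(t2 + 2):]
    kappas = geometry.path_curvatures(window)
    if len(kappas) == 0:
        return 0.0
    return float(np.mean(kappas[-t2:]))


def path_tangent(path, n_fit: int = 5) -> np.ndarray:
    """Forward unit tangent of a path: least-squares slope of the last
    ``n_fit`` points regressed on the step index."""
    p = np.asarray(path, dtype=float)[-n_fit:]
    if len(p) < 2:
        return np.array([1.0, 0.0])
    t = np.arange(len(p), dtype=float)
    t = t - t.mean()
    centered = p - p.mean(axis=0)
    direction = t @ centered            # ~ cov(t, p): forward in time
    if not np.any(direction):
        direction = p[-1] - p[0]
    return geometry.unit(direction)


def detect_collisions(agents: list[AgentState], collision_radius: float,
                      step: int = 0) -> list[CollisionEvent]:
    """New CW-CCW collision events (each pair at most once per episode).

    The meeting angle is the angle between the two forward path
    tangents: 180 degrees for a head-on link, 90 for perpendicular.
    """
    events = []
    for i, a in enumerate(agents):
        if not a.alive or a.sense != "CW":
            continue
        for k, b in enumerate(agents):
            if k == i or not b.alive or b.sense != "CCW":
                continue
            if k in a.collided_with:
                continue
            d = np.linalg.norm(a.position - b.position)
            if d > collision_radius:
                continue
            ti = path_tangent(a.path)
            tk = path_tangent(b.path)
            cosang = float(np.clip(np.dot(ti, tk), -1.0, 1.0))
            theta = float(np.degrees(np.arccos(cosang)))
            point = 0.5 * (a.position + b.position)
            events.append(CollisionEvent(i=i, k=k, point=point,
                                         theta_ik=theta, step=step))
            a.collided_with.add(k)
            b.collided_with.add(i)
    return events


class MultiAgentEnv:
    """Simulation state: image, edge map, offsets, and the agent team."""

    def __init__(self, image: np.ndarray, edge_map: np.ndarray,
                 offset_field: OffsetField, config: EnvConfig | None = None,
                 reward_config: RewardConfig | None = None):
        self.config = config or EnvConfig()
        self.rewards_cfg = reward_config or RewardConfig()
        self.image = np.asarray(image, dtype=float) / 255.0
        self.edge_map = np.asarray(edge_map, dtype=bool)
        self.offset_field = offset_field
        self.shape = self.edge_map.shape
        rc = np.argwhere(self.edge_map)
        self._edge_tree = (cKDTree(rc[:, ::-1].astype(float))
                          if len(rc) else None)
        # padded integral image for O(1) window density
        e = self.edge_map.astype(np.int64)
        self._edge_integral = np.pad(e, ((1, 0), (1, 0))).cumsum(0).cumsum(1)
        self.agents: list[AgentState] = []
        self.events: list[CollisionEvent] = []
        self.step_count = 0
        self.deg_avg = 1.0
        self._occ_cache = None
        # boundary scale: arc length of the innermost guidance offset,
        # used to distinguish a full-contour closure from a small loop
        trajs = offset_field.trajectories
        self.boundary_scale = (min(trajs, key=lambda t: abs(t.level))
                               .arc_length if trajs else 0.0)

    # ------------------------------------------------------------------
    def spawn_agents(self, n_agents: int, seed: int = 0,
                     level: float = 0.0) -> list[AgentState]:
        """Place agents at equal arc intervals on an offset trajectory,
        alternating CW/CCW, headings along the local tangent."""
        if n_agents < 2:
            raise ValueError("need at least 2 agents")
        if n_agents % 2 != 0:
            raise ValueError("n_agents must be even (half CW, half CCW)")
        trajs = self.offset_field.trajectories
        traj = min(trajs, key=lambda t: abs(t.level - level))
        pts = traj.points
        tans = traj.tangents()
        s = geometry.arc_lengths(pts, closed=True)[:-1]
        total = traj.arc_length
        targets = np.arange(n_agents) * total / n_agents
        idx = np.searchsorted(s, targets).clip(0, len(pts) - 1)
        agents = []
        for j, i0 in enumerate(idx):
            sense = "CCW" if j % 2 == 0 else "CW"
            tangent = tans[i0] if sense == "CCW" else -tans[i0]
            pos = pts[i0].copy()
            agents.append(AgentState(
                position=pos, heading=geometry.unit(tangent), sense=sense,
                departure=pos.copy(), path=[pos.copy()]))
        self.agents = agents
        self.events = []
        self.step_count = 0
        self.deg_avg = max(self._mean_degree(), 1.0)
        for a in agents:
            self._refresh_mode(a)
        return agents

    def _mean_degree(self) -> float:
        pos = np.array([a.position for a in self.agents])
        alive = np.array([a.alive for a in self.agents])
        degs = [len(neighbors(pos, alive, i, self.config.neighbor_radius))
                for i in range(len(self.agents))]
        return float(np.mean(degs)) if degs else 0.0

    def _refresh_mode(self, agent: AgentState) -> None:
        if self._edge_tree is None:
            agent.mode = "free"
            return
        d, _ = self._edge_tree.query(agent.position, k=1)
        if d <= self.config.edge_snap_tol:
            agent.mode = "edge"
            agent.t_free = 0
        else:
            agent.mode = "free"

    # ------------------------------------------------------------------
    def edge_density_at(self, position) -> float:
        r = self.config.receptive_field
        half = r // 2
        cx, cy = int(round(position[0])), int(round(position[1]))
        r0, r1 = cy - half, cy - half + r
        c0, c1 = cx - half, cx - half + r
        h, w = self.shape
        r0c, r1c = np.clip([r0, r1], 0, h)
        c0c, c1c = np.clip([c0, c1], 0, w)
        if r1c <= r0c or c1c <= c0c:
            return 0.0
        ii = self._edge_integral
        count = (ii[r1c, c1c] - ii[r0c, c1c] - ii[r1c, c0c] + ii[r0c, c0c])
        return float(count) / float(r * r)

    def _crop(self, grid: np.ndarray, position) -> np.ndarray:
        r = self.config.receptive_field
        half = r // 2
        cx, cy = int(round(position[0])), int(round(position[1]))
        out = np.zeros((r, r), dtype=float)
        h, w = grid.shape
        r0, c0 = cy - half, cx - half
        rr0, rr1 = max(r0, 0), min(r0 + r, h)
        cc0, cc1 = max(c0, 0), min(c0 + r, w)
        if rr1 > rr0 and cc1 > cc0:
            out[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = grid[rr0:rr1, cc0:cc1]
        return out

    def _occupancy(self) -> np.ndarray:
        # cached per step: all observers see the same occupancy frame
        key = getattr(self, "_occ_key", None)
        if key == self.step_count and self._occ_cache is not None:
            return self._occ_cache
        occ = np.zeros(self.shape, dtype=float)
        for a in self.agents:
            if not a.alive:
                continue
            c = int(round(a.position[0]))
            r = int(round(a.position[1]))
            if 0 <= r < self.shape[0] and 0 <= c < self.shape[1]:
                occ[r, c] = 1.0
        self._occ_key = self.step_count
        self._occ_cache = occ
        return occ

    def observe(self, i: int) -> tuple[Observation, GridMapStack]:
        """Observation + memory stack for agent i; shifts the memory."""
        agent = self.agents[i]
        if not agent.alive:
            raise ValueError("cannot observe a dead agent")
        self._refresh_mode(agent)
        tangent = tangent_at_nearest(self.offset_field, agent.position,
                                     sense=agent.sense)
        # body frame: rotate world tangent by -heading angle
        hx, hy = agent.heading
        v_body = np.array([hx * tangent[0] + hy * tangent[1],
                           -hy * tangent[0] + hx * tangent[1]])
        obs = Observation(
            mode_edge=(agent.mode == "edge"),
            v_offset=geometry.unit(v_body),
            s_curvature=average_curvature(agent.path, self.config.t2),
            t_free=agent.t_free,
            edge_density=self.edge_density_at(agent.position),
        )
        occ = self._occupancy()
        frame = np.stack([
            self._crop(self.edge_map.astype(float), agent.position),
            self._crop(self.image, agent.position),
            self._crop(occ, agent.position),
        ])
        r = self.config.receptive_field
        while len(agent.frames) < 2:
            agent.frames.append(np.zeros((3, r, r)))
        agent.frames.append(frame)
        if len(agent.frames) > 3:
            agent.frames.pop(0)
        return obs, GridMapStack(frames=list(agent.frames))

    def aggregate_for(self, i: int, obs_vectors: np.ndarray
                      ) -> AggregatedFeatures:
        pos = np.array([a.position for a in self.agents])
        alive = np.array([a.alive for a in self.agents])
        idx = neighbors(pos, alive, i, self.config.neighbor_radius)
        return aggregate(obs_vectors[i], obs_vectors[idx], self.deg_avg)

    # ------------------------------------------------------------------
    def step_agent(self, i: int, action: int) -> dict:
        """Advance one agent by one action; returns a transition record
        (without the collision-continuity reward, which is added by
        ``step_all`` after all agents have moved)."""
        agent = self.agents[i]
        if not agent.alive:
            raise ValueError("cannot step a dead agent")
        cfg = self.config
        delta = np.deg2rad(ACTION_DELTAS_DEG[action])
        # actions select the step direction in the guidance frame: the
        # new heading is the local offset tangent (in the agent's
        # traversal sense) rotated by the chosen increment, so the
        # center action follows the offset family and the other actions
        # deviate toward or away from nearby edge structure
        tangent = tangent_at_nearest(self.offset_field, agent.position,
                                     sense=agent.sense)
        agent.heading = geometry.unit(geometry.rotate(tangent, delta))
        agent.position = agent.position + cfg.step_length * agent.heading
        agent.path.append(agent.position.copy())

        h, w = self.shape
        if not (0 <= agent.position[0] <= w - 1
                and 0 <= agent.position[1] <= h - 1):
            agent.position = np.clip(agent.position, [0, 0],
                                     [w - 1, h - 1])
            agent.alive = False

        self._refresh_mode(agent)
        if agent.mode == "free":
            agent.t_free += 1
            if agent.t_free > cfg.t_live:
                agent.alive = False

        rcfg = self.rewards_cfg
        s_ic = average_curvature(agent.path, cfg.t2)
        d_i = self.edge_density_at(agent.position)
        br = RewardBreakdown(
            r_cont1=continuity1(s_ic, rcfg),
            r_prox=proximity(agent.t_free, rcfg),
            r_density=density(d_i, rcfg),
        )
        r_cl = closure(agent.position, agent.departure, rcfg,
                       cfg.closure_radius, agent.traveled(),
                       already_fired=agent.closure_fired)
        if r_cl > 0:
            agent.closure_fired = True      # reward at most once
        # completion is checked independently of the one-shot reward: a
        # return to the departure neighborhood after tracing most of the
        # boundary ends the trajectory as a closed candidate; small
        # early loops do not consume the completion check
        near = (np.linalg.norm(agent.position - agent.departure)
                <= cfg.closure_radius)
        if (near and agent.alive
                and agent.traveled() >= 0.8 * self.boundary_scale):
            agent.closed = True
            agent.alive = False
        br.r_closure = r_cl
        return {"agent": i, "breakdown": br, "s_curvature": s_ic,
                "edge_density": d_i}

    def step_all(self, actions: dict[int, int]
                 ) -> tuple[dict[int, float], list[CollisionEvent]]:
        """Advance every agent in ``actions``; detect collisions; return
        total weighted rewards per agent and the new collision events."""
        records = {}
        for i, a in actions.items():
            if self.agents[i].alive:
                records[i] = self.step_agent(i, a)
        new_events = detect_collisions(self.agents,
                                       self.config.collision_radius,
                                       step=self.step_count)
        self.events.extend(new_events)
        from .rewards import continuity2

        extra = {}
        for ev in new_events:
            bonus = continuity2(ev.theta_ik, self.rewards_cfg)
            extra[ev.i] = extra.get(ev.i, 0.0) + bonus
            extra[ev.k] = extra.get(ev.k, 0.0) + bonus
        totals = {}
        for i, rec in records.items():
            br = rec["breakdown"]
            br.r_cont2 = extra.get(i, 0.0)
            total = br.total(self.rewards_cfg)
            agent = self.agents[i]
            agent.reward_prev = total
            agent.reward_sum += total
            agent.step_rewards.append(total)
            totals[i] = total
        self.step_count += 1
        return totals, new_events

    @property
    def n_alive(self) -> int:
        return sum(a.alive for a in self.agents)
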