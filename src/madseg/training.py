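"""PPO training with generalized advantage estimation and a complexity
curriculum.

One iteration collects on-policy trajectories until the total number of
transitions exceeds ``t_max``, estimates advantages by GAE, standardizes
them, then performs ``epochs_pi`` Adam epochs on the clipped surrogate
objective and ``epochs_v`` epochs on the value L2 loss (normalized by
the number of trajectories K, value targets frozen at collection time).
Phantom episodes are presented easiest complexity category first,
advancing when a moving average of episode success plateaus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvConfig, MultiAgentEnv
from .nn import Adam
from .offsets import generate_offsets
from .phantoms import CATEGORY_ORDER
from .policy import NetworkSpec, PolicyNetwork, ValueNetwork
from .rewards import RewardConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PPOConfig:
    t_max: int = 900            # transitions per collection round
    clip_eps: float = 0.2
    gamma: float = 0.99
    lam: float = 0.95
    epochs_pi: int = 40
    epochs_v: int = 40
    lr_pi: float = 2e-4
    lr_v: float = 1e-3
    minibatch: int = 256
    seed: int = 0
    standardize_advantages: bool = True

    def __post_init__(self):
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")
        if not (0 <= self.lam <= 1):
            raise ValueError("lambda must lie in [0, 1]")
        if self.clip_eps <= 0:
            raise ValueError("clip epsilon must be positive")


@dataclass
class Trajectory:
    """Per-agent episode data; ``values`` has a trailing bootstrap entry
    (0 for terminated or truncated episodes)."""

    frames: np.ndarray          # (T, C, r, r)
    extras: np.ndarray          # (T, extra_dim)
    actions: np.ndarray         # (T,)
    logp_old: np.ndarray        # (T,)
    rewards: np.ndarray         # (T,)
    values: np.ndarray          # (T + 1,)
    agent_index: int = 0

    def __len__(self) -> int:
        return len(self.actions)


@dataclass
class AdvantageEstimate:
    deltas: np.ndarray
    advantages: np.ndarray
    v_hat: np.ndarray


def compute_gae(rewards: np.ndarray, values: np.ndarray,
                gamma: float, lam: float) -> AdvantageEstimate:
    """GAE from one trajectory.

    ``values`` must carry one trailing bootstrap entry. The advantage is
    the (gamma * lambda)-weighted forward sum of the TD residuals; the
    value target adds the plain discounted reward sum to the collected
    value estimate.
    """
    r = np.asarray(rewards, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(v) != len(r) + 1:
        raise ValueError("values must have one trailing bootstrap entry")
    deltas = r + gamma * v[1:] - v[:-1]
    adv = np.empty_like(deltas)
    acc = 0.0
    for t in range(len(r) - 1, -1, -1):
        acc = deltas[t] + gamma * lam * acc
        adv[t] = acc
    returns = np.empty_like(r)
    g = 0.0
    for t in range(len(r) - 1, -1, -1):
        g = r[t] + gamma * g
        returns[t] = g
    v_hat = v[:-1] + returns
    return AdvantageEstimate(deltas=deltas, advantages=adv, v_hat=v_hat)


def surrogate_loss(logp_new: np.ndarray, logp_old: np.ndarray,
                   advantages: np.ndarray, clip_eps: float) -> float:
    """Clipped PPO surrogate (the maximized objective), minibatch mean."""
    with np.errstate(over="ignore"):
        ratio = np.exp(logp_new - logp_old)
    if not np.isfinite(ratio).all():
        raise ValueError("non-finite probability ratios")
    unclipped = ratio * advantages
    clipped = np.clip(ratio, 1.0 - clip_eps, 1.0 + clip_eps) * advantages
    return float(np.mean(np.minimum(unclipped, clipped)))


def value_loss(v_pred: np.ndarray, v_hat: np.ndarray, k: int) -> float:
    """L2 value loss summed over transitions, normalized by the number
    of trajectories K (not by the transition count)."""
    if v_pred.shape != v_hat.shape:
        raise ValueError("shape mismatch")
    return float(np.sum((v_pred - v_hat) ** 2) / k)


# ----------------------------------------------------------------------
# episode sources

class PhantomEpisodeSource:
    """Runs multi-agent episodes on phantoms of one or more categories."""

    def __init__(self, phantoms_by_cat: dict[str, list], n_agents: int = 16,
                 env_config: EnvConfig | None = None,
                 reward_config: RewardConfig | None = None,
                 step_cap: int | None = None):
        self.phantoms_by_cat = phantoms_by_cat
        self.n_agents = n_agents
        self.env_config = env_config or EnvConfig()
        self.reward_config = reward_config or RewardConfig()
        self.step_cap = step_cap
        self.category = next(iter(phantoms_by_cat))
        self._cursor = 0
        self._field_cache: dict[int, object] = {}

    def _next_phantom(self):
        items = self.phantoms_by_cat[self.category]
        ph = items[self._cursor % len(items)]
        self._cursor += 1
        return ph

    def offsets_for(self, phantom):
        key = id(phantom)
        if key not in self._field_cache:
            self._field_cache[key] = generate_offsets(phantom.gt_contour)
        return self._field_cache[key]

    def __call__(self, policy_net, value_net, rng, budget=None):
        ph = self._next_phantom()
        field = self.offsets_for(ph)
        env = MultiAgentEnv(ph.image, ph.edge_map, field,
                            self.env_config, self.reward_config)
        env.spawn_agents(self.n_agents,
                         seed=int(rng.integers(2 ** 31)))
        cap = self.step_cap
        if cap is None:
            boundary_len = field.trajectories[0].arc_length
            cap = int(4 * boundary_len / self.env_config.step_length)
        trajs, env = rollout_episode(env, policy_net, value_net, rng, cap,
                                     max_transitions=budget)
        n = len(env.agents)
        n_candidate = sum(1 for a in env.agents
                          if a.closed or a.collided_with)
        info = {"success": n_candidate / n,
                "closed": sum(a.closed for a in env.agents) / n,
                "category": self.category}
        return trajs, info


def rollout_episode(env: MultiAgentEnv, policy_net: PolicyNetwork,
                    value_net: ValueNetwork | None,
                    rng: np.random.Generator, step_cap: int,
                    max_transitions: int | None = None):
    """Run one episode with batched policy forwards; returns per-agent
    trajectories and the finished environment.

    ``max_transitions`` truncates collection once the total stored
    transition count crosses it (the per-round data budget).
    """
    t_live = env.config.t_live
    store = {i: {"frames": [], "extras": [], "actions": [], "logp": [],
                 "rewards": [], "values": []}
             for i in range(len(env.agents))}
    n_stored = 0
    for _ in range(step_cap):
        alive = [i for i, a in enumerate(env.agents) if a.alive]
        if not alive:
            break
        if max_transitions is not None and n_stored > max_transitions:
            break
        obs_pairs = {i: env.observe(i) for i in alive}
        obs_vec_all = np.zeros((len(env.agents),
                                obs_pairs[alive[0]][0].vector(t_live).size))
        for i in alive:
            obs_vec_all[i] = obs_pairs[i][0].vector(t_live)
        frames = np.stack([obs_pairs[i][1].array() for i in alive])
        extras = []
        for i in alive:
            agg = env.aggregate_for(i, obs_vec_all)
            extras.append(np.concatenate([
                obs_vec_all[i], agg.vector, [float(agg.neighbor_count)],
                [env.agents[i].reward_prev]]))
        extras = np.asarray(extras)
        actions, logp = policy_net.sample(frames, extras, rng)
        if value_net is not None:
            vals, _ = value_net.values(frames, extras)
        else:
            vals = np.zeros(len(alive))
        totals, _ = env.step_all(dict(zip(alive, actions)))
        for j, i in enumerate(alive):
            st = store[i]
            st["frames"].append(frames[j])
            st["extras"].append(extras[j])
            st["actions"].append(int(actions[j]))
            st["logp"].append(float(logp[j]))
            st["rewards"].append(totals.get(i, 0.0))
            st["values"].append(float(vals[j]))
            n_stored += 1
    trajs = []
    for i, st in store.items():
        if not st["actions"]:
            continue
        trajs.append(Trajectory(
            frames=np.asarray(st["frames"]),
            extras=np.asarray(st["extras"]),
            actions=np.asarray(st["actions"], dtype=int),
            logp_old=np.asarray(st["logp"]),
            rewards=np.asarray(st["rewards"]),
            values=np.concatenate([st["values"], [0.0]]),  # terminal boot
            agent_index=i,
        ))
    return trajs, env


class BanditEpisodeSource:
    """One-agent corridor: the same observation every step and a single
    always-rewarded action. The smallest environment in which policy
    learning is observable end to end."""

    def __init__(self, spec: NetworkSpec, optimal_action: int = 2,
                 episode_len: int = 16):
        self.spec = spec
        self.optimal_action = optimal_action
        self.episode_len = episode_len

    def _inputs(self, t: int):
        r = self.spec.receptive_field
        frames = np.zeros((t, self.spec.in_channels, r, r))
        extras = np.zeros((t, self.spec.extra_dim))
        return frames, extras

    def __call__(self, policy_net, value_net, rng, budget=None):
        t = self.episode_len
        frames, extras = self._inputs(1)
        probs, _, _ = policy_net.distribution(frames, extras)
        p = probs[0]
        actions = rng.choice(self.spec.n_actions, size=t, p=p)
        logp = np.log(p[actions])
        rewards = (actions == self.optimal_action).astype(float)
        if value_net is not None:
            v0 = value_net.values(*self._inputs(1))[0][0]
        else:
            v0 = 0.0
        frames_t, extras_t = self._inputs(t)
        traj = Trajectory(frames=frames_t, extras=extras_t, actions=actions,
                          logp_old=logp, rewards=rewards,
                          values=np.concatenate([np.full(t, v0), [0.0]]))
        info = {"success": float(rewards.mean()),
                "optimal_prob": float(p[self.optimal_action])}
        return [traj], info


# ----------------------------------------------------------------------
# trainer

def _concat(trajs: list[Trajectory], key: str) -> np.ndarray:
    return np.concatenate([getattr(t, key) for t in trajs])


class PPOTrainer:
    """Algorithm driver: collect, estimate advantages, update both nets."""

    def __init__(self, policy_net: PolicyNetwork, value_net: ValueNetwork,
                 config: PPOConfig | None = None):
        self.policy = policy_net
        self.value = value_net
        self.cfg = config or PPOConfig()
        self.adam_pi = Adam(self.cfg.lr_pi)
        self.adam_v = Adam(self.cfg.lr_v)
        self.rng = np.random.default_rng(self.cfg.seed)
        self.logbook: list[dict] = []

    # -- collection ----------------------------------------------------
    def collect(self, source) -> tuple[list[Trajectory], list[dict]]:
        trajs: list[Trajectory] = []
        infos: list[dict] = []
        while sum(len(t) for t in trajs) <= self.cfg.t_max:
            budget = self.cfg.t_max - sum(len(t) for t in trajs)
            new, info = source(self.policy, self.value, self.rng,
                               budget=budget)
            trajs.extend(new)
            infos.append(info)
            if not new:
                break
        return trajs, infos

    # -- updates -------------------------------------------------------
    def _policy_update(self, frames, extras, actions, logp_old, adv) -> float:
        cfg = self.cfg
        n = len(actions)
        first_loss = None
        for _ in range(cfg.epochs_pi):
            order = self.rng.permutation(n)
            for lo in range(0, n, cfg.minibatch):
                idx = order[lo:lo + cfg.minibatch]
                logp_all, s, cache = self.policy.log_probs(frames[idx],
                                                           extras[idx])
                logp_new = logp_all[np.arange(len(idx)), actions[idx]]
                ratio = np.exp(logp_new - logp_old[idx])
                if first_loss is None:
                    first_loss = surrogate_loss(logp_new, logp_old[idx],
                                                adv[idx], cfg.clip_eps)
                unclipped = ratio * adv[idx]
                clipped = np.clip(ratio, 1 - cfg.clip_eps,
                                  1 + cfg.clip_eps) * adv[idx]
                active = unclipped <= clipped
                # ascend the surrogate: minimize its negative
                weights = np.where(active, ratio * adv[idx], 0.0) / len(idx)
                dz = self.policy.grad_logits_for_logp(s, actions[idx],
                                                      -weights)
                grads = self.policy.backward(cache, dz)
                self._check_finite(grads, "policy")
                self.adam_pi.step(self.policy.params, grads)
        return first_loss if first_loss is not None else 0.0

    def _value_update(self, frames, extras, v_hat, k: int) -> float:
        cfg = self.cfg
        n = len(v_hat)
        first_loss = None
        for _ in range(cfg.epochs_v):
            order = self.rng.permutation(n)
            for lo in range(0, n, cfg.minibatch):
                idx = order[lo:lo + cfg.minibatch]
                z, cache = self.value.forward(frames[idx], extras[idx])
                v = z[:, 0]
                if first_loss is None:
                    first_loss = value_loss(v, v_hat[idx], k) * n / len(idx)
                dz = (2.0 * (v - v_hat[idx]) / k)[:, None]
                grads = self.value.backward(cache, dz)
                self._check_finite(grads, "value")
                self.adam_v.step(self.value.params, grads)
        return first_loss if first_loss is not None else 0.0

    @staticmethod
    def _check_finite(grads: dict, which: str) -> None:
        for k, g in grads.items():
            if not np.isfinite(g).all():
                raise RuntimeError(
                    f"non-finite gradient in {which} network ({k}); "
                    f"aborting with diagnostic: "
                    f"max |g| = {np.nanmax(np.abs(g))}")

    # -- one iteration -------------------------------------------------
    def iteration(self, source) -> dict:
        cfg = self.cfg
        trajs, infos = self.collect(source)
        ests = [compute_gae(t.rewards, t.values, cfg.gamma, cfg.lam)
                for t in trajs]
        adv = np.concatenate([e.advantages for e in ests])
        v_hat = np.concatenate([e.v_hat for e in ests])
        if cfg.standardize_advantages:
            adv = (adv - adv.mean()) / (adv.std() + 1e-8)
        frames = _concat(trajs, "frames")
        extras = _concat(trajs, "extras")
        actions = _concat(trajs, "actions")
        logp_old = _concat(trajs, "logp_old")
        l_pi = self._policy_update(frames, extras, actions, logp_old, adv)
        l_v = self._value_update(frames, extras, v_hat, k=len(trajs))
        entry = {
            "iteration": len(self.logbook),
            "n_transitions": len(actions),
            "n_trajectories": len(trajs),
            "surrogate_loss": l_pi,
            "value_loss": l_v,
            "mean_reward": float(_concat(trajs, "rewards").mean()),
            "success": float(np.mean([i.get("success", 0.0)
                                      for i in infos])),
        }
        entry.update({k: v for k, v in infos[-1].items()
                      if k not in entry and np.isscalar(v)})
        self.logbook.append(entry)
        return entry

    def train(self, source, iterations: int,
              stop_when: "callable | None" = None) -> list[dict]:
        for _ in range(iterations):
            entry = self.iteration(source)
            if stop_when is not None and stop_when(entry):
                break
        return self.logbook


# ----------------------------------------------------------------------
# curriculum

def curriculum_schedule(logbook: list[dict],
                        order: tuple = CATEGORY_ORDER,
                        window: int = 20, rel_tol: float = 0.02) -> str:
    """Next category to train on.

    Categories are visited easiest first (fewest tough letters, tougher
    letters in later slots first). The current category is advanced when
    the moving average of episode success over the last ``window``
    iterations changes by less than ``rel_tol`` relative to the previous
    window's average.
    """
    if not logbook:
        return order[0]
    current = logbook[-1].get("category", order[0])
    pos = order.index(current)
    recent = [e["success"] for e in logbook if e.get("category") == current]
    if len(recent) < 2 * window:
        return current
    ma_now = float(np.mean(recent[-window:]))
    ma_prev = float(np.mean(recent[-2 * window:-window]))
    denom = max(abs(ma_prev), 1e-9)
    if abs(ma_now - ma_prev) / denom < rel_tol and pos + 1 < len(order):
        return order[pos + 1]
    return current


def train_on_corpus(corpus, policy_net: PolicyNetwork,
                    value_net: ValueNetwork,
                    ppo_config: PPOConfig | None = None,
                    env_config: EnvConfig | None = None,
                    reward_config: RewardConfig | None = None,
                    n_agents: int = 16, iterations: int = 100,
                    step_cap: int | None = None,
                    curriculum_window: int = 20) -> list[dict]:
    """Curriculum training over a labeled phantom corpus."""
    by_cat: dict[str, list] = {}
    for ph, code in corpus:
        by_cat.setdefault(code, []).append(ph)
    order = tuple(c for c in CATEGORY_ORDER if c in by_cat)
    source = PhantomEpisodeSource(by_cat, n_agents=n_agents,
                                  env_config=env_config,
                                  reward_config=reward_config,
                                  step_cap=step_cap)
    trainer = PPOTrainer(policy_net, value_net, ppo_config)
    source.category = order[0]
    for _ in range(iterations):
        trainer.iteration(source)
        source.category = curriculum_schedule(
            trainer.logbook, order=order, window=curriculum_window)
    return trainer.logbook
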