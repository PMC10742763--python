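"""End-to-end segmentation: run agents, assemble the final contour.

Successful agent trajectories — those that closed on themselves or took
part in a CW/CCW collision — are boundary candidates. Collision events
link candidate paths into chains; a chain that closes becomes a contour
proposal, scored by its accumulated weighted reward per unit length (the
reward doubles as a boundary-saliency measure). The winning chain is
smoothed by a periodic cubic spline and rasterized. If no chain closes,
the single best candidate is closed by spline interpolation across its
endpoint gap and flagged low confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .environment import CollisionEvent, EnvConfig, MultiAgentEnv
from .metrics import MetricsReport, evaluate_contours
from .offsets import OffsetField, _fit_periodic_spline, generate_offsets
from .preprocessing import EdgeMap, attention_pipeline, detect_edges
from .rewards import RewardConfig
from .training import rollout_episode

log = logging.getLogger(__name__)


@dataclass
class Candidate:
    agent_index: int
    path: np.ndarray                # (N, 2)
    step_rewards: np.ndarray        # (N - 1,)
    closed: bool


@dataclass
class SegmentationResult:
    contour: np.ndarray
    mask: np.ndarray
    candidate_trajectories: list[Candidate]
    provenance: dict = field(default_factory=dict)
    low_confidence: bool = False


class NoCandidatesError(RuntimeError):
    pass


def collect_candidates(env: MultiAgentEnv) -> list[Candidate]:
    """Agents that closed or participated in a CW-CCW collision."""
    out = []
    for i, a in enumerate(env.agents):
        if not (a.closed or a.collided_with):
            continue
        out.append(Candidate(agent_index=i,
                             path=np.asarray(a.path, dtype=float),
                             step_rewards=np.asarray(a.step_rewards),
                             closed=a.closed))
    return out


def run_episode(phantom_or_inputs, policy_net, value_net=None,
                env_config: EnvConfig | None = None,
                reward_config: RewardConfig | None = None,
                offset_field: OffsetField | None = None,
                n_agents: int = 16, seed: int = 0,
                step_cap: int | None = None):
    """Run one policy-driven episode; returns (env, candidates).

    ``phantom_or_inputs`` is either a Phantom or an ``(image, edge_map)``
    pair; the offset field defaults to offsets of the phantom ground
    truth (for phantoms) or must be supplied.
    """
    env_config = env_config or EnvConfig()
    if hasattr(phantom_or_inputs, "edge_map"):
        ph = phantom_or_inputs
        image, edges = ph.image, ph.edge_map
        if offset_field is None:
            offset_field = generate_offsets(ph.gt_contour)
    else:
        image, edges = phantom_or_inputs
        if offset_field is None:
            raise ValueError("offset_field required for raw image input")
    env = MultiAgentEnv(image, edges, offset_field, env_config,
                        reward_config)
    env.spawn_agents(n_agents, seed=seed)
    if step_cap is None:
        boundary_len = offset_field.trajectories[0].arc_length
        step_cap = int(4 * boundary_len / env_config.step_length)
    rng = np.random.default_rng(seed)
    rollout_episode(env, policy_net, value_net, rng, step_cap)
    candidates = collect_candidates(env)
    if not candidates:
        log.warning("episode produced no candidate trajectories")
    return env, candidates


# ----------------------------------------------------------------------
# chain assembly

def _event_indices(events: list[CollisionEvent], candidates):
    """Map agent index -> list of (event id, path index at collision)."""
    by_agent: dict[int, list[tuple[int, int]]] = {}
    idx_of = {c.agent_index: c for c in candidates}
    for eid, ev in enumerate(events):
        for who in (ev.i, ev.k):
            if who not in idx_of:
                continue
            path_idx = min(ev.step + 1, len(idx_of[who].path) - 1)
            by_agent.setdefault(who, []).append((eid, path_idx))
    for lst in by_agent.values():
        lst.sort(key=lambda t: t[1])
    return by_agent


def _cycles_of(multi_edges: list[tuple[int, int, dict]]):
    """Closed chains in the event graph: 2-cycles from parallel edges
    plus simple cycles from the cycle basis."""
    import networkx as nx

    g = nx.MultiGraph()
    for u, v, data in multi_edges:
        g.add_edge(u, v, **data)
    cycles = []
    seen_pairs = set()
    for u, v in g.edges():
        if u == v or (u, v) in seen_pairs or (v, u) in seen_pairs:
            continue
        seen_pairs.add((u, v))
        keys = list(g[u][v])
        if len(keys) >= 2:
            cycles.append([g[u][v][keys[0]], g[u][v][keys[1]]])
    simple = nx.Graph(g)
    for cyc in nx.cycle_basis(simple):
        if len(cyc) < 3:
            continue
        segs = []
        ok = True
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            if not g.has_edge(a, b):
                ok = False
                break
            segs.append(next(iter(g[a][b].values())))
        if ok:
            cycles.append(segs)
    return cycles


def _chain_points(segs: list[dict], candidates_by_agent) -> np.ndarray:
    """Concatenate path segments head-to-tail into one closed polyline."""
    pieces = []
    for seg in segs:
        path = candidates_by_agent[seg["agent"]].path
        a, b = sorted((seg["ia"], seg["ib"]))
        pieces.append(path[a:b + 1])
    ordered = [pieces[0]]
    for nxt in pieces[1:]:
        tail = ordered[-1][-1]
        if np.linalg.norm(nxt[0] - tail) > np.linalg.norm(nxt[-1] - tail):
            nxt = nxt[::-1]
        ordered.append(nxt)
    # orient the first piece to meet the second
    if len(ordered) > 1:
        d_keep = np.linalg.norm(ordered[0][-1] - ordered[1][0])
        d_flip = np.linalg.norm(ordered[0][0] - ordered[1][0])
        if d_flip < d_keep:
            ordered[0] = ordered[0][::-1]
    return np.vstack(ordered)


def _smooth_closed(points: np.ndarray, n_out: int = 400) -> np.ndarray:
    from scipy import interpolate as si

    pts = geometry.resample_closed(points, spacing=1.5)
    if len(pts) < 8:
        raise ValueError("chain too short")
    tck = _fit_periodic_spline(pts, smooth=1.0 * len(pts))
    u = np.linspace(0.0, 1.0, n_out, endpoint=False)
    x, y = si.splev(u, tck)
    return np.column_stack([x, y])


def _longest_open_chain(multi_edges, by_agent):
    """Approximate longest path through the event graph (double-BFS tree
    heuristic), returned as concatenated path points, or None."""
    import networkx as nx

    if not multi_edges:
        return None
    g = nx.Graph()
    for u, v, data in multi_edges:
        if not g.has_edge(u, v):
            g.add_edge(u, v, seg=data)
    best_pts = None
    best_len = 0.0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        start = next(iter(comp))
        far = max(nx.single_source_shortest_path(sub, start).items(),
                  key=lambda kv: len(kv[1]))[0]
        paths = nx.single_source_shortest_path(sub, far)
        end = max(paths.items(), key=lambda kv: len(kv[1]))[0]
        nodes = paths[end]
        segs = [sub[a][b]["seg"] for a, b in zip(nodes, nodes[1:])]
        if not segs:
            continue
        try:
            pts = _chain_points(segs, by_agent)
        except Exception:
            continue
        length = geometry.polyline_length(pts, closed=False)
        if length > best_len:
            best_len, best_pts = length, pts
    return best_pts


def assemble_contour(candidates: list[Candidate],
                     events: list[CollisionEvent],
                     env_config: EnvConfig,
                     shape: tuple[int, int],
                     min_length: float = 0.0) -> SegmentationResult:
    """Build the final closed contour from candidate trajectories.

    ``min_length`` filters out chains much shorter than the expected
    boundary scale (callers pass half the innermost offset arc length):
    the reward-per-length saliency score would otherwise prefer short
    dense loops over full-boundary chains.
    """
    if not candidates:
        raise NoCandidatesError("no candidate trajectories")
    by_agent = {c.agent_index: c for c in candidates}
    ev_idx = _event_indices(events, candidates)

    proposals = []      # (score, length, chain points, n segments, agent)

    # self-closed single trajectories
    for c in candidates:
        if c.closed and len(c.path) > 8:
            length = geometry.polyline_length(c.path, closed=True)
            score = float(c.step_rewards.sum()) / max(length, 1.0)
            proposals.append((score, length, c.path, 1, c.agent_index))

    # collision-linked chains: edges connect consecutive events on a path
    multi_edges = []
    for agent, lst in ev_idx.items():
        for (e1, i1), (e2, i2) in zip(lst, lst[1:]):
            multi_edges.append((e1, e2, {"agent": agent, "ia": i1,
                                         "ib": i2}))
    for cyc in _cycles_of(multi_edges):
        try:
            pts = _chain_points(cyc, by_agent)
        except Exception:
            continue
        if len(pts) < 8:
            continue
        length = geometry.polyline_length(pts, closed=True)
        score = sum(by_agent[s["agent"]].step_rewards[
            min(s["ia"], s["ib"]):max(s["ia"], s["ib"])].sum()
            for s in cyc) / max(length, 1.0)
        proposals.append((score, length,
                          pts, len(cyc), min(s["agent"] for s in cyc)))

    def _finalize(points):
        contour = _smooth_closed(points)
        if not geometry.polyline_is_simple(contour):
            raise ValueError("self-intersecting contour")
        return contour

    low_confidence = False
    contour = None
    qualified = sorted((p for p in proposals if p[1] >= min_length),
                       key=lambda p: (-p[0], -p[1], p[4]))
    for prop in qualified:
        try:
            contour = _finalize(prop[2])
            break
        except Exception:
            continue
    if contour is None:
        # no closed chain at boundary scale: longest open chain through
        # the collision graph, closed by the periodic spline fit
        low_confidence = True
        chain_pts = _longest_open_chain(multi_edges, by_agent)
        if chain_pts is None:
            # last resort: the single best candidate path
            best = max(candidates,
                       key=lambda c: (len(c.path),
                                      c.step_rewards.sum()
                                      / max(len(c.path), 1)))
            chain_pts = best.path
        if len(chain_pts) < 8:
            raise NoCandidatesError("candidates too short to assemble")
        try:
            contour = _finalize(chain_pts)
        except Exception:
            try:
                contour = _finalize(
                    geometry.resample_closed(chain_pts, spacing=3.0))
            except Exception:
                from scipy.spatial import ConvexHull

                hull = ConvexHull(chain_pts)
                contour = _smooth_closed(chain_pts[hull.vertices])
    mask = geometry.fill_contour(contour, shape)
    return SegmentationResult(contour=contour, mask=mask,
                              candidate_trajectories=candidates,
                              low_confidence=low_confidence)


# ----------------------------------------------------------------------

def segment(phantom_or_image, policy_net, value_net=None,
            env_config: EnvConfig | None = None,
            reward_config: RewardConfig | None = None,
            n_agents: int = 16, seed: int = 0,
            guidance: str = "attention",
            gt_contour=None, gt_mask=None
            ) -> tuple[SegmentationResult, MetricsReport | None]:
    """Full pipeline on a phantom or raw grayscale image.

    ``guidance`` selects where the offset family comes from: the
    attention mask (the deployable route, default) or the phantom ground
    truth (``"ground_truth"``, for controlled experiments). Phantoms use
    their synthetic edge map; raw images run the edge detector.
    """
    env_config = env_config or EnvConfig()
    is_phantom = hasattr(phantom_or_image, "edge_map")
    if is_phantom:
        ph = phantom_or_image
        gt_contour = ph.gt_contour if gt_contour is None else gt_contour
        gt_mask = ph.gt_mask if gt_mask is None else gt_mask
        if guidance == "ground_truth":
            offset_field = generate_offsets(ph.gt_contour)
        else:
            att = attention_pipeline(ph.image)
            offset_field = generate_offsets(att.contour)
        inputs = (ph.image, ph.edge_map)
    else:
        image = np.asarray(phantom_or_image)
        att = attention_pipeline(image)
        edges: EdgeMap = detect_edges(image)
        offset_field = generate_offsets(att.contour)
        inputs = (image, edges.edges)
    env, candidates = run_episode(
        inputs, policy_net, value_net, env_config, reward_config,
        offset_field=offset_field, n_agents=n_agents, seed=seed)
    result = assemble_contour(candidates, env.events, env_config, env.shape,
                              min_length=0.7 * env.boundary_scale)
    result.provenance = {"seed": seed, "n_agents": n_agents}
    report = None
    if gt_contour is not None and gt_mask is not None:
        report = evaluate_contours(gt_contour, result.contour,
                                   gt_mask, result.mask)
    return result, report
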