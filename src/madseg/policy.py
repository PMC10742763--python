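"""Policy and value networks.

Both networks share one architecture with disjoint parameters: three
3x3 convolution layers (32, 64, 128 filters, stride 1), each followed by
2x2 max pooling, applied to the stacked memory frames (3 time steps x 3
channels); the raw convolutional features are projected by a linear
flattening stage to a 256-vector (for the 24 px receptive field the raw
flatten size is 128*3*3 = 1152, so the projection honors both the
printed layer counts and the 256-dimensional feature contract), then
concatenated with the observation vector, the aggregated neighbor
features and the previous reward, passed through two dense layers of 128
rectifier units, and read out by a head of five sigmoid units (policy;
renormalized to a categorical distribution over the heading increments)
or one linear unit (value).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .aggregation import AggregatedFeatures
from .environment import N_ACTIONS, OBS_DIM


@dataclass(frozen=True)
class NetworkSpec:
    receptive_field: int = 24           # must be divisible by 8
    in_channels: int = 9                # 3 frames x 3 channels
    conv_channels: tuple = (32, 64, 128)
    conv_feature_dim: int = 256
    hidden: tuple = (128, 128)
    n_actions: int = N_ACTIONS
    extra_dim: int = (OBS_DIM           # observation vector
                      + AggregatedFeatures.width(OBS_DIM) + 1  # + deg
                      + 1)              # + previous reward

    def __post_init__(self):
        if self.receptive_field % 8 != 0:
            raise ValueError("receptive_field must be divisible by 8 "
                             "(three 2x pooling stages)")

    @property
    def raw_flat_dim(self) -> int:
        side = self.receptive_field // 8
        return self.conv_channels[-1] * side * side

    def spec_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()


class _BackboneNet:
    """Shared forward/backward machinery; heads differ by output size."""

    def __init__(self, spec: NetworkSpec, n_out: int, seed: int):
        self.spec = spec
        self.n_out = n_out
        rng = np.random.default_rng(seed)
        c1, c2, c3 = spec.conv_channels
        p = {}
        p["conv1_w"], p["conv1_b"] = nn.he_conv(rng, c1, spec.in_channels)
        p["conv2_w"], p["conv2_b"] = nn.he_conv(rng, c2, c1)
        p["conv3_w"], p["conv3_b"] = nn.he_conv(rng, c3, c2)
        p["proj_w"], p["proj_b"] = nn.orthogonal(
            rng, spec.conv_feature_dim, self.spec.raw_flat_dim, gain=1.0)
        in1 = spec.conv_feature_dim + spec.extra_dim
        p["fc1_w"], p["fc1_b"] = nn.orthogonal(rng, spec.hidden[0], in1)
        p["fc2_w"], p["fc2_b"] = nn.orthogonal(rng, spec.hidden[1],
                                               spec.hidden[0])
        # small positive bias keeps rectifier units active for sparse or
        # all-zero observations, so gradient reaches every layer
        p["fc1_b"] += 0.1
        p["fc2_b"] += 0.1
        p["head_w"], p["head_b"] = nn.orthogonal(rng, n_out, spec.hidden[1],
                                                 gain=0.01)
        self.params = p

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, frames: np.ndarray, extras: np.ndarray):
        """frames (B, C, r, r), extras (B, extra_dim) -> logits (B, n_out)."""
        if not (np.isfinite(frames).all() and np.isfinite(extras).all()):
            raise ValueError("non-finite network inputs")
        p = self.params
        cache = {}
        h, cache["c1"] = nn.conv3x3_forward(frames, p["conv1_w"], p["conv1_b"])
        h, cache["r1"] = nn.relu_forward(h)
        h, cache["p1"] = nn.maxpool2_forward(h)
        h, cache["c2"] = nn.conv3x3_forward(h, p["conv2_w"], p["conv2_b"])
        h, cache["r2"] = nn.relu_forward(h)
        h, cache["p2"] = nn.maxpool2_forward(h)
        h, cache["c3"] = nn.conv3x3_forward(h, p["conv3_w"], p["conv3_b"])
        h, cache["r3"] = nn.relu_forward(h)
        h, cache["p3"] = nn.maxpool2_forward(h)
        flat = h.reshape(h.shape[0], -1)
        feat, cache["proj_x"] = nn.dense_forward(flat, p["proj_w"],
                                                 p["proj_b"])
        cache["pool_shape"] = h.shape
        z = np.concatenate([feat, extras], axis=1)
        cache["extras_dim"] = extras.shape[1]
        h1, cache["fc1_x"] = nn.dense_forward(z, p["fc1_w"], p["fc1_b"])
        h1, cache["fr1"] = nn.relu_forward(h1)
        h2, cache["fc2_x"] = nn.dense_forward(h1, p["fc2_w"], p["fc2_b"])
        h2, cache["fr2"] = nn.relu_forward(h2)
        out, cache["head_x"] = nn.dense_forward(h2, p["head_w"], p["head_b"])
        return out, cache

    def backward(self, cache, dout: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        g = {}
        g["head_w"], g["head_b"], dh2 = nn.dense_backward(
            dout, cache["head_x"], p["head_w"])
        dh2 = nn.relu_backward(dh2, cache["fr2"])
        g["fc2_w"], g["fc2_b"], dh1 = nn.dense_backward(
            dh2, cache["fc2_x"], p["fc2_w"])
        dh1 = nn.relu_backward(dh1, cache["fr1"])
        g["fc1_w"], g["fc1_b"], dz = nn.dense_backward(
            dh1, cache["fc1_x"], p["fc1_w"])
        dfeat = dz[:, :-cache["extras_dim"]]
        g["proj_w"], g["proj_b"], dflat = nn.dense_backward(
            dfeat, cache["proj_x"], p["proj_w"])
        dh = dflat.reshape(cache["pool_shape"])
        dh = nn.maxpool2_backward(dh, cache["p3"])
        dh = nn.relu_backward(dh, cache["r3"])
        g["conv3_w"], g["conv3_b"], dmat = nn.conv3x3_backward(dh, cache["c3"])
        dh = nn.conv3x3_input_grad(dmat, p["conv3_w"], cache["c3"][1])
        dh = nn.maxpool2_backward(dh, cache["p2"])
        dh = nn.relu_backward(dh, cache["r2"])
        g["conv2_w"], g["conv2_b"], dmat = nn.conv3x3_backward(dh, cache["c2"])
        dh = nn.conv3x3_input_grad(dmat, p["conv2_w"], cache["c2"][1])
        dh = nn.maxpool2_backward(dh, cache["p1"])
        dh = nn.relu_backward(dh, cache["r1"])
        g["conv1_w"], g["conv1_b"], _ = nn.conv3x3_backward(dh, cache["c1"])
        return g

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        np.savez(path, _spec=json.dumps(asdict(self.spec)),
                 _n_out=self.n_out, **self.params)

    def load(self, path: str | Path) -> None:
        data = np.load(path, allow_pickle=False)
        stored = json.loads(str(data["_spec"]))
        mine = asdict(self.spec)
        mine = {k: list(v) if isinstance(v, tuple) else v
                for k, v in mine.items()}
        if stored != mine or int(data["_n_out"]) != self.n_out:
            raise ValueError("checkpoint architecture mismatch")
        for k in self.params:
            self.params[k] = data[k].copy()


class PolicyNetwork(_BackboneNet):
    """Sigmoid-head policy; outputs a categorical action distribution.

    The head biases start at a straight-ahead motion prior: agents spawn
    aligned with the offset tangent, so a policy that initially keeps
    its heading traces the guidance curve and collects the continuity
    reward from the first iteration; training refines the corrections
    instead of having to discover locomotion from an undirected walk.
    """

    #: initial head biases per heading increment (-45..+45 degrees)
    ACTION_PRIOR_LOGITS = (-5.0, -2.5, 3.0, -2.5, -5.0)

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0,
                 action_prior: tuple | None = None):
        spec = spec or NetworkSpec()
        super().__init__(spec, n_out=spec.n_actions, seed=seed)
        prior = self.ACTION_PRIOR_LOGITS if action_prior is None \
            else action_prior
        if len(prior) == spec.n_actions:
            self.params["head_b"] += np.asarray(prior, dtype=float)

    def distribution(self, frames, extras):
        """(probs, sigmoids, cache): 5 sigmoid outputs normalized to a
        probability vector."""
        z, cache = self.forward(frames, extras)
        s = nn.sigmoid(z)
        probs = s / s.sum(axis=1, keepdims=True)
        return probs, s, cache

    def log_probs(self, frames, extras):
        probs, s, cache = self.distribution(frames, extras)
        return np.log(np.maximum(probs, 1e-300)), s, cache

    def sample(self, frames, extras, rng: np.random.Generator):
        """(actions, log-probabilities of the sampled actions)."""
        probs, _, _ = self.distribution(frames, extras)
        cum = probs.cumsum(axis=1)
        u = rng.random((len(probs), 1))
        actions = (u > cum).sum(axis=1)
        logp = np.log(probs[np.arange(len(probs)), actions])
        return actions, logp

    def grad_logits_for_logp(self, s: np.ndarray, actions: np.ndarray,
                             weights: np.ndarray) -> np.ndarray:
        """d/dz of sum_b weights_b * log p(actions_b) for the
        sigmoid-normalized categorical head."""
        bsz, n = s.shape
        ssum = s.sum(axis=1, keepdims=True)
        dz = -(s * (1.0 - s)) / ssum
        rows = np.arange(bsz)
        dz[rows, actions] += 1.0 - s[rows, actions]
        return dz * weights[:, None]


class ValueNetwork(_BackboneNet):
    """Linear-head state-value estimator (parameters disjoint from the
    policy's)."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 1):
        spec = spec or NetworkSpec()
        super().__init__(spec, n_out=1, seed=seed)

    def values(self, frames, extras):
        v, cache = self.forward(frames, extras)
        return v[:, 0], cache


def conv_parameter_count(spec: NetworkSpec) -> int:
    """Closed-form parameter count of the convolution stack."""
    total = 0
    c_in = spec.in_channels
    for c_out in spec.conv_channels:
        total += c_out * (c_in * 9 + 1)
        c_in = c_out
    return total
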