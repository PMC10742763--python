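import numpy as np
import pytest

from madseg.policy import (NetworkSpec, PolicyNetwork, ValueNetwork,
                           conv_parameter_count)


def random_inputs(spec, n=4, seed=0):
    rng = np.random.default_rng(seed)
    r = spec.receptive_field
    frames = rng.normal(size=(n, spec.in_channels, r, r))
    extras = rng.normal(size=(n, spec.extra_dim))
    return frames, extras


class TestNetworkSpec:
    def test_receptive_field_must_be_divisible_by_8(self):
        with pytest.raises(ValueError):
            NetworkSpec(receptive_field=20)

    def test_default_flatten_geometry(self):
        spec = NetworkSpec()                  # r = 24
        assert spec.raw_flat_dim == 128 * 3 * 3
        net = ValueNetwork(spec)
        assert net.params["proj_w"].shape == (256, 1152)

    def test_conv_parameter_count_closed_form(self, small_spec):
        # 32*(9*9+1) + 64*(32*9+1) + 128*(64*9+1)
        expected = 32 * 82 + 64 * 289 + 128 * 577
        assert conv_parameter_count(small_spec) == expected
        net = PolicyNetwork(small_spec, seed=0)
        actual = sum(net.params[k].size for k in net.params
                     if k.startswith("conv"))
        assert actual == expected


class TestPolicyForward:
    def test_probabilities_sum_to_one(self, small_policy, small_spec):
        frames, extras = random_inputs(small_spec, n=8)
        probs, s, _ = small_policy.distribution(frames, extras)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs > 0) & (probs < 1))
        assert np.all((s > 0) & (s < 1))      # sigmoid head

    def test_zero_inputs_valid_distribution(self, small_policy, small_spec):
        r = small_spec.receptive_field
        frames = np.zeros((2, 9, r, r))
        extras = np.zeros((2, small_spec.extra_dim))
        probs, _, _ = small_policy.distribution(frames, extras)
        assert np.isfinite(probs).all()
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_nonfinite_inputs_rejected(self, small_policy, small_spec):
        frames, extras = random_inputs(small_spec)
        frames[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            small_policy.forward(frames, extras)

    def test_sampling_reproducible(self, small_policy, small_spec):
        frames, extras = random_inputs(small_spec, n=16)
        a1, l1 = small_policy.sample(frames, extras,
                                     np.random.default_rng(3))
        a2, l2 = small_policy.sample(frames, extras,
                                     np.random.default_rng(3))
        assert np.array_equal(a1, a2)
        assert np.array_equal(l1, l2)


class TestValueNetwork:
    def test_deterministic_and_finite_for_extreme_inputs(self, small_value,
                                                         small_spec):
        frames, extras = random_inputs(small_spec)
        v1, _ = small_value.values(frames, extras)
        v2, _ = small_value.values(frames, extras)
        assert np.array_equal(v1, v2)
        big = np.full_like(extras, 1e6)
        v3, _ = small_value.values(frames, big)
        assert np.isfinite(v3).all()

    def test_parameters_disjoint_from_policy(self, small_spec):
        pol = PolicyNetwork(small_spec, seed=0)
        val = ValueNetwork(small_spec, seed=1)
        frames, extras = random_inputs(small_spec)
        v_before, _ = val.values(frames, extras)
        for k in pol.params:
            pol.params[k] = pol.params[k] + 0.5
        v_after, _ = val.values(frames, extras)
        assert np.array_equal(v_before, v_after)


class TestGradients:
    def test_every_parameter_receives_gradient(self, small_spec):
        net = ValueNetwork(small_spec, seed=7)
        frames, extras = random_inputs(small_spec, n=8, seed=5)
        z, cache = net.forward(frames, extras)
        grads = net.backward(cache, np.ones_like(z))
        assert set(grads) == set(net.params)
        for name, g in grads.items():
            assert np.abs(g).max() > 0, f"dead gradient for {name}"

    def test_backward_matches_finite_differences(self, small_spec):
        net = ValueNetwork(small_spec, seed=3)
        frames, extras = random_inputs(small_spec, n=2, seed=9)
        target = np.array([0.3, -0.7])

        def loss():
            z, _ = net.forward(frames, extras)
            return float(np.mean((z[:, 0] - target) ** 2))

        z, cache = net.forward(frames, extras)
        dz = (2 * (z[:, 0] - target) / len(target))[:, None]
        grads = net.backward(cache, dz)
        rng = np.random.default_rng(0)
        for key in ("conv1_w", "conv3_w", "proj_w", "fc2_w", "head_w"):
            p = net.params[key]
            idx = tuple(int(rng.integers(0, s)) for s in p.shape)
            eps, orig = 1e-6, p[idx]
            p[idx] = orig + eps
            up = loss()
            p[idx] = orig - eps
            down = loss()
            p[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, abs=1e-5,
                                                    rel=1e-4)


class TestCheckpoints:
    def test_roundtrip(self, small_spec, tmp_path):
        net = PolicyNetwork(small_spec, seed=0)
        net.save(tmp_path / "p.npz")
        other = PolicyNetwork(small_spec, seed=99)
        other.load(tmp_path / "p.npz")
        for k in net.params:
            assert np.array_equal(net.params[k], other.params[k])

    def test_architecture_mismatch_refused(self, small_spec, tmp_path):
        net = PolicyNetwork(small_spec, seed=0)
        net.save(tmp_path / "p.npz")
        wrong = PolicyNetwork(NetworkSpec(receptive_field=16), seed=0)
        with pytest.raises(ValueError):
            wrong.load(tmp_path / "p.npz")

    def test_spec_hash_stable(self, small_spec):
        assert small_spec.spec_hash() == NetworkSpec(
            receptive_field=8).spec_hash()
        assert small_spec.spec_hash() != NetworkSpec().spec_hash()
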