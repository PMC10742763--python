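import numpy as np
import pytest

from madseg.phantoms import CATEGORY_ORDER
from madseg.training import (BanditEpisodeSource, PPOConfig, PPOTrainer,
                             compute_gae, curriculum_schedule,
                             surrogate_loss, value_loss)


class TestComputeGAE:
    def test_single_step(self):
        est = compute_gae(np.array([1.0]), np.array([0.0, 0.0]),
                          gamma=0.99, lam=0.95)
        assert est.deltas[0] == pytest.approx(1.0)
        assert est.advantages[0] == pytest.approx(1.0)
        assert est.v_hat[0] == pytest.approx(1.0)

    def test_gamma_zero_no_lookahead(self):
        r = np.array([1.0, 2.0, 3.0])
        v = np.array([0.5, 0.1, 0.2, 0.0])
        est = compute_gae(r, v, gamma=0.0, lam=0.7)
        np.testing.assert_allclose(est.advantages, r - v[:-1])

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            t = int(rng.integers(1, 20))
            r = rng.normal(size=t)
            v = rng.normal(size=t + 1)
            gamma, lam = 0.97, 0.9
            est = compute_gae(r, v, gamma, lam)
            deltas = r + gamma * v[1:] - v[:-1]
            brute = np.array([
                sum((gamma * lam) ** (j - s) * deltas[j]
                    for j in range(s, t)) for s in range(t)])
            np.testing.assert_allclose(est.advantages, brute, atol=1e-10)

    def test_lambda_one_telescopes_to_discounted_return(self):
        rng = np.random.default_rng(1)
        t = 15
        r = rng.normal(size=t)
        v = np.concatenate([rng.normal(size=t), [0.0]])
        gamma = 0.95
        est = compute_gae(r, v, gamma, lam=1.0)
        returns = np.array([sum(gamma ** (j - s) * r[j]
                                for j in range(s, t)) for s in range(t)])
        np.testing.assert_allclose(est.advantages + v[:-1], returns,
                                   atol=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_gae(np.ones(3), np.ones(3), 0.99, 0.95)


class TestSurrogateLoss:
    def test_ratio_one_identity(self):
        rng = np.random.default_rng(2)
        logp = rng.normal(size=50)
        adv = rng.normal(size=50)
        assert surrogate_loss(logp, logp, adv, 0.2) == pytest.approx(
            adv.mean(), abs=1e-12)

    def test_clip_activates_for_large_ratio(self):
        adv = np.array([2.0])
        logp_old = np.array([0.0])
        logp_new = np.array([np.log(1.4)])   # ratio = 1 + 2*eps
        got = surrogate_loss(logp_new, logp_old, adv, clip_eps=0.2)
        assert got == pytest.approx(1.2 * 2.0)

    def test_matches_termwise_transcription(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            lo = rng.normal(size=n)
            ln = lo + rng.normal(scale=0.3, size=n)
            adv = rng.normal(size=n)
            eps = 0.2
            terms = []
            for i in range(n):
                ratio = np.exp(ln[i] - lo[i])
                clipped = min(max(ratio, 1 - eps), 1 + eps)
                terms.append(min(ratio * adv[i], clipped * adv[i]))
            assert surrogate_loss(ln, lo, adv, eps) == pytest.approx(
                np.mean(terms), abs=1e-12)

    def test_nonfinite_ratio_rejected(self):
        with pytest.raises(ValueError):
            surrogate_loss(np.array([1e4]), np.array([-1e4]),
                           np.array([1.0]), 0.2)


class TestValueLoss:
    def test_normalizes_by_trajectory_count(self):
        # two trajectories with per-trajectory squared-error sums 3 and 5
        v_pred = np.array([1.0, 1.0, 1.0, 2.0, 0.0])
        v_hat = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        # first trajectory: 1+1+1 = 3; second: 4+1 = 5
        assert value_loss(v_pred, v_hat, k=2) == pytest.approx(4.0)

    def test_zero_when_equal_and_quadratic_scaling(self):
        v = np.array([0.3, -0.2, 1.0])
        assert value_loss(v, v, k=1) == 0.0
        l1 = value_loss(v, v + 1.0, k=1)
        l2 = value_loss(v, v + 2.0, k=1)
        assert l2 == pytest.approx(4 * l1)


class TestCurriculum:
    def test_starts_easiest(self):
        assert curriculum_schedule([]) == "B|B|B"

    def test_category_order_by_tough_count_then_position(self):
        assert CATEGORY_ORDER == ("B|B|B", "B|B|T", "B|T|B", "T|B|B",
                                  "B|T|T", "T|B|T", "T|T|B", "T|T|T")

    def test_advances_on_plateau(self):
        logbook = [{"category": "B|B|B", "success": 0.8}] * 40
        assert curriculum_schedule(logbook, window=20) == "B|B|T"

    def test_holds_while_improving(self):
        logbook = [{"category": "B|B|B", "success": i / 40}
                   for i in range(40)]
        assert curriculum_schedule(logbook, window=20) == "B|B|B"

    def test_holds_until_enough_history(self):
        logbook = [{"category": "B|B|B", "success": 0.8}] * 10
        assert curriculum_schedule(logbook, window=20) == "B|B|B"


class TestTrainerSmoke:
    def test_two_iterations_finite_losses(self, small_spec):
        from madseg.policy import PolicyNetwork, ValueNetwork

        pol = PolicyNetwork(small_spec, seed=0)
        val = ValueNetwork(small_spec, seed=1)
        cfg = PPOConfig(t_max=32, epochs_pi=3, epochs_v=3, seed=0)
        trainer = PPOTrainer(pol, val, cfg)
        src = BanditEpisodeSource(small_spec, episode_len=8)
        for _ in range(2):
            entry = trainer.iteration(src)
            assert np.isfinite(entry["surrogate_loss"])
            assert np.isfinite(entry["value_loss"])
            assert entry["n_transitions"] > cfg.t_max  # break after exceed

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PPOConfig(gamma=0.0)
        with pytest.raises(ValueError):
            PPOConfig(lam=1.5)
        with pytest.raises(ValueError):
            PPOConfig(clip_eps=0.0)
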