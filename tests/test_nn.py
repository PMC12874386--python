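"""Generative stack: encodings, autodiff, equivariance, diffusion mechanics."""

import numpy as np
import pytest

from writhekit.chain import ChainCoordinates, ParameterError
from writhekit.fixtures import helical_fragment
from writhekit.nn.autodiff import (
    MLP,
    Adam,
    Parameter,
    Tensor,
    channel_linear,
    concat,
    gather,
    scatter_sum,
    segment_sum_contiguous,
    vector_norm,
)
from writhekit.nn.diffusion import (
    DiffusionModel,
    NoiseSchedule,
    TrainConfig,
    sample_ensemble,
    train_ddpm,
)
from writhekit.nn.encoding import EncodingSpec, positional_encoding
from writhekit.nn.network import (
    NetworkConfig,
    ScoreNetwork,
    chain_edge_features,
    scalar_message,
    vector_message,
)

from .conftest import random_rotation


class TestPositionalEncoding:
    def test_sine_only_is_odd(self, rng):
        spec = EncodingSpec(8, 1.0, "sine_only")
        x = rng.uniform(-1, 1, size=20)
        np.testing.assert_array_equal(
            positional_encoding(-x, spec), -positional_encoding(x, spec)
        )
        np.testing.assert_array_equal(positional_encoding(0.0, spec), 0.0)

    def test_both_mode_at_zero(self):
        spec = EncodingSpec(8, 2.0, "both")
        enc = positional_encoding(0.0, spec)
        np.testing.assert_array_equal(enc[0::2], 0.0)  # sines
        np.testing.assert_array_equal(enc[1::2], 1.0)  # cosines

    def test_dimensions(self):
        assert positional_encoding(0.3, EncodingSpec(10, 1.0, "both")).shape == (10,)
        assert positional_encoding(0.3, EncodingSpec(10, 1.0, "sine_only")).shape == (5,)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            EncodingSpec(7, 1.0, "both")
        with pytest.raises(ParameterError):
            EncodingSpec(8, -1.0, "both")


class TestAutodiff:
    def test_mlp_gradients_match_finite_differences(self, rng):
        mlp = MLP(np.random.default_rng(0), 4, 8, 3)
        x = Tensor(rng.normal(size=(5, 4)))
        loss = (mlp(x) * mlp(x)).mean()
        loss.backward()
        p = mlp.l1.W
        idx = (1, 2)
        analytic = p.grad[idx]
        eps = 1e-2
        p.data[idx] += eps
        up = float((mlp(x) * mlp(x)).mean().data)
        p.data[idx] -= 2 * eps
        dn = float((mlp(x) * mlp(x)).mean().data)
        p.data[idx] += eps
        assert analytic == pytest.approx((up - dn) / (2 * eps), rel=1e-2)

    def test_scatter_and_segment_sum_agree(self, rng):
        x = Tensor(rng.normal(size=(12, 3)), requires_grad=True)
        idx = np.repeat(np.arange(4), 3)
        a = scatter_sum(x, idx, 4)
        b = segment_sum_contiguous(x, 3)
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)

    def test_gather_backward_accumulates(self, rng):
        p = Parameter(rng.normal(size=(3, 2)))
        out = gather(p, np.array([0, 0, 1]))
        loss = out.sum()
        loss.backward()
        np.testing.assert_allclose(p.grad, [[2, 2], [1, 1], [0, 0]])

    def test_channel_linear_commutes_with_rotation(self, rng):
        w = Parameter(rng.normal(size=(4, 6)))
        v = rng.normal(size=(5, 4, 3))
        rot = random_rotation(rng)
        out1 = channel_linear(Tensor(v), w).data @ rot.T
        out2 = channel_linear(Tensor(v @ rot.T), w).data
        np.testing.assert_allclose(out1, out2, atol=1e-5)

    def test_adam_reduces_quadratic(self):
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 0.1


class TestEdgeFeatures:
    def test_parity_split(self):
        pts = helical_fragment(8)
        coords = ChainCoordinates(pts[None])
        mirror = coords.mirrored()
        f = chain_edge_features(coords, (1, 3))
        f_m = chain_edge_features(mirror, (1, 3))
        np.testing.assert_allclose(f["distance"], f_m["distance"], atol=1e-10)
        for w, w_m in zip(f["w"], f_m["w"]):
            np.testing.assert_allclose(w, -w_m, atol=1e-10)

    def test_planar_chain_zero_writhe_block(self):
        x = np.arange(8, dtype=float)
        pos = np.stack([3.8 * x, 2.0 * (x % 2), np.zeros(8)], axis=1)
        f = chain_edge_features(ChainCoordinates(pos[None]))
        np.testing.assert_allclose(f["w"][0], 0.0, atol=1e-12)

    def test_rotation_maps_crossing_normals(self, rng):
        pts = helical_fragment(8)
        rot = random_rotation(rng)
        f = chain_edge_features(ChainCoordinates(pts[None]))
        f_r = chain_edge_features(ChainCoordinates((pts @ rot.T)[None]))
        np.testing.assert_allclose(f_r["w_vec"], f["w_vec"] @ rot.T, atol=1e-6)


class TestMessageResiduals:
    def test_zero_filter_zero_message(self, rng):
        phi_s = rng.normal(size=(6, 4))
        out = scalar_message(phi_s, np.zeros((6, 4)), np.repeat(np.arange(2), 3), 2)
        np.testing.assert_array_equal(out, 0.0)

    def test_vector_message_reduces_to_parity_symmetric_form(self, rng):
        """Dropping the writhe gate recovers the E(3) message exactly."""
        E, F = 6, 4
        v_j = rng.normal(size=(E, F, 3))
        rhat = rng.normal(size=(E, 3))
        wvec = rng.normal(size=(E, 3))
        g1, g2, g3 = (rng.normal(size=(E, F)) for _ in range(3))
        src = np.repeat(np.arange(2), 3)
        with_w = vector_message(v_j, rhat, wvec, g1, g2, g3, src, 2)
        without = vector_message(v_j, rhat, None, g1, g2, None, src, 2)
        contribution = vector_message(
            np.zeros_like(v_j), rhat * 0, wvec, g1 * 0, g2 * 0, g3, src, 2
        )
        np.testing.assert_allclose(with_w, without + contribution, atol=1e-12)


class TestScoreNetworkSymmetry:
    @pytest.fixture(scope="class")
    def nets(self):
        cfg_w = NetworkConfig(n_atoms=8, hidden_dim=16, n_layers=2, enc_dim=8,
                              use_writhe=True, seed=0)
        cfg_b = NetworkConfig(n_atoms=8, hidden_dim=16, n_layers=2, enc_dim=8,
                              use_writhe=False, seed=0)
        return ScoreNetwork(cfg_w), ScoreNetwork(cfg_b)

    @pytest.fixture(scope="class")
    def chains(self):
        rng = np.random.default_rng(7)
        return helical_fragment(8)[None] + 0.3 * rng.normal(size=(3, 8, 3))

    def test_rotation_equivariance(self, nets, chains, rng):
        net, _ = nets
        rot = random_rotation(rng)
        out = net(chains, 0.4).reshape(3, 8, 3)
        out_r = net(chains @ rot.T, 0.4).reshape(3, 8, 3)
        assert np.abs(out_r - out @ rot.T).max() <= 1e-4

    def test_translation_invariance(self, nets, chains):
        net, _ = nets
        out = net(chains, 0.4)
        out_t = net(chains + np.array([5.0, -2.0, 9.0]), 0.4)
        assert np.abs(out - out_t).max() <= 1e-4

    def test_writhe_network_breaks_reflection(self, nets, chains):
        net, _ = nets
        mirror = chains * np.array([1.0, 1.0, -1.0])
        out = net(chains, 0.4).reshape(3, 8, 3)
        out_m = net(mirror, 0.4).reshape(3, 8, 3)
        reflected = out * np.array([1.0, 1.0, -1.0])
        assert np.abs(out_m - reflected).max() > 1e-3

    def test_baseline_network_reflection_equivariant(self, nets, chains):
        _, net = nets
        mirror = chains * np.array([1.0, 1.0, -1.0])
        out = net(chains, 0.4).reshape(3, 8, 3)
        out_m = net(mirror, 0.4).reshape(3, 8, 3)
        reflected = out * np.array([1.0, 1.0, -1.0])
        assert np.abs(out_m - reflected).max() <= 1e-4

    def test_zeroed_head_zero_score(self, chains):
        cfg = NetworkConfig(n_atoms=8, hidden_dim=16, n_layers=2, enc_dim=8,
                            seed=0)
        net = ScoreNetwork(cfg)
        net.head_vec.data[...] = 0.0
        np.testing.assert_array_equal(net(chains, 0.2), 0.0)

    def test_output_is_mean_centered(self, nets, chains):
        net, _ = nets
        out = net(chains, 0.6).reshape(3, 8, 3)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-5)


class TestNoiseSchedule:
    def test_variance_monotone_and_prior_limit(self):
        sched = NoiseSchedule()
        t = np.linspace(0.0, 1.0, 200)
        sigma = sched.sigma(t)
        assert np.all(np.diff(sigma) >= 0.0)
        assert sched.alpha(1.0) < 0.01
        assert sigma[-1] == pytest.approx(1.0, abs=1e-4)

    def test_terminal_marginal_matches_prior(self, rng):
        """KS distance of forward-noised data vs prior draws at t = T."""
        from scipy import stats

        sched = NoiseSchedule()
        x0 = rng.uniform(-2, 2, size=10000)
        noised = sched.alpha(1.0) * x0 + sched.sigma(1.0) * rng.normal(size=10000)
        ks = stats.ks_2samp(noised, rng.normal(size=10000)).statistic
        assert ks < 0.02


class TestDiffusionTraining:
    @pytest.fixture(scope="class")
    def tiny_ensemble(self):
        rng = np.random.default_rng(5)
        base = helical_fragment(6)
        return ChainCoordinates(base[None] + 0.25 * rng.normal(size=(256, 6, 3)))

    def test_loss_decreases(self, tiny_ensemble):
        ncfg = NetworkConfig(n_atoms=6, hidden_dim=16, n_layers=2, enc_dim=8,
                             seed=0)
        tcfg = TrainConfig(epochs=8, batch_size=64, seed=0)
        model = train_ddpm(tiny_ensemble, ncfg, tcfg)
        assert model.loss_curve[-1] < model.loss_curve[0]

    def test_seeded_rerun_reproduces_loss_curve(self, tiny_ensemble):
        ncfg = NetworkConfig(n_atoms=6, hidden_dim=16, n_layers=1, enc_dim=8,
                             seed=0)
        tcfg = TrainConfig(epochs=3, batch_size=64, seed=0)
        a = train_ddpm(tiny_ensemble, ncfg, tcfg)
        b = train_ddpm(tiny_ensemble, ncfg, tcfg)
        np.testing.assert_allclose(a.loss_curve, b.loss_curve, rtol=1e-4)

    def test_point_mass_ensemble_collapses(self):
        """All-identical training frames: samples concentrate near the target."""
        base = helical_fragment(6)
        ens = ChainCoordinates(np.repeat(base[None], 256, axis=0))
        ncfg = NetworkConfig(n_atoms=6, hidden_dim=24, n_layers=2, enc_dim=8,
                             seed=0)
        tcfg = TrainConfig(epochs=150, batch_size=128, seed=0)
        model = train_ddpm(ens, ncfg, tcfg)
        samp = sample_ensemble(model, 32, method="sde", seed=1, n_steps=60,
                               t_min=0.02)
        # compare rotation-invariant geometry: inter-bead distance matrix
        from writhekit.features import distance_features

        d_ref = distance_features(ChainCoordinates(base[None])).values[0]
        d_s = distance_features(samp).values
        rmse = np.sqrt(((d_s - d_ref) ** 2).mean())
        # prior draws at the data scale sit at ~2.5 Å on this metric
        prior = ChainCoordinates(
            np.random.default_rng(0).normal(size=(32, 6, 3))
            * ens.positions.std()
        )
        rmse_prior = np.sqrt(
            ((distance_features(prior).values - d_ref) ** 2).mean()
        )
        assert rmse < 1.0  # Å; well under the 3.8 Å bond scale
        assert rmse < 0.5 * rmse_prior

    def test_sampling_deterministic_given_seed(self, tiny_ensemble):
        ncfg = NetworkConfig(n_atoms=6, hidden_dim=16, n_layers=1, enc_dim=8,
                             seed=0)
        tcfg = TrainConfig(epochs=2, batch_size=64, seed=0)
        model = train_ddpm(tiny_ensemble, ncfg, tcfg)
        a = sample_ensemble(model, 8, method="ode", seed=3, n_steps=10)
        b = sample_ensemble(model, 8, method="ode", seed=3, n_steps=10)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_rotated_prior_rotates_output_distribution(self, tiny_ensemble):
        """Equivariance consequence: rotating prior draws rotates samples."""
        ncfg = NetworkConfig(n_atoms=6, hidden_dim=16, n_layers=1, enc_dim=8,
                             seed=0)
        tcfg = TrainConfig(epochs=2, batch_size=64, seed=0)
        model = train_ddpm(tiny_ensemble, ncfg, tcfg)
        samp = sample_ensemble(model, 16, method="ode", seed=3, n_steps=10)
        # rotation-invariant summaries are unchanged under a different seed's
        # implicit prior orientation; check via distance statistics
        samp2 = sample_ensemble(model, 16, method="ode", seed=4, n_steps=10)
        from writhekit.features import distance_features

        m1 = distance_features(samp).values.mean()
        m2 = distance_features(samp2).values.mean()
        assert abs(m1 - m2) / m1 < 0.2

    def test_bad_method_rejected(self, tiny_ensemble):
        ncfg = NetworkConfig(n_atoms=6, hidden_dim=16, n_layers=1, enc_dim=8,
                             seed=0)
        model = train_ddpm(tiny_ensemble, ncfg, TrainConfig(epochs=1, seed=0))
        with pytest.raises(ParameterError):
            sample_ensemble(model, 4, method="euler")
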