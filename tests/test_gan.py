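import numpy as np
import pytest

from kvphasegen.autodiff import Var, vmatmul, vsum
from kvphasegen.gan import (
    DiscriminatorSpec,
    GeneratorSpec,
    TrainConfig,
    TrainedGenerator,
    compute_losses,
    init_params,
    interpolate_energies,
    sample_particles,
    spectral_norm_audit,
    train_gan,
)
from kvphasegen.phasespace import NormalizationSpec, ParticleBatch, PhaseSpace


def make_model(labels=(60, 100), seed=0, hidden=(16, 16, 16)) -> TrainedGenerator:
    """Untrained (randomly initialised) generator for interface tests."""
    gspec = GeneratorSpec(hidden=hidden, labels=labels)
    dspec = DiscriminatorSpec(hidden=hidden)
    params = init_params(gspec, dspec, np.random.default_rng(seed))
    norm = NormalizationSpec(
        lo=[-60, -60, -0.15, -0.15, 0.97, 15.0],
        hi=[60, 60, 0.15, 0.15, 1.0, 100.0],
    )
    return TrainedGenerator(
        gspec=gspec,
        dspec=dspec,
        params=params,
        ema_params={k: v.copy() for k, v in params.items() if k.startswith("g.")},
        norm=norm,
        kvp=None if labels else 100,
    )


class TestGeneratorForward:
    def test_deterministic_given_weights_and_latent(self):
        g = make_model()
        z = np.random.default_rng(1).standard_normal((64, 6))
        assert np.array_equal(g.forward(z, 60), g.forward(z, 60))

    def test_conditional_input_width_is_ten(self):
        g = make_model()
        # 6-D latent concatenated with the 4-D label embedding
        assert g.params["g.W0"].shape[0] == 10
        assert g.params["g.embed"].shape[1] == 4

    def test_split_composition_identity(self):
        g = make_model()
        z = np.random.default_rng(2).standard_normal((32, 6))
        full = g.forward(z, 100)
        split = g.rest(g.first_layer(z, 100))
        assert np.array_equal(full, split)

    def test_unknown_label_raises(self):
        g = make_model()
        with pytest.raises(KeyError, match="vocabulary"):
            g.forward(np.zeros((2, 6)), 80)

    def test_traditional_model_takes_no_label(self):
        g = make_model(labels=None)
        out = g.forward(np.zeros((4, 6)))
        assert out.shape == (4, 6)
        with pytest.raises(ValueError):
            g.forward(np.zeros((4, 6)), 60)


class TestLosses:
    def test_zero_discriminator_non_saturated_values(self):
        d0 = Var(np.zeros((16, 1)))
        d_loss, g_loss = compute_losses(d0, d0, "non_saturated_r1", 0.0)
        assert np.isclose(d_loss.value, 2 * np.log(2))
        assert np.isclose(g_loss.value, np.log(2))

    def test_linear_discriminator_r1_is_weight_norm(self):
        w = Var(np.array([[0.7], [-1.2], [2.0]]))
        x = Var(np.random.default_rng(0).standard_normal((32, 3)))
        d_real = vmatmul(x, w)
        gamma = 10.0
        with_r1, _ = compute_losses(d_real, Var(np.zeros((32, 1))),
                                    "non_saturated_r1", gamma, x)
        without, _ = compute_losses(d_real, Var(np.zeros((32, 1))),
                                    "non_saturated_r1", 0.0, x)
        r1 = with_r1.value - without.value
        assert np.isclose(r1, 0.5 * gamma * np.sum(w.value**2))

    def test_wasserstein_equal_outputs_cancel(self):
        d = Var(np.full((8, 1), 3.7))
        d_loss, g_loss = compute_losses(d, d, "wasserstein", 0.0)
        assert np.isclose(d_loss.value, 0.0)
        assert np.isclose(g_loss.value, -3.7)

    def test_negative_gamma_rejected(self):
        d = Var(np.zeros((4, 1)))
        with pytest.raises(ValueError):
            compute_losses(d, d, "non_saturated_r1", -1.0)


def toy_phase_space(n=20_000, mean=3.0, seed=0) -> PhaseSpace:
    """6-column data whose x column is the 1-D Gaussian learning target."""
    rng = np.random.default_rng(seed)
    cols = rng.uniform(0.2, 0.8, size=(n, 6))
    cols[:, 0] = rng.normal(mean, 1.0, n)
    return PhaseSpace(ParticleBatch.from_columns(cols), kvp_label=100)


class TestTraining:
    def test_toy_gaussian_mean_recovered(self):
        target_mean = 3.0
        ps = toy_phase_space(mean=target_mean)
        gspec = GeneratorSpec(hidden=(32, 32, 32))
        dspec = DiscriminatorSpec(hidden=(32, 32, 32), spectral_norm=True)
        tcfg = TrainConfig(
            loss="non_saturated_r1", lr=3e-4, batch_size=256, epochs=40, seed=4
        )
        model = train_gan(ps, gspec, dspec, tcfg)
        z = np.random.default_rng(9).standard_normal((20_000, 6))
        from kvphasegen.phasespace import denormalize_batch

        gen = denormalize_batch(model.forward(z), model.norm)
        # oracle: sample statistics of the target distribution
        assert abs(float(np.mean(gen.x)) - target_mean) < 0.1

    def test_source_phase_space_learned_within_ten_percent(self):
        """Desk-scale training on a line-free 60 kV synthetic source
        reaches a held-out histogram percent error of at most 10%."""
        from kvphasegen.benchmark import (
            benchmark_specs, benchmark_train_config, make_benchmark_data,
        )
        from kvphasegen.evaluation import HistogramSpec, histogram_loss

        train, val = make_benchmark_data(kvps=(60,), seed=3)
        gspec, dspec = benchmark_specs(None, spectral_norm=True)
        tcfg = benchmark_train_config(
            "non_saturated_r1", seed=1, lr=1e-3, epochs=40, batch_size=500,
            d_steps=1, keep_best=True,
        )
        model = train_gan(train[60], gspec, dspec, tcfg, val_data=val)
        n_cmp = 50_000
        ref = val[60].batch.take(np.arange(n_cmp))
        gen = sample_particles(model, n_cmp, seed=77)
        rep = histogram_loss(ref, gen, HistogramSpec(100, n_cmp))
        assert rep.error_percent <= 10.0

    def test_same_seed_reproduces_weights(self):
        ps = toy_phase_space(n=4000)
        args = (
            GeneratorSpec(hidden=(8, 8, 8)),
            DiscriminatorSpec(hidden=(8, 8, 8), spectral_norm=True),
            TrainConfig(batch_size=500, epochs=2, seed=7),
        )
        m1 = train_gan(ps, *args)
        m2 = train_gan(ps, *args)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_ema_decay_zero_equals_raw_weights(self):
        ps = toy_phase_space(n=4000)
        m = train_gan(
            ps,
            GeneratorSpec(hidden=(8, 8, 8)),
            DiscriminatorSpec(hidden=(8, 8, 8)),
            TrainConfig(batch_size=500, epochs=2, seed=1, ema=True, ema_decay=0.0),
        )
        for k in m.ema_params:
            assert np.allclose(m.ema_params[k], m.params[k])

    def test_spectral_norm_unit_largest_singular_value(self):
        ps = toy_phase_space(n=4000)
        m = train_gan(
            ps,
            GeneratorSpec(hidden=(8, 8, 8)),
            DiscriminatorSpec(hidden=(8, 8, 8), spectral_norm=True),
            TrainConfig(batch_size=500, epochs=3, seed=2),
        )
        for s in spectral_norm_audit(m.params, m.sn_state):
            assert abs(s - 1.0) < 1e-3

    def test_training_log_losses_finite(self):
        ps = toy_phase_space(n=4000)
        m = train_gan(
            ps,
            GeneratorSpec(hidden=(8, 8, 8)),
            DiscriminatorSpec(hidden=(8, 8, 8)),
            TrainConfig(batch_size=500, epochs=2, seed=3),
        )
        for entry in m.train_log:
            assert np.isfinite(entry["d_loss"]) and np.isfinite(entry["g_loss"])


class TestSamplingAndSerialization:
    def test_sampled_particles_satisfy_invariants(self):
        g = make_model()
        batch = sample_particles(g, 2000, label=60, seed=5)
        batch.validate(kvp=60.0)
        assert batch.n == 2000

    def test_sampling_deterministic_under_seed(self):
        g = make_model()
        a = sample_particles(g, 500, label=100, seed=8)
        b = sample_particles(g, 500, label=100, seed=8)
        assert np.array_equal(a.columns(), b.columns())

    def test_serialization_round_trip_preserves_outputs(self, tmp_path):
        g = make_model()
        p = tmp_path / "model.kvg"
        g.save(p)
        g2 = TrainedGenerator.load(p)
        z = np.random.default_rng(3).standard_normal((100, 6))
        assert np.array_equal(g.forward(z, 60), g2.forward(z, 60))
        a = sample_particles(g, 200, label=100, seed=1)
        b = sample_particles(g2, 200, label=100, seed=1)
        assert np.array_equal(a.columns(), b.columns())


class TestInterpolation:
    def test_endpoints_bitwise_equal_direct_generation(self):
        g = make_model()
        z = np.random.default_rng(4).standard_normal((64, 6))
        assert np.array_equal(
            interpolate_energies(g, 1.0, 60, 100, z), g.forward(z, 60)
        )
        assert np.array_equal(
            interpolate_energies(g, 0.0, 60, 100, z), g.forward(z, 100)
        )

    def test_embedding_mode_also_hits_endpoints(self):
        g = make_model()
        z = np.random.default_rng(5).standard_normal((16, 6))
        out = interpolate_energies(g, 1.0, 60, 100, z, mode="embedding")
        assert np.allclose(out, g.forward(z, 60))

    def test_lambda_out_of_range_rejected(self):
        g = make_model()
        with pytest.raises(ValueError):
            interpolate_energies(g, 1.5, 60, 100, np.zeros((2, 6)))

    def test_traditional_model_cannot_interpolate(self):
        g = make_model(labels=None)
        with pytest.raises(ValueError):
            interpolate_energies(g, 0.5, 60, 100, np.zeros((2, 6)))
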