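import numpy as np
import pytest

from kvphasegen.evaluation import (
    HistogramSpec,
    ProfileShapeError,
    ProfileTrace,
    conditional_total_loss,
    fit_gaussian_mixture,
    fw_at_fraction,
    histogram_loss,
    lateral_profile,
)
from kvphasegen.phasespace import COLUMNS, ParticleBatch
from kvphasegen.source import GaussianMixture1D
from conftest import make_batch

FW15_FACTOR = 2.0 * np.sqrt(2.0 * np.log(1.0 / 0.15))  # ~3.8959


def batch_of(values) -> ParticleBatch:
    """Batch whose six columns all equal the given value list."""
    v = np.asarray(values, float)
    return ParticleBatch.from_columns(np.tile(v[:, None], (1, 6)))


def explicit_spec(n_particles, edges) -> HistogramSpec:
    return HistogramSpec(
        n_bins=len(edges) - 1,
        n_particles=n_particles,
        edges={c: np.asarray(edges, float) for c in COLUMNS},
    )


class TestHistogramLoss:
    def test_identity_gives_zero_error(self):
        b = make_batch(500, seed=0)
        rep = histogram_loss(b, b, HistogramSpec(50, 500))
        assert rep.l_total == 0.0
        assert rep.error_percent == 0.0

    def test_disjoint_supports_give_200_percent(self):
        ref = batch_of([0.5] * 10)
        gen = batch_of([2.5] * 10)
        rep = histogram_loss(ref, gen, explicit_spec(10, [0, 1, 2, 3]))
        for c in COLUMNS:
            assert rep.per_parameter[c] == 20.0
        assert rep.error_percent == 200.0

    def test_three_bin_worked_example(self):
        # per parameter: ref counts (4,3,3), gen (2,5,3) -> L1 = 4;
        # six parameters, ten particles -> E = 24/(6*10)*100 ... per Eq. 1-4
        ref = batch_of([0.1] * 4 + [1.1] * 3 + [2.1] * 3)
        gen = batch_of([0.1] * 2 + [1.1] * 5 + [2.1] * 3)
        rep = histogram_loss(ref, gen, explicit_spec(10, [0, 1, 2, 3]))
        assert all(v == 4.0 for v in rep.per_parameter.values())
        assert rep.l_total == 24.0
        assert rep.error_percent == pytest.approx(40.0)

    def test_symmetry_and_triangle_inequality(self):
        spec = explicit_spec(300, np.linspace(-4, 4, 40))
        rng = np.random.default_rng(1)
        a, b, c = (
            batch_of(rng.normal(mu, 1.0, 300)) for mu in (0.0, 0.5, 1.0)
        )
        lab = histogram_loss(a, b, spec).l_total
        lba = histogram_loss(b, a, spec).l_total
        lac = histogram_loss(a, c, spec).l_total
        lbc = histogram_loss(b, c, spec).l_total
        assert lab == lba
        assert lac <= lab + lbc

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="n_particles"):
            histogram_loss(make_batch(10), make_batch(20), HistogramSpec(5, 10))

    def test_error_percent_invariant_under_count_scaling(self):
        spec_small = explicit_spec(200, np.linspace(-4, 4, 30))
        spec_big = explicit_spec(600, np.linspace(-4, 4, 30))
        rng = np.random.default_rng(2)
        a1 = rng.normal(0, 1, 200)
        b1 = rng.normal(0.4, 1, 200)
        small = histogram_loss(batch_of(a1), batch_of(b1), spec_small)
        big = histogram_loss(
            batch_of(np.repeat(a1, 3)), batch_of(np.repeat(b1, 3)), spec_big
        )
        assert big.l_total == 3 * small.l_total
        assert big.error_percent == pytest.approx(small.error_percent)


class TestConditionalTotalLoss:
    def test_mean_and_symmetry(self):
        r1 = histogram_loss(batch_of([0.5] * 4), batch_of([0.5] * 4),
                            explicit_spec(4, [0, 1]))
        r2 = histogram_loss(batch_of([0.5] * 4), batch_of([1.5] * 4),
                            explicit_spec(4, [0, 1, 2]))
        assert conditional_total_loss([r1]) == r1.l_total
        assert conditional_total_loss([r1, r2]) == pytest.approx(
            (r1.l_total + r2.l_total) / 2
        )
        assert conditional_total_loss([r2, r1]) == conditional_total_loss([r1, r2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            conditional_total_loss([])


class TestFwAtFraction:
    def test_analytic_gaussian_closed_form(self):
        sigma = 0.3
        x = np.arange(-2.0, 2.0, 0.01)  # 10 um sampling
        y = np.exp(-0.5 * (x / sigma) ** 2)
        w = fw_at_fraction(ProfileTrace(x, y), 0.15)
        assert abs(w - FW15_FACTOR * sigma) / (FW15_FACTOR * sigma) < 0.005

    def test_symmetric_triangle(self):
        wbase = 1.0
        x = np.linspace(-1.2, 1.2, 4001)
        y = np.clip(1 - np.abs(x) / wbase, 0, None)
        w = fw_at_fraction(ProfileTrace(x, y), 0.15)
        assert w == pytest.approx(1.7 * wbase, rel=1e-3)

    def test_unbiased_across_sigma_sweep(self):
        for sigma in np.linspace(0.05, 1.0, 12):
            x = np.arange(-5 * sigma, 5 * sigma, 0.01)
            y = np.exp(-0.5 * (x / sigma) ** 2)
            w = fw_at_fraction(ProfileTrace(x, y), 0.15)
            assert abs(w - FW15_FACTOR * sigma) / (FW15_FACTOR * sigma) < 0.005

    def test_boundary_peak_is_shape_error(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(ProfileShapeError, match="boundary"):
            fw_at_fraction(ProfileTrace(x, np.exp(-x)), 0.15)

    def test_strict_mode_rejects_multimodal_crossings(self):
        x = np.linspace(-3, 3, 601)
        y = np.exp(-0.5 * (x / 0.3) ** 2) + 0.5 * np.exp(-0.5 * ((x - 2) / 0.1) ** 2)
        with pytest.raises(ProfileShapeError, match="crossing"):
            fw_at_fraction(ProfileTrace(x, y), 0.15, strict=True)


class TestGaussianMixtureFit:
    def test_noiseless_single_gaussian_recovered(self):
        x = np.linspace(-2, 2, 400)
        truth = GaussianMixture1D([1.0], [0.12], [0.35])
        mix, rms = fit_gaussian_mixture(ProfileTrace(x, truth.pdf(x)), k=1)
        assert rms < 1e-8
        assert abs(mix.means_mm[0] - 0.12) < 1e-6
        assert abs(mix.sigmas_mm[0] - 0.35) / 0.35 < 1e-6

    def test_noiseless_four_component_recovered(self):
        from kvphasegen.source import default_focal_spot

        truth = default_focal_spot().horizontal
        x = np.linspace(-0.8, 0.8, 1601)
        mix, rms = fit_gaussian_mixture(ProfileTrace(x, truth.pdf(x)), k=4)
        assert rms < 1e-6
        assert np.allclose(mix.means_mm, truth.means_mm, atol=1e-3)
        assert np.allclose(mix.weights, truth.weights, atol=1e-3)

    def test_nested_models_do_not_fit_worse(self):
        from kvphasegen.source import default_focal_spot

        truth = default_focal_spot().horizontal
        x = np.linspace(-0.8, 0.8, 801)
        trace = ProfileTrace(x, truth.pdf(x))
        _, rms4 = fit_gaussian_mixture(trace, k=4)
        _, rms1 = fit_gaussian_mixture(trace, k=1)
        assert rms4 <= rms1


class TestLateralProfile:
    def test_counts_are_conserved(self, source_ps_100):
        trace = lateral_profile(source_ps_100, "x", bins=60)
        assert trace.intensity.sum() == source_ps_100.n

    def test_heel_asymmetry_integral_ratio(self, source_ps_100):
        trace = lateral_profile(source_ps_100, "x", bins=60)
        anode = trace.intensity[trace.positions_mm > 0].sum()
        cathode = trace.intensity[trace.positions_mm < 0].sum()
        assert anode / cathode < 1.0

    def test_bad_axis_rejected(self, source_ps_100):
        with pytest.raises(ValueError):
            lateral_profile(source_ps_100, "z")
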