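import numpy as np
import pytest
from scipy.special import eval_legendre

from padftex import (
    BlMatrices,
    CorrelationVolume,
    HexLattice2D,
    OrientationModel,
    PolarGrid,
    SimConfig,
    average_correlations,
    balance_ratio,
    bl_power,
    bl_to_correlation,
    correlate_pattern,
    correlation_to_bl,
    domain_pattern,
    hex_ring_profile,
    legendre_design,
    pole_to_ql,
    predict_nanostructure_bl,
    predict_texture_bl,
    ring_modulation_pattern,
    ring_texture_components,
    scaling_experiment,
    simulate_ensemble,
    subtract_angular_mean,
    tune_lorentzian_width,
)


def ring_ensemble_bl(model, lattice, grid, n_d=50, seed=0, l_max=8):
    """Helper: ring-mode ensemble -> averaged correlation -> B_l."""
    config = SimConfig(n_patterns=n_d, mode="rings", seed=seed)
    patterns, _ = simulate_ensemble(config, lattice, model, grid)
    vol = average_correlations([subtract_angular_mean(p) for p in patterns])
    return correlation_to_bl(vol, l_max=l_max), vol


class TestLegendreDesign:
    def test_p0_column_is_ones(self):
        dphi = np.linspace(0, 2 * np.pi, 37)
        design = legendre_design(dphi, [0, 2, 4])
        np.testing.assert_allclose(design[:, 0], 1.0)

    def test_standard_values_at_90_degrees(self):
        design = legendre_design(np.array([np.pi / 2]), [0, 2, 4])
        assert design[0, 1] == pytest.approx(-0.5)
        assert design[0, 2] == pytest.approx(0.375)

    def test_ewald_reduces_to_small_angle(self):
        dphi = np.linspace(0, 2 * np.pi, 90)
        # q * lambda / 4 pi ~ 2e-3 -> designs agree to 1e-4
        q, wavelength = 0.5, 0.5  # nm^-1, angstrom
        assert q * (wavelength / 10) / (4 * np.pi) < 1e-2
        a = legendre_design(dphi, [2, 4])
        b = legendre_design(dphi, [2, 4], mapping="ewald", q=q,
                            wavelength=wavelength)
        assert np.max(np.abs(a - b)) < 1e-4

    def test_unknown_mapping(self):
        with pytest.raises(ValueError):
            legendre_design(np.array([0.0]), [2], mapping="conical")


def make_volume(values, n_q=1):
    return CorrelationVolume(
        values=np.broadcast_to(values, (n_q, n_q, values.size)).copy(),
        q_values=np.linspace(1.0, 1.0 + 0.1 * (n_q - 1), n_q),
        n_d=1,
    )


class TestCorrelationToBl:
    def test_legendre_basis_function_recovered(self):
        dphi = np.arange(360) * (2 * np.pi / 360)
        vol = make_volume(eval_legendre(2, np.cos(dphi)))
        bl = correlation_to_bl(vol, l_max=8)
        assert bl.matrix(2)[0, 0] == pytest.approx(1.0, abs=1e-10)
        for l in (0, 4, 6, 8):
            assert abs(bl.matrix(l)[0, 0]) < 1e-8

    def test_cos_two_dphi_decomposition(self):
        # cos 2x = (4 P2(cos x) - 1) / 3, so B2/B0 = -4
        dphi = np.arange(360) * (2 * np.pi / 360)
        bl = correlation_to_bl(make_volume(np.cos(2 * dphi)), l_max=6)
        assert bl.matrix(2)[0, 0] / bl.matrix(0)[0, 0] == pytest.approx(-4.0,
                                                                        rel=1e-9)
        assert abs(bl.matrix(4)[0, 0]) < 1e-10

    def test_round_trip_band_limited(self, rng):
        n_q, l_max = 5, 8
        ls = np.arange(0, l_max + 1, 2)
        mats = rng.standard_normal((ls.size, n_q, n_q))
        mats = 0.5 * (mats + np.transpose(mats, (0, 2, 1)))
        bl = BlMatrices(l_values=ls, matrices=mats,
                        q_values=np.linspace(1, 2, n_q))
        vol = bl_to_correlation(bl, n_phi=180)
        back = correlation_to_bl(vol, l_max=l_max)
        np.testing.assert_allclose(back.matrices, mats, atol=1e-8)
        resynth = bl_to_correlation(back, n_phi=180)
        assert np.max(np.abs(resynth.values - vol.values)) < 1e-8

    def test_symmetric_output(self, rng):
        n_q = 4
        values = rng.standard_normal((n_q, n_q, 64))
        values = 0.5 * (values + values.transpose(1, 0, 2)[:, :, ::-1]
                        .take(np.r_[0, np.arange(63, 0, -1)], axis=2))
        vol = CorrelationVolume(values=values, q_values=np.linspace(1, 2, n_q),
                                n_d=1)
        bl = correlation_to_bl(vol, l_max=6)
        for i in range(bl.l_values.size):
            np.testing.assert_allclose(bl.matrices[i], bl.matrices[i].T,
                                       atol=1e-10)

    def test_nphi_too_small_rejected(self):
        vol = make_volume(np.zeros(16))
        with pytest.raises(ValueError):
            correlation_to_bl(vol, l_max=12)

    def test_zero_matrices_synthesize_zero(self):
        bl = BlMatrices(l_values=np.array([0, 2]), matrices=np.zeros((2, 2, 2)),
                        q_values=np.array([1.0, 1.5]))
        assert np.all(bl_to_correlation(bl, n_phi=32).values == 0.0)

    def test_single_l_synthesis_matches_polynomial(self):
        bl = BlMatrices(l_values=np.array([4]), matrices=np.ones((1, 1, 1)),
                        q_values=np.array([1.0]))
        vol = bl_to_correlation(bl, n_phi=60)
        dphi = np.arange(60) * (2 * np.pi / 60)
        np.testing.assert_allclose(vol.values[0, 0],
                                   eval_legendre(4, np.cos(dphi)), atol=1e-12)


class TestBlPower:
    def test_pure_l2(self):
        ls = np.array([0, 2, 4])
        mats = np.zeros((3, 2, 2))
        mats[1] = np.eye(2)
        bl = BlMatrices(l_values=ls, matrices=mats, q_values=np.array([1.0, 2.0]))
        table = bl_power(bl)
        assert table.loc[table["l"] == 2, "fraction_of_l2"].iloc[0] == 1.0
        assert table.loc[table["l"] == 4, "fraction_of_l2"].iloc[0] == 0.0

    def test_zero_l2_rejected(self):
        bl = BlMatrices(l_values=np.array([2]), matrices=np.zeros((1, 1, 1)),
                        q_values=np.array([1.0]))
        with pytest.raises(ValueError):
            bl_power(bl)

    def test_sinusoidal_fractions_negligible(self, lattice, grid):
        model = OrientationModel(kind="sinusoidal", epsilon=0.1)
        bl, _ = ring_ensemble_bl(model, lattice, grid, n_d=20, seed=2)
        table = bl_power(bl).set_index("l")
        assert table.loc[4, "fraction_of_l2"] < 0.01
        assert table.loc[6, "fraction_of_l2"] < 0.01

    def test_lorentzian_exceeds_sinusoidal(self, lattice, grid):
        sin_bl, _ = ring_ensemble_bl(
            OrientationModel(kind="sinusoidal", epsilon=0.1),
            lattice, grid, n_d=20, seed=3,
        )
        lor_bl, _ = ring_ensemble_bl(
            OrientationModel(kind="lorentzian", gamma=0.35),
            lattice, grid, n_d=20, seed=3,
        )
        f_sin = bl_power(sin_bl).set_index("l").loc[4, "fraction_of_l2"]
        f_lor = bl_power(lor_bl).set_index("l").loc[4, "fraction_of_l2"]
        assert f_lor > f_sin


class TestPoleSpectrum:
    def test_uniform_all_zero(self):
        spec = pole_to_ql(OrientationModel(kind="uniform"))
        np.testing.assert_allclose(spec.q_l, 0.0, atol=1e-12)

    def test_linearity_in_epsilon(self):
        q1 = pole_to_ql(OrientationModel(kind="sinusoidal", epsilon=0.1))
        q2 = pole_to_ql(OrientationModel(kind="sinusoidal", epsilon=0.2))
        assert q2.coefficient(2) == pytest.approx(2 * q1.coefficient(2), rel=1e-9)

    def test_sinusoidal_populates_l2_only(self):
        spec = pole_to_ql(OrientationModel(kind="sinusoidal", epsilon=0.1))
        assert spec.coefficient(2) != 0.0
        for l in (4, 6, 8):
            assert abs(spec.coefficient(l)) < 1e-9 * abs(spec.coefficient(2))

    def test_lorentzian_decreasing_orders(self):
        spec = pole_to_ql(OrientationModel(kind="lorentzian", gamma=0.35))
        q2, q4, q6 = (abs(spec.coefficient(l)) for l in (2, 4, 6))
        assert q2 > q4 > q6 > 0


class TestPredictions:
    def test_uniform_texture_prediction_is_zero(self, grid):
        spec = pole_to_ql(OrientationModel(kind="uniform"))
        profile = np.ones(grid.n_q)
        bl = predict_texture_bl(spec, profile, grid.q_values, n_c=10)
        assert np.all(bl.matrices == 0.0)

    def test_texture_quadratic_in_nc(self, grid):
        spec = pole_to_ql(OrientationModel(kind="sinusoidal", epsilon=0.2))
        profile = np.linspace(1, 2, grid.n_q)
        b1 = predict_texture_bl(spec, profile, grid.q_values, n_c=3)
        b2 = predict_texture_bl(spec, profile, grid.q_values, n_c=6)
        np.testing.assert_allclose(b2.matrices, 4.0 * b1.matrices, atol=1e-12)

    def test_predicted_sinusoidal_l4_negligible(self, grid):
        spec = pole_to_ql(OrientationModel(kind="sinusoidal", epsilon=0.1))
        profile = np.ones(grid.n_q)
        bl = predict_texture_bl(spec, profile, grid.q_values, n_c=100)
        table = bl_power(bl).set_index("l")
        assert table.loc[4, "fraction_of_l2"] < 1e-6

    def test_texture_prediction_matches_measurement(self, lattice, grid):
        # ring-mode sinusoidal ensembles: the measured B2(q,q') equals the
        # (3/8) Q2^2 I0 I0' prediction
        eps = 0.1
        model = OrientationModel(kind="sinusoidal", epsilon=eps)
        bl, _vol = ring_ensemble_bl(model, lattice, grid, n_d=30, seed=6)
        profile = hex_ring_profile(lattice, grid.q_values, 0.05)
        predicted = predict_texture_bl(pole_to_ql(model), profile,
                                       grid.q_values, n_c=1)
        i10 = np.argmin(np.abs(grid.q_values - lattice.q10))
        measured = bl.matrix(2)[i10, i10]
        assert measured == pytest.approx(predicted.matrix(2)[i10, i10], rel=0.2)

    def test_nanostructure_linear_in_nc(self, ring_lattice, ring_grid):
        p = subtract_angular_mean(domain_pattern(ring_lattice, 0.0, ring_grid))
        single = correlation_to_bl(correlate_pattern(p), l_max=8)
        b1 = predict_nanostructure_bl(single, 1)
        b2 = predict_nanostructure_bl(single, 2)
        np.testing.assert_allclose(b1.matrices, single.matrices)
        np.testing.assert_allclose(b2.matrices, 2.0 * single.matrices)

    def test_single_domain_comb_against_quadrature_oracle(self, ring_lattice,
                                                          ring_grid):
        # oracle: dense-quadrature autocorrelation of the 60-degree comb,
        # fitted with an independently built Legendre Vandermonde matrix
        sigma = np.deg2rad(2.0)
        p = subtract_angular_mean(
            domain_pattern(ring_lattice, 0.7, ring_grid, sigma_phi=sigma)
        )
        single = correlation_to_bl(correlate_pattern(p), l_max=8)

        n_dense = 2880
        phi = np.arange(n_dense) * (2 * np.pi / n_dense)
        comb = np.zeros(n_dense)
        for k in range(6):
            delta = np.angle(np.exp(1j * (phi - 0.7 - k * np.pi / 3)))
            comb += np.exp(-0.5 * (delta / sigma) ** 2)
        comb -= comb.mean()
        dphi = ring_grid.phi_values
        oracle_c = np.array([
            np.mean(comb * np.roll(comb, -d))
            for d in range(0, n_dense, n_dense // 360)
        ])
        vander = np.polynomial.legendre.legvander(np.cos(dphi), 8)[:, ::2]
        coef, *_ = np.linalg.lstsq(vander, oracle_c, rcond=None)
        oracle = dict(zip([0, 2, 4, 6, 8], coef))
        for l in (2, 4, 6, 8):
            measured = single.matrix(l)[0, 0]
            assert measured == pytest.approx(oracle[l], rel=0.02)
            assert measured != 0.0


class TestBalance:
    def _single_domain_bl(self, ring_lattice, ring_grid):
        p = subtract_angular_mean(domain_pattern(ring_lattice, 0.0, ring_grid))
        return correlation_to_bl(correlate_pattern(p), l_max=8)

    def test_zero_epsilon_zero_ratio(self, ring_lattice, ring_grid):
        single = self._single_domain_bl(ring_lattice, ring_grid)
        spec = pole_to_ql(OrientationModel(kind="sinusoidal", epsilon=0.0))
        profile = np.ones(1)
        report = balance_ratio(
            predict_texture_bl(spec, profile, ring_grid.q_values, 10),
            predict_nanostructure_bl(single, 10),
            n_c=10,
        )
        assert report.ratio == 0.0
        assert np.isinf(report.crossover_nc)

    def test_ratio_linear_in_nc(self, ring_lattice, ring_grid):
        single = self._single_domain_bl(ring_lattice, ring_grid)
        spec = pole_to_ql(OrientationModel(kind="sinusoidal", epsilon=0.1))
        profile = np.ones(1)
        reports = [
            balance_ratio(
                predict_texture_bl(spec, profile, ring_grid.q_values, nc),
                predict_nanostructure_bl(single, nc),
                n_c=nc,
            )
            for nc in (5, 10)
        ]
        assert reports[1].ratio / reports[0].ratio == pytest.approx(2.0,
                                                                    abs=1e-10)
        assert reports[0].crossover_nc == pytest.approx(reports[1].crossover_nc,
                                                        rel=1e-9)

    def test_crossover_matches_simulation(self, ring_lattice, ring_grid):
        # empirical crossover: measured ensemble B_l split into the known
        # n_c * single-domain part and the remainder (texture)
        eps = 0.3
        model = OrientationModel(kind="sinusoidal", epsilon=eps)
        p = subtract_angular_mean(domain_pattern(ring_lattice, 0.0, ring_grid))
        single = correlation_to_bl(correlate_pattern(p), l_max=8)
        profile = np.array([p.meta.get("mean", 0.0)])

        def power(mats):
            return sum(
                abs(np.trace(np.atleast_2d(mats[i])))
                for i, l in enumerate(single.l_values) if l >= 2
            )

        ratios = []
        ncs = [16, 64]
        for i, nc in enumerate(ncs):
            config = SimConfig(n_domains=nc, n_patterns=150, mode="domains",
                               seed=60 + i)
            patterns, _ = simulate_ensemble(config, ring_lattice, model,
                                            ring_grid)
            vol = average_correlations(
                [subtract_angular_mean(q) for q in patterns]
            )
            measured = correlation_to_bl(vol, l_max=8)
            texture_mats = measured.matrices - nc * single.matrices
            ratios.append(power(texture_mats) / power(nc * single.matrices))
        # ratio grows linearly in n_c; extrapolate to ratio = 1
        slope = (ratios[1] - ratios[0]) / (ncs[1] - ncs[0])
        empirical_crossover = ncs[0] + (1.0 - ratios[0]) / slope

        mean_profile = np.array([
            domain_pattern(ring_lattice, 0.0, ring_grid).intensity.mean()
        ])
        nc_ref = 10
        report = balance_ratio(
            predict_texture_bl(pole_to_ql(model), mean_profile,
                               ring_grid.q_values, nc_ref),
            predict_nanostructure_bl(single, nc_ref),
            n_c=nc_ref,
        )
        assert report.crossover_nc == pytest.approx(empirical_crossover,
                                                    rel=1.0)  # within factor 2


class TestScalingExperiment:
    def test_exponents_light(self, ring_lattice, ring_grid):
        model = OrientationModel(kind="sinusoidal", epsilon=0.1)
        result = scaling_experiment([8, 32, 128], model, reps=60, seed=9,
                                    lattice=ring_lattice, grid=ring_grid)
        assert result.texture_exponent == pytest.approx(2.0, abs=0.3)
        assert result.nanostructure_exponent == pytest.approx(1.0, abs=0.3)

    def test_zero_epsilon_texture_ci_covers_zero(self, ring_lattice, ring_grid):
        model = OrientationModel(kind="uniform")
        config = SimConfig(n_domains=16, n_patterns=60, mode="domains", seed=13)
        patterns, _ = simulate_ensemble(config, ring_lattice, model, ring_grid)
        per_pattern = []
        for p in patterns:
            vol = correlate_pattern(subtract_angular_mean(p))
            texture, _nano = ring_texture_components(vol.values[0, 0])
            per_pattern.append(texture)
        per_pattern = np.asarray(per_pattern)
        half_width = 1.96 * per_pattern.std(ddof=1) / np.sqrt(per_pattern.size)
        assert abs(per_pattern.mean()) < half_width

    def test_too_few_nc_values(self):
        with pytest.raises(ValueError):
            scaling_experiment([8, 8, 8], OrientationModel(), reps=2)


def test_tune_lorentzian_width(lattice, grid):
    model = tune_lorentzian_width(0.06, lattice, grid)
    bl, _ = ring_ensemble_bl(model, lattice, grid, n_d=5, seed=1)
    frac4 = bl_power(bl).set_index("l").loc[4, "fraction_of_l2"]
    assert frac4 == pytest.approx(0.06, rel=0.05)
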