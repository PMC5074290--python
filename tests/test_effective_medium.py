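"""Mixing rules: polarizability, orientation averages, MG / Bruggeman / AP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from powderspec import (
    MixingScenario,
    ShapeSpec,
    SpectralGrid,
    averaged_permittivity,
    bruggeman,
    depolarization,
    effective_permittivity,
    from_oscillator_table,
    maxwell_garnett,
    orientational_average,
    permittivity,
    polarizability,
    powder_spectrum,
    peak_position,
)


def scenario(method="maxwell", f=0.1, eps_e=2.0, shape=None, volume=19.148):
    if shape is None:
        shape = depolarization(ShapeSpec("sphere"))
    return MixingScenario(method, f, eps_e, shape, volume)


class TestPolarizability:
    def test_no_contrast_gives_zero(self):
        L = depolarization(ShapeSpec("sphere")).tensor
        alpha = polarizability(2.0 * np.eye(3), 2.0, L, 100.0)
        np.testing.assert_allclose(alpha, 0.0, atol=1e-14)

    def test_isotropic_sphere_closed_form(self):
        eps_i, eps_e, v = 5.0 + 1.0j, 2.0, 77.0
        L = depolarization(ShapeSpec("sphere")).tensor
        alpha = polarizability(eps_i * np.eye(3), eps_e, L, v)
        expected = 3.0 * v * eps_e * (eps_i - eps_e) / (eps_i + 2.0 * eps_e)
        np.testing.assert_allclose(alpha, expected * np.eye(3), rtol=1e-12)

    def test_slab_closed_forms_along_and_across_normal(self):
        eps_i, eps_e, v = 4.0 + 0.5j, 2.0, 10.0
        axes = np.eye(3)
        L = depolarization(ShapeSpec("plate", (0, 0, 1)), axes).tensor  # normal x
        alpha = polarizability(eps_i * np.eye(3), eps_e, L, v)
        along = v * eps_e * (eps_i - eps_e) / eps_i
        transverse = v * (eps_i - eps_e)
        assert alpha[0, 0] == pytest.approx(along, rel=1e-12)
        assert alpha[1, 1] == pytest.approx(transverse, rel=1e-12)
        assert alpha[2, 2] == pytest.approx(transverse, rel=1e-12)


class TestOrientationalAverage:
    def test_isotropic_tensor_is_fixed_point(self):
        L = depolarization(ShapeSpec("sphere")).tensor
        a_mean, _ = orientational_average(4.2 * np.eye(3), L)
        assert a_mean == pytest.approx(4.2)

    def test_diagonal_tensor_averages_to_mean_eigenvalue(self):
        L = depolarization(ShapeSpec("sphere")).tensor
        a_mean, _ = orientational_average(np.diag([1.0, 2.0, 3.0]), L)
        assert a_mean == pytest.approx(2.0)

    def test_trace_average_matches_monte_carlo_rotations(self, rng):
        alpha = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        L = depolarization(ShapeSpec("ellipsoid", (0, 0, 1), z_ratio=2.0)).tensor
        n_rot = 100_000
        rots = Rotation.random(n_rot, random_state=314).as_matrix()
        # tensors co-rotate with the particle: lab average of R a R^T, R a L R^T
        for tensor, exact in (
            (alpha, orientational_average(alpha, L)[0]),
            (alpha @ L, orientational_average(alpha, L)[1]),
        ):
            lab = np.einsum("nij,jk,nlk->nil", rots, tensor, rots)
            mean = lab.mean(axis=0)
            iso = mean.trace() / 3.0
            sample_scale = np.std(lab.real, axis=0) + np.std(lab.imag, axis=0)
            se = sample_scale / np.sqrt(n_rot)
            # every component within 3 standard errors of (tr/3) * identity
            target = exact * np.eye(3)
            assert np.all(np.abs(mean - target) <= 3.0 * se + 1e-12)
            assert iso == pytest.approx(exact, rel=1e-10)


class TestMaxwellGarnett:
    def test_dilute_limit_returns_matrix(self, mgo_model):
        sc = scenario(f=1e-12, volume=mgo_model.cell_volume)
        eps_i = permittivity(mgo_model, np.linspace(300, 800, 20))
        eff = maxwell_garnett(sc, eps_i)
        np.testing.assert_allclose(eff.values, 2.0, atol=1e-9)

    def test_matches_textbook_scalar_formula_for_sphere(self):
        f, eps_e = 0.23, 2.5
        eps_i = 6.0 + 1.5j
        sc = scenario(f=f, eps_e=eps_e)
        eff = maxwell_garnett(sc, np.array([eps_i * np.eye(3)]))
        textbook = eps_e + 3 * f * eps_e * (eps_i - eps_e) / (
            eps_i + 2 * eps_e - f * (eps_i - eps_e)
        )
        assert eff.values[0] == pytest.approx(textbook, rel=1e-10)

    def test_dilute_froehlich_resonance_position(self, models):
        model = from_oscillator_table(models["mgo"], sigma=1.0)
        grid = SpectralGrid(500, 600, 0.1)
        sc = scenario(f=1e-6, volume=model.cell_volume)
        table = powder_spectrum(model, sc, grid)
        eps_s = 10.00302  # static permittivity of the model
        target = 388.3 * np.sqrt((eps_s + 2 * 2.0) / (3.14 + 2 * 2.0))
        peak = peak_position(table.frequencies, table.molar_absorption)
        assert abs(peak - target) <= grid.increment

    def test_pole_condition_for_lossless_sphere(self):
        # MG denominator pole: eps_i = -eps_e (2 + f) / (1 - f)
        f, eps_e = 0.3, 2.0
        pole = -eps_e * (2 + f) / (1 - f)
        sc = scenario(f=f, eps_e=eps_e)
        lo = maxwell_garnett(sc, np.array([(pole - 1e-3) * np.eye(3)])).values[0]
        hi = maxwell_garnett(sc, np.array([(pole + 1e-3) * np.eye(3)])).values[0]
        assert abs(lo) > 1e2 and abs(hi) > 1e2
        assert np.sign(lo.real) != np.sign(hi.real)

    def test_peak_frequency_decreases_with_volume_fraction(self, models):
        model = from_oscillator_table(models["mgo"], sigma=10.0)
        grid = SpectralGrid(300, 800, 0.2)
        peaks = []
        for f in (0.01, 0.1, 0.5, 0.9):
            table = powder_spectrum(
                model, scenario(f=f, volume=model.cell_volume), grid
            )
            peaks.append(peak_position(table.frequencies, table.molar_absorption))
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_passivity_across_fixture_grid(self, models):
        for name in ("mgo", "zno", "calcite"):
            model = from_oscillator_table(models[name], sigma=5.0)
            eps_i = permittivity(model, np.linspace(50, 1600, 200))
            for shape_kind in ("sphere", "plate", "needle"):
                shape = depolarization(ShapeSpec(shape_kind, (0, 0, 1)))
                sc = scenario(shape=shape, volume=model.cell_volume)
                eff = maxwell_garnett(sc, eps_i)
                assert eff.values.imag.min() > -1e-10


class TestBruggeman:
    def test_equal_phases_are_fixed_point(self):
        sc = scenario(method="bruggeman", f=0.4)
        eps = 2.0 + 0.0j
        eff = bruggeman(sc, np.array([eps * np.eye(3)] * 3))
        np.testing.assert_allclose(eff.values, eps, rtol=1e-7)

    def test_matches_exact_quadratic_root_for_isotropic_sphere(self, models):
        model = from_oscillator_table(models["mgo"], sigma=5.0)
        grid = np.linspace(300, 800, 60)
        eps_i = permittivity(model, grid)
        f, eps_e = 0.1, 2.0
        eff = bruggeman(
            scenario(method="bruggeman", f=f, volume=model.cell_volume), eps_i
        )
        e1 = eps_i[:, 0, 0]
        b = f * (2 * e1 - eps_e) + (1 - f) * (2 * eps_e - e1)
        disc = np.sqrt(b * b + 8 * e1 * eps_e)
        r1 = (b + disc) / 4.0
        r2 = (b - disc) / 4.0
        root = np.where(r1.imag > 0, r1, r2)
        np.testing.assert_allclose(eff.values, root, rtol=1e-6)
        assert eff.converged.all()

    def test_symmetric_under_phase_swap(self):
        # swapping (eps1, f) and (eps2, 1-f) leaves the root unchanged
        eps_a = (6.0 + 2.0j) * np.eye(3)
        f = 0.3
        sc = scenario(method="bruggeman", f=f, eps_e=2.0)
        direct = bruggeman(sc, np.array([eps_a])).values[0]
        # swapped: crystal is the "matrix" phase; emulate via tensor grid
        from powderspec.effective_medium import _iterate_bruggeman

        L = depolarization(ShapeSpec("sphere")).tensor
        phases = (((2.0 + 0j) * np.eye(3), 1 - f), (eps_a, f))
        swapped, ok = _iterate_bruggeman(direct, phases, L)
        assert ok
        assert swapped == pytest.approx(direct, rel=1e-8)

    def test_approaches_mg_in_dilute_limit(self, models):
        model = from_oscillator_table(models["mgo"], sigma=5.0)
        grid = np.linspace(300, 800, 26)
        eps_i = permittivity(model, grid)
        ratios = []
        for f in (1e-4, 1e-5, 1e-6):
            eb = bruggeman(
                scenario(method="bruggeman", f=f, volume=model.cell_volume), eps_i
            ).values
            em = maxwell_garnett(
                scenario(f=f, volume=model.cell_volume), eps_i
            ).values
            ratios.append(float(np.max(np.abs(eb - em) / np.abs(em - 2.0))))
        # convergence to the shared dilute limit is linear in f
        assert ratios[1] < 0.2 * ratios[0]
        assert ratios[2] < 0.2 * ratios[1]

    def test_unphysical_roots_are_flagged_not_silent(self, models):
        model = from_oscillator_table(models["mgo"], sigma=5.0)
        eps_i = permittivity(model, np.linspace(300, 800, 60))
        eff = bruggeman(
            scenario(method="bruggeman", f=0.1, volume=model.cell_volume), eps_i
        )
        # flags exist for every frequency; any negative-absorption value
        # must be marked non-passive
        assert eff.passive.shape == eff.values.shape
        bad = eff.values.imag < -1e-10
        assert np.all(~eff.passive[bad] | ~bad[bad])


class TestAveragedPermittivity:
    def test_f_zero_limit(self, mgo_model):
        eps_i = permittivity(mgo_model, np.linspace(300, 800, 10))
        eff = averaged_permittivity(
            scenario(method="ap", f=1e-12, volume=mgo_model.cell_volume), eps_i
        )
        np.testing.assert_allclose(eff.values, 2.0, atol=1e-9)

    def test_f_one_limit_recovers_crystal(self, mgo_model):
        eps_i = permittivity(mgo_model, np.array([100.0]))
        eff = averaged_permittivity(
            scenario(method="ap", f=1 - 1e-12, volume=mgo_model.cell_volume), eps_i
        )
        assert eff.values[0] == pytest.approx(eps_i[0].trace() / 3.0, rel=1e-9)

    def test_low_f_peaks_at_to_frequency(self, models):
        model = from_oscillator_table(models["mgo"], sigma=5.0)
        grid = SpectralGrid(300, 500, 0.2)
        table = powder_spectrum(
            model,
            scenario(method="ap", f=0.01, volume=model.cell_volume),
            grid,
        )
        peak = peak_position(table.frequencies, table.eps_eff.imag)
        assert peak == pytest.approx(388.3, abs=1.0)


def test_all_methods_coincide_at_vanishing_fraction(mgo_model):
    eps_i = permittivity(mgo_model, np.linspace(300, 800, 12))
    values = {}
    for method in ("maxwell", "bruggeman", "ap"):
        sc = scenario(method=method, f=1e-10, volume=mgo_model.cell_volume)
        values[method] = effective_permittivity(sc, eps_i).values
    for method, vals in values.items():
        np.testing.assert_allclose(vals, 2.0, atol=1e-6)


def test_scenario_validation():
    with pytest.raises(ValueError):
        scenario(f=0.0)
    with pytest.raises(ValueError):
        scenario(f=1.5)
    with pytest.raises(ValueError):
        scenario(eps_e=0.5)
    with pytest.raises(ValueError):
        scenario(method="nonsense")
    assert scenario(f=0.25, volume=50.0).number_density == pytest.approx(0.005)
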