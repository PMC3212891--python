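"""Ensemble averaging, the joint objective, and modulus recovery."""

import dataclasses

import numpy as np
import pytest

import embryoelast as ee


def _flat_grid(u_value, shape=(4, 5)):
    ny, nx = shape
    return ee.DisplacementGrid(
        x=np.arange(nx) * 0.024,
        y=np.arange(ny) * 0.024,
        u=np.broadcast_to(np.asarray(u_value, float), (ny, nx, 2)).copy(),
    )


class TestNormalizeAndAverage:
    def test_identical_fields_equal_forces(self):
        g = _flat_grid([2.0, -1.0])
        ens = ee.normalize_and_average([g, g, g], [200e-9] * 3)
        assert np.allclose(ens.mean.u, np.array([2.0, -1.0]) / 200.0)
        assert np.allclose(ens.sd, 0.0)
        assert ens.n == 3

    def test_linear_scaling_consistency(self):
        g1 = _flat_grid([2.0, -1.0])
        g2 = _flat_grid([4.0, -2.0])
        ens = ee.normalize_and_average([g1, g2], [150e-9, 300e-9])
        assert np.allclose(ens.mean.u, np.array([2.0, -1.0]) / 150.0)
        assert np.allclose(ens.sd, 0.0)

    def test_mismatched_lattices_rejected(self):
        g1 = _flat_grid([1.0, 0.0], shape=(4, 5))
        g2 = _flat_grid([1.0, 0.0], shape=(5, 4))
        with pytest.raises(ValueError, match="lattice"):
            ee.normalize_and_average([g1, g2], [1e-7, 1e-7])

    def test_sd_is_standard_error_of_mean(self):
        """16 replicates with i.i.d. noise sigma: sd ~= sigma / (F * 4),
        verified over 200 Monte-Carlo repetitions."""
        rng = np.random.default_rng(4)
        sigma, F = 0.8, 200e-9
        base = _flat_grid([3.0, 1.0])
        collected = []
        for _ in range(200):
            reps = [
                dataclasses.replace(
                    base, u=base.u + rng.normal(0, sigma, base.u.shape)
                )
                for _ in range(16)
            ]
            ens = ee.normalize_and_average(reps, [F] * 16)
            collected.append(np.mean(ens.sd))
        expected = sigma / (F * 1e9 * 4.0)
        assert np.mean(collected) == pytest.approx(expected, rel=0.05)

    def test_valid_mask_intersection(self):
        g1 = _flat_grid([1.0, 0.0])
        g2 = _flat_grid([1.0, 0.0])
        g2.valid[0, 0] = False
        ens = ee.normalize_and_average([g1, g2], [1e-7, 1e-7])
        assert not ens.mean.valid[0, 0]
        assert ens.mean.valid[1, 1]


@pytest.fixture(scope="module")
def noiseless_cases(materials, geometry):
    exp = ee.synth_measurement_set(
        materials, geometry,
        [ee.midline_load(190.0), ee.pellucida_load(200.0)],
        ee.NoiseSpec(per_measurement_snr=1e12, replicates_per_load=1,
                     n_embryos=1, seed=0),
        target_nodes=2500,
    )
    return [
        ee.LoadCase(load=c.load, measured=c.truth_grid, mesh=c.mesh)
        for c in exp.cases
    ]


class TestObjective:
    def test_zero_at_generating_moduli(self, noiseless_cases, geometry):
        err = ee.objective(ee.DEFAULT_MODULI_PA, noiseless_cases, geometry, 0.3)
        assert err == pytest.approx(0.0, abs=1e-16)

    def test_two_case_error_is_sum_of_single_case_errors(
        self, noiseless_cases, geometry
    ):
        wrong = {r: 2.0 * v for r, v in ee.DEFAULT_MODULI_PA.items()}
        e_both = ee.objective(wrong, noiseless_cases, geometry, 0.3)
        e_each = [
            ee.objective(wrong, [c], geometry, 0.3) for c in noiseless_cases
        ]
        assert e_both == pytest.approx(sum(e_each), rel=1e-12)
        assert e_both > 0  # doubling all moduli halves u: residual is nonzero

    def test_far_worse_at_bad_initial_guess(self, noiseless_cases, geometry):
        """Objective at truth is < 1e-6 of its value at the 100 Pa guess."""
        e_truth = ee.objective(ee.DEFAULT_MODULI_PA, noiseless_cases, geometry, 0.3)
        e_bad = ee.objective(
            {r: 100.0 for r in geometry.region_names}, noiseless_cases, geometry, 0.3
        )
        assert e_truth <= 1e-6 * e_bad


class TestFitModuli:
    def test_init_at_truth_converges_immediately(self, noiseless_cases, geometry):
        fit = ee.fit_moduli(noiseless_cases, geometry, init=ee.DEFAULT_MODULI_PA)
        assert fit.converged
        assert fit.n_iterations <= 1
        for r, v in ee.DEFAULT_MODULI_PA.items():
            assert fit.youngs_moduli[r] == pytest.approx(v, rel=1e-6)

    def test_bad_init_recovers_truth(self, noiseless_cases, geometry):
        """From 100 Pa everywhere the bounded fit converges to the
        generating moduli within 100 iterations."""
        fit = ee.fit_moduli(
            noiseless_cases, geometry, init={r: 100.0 for r in geometry.region_names}
        )
        assert fit.converged
        assert fit.n_iterations <= 100
        for r, v in ee.DEFAULT_MODULI_PA.items():
            assert fit.youngs_moduli[r] == pytest.approx(v, rel=1e-4)

    def test_error_trace_monotone_nonincreasing(self, noiseless_cases, geometry):
        fit = ee.fit_moduli(
            noiseless_cases, geometry, init={r: 100.0 for r in geometry.region_names}
        )
        assert np.all(np.diff(fit.error_trace) <= 1e-12)

    def test_residual_rms_definition(self, materials, geometry):
        """residual_rms = sqrt(error / n_valid_sites); e.g. a total error of
        500 um^2 over the 40x32 lattice pair of sites gives ~0.6 um/site."""
        exp = ee.synth_measurement_set(
            materials, geometry, [ee.midline_load(190.0)],
            ee.NoiseSpec(seed=5), target_nodes=1500,
        )
        c = exp.cases[0]
        ens = ee.normalize_and_average(c.replicates, c.forces_n)
        fit = ee.fit_moduli(
            [ee.LoadCase(load=c.load, measured=ens, mesh=c.mesh)],
            geometry, init=ee.DEFAULT_MODULI_PA,
        )
        assert fit.residual_rms_um == pytest.approx(
            np.sqrt(fit.final_error_um2 / fit.n_sites), rel=1e-9
        )
        # the convention: 500 um^2 over 1280 sites would read ~0.625 um/site
        assert np.sqrt(500.0 / 1280.0) == pytest.approx(0.625, abs=0.001)

    def test_init_outside_bounds_rejected(self, noiseless_cases, geometry):
        with pytest.raises(ValueError, match="bounds"):
            ee.fit_moduli(noiseless_cases, geometry,
                          init={r: 1.0 for r in geometry.region_names})

    def test_nonconvergence_returns_best_point(self, materials, geometry):
        exp = ee.synth_measurement_set(
            materials, geometry, [ee.midline_load(190.0)],
            ee.NoiseSpec(seed=6, n_embryos=1), target_nodes=1200,
        )
        c = exp.cases[0]
        case = ee.LoadCase(load=c.load, measured=c.replicates[0], mesh=c.mesh)
        fit = ee.fit_moduli([case], geometry,
                            init={r: 100.0 for r in geometry.region_names},
                            max_iter=2)
        assert not fit.converged
        assert np.isfinite(fit.final_error_um2)


class TestGeometryFit:
    def test_truth_init_returns_truth(self, geometry, materials):
        exp = ee.synth_measurement_set(
            materials, geometry,
            [ee.midline_load(190.0), ee.pellucida_load(200.0)],
            ee.NoiseSpec(per_measurement_snr=1e12, replicates_per_load=1,
                         n_embryos=1, seed=2),
            target_nodes=1200,
        )
        cases = [
            ee.LoadCase(load=c.load, measured=c.truth_grid, mesh=c.mesh)
            for c in exp.cases
        ]
        fit, geo = ee.fit_geometry_and_moduli(
            cases, geometry, init=ee.DEFAULT_MODULI_PA, max_iter=30
        )
        assert geo.pellucida_semi_axes == pytest.approx(
            geometry.pellucida_semi_axes, rel=0.02
        )
        for r, v in ee.DEFAULT_MODULI_PA.items():
            assert fit.youngs_moduli[r] == pytest.approx(v, rel=0.05)

    def test_requires_two_cases(self, geometry, noiseless_cases):
        with pytest.raises(ValueError, match="2 load cases"):
            ee.fit_geometry_and_moduli(noiseless_cases[:1], geometry)

    def test_perturbed_radii_recovered_and_beat_fixed_fit(self, materials):
        """Pellucida semi-axes +10% in the generator are recovered within 5%,
        and the joint fit ends below the wrong-fixed-radii fit."""
        true_geom = ee.build_default_geometry(
            4, {"pellucida_semi_axes": (1.15 * 1.1, 2.8 * 1.1)}
        )
        ref_geom = ee.build_default_geometry(4)
        wide = lambda load: ee.default_lattice(center=load.position,
                                               spacing_um=80.0)
        exp = ee.synth_measurement_set(
            materials, true_geom,
            [ee.midline_load(190.0), ee.pellucida_load(200.0)],
            ee.NoiseSpec(per_measurement_snr=1e12, replicates_per_load=1,
                         n_embryos=1, seed=3),
            target_nodes=1500, lattice_for=wide,
        )
        cases = []
        for c in exp.cases:
            mesh = ee.generate_mesh(ref_geom, target_nodes=1500,
                                    refine_points=[c.load.position])
            cases.append(ee.LoadCase(load=c.load, measured=c.truth_grid, mesh=mesh))
        joint, geo = ee.fit_geometry_and_moduli(
            cases, ref_geom, init=ee.DEFAULT_MODULI_PA, max_iter=60
        )
        assert geo.pellucida_semi_axes == pytest.approx(
            true_geom.pellucida_semi_axes, rel=0.05
        )
        fixed = ee.fit_moduli(cases, ref_geom, init=ee.DEFAULT_MODULI_PA)
        assert joint.final_error_um2 < fixed.final_error_um2


class TestBootstrap:
    def test_bootstrap_spread_positive_and_centered(self, materials, geometry):
        exp = ee.synth_measurement_set(
            materials, geometry, [ee.midline_load(190.0)],
            ee.NoiseSpec(seed=8), target_nodes=1200,
        )
        c = exp.cases[0]
        draws = ee.bootstrap_fit(
            [(c.replicates, c.forces_n)], [c.load], [c.mesh], geometry,
            n_bootstrap=5, seed=1, init=ee.DEFAULT_MODULI_PA,
        )
        for r in geometry.region_names:
            assert len(draws[r]) == 5
            assert np.all(draws[r] > 0)
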