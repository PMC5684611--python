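"""Forward-solver checks against closed-form fields and physical invariants."""

import numpy as np
import pytest

from elfdosim import (
    UniformFieldSource,
    analytic_sphere_field,
    build_homogeneous_ellipsoid,
    build_homogeneous_sphere,
    solve_scalar_potential,
    vector_potential,
)


class TestVectorPotential:
    def test_cross_product_identity(self):
        src = UniformFieldSource(theta_deg=0.0, phi_deg=0.0)  # B along +z
        d = 0.01
        A = vector_potential(src, np.array([d, 0.0, 0.0]), np.zeros(3))
        assert np.allclose(A, [0.0, src.B_rms_T * d / 2.0, 0.0])

    def test_zero_at_center(self):
        src = UniformFieldSource(theta_deg=37.0, phi_deg=-100.0)
        c = np.array([0.1, -0.2, 0.3])
        assert np.allclose(vector_potential(src, c, c), 0.0)

    def test_discrete_curl_recovers_B(self):
        # finite-difference curl of A on a 10^3 grid must equal B
        src = UniformFieldSource(theta_deg=63.0, phi_deg=20.0)
        h = 0.005
        ax = (np.arange(10) + 0.5) * h
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        A = vector_potential(src, pts, np.full(3, 5 * h / 2))
        curl = np.empty(3)
        # interior central differences; A is linear so truncation is exact
        dA = [[np.gradient(A[..., c], h, axis=a) for a in range(3)] for c in range(3)]
        curl[0] = np.mean(dA[2][1] - dA[1][2])
        curl[1] = np.mean(dA[0][2] - dA[2][0])
        curl[2] = np.mean(dA[1][0] - dA[0][1])
        assert np.allclose(curl, src.B_vector, rtol=1e-10, atol=1e-16)
        div = dA[0][0] + dA[1][1] + dA[2][2]
        assert np.max(np.abs(div)) < 1e-12


class TestSourceValidation:
    def test_angle_ranges_enforced(self):
        with pytest.raises(ValueError):
            UniformFieldSource(theta_deg=200.0)
        with pytest.raises(ValueError):
            UniformFieldSource(phi_deg=190.0)

    def test_direction_convention(self):
        assert np.allclose(UniformFieldSource(theta_deg=0).direction, [0, 0, 1])
        assert np.allclose(
            UniformFieldSource(theta_deg=90, phi_deg=90).direction, [0, 1, 0], atol=1e-15
        )


class TestAnalyticSphere:
    def test_formula_value(self):
        assert analytic_sphere_field(50.0, 2e-4, 0.1) == pytest.approx(3.1416e-3, rel=1e-4)

    def test_zero_axis_and_linearity(self):
        assert analytic_sphere_field(50.0, 2e-4, 0.0) == 0.0
        assert analytic_sphere_field(50.0, 2e-4, 0.2) == 2 * analytic_sphere_field(50.0, 2e-4, 0.1)

    def test_negative_rho_refused(self):
        with pytest.raises(ValueError):
            analytic_sphere_field(50.0, 2e-4, -0.1)


class TestScalarPotentialSolver:
    def test_sphere_field_matches_oracle_voxelwise(self, sphere_small, sphere_small_solution):
        # relative L2 error of the whole field against |E| = pi f B rho
        sol = sphere_small_solution
        mask = sphere_small.conductive_mask()
        x, y, z = np.meshgrid(*sphere_small.voxel_centers_axes(), indexing="ij", sparse=True)
        rho = np.broadcast_to(np.sqrt(x**2 + y**2) + 0 * z, sphere_small.shape)[mask]
        Ea = analytic_sphere_field(50.0, 200e-6, rho)
        err = np.linalg.norm(sol.E_mag_rms[mask] - Ea) / np.linalg.norm(Ea)
        assert err < 0.25  # staircase-limited at 3 mm voxels; see convergence test

    def test_orientation_invariance_of_sphere_distribution(self):
        # spherical symmetry: any (theta, phi) gives the same |E| distribution
        p = build_homogeneous_sphere(0.05, sigma=0.1, voxel_size_m=0.002)
        first = solve_scalar_potential(p, UniformFieldSource(theta_deg=0.0, phi_deg=0.0))
        other = solve_scalar_potential(p, UniformFieldSource(theta_deg=67.0, phi_deg=-120.0))
        mask = p.conductive_mask()
        a = np.sort(first.E_mag_rms[mask])
        b = np.sort(other.E_mag_rms[mask])
        # quantile-function distance relative to the distribution scale
        assert np.linalg.norm(a - b) / np.linalg.norm(a) < 0.01
        assert abs(np.percentile(b, 99) / np.percentile(a, 99) - 1) < 0.01

    def test_linear_in_B(self, sphere_small, sphere_small_solution):
        doubled = solve_scalar_potential(
            sphere_small,
            UniformFieldSource(B_rms_T=400e-6, theta_deg=0.0, phi_deg=0.0),
        )
        mask = sphere_small.conductive_mask()
        assert np.allclose(
            doubled.E_mag_rms[mask], 2 * sphere_small_solution.E_mag_rms[mask], rtol=1e-12
        )

    def test_sigma_scale_invariance_homogeneous(self, sphere_small_solution):
        p10 = build_homogeneous_sphere(0.03, sigma=1.0, voxel_size_m=0.003)
        sol10 = solve_scalar_potential(p10, UniformFieldSource(theta_deg=0.0, phi_deg=0.0))
        assert np.allclose(
            sol10.E_mag_rms, sphere_small_solution.E_mag_rms, rtol=1e-9, atol=1e-12
        )

    def test_mirror_symmetry_phi(self):
        # phantom symmetric under y -> -y: phi and -phi give identical
        # per-tissue E-magnitude distributions
        p = build_homogeneous_ellipsoid((0.03, 0.04, 0.05), sigma=0.1, voxel_size_m=0.004)
        mask = p.conductive_mask()
        a = solve_scalar_potential(p, UniformFieldSource(theta_deg=70, phi_deg=55))
        b = solve_scalar_potential(p, UniformFieldSource(theta_deg=70, phi_deg=-55))
        q = np.linspace(1, 99, 25)
        assert np.allclose(
            np.percentile(a.E_mag_rms[mask], q), np.percentile(b.E_mag_rms[mask], q), rtol=1e-6
        )

    def test_current_conservation(self, sphere_small, sphere_small_solution):
        # independent recomputation of the net current out of each voxel
        p, sol = sphere_small, sphere_small_solution
        sigma = p.sigma_grid()
        mask = sigma > 0
        h = p.voxel_size_m
        src = sol.source
        ax = p.voxel_centers_axes()
        ii, jj, kk = np.nonzero(mask)
        center = np.array([ax[0][ii].mean(), ax[1][jj].mean(), ax[2][kk].mean()])
        net = np.zeros(p.shape)
        scale = 0.0
        for axis in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(None, -1)
            sl_hi[axis] = slice(1, None)
            s_lo, s_hi = sigma[tuple(sl_lo)], sigma[tuple(sl_hi)]
            both = (s_lo > 0) & (s_hi > 0)
            sf = np.where(both, 2 * s_lo * s_hi / np.where(s_lo + s_hi > 0, s_lo + s_hi, 1), 0.0)
            dpsi = (sol.psi[tuple(sl_hi)] - sol.psi[tuple(sl_lo)]) / h
            coords = list(np.meshgrid(*ax, indexing="ij", sparse=False))
            fc = coords[axis][tuple(sl_lo)] + h / 2
            rel = [coords[c][tuple(sl_lo)] - center[c] for c in range(3)]
            rel[axis] = fc - center[axis]
            B = src.B_vector
            a_n = 0.5 * (
                B[(axis + 1) % 3] * rel[(axis + 2) % 3] - B[(axis + 2) % 3] * rel[(axis + 1) % 3]
            )
            flux = sf * (dpsi + a_n) * h * h
            net[tuple(sl_lo)] += flux
            net[tuple(sl_hi)] -= flux
            scale += np.abs(flux).sum()
        # total imbalance is bounded by the solver's relative residual
        assert np.linalg.norm(net[mask]) <= 1e-6 * scale

    def test_non_convergence_raises_with_residual(self, sphere_small):
        from elfdosim import SolverError

        with pytest.raises(SolverError) as err:
            solve_scalar_potential(
                sphere_small, UniformFieldSource(theta_deg=0, phi_deg=0), tol=1e-8, max_iter=2
            )
        assert err.value.residual is not None

    def test_empty_phantom_refused(self):
        from elfdosim.phantoms import AIR, VoxelPhantom

        p = VoxelPhantom(np.zeros((5, 5, 5), dtype=np.int16), 0.002, [AIR])
        with pytest.raises(ValueError, match="no conductive"):
            solve_scalar_potential(p, UniformFieldSource())
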