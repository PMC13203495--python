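"""Viscoelastic solid core: relaxation modulus, Maxwell stress update,
element assembly, explicit time stepping."""

import numpy as np
import pytest

from nestedfsi.solid import (SolidMesh, SolidState, StressState,
                             ViscoelasticMaterial, element_strains,
                             internal_force, relaxation_modulus, solid_step,
                             update_viscoelastic_stress)

BRAINISH = ViscoelasticMaterial(
    long_term_shear_modulus=800.0, mode_moduli=(600.0,),
    relaxation_times=(0.05,), density=1040.0, bulk_modulus=5e4)


def single_triangle(material=BRAINISH):
    nodes = np.array([[0.0, 0.0], [0.01, 0.0], [0.0, 0.01]])
    return SolidMesh(nodes=nodes, elements=np.array([[0, 1, 2]]),
                     material=material, name="tri")


class TestRelaxationModulus:
    def test_limits_and_single_mode_value(self):
        mat = ViscoelasticMaterial(1000.0, (500.0,), (0.1,))
        assert relaxation_modulus(0.0, mat) == pytest.approx(1500.0)
        assert relaxation_modulus(1e3, mat) == pytest.approx(1000.0)
        assert relaxation_modulus(0.1, mat) == pytest.approx(
            1000.0 + 500.0 / np.e)

    def test_monotone_non_increasing(self):
        mat = ViscoelasticMaterial(900.0, (400.0, 250.0), (0.02, 0.6))
        t = np.linspace(0, 3, 400)
        g = relaxation_modulus(t, mat)
        assert np.all(np.diff(g) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            relaxation_modulus(-0.1, BRAINISH)


class TestMaxwellUpdate:
    def test_zero_strain_history_zero_stress(self):
        st = StressState.zeros(1, 1)
        st = update_viscoelastic_stress(np.zeros((1, 4)), 1e-3, st, BRAINISH)
        np.testing.assert_allclose(st.total, 0.0)

    def test_constant_strain_relaxes_to_equilibrium(self):
        """Held strain for t >> tau: total stress converges to the
        equilibrium branch alone."""
        eps = np.array([[2e-3, -1e-3, 0.0, 5e-4]])
        dt = 1e-3
        st = StressState.zeros(1, 1)
        for _ in range(2000):  # 2 s >> tau = 0.05 s
            st = update_viscoelastic_stress(eps, dt, st, BRAINISH)
        np.testing.assert_allclose(st.total, st.equilibrium,
                                   atol=1e-9 * np.abs(st.equilibrium).max())

    def test_step_strain_matches_hereditary_integral_oracle(self):
        """Step deviatoric strain: recurrence history must match the
        convolution result sigma(t) = 2 G(t) eps0 within 1% at dt = tau/100."""
        tau = 0.05
        dt = tau / 100.0
        e0 = 1e-3
        eps = np.array([[e0, -e0, 0.0, 0.0]])  # purely deviatoric, traceless
        st = StressState.zeros(1, 1)
        rel_err = []
        for n in range(1, 301):
            st = update_viscoelastic_stress(eps, dt, st, BRAINISH)
            expected = 2.0 * relaxation_modulus(n * dt, BRAINISH) * e0
            rel_err.append(abs(st.total[0, 0] - expected) / expected)
        assert max(rel_err) < 0.01

    def test_convergence_under_dt_refinement(self):
        """Halving dt at fixed physical time shrinks the hereditary-integral
        error (first order or better)."""
        tau, e0, t_end = 0.05, 1e-3, 0.1
        eps = np.array([[e0, -e0, 0.0, 0.0]])

        def err(dt):
            st = StressState.zeros(1, 1)
            n = int(round(t_end / dt))
            for _ in range(n):
                st = update_viscoelastic_stress(eps, dt, st, BRAINISH)
            expected = 2.0 * relaxation_modulus(t_end, BRAINISH) * e0
            return abs(st.total[0, 0] - expected)

        assert err(tau / 200) < 0.6 * err(tau / 50)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            update_viscoelastic_stress(np.zeros((1, 4)), 0.0,
                                       StressState.zeros(1, 1), BRAINISH)


class TestInternalForce:
    def test_zero_displacement_zero_force(self):
        mesh = single_triangle()
        state = SolidState.zeros(mesh)
        np.testing.assert_allclose(internal_force(mesh, state), 0.0)

    def test_rigid_motion_patch(self):
        """Rigid translation and small rigid rotation produce zero strain,
        hence zero internal force."""
        mesh = single_triangle()
        state = SolidState.zeros(mesh)
        state.displacements[:] = [1e-3, -2e-3]
        np.testing.assert_allclose(internal_force(mesh, state), 0.0,
                                   atol=1e-12)
        # linearised rigid rotation: u = theta * (-y, x)
        th = 1e-5
        state.displacements = th * np.stack(
            [-mesh.nodes[:, 1], mesh.nodes[:, 0]], axis=1)
        f = internal_force(mesh, state)
        # forces scale like G * L * theta; demand many orders below that
        scale = BRAINISH.long_term_shear_modulus * 0.01 * th
        assert np.abs(f).max() < 1e-8 * scale + 1e-15

    def test_uniaxial_stretch_matches_hand_assembly(self):
        """Uniaxial stretch of one right triangle against the closed-form
        plane-strain stiffness action."""
        mesh = single_triangle()
        state = SolidState.zeros(mesh)
        u1 = 1e-4
        state.displacements[1] = [u1, 0.0]  # stretch along x
        f = internal_force(mesh, state)
        # hand assembly: exx = u1/L, sigma_xx = (K + 4G/3) exx, and the
        # traction integrates over the element area A with B^T
        L = 0.01
        exx = u1 / L
        K, G = BRAINISH.bulk_modulus, BRAINISH.long_term_shear_modulus
        sxx = K * exx + 2 * G * (exx - exx / 3.0)
        syy = K * exx + 2 * G * (-exx / 3.0)
        A = 0.5 * L * L
        # dN/dx = [-1/L, 1/L, 0], dN/dy = [-1/L, 0, 1/L]
        expected = np.zeros((3, 2))
        expected[:, 0] = A * sxx * np.array([-1 / L, 1 / L, 0.0])
        expected[:, 1] = A * syy * np.array([-1 / L, 0.0, 1 / L])
        np.testing.assert_allclose(f, expected, rtol=1e-12)

    def test_degenerate_element_named(self):
        nodes = np.array([[0.0, 0.0], [0.01, 0.0], [0.02, 0.0]])
        with pytest.raises(ValueError, match="element 0"):
            SolidMesh(nodes=nodes, elements=np.array([[0, 1, 2]]),
                      material=BRAINISH, name="bad")


class TestSolidStep:
    def test_oscillator_period_within_1_percent(self):
        """Free node on one element: the oscillation period must match
        2 pi sqrt(m / k) with k probed from the linear stiffness action."""
        mat = ViscoelasticMaterial(2000.0, (), (), density=1200.0,
                                   bulk_modulus=8e4)
        mesh = single_triangle(mat)
        mesh.fixed[:] = [True, False, True]
        state = SolidState.zeros(mesh)
        # numerically probe the diagonal stiffness seen by node 1 along x
        probe = SolidState.zeros(mesh)
        du = 1e-6
        probe.displacements[1, 0] = du
        k = internal_force(mesh, probe)[1, 0] / du
        m = mesh.node_mass[1]
        period = 2.0 * np.pi * np.sqrt(m / k)
        dt = period / 200.0
        u0 = 1e-5
        state.displacements[1, 0] = u0
        # record zero crossings of displacement over several periods
        prev = u0
        crossings = []
        for n in range(1, 1400):
            solid_step(mesh, state, dt)
            cur = state.displacements[1, 0]
            if prev > 0 >= cur or prev < 0 <= cur:
                # linear interpolation of the crossing time
                frac = prev / (prev - cur)
                crossings.append((n - 1 + frac) * dt)
            prev = cur
        assert len(crossings) >= 6
        half_periods = np.diff(crossings)
        measured = 2.0 * np.mean(half_periods)
        assert measured == pytest.approx(period, rel=0.01)

    def test_zero_force_uniform_motion(self):
        mesh = single_triangle()
        state = SolidState.zeros(mesh)
        v = np.array([0.01, -0.02])
        state.velocities[:] = v
        dt = 1e-4
        for _ in range(100):
            solid_step(mesh, state, dt)
        np.testing.assert_allclose(state.displacements,
                                   np.tile(v * 100 * dt, (3, 1)), rtol=1e-9)

    def test_damped_free_vibration_energy_non_increasing(self):
        """With mass-proportional damping and no forcing, mechanical energy
        (kinetic + stored elastic) must decay."""
        mat = ViscoelasticMaterial(2000.0, (), (), density=1200.0,
                                   bulk_modulus=8e4)
        mesh = single_triangle(mat)
        mesh.fixed[:] = [True, False, True]
        mesh.damping_coefficient = 20.0
        state = SolidState.zeros(mesh)
        state.displacements[1, 0] = 1e-5
        dt = 2e-5

        def energy():
            ke = 0.5 * np.sum(mesh.node_mass[:, None] * state.velocities**2)
            eps = element_strains(mesh, state.displacements)
            # stored elastic energy of the equilibrium branch
            tr = eps[:, 0] + eps[:, 1] + eps[:, 2]
            dev = eps.copy()
            dev[:, :3] -= (tr / 3.0)[:, None]
            dev_sq = np.sum(dev[:, :3]**2, axis=1) + 2 * dev[:, 3]**2
            se = np.sum(mesh.areas * (0.5 * mat.bulk_modulus * tr**2
                                      + mat.long_term_shear_modulus * dev_sq))
            return ke + se

        energies = [energy()]
        for _ in range(40):
            for _ in range(50):
                solid_step(mesh, state, dt)
            energies.append(energy())
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-12 * energies[0])
        assert energies[-1] < 0.5 * energies[0]

    def test_nan_detection_aborts_with_step(self):
        mesh = single_triangle()
        state = SolidState.zeros(mesh)
        state.displacements[1] = [np.nan, 0.0]
        from nestedfsi.solid import SolidInstabilityError
        with pytest.raises(SolidInstabilityError, match="step"):
            solid_step(mesh, state, 1e-4, step=7)
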