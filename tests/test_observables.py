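"""Fidelity, reduced density matrices, measurement planning, and tomography."""

import numpy as np
import pytest

from preboq.observables import (
    electron_density,
    fidelity,
    fractional_occupation,
    joint_density,
    nuclear_density,
    one_rdm,
    one_rdm_from_pauli,
    plan_density_measurements,
    q_resolved_rdm,
    real_space_resolution,
    sample_expectation,
)
from preboq.operator_algebra import HilbertLayout
from preboq.propagation import exact_evolve, prepare_initial_state
from preboq.vibronic_hamiltonian import ModeSet, VibronicState


def random_state(layout, seed=0):
    rng = np.random.default_rng(seed)
    amps = rng.normal(size=layout.dim) + 1j * rng.normal(size=layout.dim)
    return VibronicState(amps / np.linalg.norm(amps), layout)


class TestFidelity:
    def test_self_fidelity_is_one(self):
        layout = HilbertLayout(2, (3,))
        psi = random_state(layout)
        assert fidelity(psi, psi) == pytest.approx(1.0)

    def test_orthogonal_states_give_zero(self):
        layout = HilbertLayout(1, ())
        a = VibronicState(np.array([1.0, 0.0]), layout)
        b = VibronicState(np.array([0.0, 1.0]), layout)
        assert fidelity(a, b) == 0.0

    def test_mixed_state_fidelity_is_expectation(self):
        layout = HilbertLayout(1, ())
        rho = np.diag([0.7, 0.3]).astype(complex)
        ref = VibronicState(np.array([1.0, 0.0]), layout)
        assert fidelity(rho, ref) == pytest.approx(0.7)

    def test_dimension_mismatch(self):
        layout = HilbertLayout(1, ())
        with pytest.raises(ValueError):
            fidelity(np.zeros(4), VibronicState(np.array([1.0, 0.0]), layout))


class TestRDM:
    def test_onv_occupations(self):
        modes = ModeSet((1.0,), (0.0,), (2,))
        layout = modes.layout(4)
        psi = prepare_initial_state((1, 0, 1, 0), layout, modes)
        assert fractional_occupation(psi, layout, 0) == pytest.approx(1.0)
        assert fractional_occupation(psi, layout, 1) == pytest.approx(0.0)
        rdm = one_rdm(psi, layout)
        assert np.trace(rdm).real == pytest.approx(2.0)

    def test_pauli_route_equals_direct_contraction(self):
        layout = HilbertLayout(4, (3,))
        psi = random_state(layout, seed=4)
        direct = one_rdm(psi, layout)
        via_pauli = one_rdm_from_pauli(psi, layout)
        assert np.abs(direct - via_pauli).max() < 1e-12
        # physical 1RDM: Hermitian with eigenvalues in [0, 1]
        evals = np.linalg.eigvalsh(direct)
        assert evals.min() > -1e-10 and evals.max() < 1 + 1e-10


class TestMeasurementPlanning:
    def test_model_basis_needs_twelve_settings_six_with_spin(self):
        settings, count = plan_density_measurements(4, [(0, 1), (2, 3)])
        assert count == 12
        _, halved = plan_density_measurements(4, [(0, 1), (2, 3)], spin_symmetry=True)
        assert halved == 6

    def test_single_spatial_orbital(self):
        _, count = plan_density_measurements(2, [])
        assert count == 4
        _, halved = plan_density_measurements(2, [], spin_symmetry=True)
        assert halved == 2

    def test_diagonal_only_counting_rule(self):
        for no in (2, 4, 6):
            _, count = plan_density_measurements(no, [])
            assert count == 2 * no

    def test_count_invariant_under_orbital_relabeling(self):
        perm = [2, 0, 3, 1]
        pairs = [(0, 1), (2, 3)]
        relabeled = [(perm[p], perm[q]) for p, q in pairs]
        _, a = plan_density_measurements(4, pairs)
        _, b = plan_density_measurements(4, relabeled)
        assert a == b

    def test_parts_cover_real_and_imag(self):
        settings, _ = plan_density_measurements(2, [(0, 1)])
        assert {s.part for s in settings} == {"real", "imag"}


class TestTomography:
    def test_resolution_formula(self):
        assert real_space_resolution(1.26, 250) == pytest.approx(2 * np.pi / (250 * 1.26))

    def test_vacuum_density_is_harmonic_gaussian(self):
        omega = 0.4
        layout = HilbertLayout(0, (16,))
        modes = ModeSet((omega,), (0.0,), (16,))
        psi = prepare_initial_state((), layout, modes)
        grid = nuclear_density(psi, layout, modes, xi_spacing=0.35, n_points=64)
        q = grid.axes["Q"]
        analytic = np.sqrt(omega / np.pi) * np.exp(-omega * q ** 2)
        assert np.abs(grid.values - analytic).max() < 1e-6
        assert grid.integral() == pytest.approx(1.0, abs=1e-3)

    def test_coherent_density_matches_direct_wavefunction(self):
        omega = 1.0
        layout = HilbertLayout(0, (40,))
        modes = ModeSet((omega,), (0.0,), (40,))
        q0 = 1.3
        psi = prepare_initial_state((), layout, modes, nuclear="coherent",
                                    displacements=(q0,))
        grid = nuclear_density(psi, layout, modes, xi_spacing=0.6, n_points=32)
        q = grid.axes["Q"]
        analytic = np.sqrt(omega / np.pi) * np.exp(-omega * (q - q0) ** 2)
        assert np.abs(grid.values - analytic).max() < 1e-6

    def test_density_operator_input_agrees_with_pure_state(self):
        omega = 0.8
        layout = HilbertLayout(1, (12,))
        modes = ModeSet((omega,), (0.0,), (12,))
        psi = prepare_initial_state((1,), layout, modes, nuclear="coherent",
                                    displacements=(0.9,))
        rho = np.outer(psi.amplitudes, psi.amplitudes.conj())
        a = nuclear_density(psi, layout, modes, xi_spacing=0.5, n_points=40)
        b = nuclear_density(rho, layout, modes, xi_spacing=0.5, n_points=40)
        assert np.abs(a.values - b.values).max() < 1e-10


class TestModelDensities:
    def test_tomography_matches_amplitude_squared_marginal(self, charge_transfer_model,
                                                           exact_state_at):
        """Central oracle: reconstructed nuclear density equals the direct
        |C|^2 marginal evaluated in the position representation."""
        sm = charge_transfer_model
        state = VibronicState(exact_state_at(56.1), sm.layout, time=56.1)
        xi = 1.26 / np.sqrt(sm.params.mass)
        grid = nuclear_density(state, sm.layout, sm.modes, xi_spacing=xi, n_points=250)
        # direct marginal: harmonic-oscillator eigenfunctions on the Q grid
        q = grid.axes["Q"]
        omega = sm.modes.omegas[0]
        cutoff = sm.layout.mode_cutoffs[0]
        from math import factorial
        from numpy.polynomial.hermite import hermval
        x = np.sqrt(omega) * q
        funcs = []
        for n in range(cutoff):
            c = np.zeros(n + 1)
            c[n] = 1.0
            norm = (omega / np.pi) ** 0.25 / np.sqrt(2.0 ** n * factorial(n))
            funcs.append(norm * hermval(x, c) * np.exp(-x ** 2 / 2.0))
        funcs = np.array(funcs)
        amps = state.amplitudes.reshape(cutoff, sm.layout.qubit_dim)
        wave = funcs.T @ amps  # (n_q, qubit)
        direct = np.sum(np.abs(wave) ** 2, axis=1)
        assert np.abs(grid.values - direct).max() < 1e-4

    def test_nuclear_density_equals_joint_integrated_over_r(self, charge_transfer_model,
                                                            exact_state_at):
        sm = charge_transfer_model
        state = VibronicState(exact_state_at(28.0), sm.layout, time=28.0)
        xi = 1.26 / np.sqrt(sm.params.mass)
        r_grid = np.linspace(-6.0, 6.0, 121)
        joint = joint_density(state, sm.layout, sm.modes, orbital_fn=sm.orbital_fn,
                              r_grid=r_grid, xi_spacing=xi, n_points=120,
                              mass=sm.params.mass)
        nuc = nuclear_density(state, sm.layout, sm.modes, xi_spacing=xi, n_points=120,
                              coordinate="R", mass=sm.params.mass)
        marginal = np.trapezoid(joint.values, joint.axes["r"], axis=0)
        # compare on the shared R axis
        interp = np.interp(nuc.axes["R"], joint.axes["R"], marginal)
        mask = np.abs(nuc.axes["R"]) < 1.5
        assert np.abs(interp[mask] - nuc.values[mask]).max() < 5e-3
        electron = electron_density(joint)
        assert electron.integral() == pytest.approx(1.0, abs=1e-6)


def test_shot_sampling_converges_to_expectation():
    rng = np.random.default_rng(123)
    value = 0.42
    samples = [sample_expectation(value, 4000, rng) for _ in range(50)]
    assert np.mean(samples) == pytest.approx(value, abs=0.02)
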