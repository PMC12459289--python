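"""Exact and Trotterized closed-system propagation."""

import numpy as np
import pytest

from preboq.cmqb_mapping import assemble_cmqb
from preboq.observables import fidelity
from preboq.operator_algebra import HilbertLayout
from preboq.propagation import (
    TrotterSchedule,
    exact_evolve,
    prepare_initial_state,
    trotter_evolve,
    trotter_step_unitary,
)
from preboq.vibronic_hamiltonian import (
    BosonPolynomial,
    IntegralExpansion,
    ModeSet,
    SecondQuantizedOperator,
    build_hamiltonian,
    position_operator,
)


class TestExactEvolve:
    def test_zero_hamiltonian_is_stationary(self):
        layout = HilbertLayout(1, (3,))
        modes = ModeSet((1.0,), (0.0,), (3,))
        psi0 = prepare_initial_state((1,), layout, modes)
        traj = exact_evolve(np.zeros((6, 6)), psi0, [0.0, 1.0, 5.0])
        for s in traj.states:
            assert np.allclose(s, psi0.amplitudes)

    def test_coherent_state_oscillates_classically(self):
        omega = 0.7
        modes = ModeSet((omega,), (0.0,), (28,))
        layout = HilbertLayout(0, (28,))
        q0 = 1.1
        psi0 = prepare_initial_state((), layout, modes, nuclear="coherent",
                                     displacements=(q0,))
        exp_ = IntegralExpansion(0, 1, 0)
        exp_.vnn = {(2,): 0.5 * omega ** 2}
        H = build_hamiltonian(exp_, modes)
        times = np.linspace(0.0, 2 * np.pi / omega, 9)
        traj = exact_evolve(H, psi0, times)
        q = position_operator(0, modes).matrix((28,))
        for t, s in zip(times, traj.states):
            assert np.vdot(s, q @ s).real == pytest.approx(q0 * np.cos(omega * t), abs=1e-6)

    def test_two_level_rabi_period(self):
        # resonant coupling c between |01> and |10>: P flips with period pi/c
        c = 0.23
        op = SecondQuantizedOperator(2, 1)
        op.add(((0, True), (1, False)), BosonPolynomial.constant(1, c))
        op.add(((1, True), (0, False)), BosonPolynomial.constant(1, c))
        modes = ModeSet((1.0,), (0.0,), (2,))
        layout = modes.layout(2)
        psi0 = prepare_initial_state((1, 0), layout, modes)
        half = np.pi / (2 * c)
        traj = exact_evolve(op, psi0, [half, 2 * half])
        flipped = prepare_initial_state((0, 1), layout, modes)
        assert fidelity(traj.states[0], flipped) == pytest.approx(1.0, abs=1e-10)
        assert fidelity(traj.states[1], psi0) == pytest.approx(1.0, abs=1e-10)

    def test_norm_and_energy_conserved(self, random_model):
        layout = random_model["layout"]
        modes = random_model["modes"]
        psi0 = prepare_initial_state((1, 0, 1, 0), layout, modes)
        H = random_model["ham"].to_matrix(layout)
        traj = exact_evolve(random_model["ham"], psi0, np.linspace(0, 8, 5))
        e0 = np.vdot(psi0.amplitudes, H @ psi0.amplitudes).real
        for s in traj.states:
            assert np.linalg.norm(s) == pytest.approx(1.0, abs=1e-10)
            assert np.vdot(s, H @ s).real == pytest.approx(e0, abs=1e-8)

    def test_non_hermitian_rejected(self):
        psi0 = prepare_initial_state((0,), HilbertLayout(1, ()), None)
        with pytest.raises(ValueError):
            exact_evolve(np.array([[0.0, 1.0], [0.0, 0.0]]), psi0, [1.0])


class TestTrotterEvolve:
    def test_commuting_terms_are_exact_for_any_step(self):
        op = SecondQuantizedOperator(2, 1)
        op.add(((0, True), (0, False)), BosonPolynomial.constant(1, 0.9))
        op.add(((1, True), (1, False)), BosonPolynomial.constant(1, -0.4))
        op.add((), BosonPolynomial(1, {((1, 1),): 0.3}))
        ham = assemble_cmqb(op)
        modes = ModeSet((1.0,), (0.0,), (4,))
        layout = modes.layout(2)
        rng = np.random.default_rng(0)
        amps = rng.normal(size=layout.dim) + 1j * rng.normal(size=layout.dim)
        from preboq.vibronic_hamiltonian import VibronicState
        psi0 = VibronicState(amps / np.linalg.norm(amps), layout)
        exact = exact_evolve(ham, psi0, [4.0])
        trot = trotter_evolve(ham, psi0, TrotterSchedule(2.0, 2, order=1))
        assert fidelity(trot.final(), exact.final()) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("order, slope_range", [(1, (0.8, 1.3)), (2, (1.7, 2.4))])
    def test_error_scaling_with_step_size(self, random_model, order, slope_range):
        """State error is O(dt) for the first-order formula, O(dt^2) for Strang."""
        layout = random_model["layout"]
        modes = random_model["modes"]
        psi0 = prepare_initial_state((1, 0, 1, 0), layout, modes)
        T = 2.0
        exact = exact_evolve(random_model["ham"], psi0, [T]).final()
        errs = []
        for dt in (0.1, 0.05, 0.025):
            sch = TrotterSchedule(dt, int(round(T / dt)), order=order,
                                  base_compensation=False)
            tr = trotter_evolve(random_model["ham"], psi0, sch, record_every=10 ** 6)
            errs.append(np.linalg.norm(tr.final() - exact))
        slopes = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert slope_range[0] < slopes.mean() < slope_range[1]

    def test_unitarity_along_trajectory(self, random_model):
        layout = random_model["layout"]
        psi0 = prepare_initial_state((1, 0, 1, 0), layout, random_model["modes"])
        tr = trotter_evolve(random_model["ham"], psi0, TrotterSchedule(0.2, 10))
        for s in tr.states:
            assert np.linalg.norm(s) == pytest.approx(1.0, abs=1e-10)

    def test_step_unitary_matches_stepping(self, random_model):
        layout = random_model["layout"]
        psi0 = prepare_initial_state((1, 0, 1, 0), layout, random_model["modes"])
        sch = TrotterSchedule(0.3, 3)
        U = trotter_step_unitary(random_model["ham"], sch, layout)
        by_matrix = np.linalg.matrix_power(U, 3) @ psi0.amplitudes
        by_stepping = trotter_evolve(random_model["ham"], psi0, sch).final()
        assert np.abs(by_matrix - by_stepping).max() < 1e-10


def test_trajectory_hdf5_round_trip(tmp_path, random_model):
    from preboq.propagation import load_trajectory, save_trajectory
    layout = random_model["layout"]
    psi0 = prepare_initial_state((1, 0, 1, 0), layout, random_model["modes"])
    traj = exact_evolve(random_model["ham"], psi0, [0.0, 1.0])
    path = tmp_path / "traj.h5"
    save_trajectory(path, traj)
    loaded = load_trajectory(path)
    assert loaded.layout == layout
    assert np.allclose(loaded.states, traj.states)
    assert loaded.metadata["method"] == "exact"


class TestInitialState:
    def test_vacuum_product_state(self):
        modes = ModeSet((1.0,), (0.0,), (3,))
        layout = modes.layout(2)
        psi = prepare_initial_state((0, 0), layout, modes)
        expected = np.zeros(12)
        expected[0] = 1.0
        assert np.allclose(psi.amplitudes, expected)

    def test_closed_shell_onv_sets_alternating_qubits(self):
        # X1 X3-type preparation: orbitals 1 and 3 occupied -> |1010>
        modes = ModeSet((1.0,), (0.0,), (2,))
        layout = modes.layout(4)
        psi = prepare_initial_state((1, 0, 1, 0), layout, modes)
        index = int(np.argmax(np.abs(psi.amplitudes)))
        v, n = layout.index_to_occupations(index)
        assert n == (1, 0, 1, 0) and v == (0,)

    def test_invalid_occupation_rejected(self):
        modes = ModeSet((1.0,), (0.0,), (2,))
        with pytest.raises(ValueError):
            prepare_initial_state((2, 0), modes.layout(2), modes)
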