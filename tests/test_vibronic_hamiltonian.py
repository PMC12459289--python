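"""Second-quantized vibronic Hamiltonian assembly and active-space reduction."""

import numpy as np
import pytest

from preboq.operator_algebra import HilbertLayout
from preboq.propagation import exact_evolve, prepare_initial_state
from preboq.vibronic_hamiltonian import (
    BosonPolynomial,
    IntegralExpansion,
    ModeSet,
    VibronicState,
    apply_active_space,
    build_hamiltonian,
    fermion_string_matrix,
    momentum_operator,
    number_operator_matrix,
    position_operator,
)


@pytest.fixture
def single_mode():
    return ModeSet((0.8,), (0.0,), (10,))


class TestPositionMomentum:
    def test_ground_state_position_variance(self, single_mode):
        q = position_operator(0, single_mode).matrix((10,))
        assert (q @ q)[0, 0].real == pytest.approx(1.0 / (2 * 0.8), abs=1e-12)

    def test_canonical_commutator_on_untruncated_block(self, single_mode):
        q = position_operator(0, single_mode).matrix((10,))
        p = momentum_operator(0, single_mode).matrix((10,))
        comm = (q @ p - p @ q)[:9, :9]
        assert np.allclose(comm, 1j * np.eye(9))

    def test_coherent_displacement_expectation(self):
        # a state displaced by Q0 in mass-weighted coordinates has <Q> = Q0
        modes = ModeSet((0.5,), (0.0,), (24,))
        layout = HilbertLayout(0, (24,))
        q0 = 1.7  # e.g. R0 sqrt(M) for a real-space displacement R0
        psi = prepare_initial_state((), layout, modes, nuclear="coherent",
                                    displacements=(q0,))
        q = position_operator(0, modes).matrix((24,))
        assert psi.expectation(q).real == pytest.approx(q0, rel=1e-8)
        n = BosonPolynomial(1, {((1, 1),): 1.0}).matrix((24,))
        alpha = q0 * np.sqrt(0.5 / 2)
        assert psi.expectation(n).real == pytest.approx(abs(alpha) ** 2, rel=1e-8)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            ModeSet((0.0,), (0.0,), (4,))


class TestBosonPolynomialAlgebra:
    def test_normal_ordered_product_matches_matrix_product(self):
        rng = np.random.default_rng(11)
        cutoffs = (7,)
        for _ in range(5):
            a = BosonPolynomial(1, {((int(rng.integers(0, 3)), int(rng.integers(0, 3))),):
                                    complex(*rng.normal(size=2))})
            b = BosonPolynomial(1, {((int(rng.integers(0, 3)), int(rng.integers(0, 3))),):
                                    complex(*rng.normal(size=2))})
            direct = a.matrix(cutoffs) @ b.matrix(cutoffs)
            ordered = (a * b).matrix(cutoffs)
            # normal ordering is exact on the block untouched by truncation
            k = cutoffs[0] - 6
            assert np.allclose(direct[:k, :k], ordered[:k, :k], atol=1e-10)

    def test_dagger_matches_matrix_adjoint(self):
        poly = BosonPolynomial(1, {((2, 1),): 1.0 + 2.0j, ((0, 1),): -0.5j})
        assert np.allclose(poly.dagger().matrix((8,)), poly.matrix((8,)).conj().T)


class TestBuildHamiltonian:
    def test_zero_integrals_give_bare_oscillator(self):
        modes = ModeSet((0.3,), (0.0,), (6,))
        exp_ = IntegralExpansion(2, 1, 0)
        exp_.vnn = {(2,): 0.5 * 0.3 ** 2}
        H = build_hamiltonian(exp_, modes).to_matrix(modes.layout(2))
        evals = np.sort(np.linalg.eigvalsh(H))[:4]
        # each oscillator level is 4-fold degenerate over the qubit register
        assert np.allclose(evals, 0.3 * (0 + 0.5), atol=1e-10)

    def test_diagonal_one_electron_spectrum(self):
        modes = ModeSet((0.5,), (0.0,), (4,))
        eps = np.array([0.2, -0.4, 0.7])
        exp_ = IntegralExpansion(3, 1, 0)
        exp_.h[0] = np.diag(eps)
        exp_.vnn = {(2,): 0.5 * 0.5 ** 2}
        H = build_hamiltonian(exp_, modes).to_matrix(modes.layout(3))
        # closed form: sum_p eps_p n_p + omega (v + 1/2)
        expected = sorted(
            float(sum(eps[p] for p in range(3) if (j >> (2 - p)) & 1) + 0.5 * (v + 0.5))
            for v in range(4) for j in range(8))
        assert np.allclose(np.sort(np.linalg.eigvalsh(H)), expected, atol=1e-10)

    def test_hermiticity_and_number_conservation(self, random_model):
        H = random_model["sq"].to_matrix(random_model["layout"])
        assert np.abs(H - H.conj().T).max() < 1e-12
        N = np.kron(np.eye(random_model["layout"].boson_dim),
                    number_operator_matrix(4))
        assert np.abs(H @ N - N @ H).max() < 1e-10

    def test_non_hermitian_input_rejected(self):
        exp_ = IntegralExpansion(2, 1, 0)
        exp_.h[0] = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            build_hamiltonian(exp_, ModeSet((1.0,), (0.0,), (3,)))

    def test_bo_factorization_limit_keeps_product_states(self):
        # with d = g = 0 and Q-independent integrals the electronic and
        # nuclear factors evolve independently: purity of each marginal stays 1
        rng = np.random.default_rng(5)
        modes = ModeSet((1.0,), (0.0,), (6,))
        exp_ = IntegralExpansion(2, 1, 0)
        h = rng.normal(size=(2, 2))
        exp_.h[0] = 0.5 * (h + h.T)
        exp_.vnn = {(2,): 0.5}
        layout = modes.layout(2)
        psi0 = prepare_initial_state((1, 0), layout, modes, nuclear="coherent",
                                     displacements=(0.7,))
        traj = exact_evolve(build_hamiltonian(exp_, modes), psi0, [0.9, 2.7])
        for state in traj.states:
            m = state.reshape(layout.boson_dim, layout.qubit_dim)
            rho_e = m.conj().T @ m
            purity = np.trace(rho_e @ rho_e).real
            assert purity == pytest.approx(1.0, abs=1e-10)


class TestActiveSpace:
    @pytest.fixture
    def four_orbital_expansion(self):
        rng = np.random.default_rng(7)
        exp_ = IntegralExpansion(4, 1, 0)
        h = rng.normal(size=(4, 4))
        exp_.h[0] = 0.5 * (h + h.T)
        v = rng.normal(size=(4,) * 4) * 0.3
        v = 0.5 * (v + v.transpose(2, 3, 0, 1))
        v = 0.5 * (v + v.transpose(1, 0, 3, 2))
        exp_.v[0] = v
        return exp_

    def test_empty_inactive_set_is_identity(self, four_orbital_expansion):
        out = apply_active_space(four_orbital_expansion, [0, 1, 2, 3], {})
        assert np.allclose(out.h[0], four_orbital_expansion.h[0])
        assert np.allclose(out.v[0], four_orbital_expansion.v[0])

    def test_frozen_spectrum_matches_symmetry_block(self, four_orbital_expansion):
        modes = ModeSet((1.0,), (0.0,), (3,))
        H_full = build_hamiltonian(four_orbital_expansion, modes).to_matrix(modes.layout(4))
        red = apply_active_space(four_orbital_expansion, [1, 3], {0: 1, 2: 0})
        H_red = build_hamiltonian(red, modes).to_matrix(modes.layout(2))
        sel = [q for q in range(16) if (q >> 3) & 1 == 1 and (q >> 1) & 1 == 0]
        idx = [b * 16 + q for b in range(3) for q in sel]
        block = np.sort(np.linalg.eigvalsh(H_full[np.ix_(idx, idx)]))
        assert np.allclose(block, np.sort(np.linalg.eigvalsh(H_red)), atol=1e-10)

    def test_all_inactive_gives_frozen_determinant_energy(self, four_orbital_expansion):
        modes = ModeSet((1.0,), (0.0,), (3,))
        H_full = build_hamiltonian(four_orbital_expansion, modes).to_matrix(modes.layout(4))
        red = apply_active_space(four_orbital_expansion, [], {0: 1, 1: 1, 2: 0, 3: 0})
        const = red.vnn.get((0,), 0.0)
        det = 0b1100
        # subtract the boson-vacuum kinetic energy <0|P^2/2|0> = omega/4
        assert const == pytest.approx(H_full[det, det].real - 0.25, abs=1e-10)

    def test_overlapping_sets_rejected(self, four_orbital_expansion):
        with pytest.raises(ValueError):
            apply_active_space(four_orbital_expansion, [0, 1], {1: 1, 2: 0, 3: 0})


def test_state_normalization_enforced():
    layout = HilbertLayout(1, ())
    with pytest.raises(ValueError):
        VibronicState(np.array([1.0, 1.0]), layout)


def test_fermion_matrices_anticommute():
    a0 = fermion_string_matrix(((0, False),), 3)
    a2d = fermion_string_matrix(((2, True),), 3)
    assert np.abs(a0 @ a2d + a2d @ a0).max() < 1e-12
    anti = a0 @ a0.conj().T + a0.conj().T @ a0
    assert np.allclose(anti, np.eye(8))
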