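"""Born-Oppenheimer-framework comparator: BO surfaces, Born-Huang propagation,
and the group-BO approximation (GBOA) truncation.

The electronic Hamiltonian H^e(Q) is the h- and v-integral part of the
vibronic Hamiltonian at frozen nuclear position Q, represented on a chosen
electronic sector (fixed electron number / S_z / total spin).  Diagonalizing
it at the spectral nodes of the truncated position operator Q_hat gives BO
states W(Q); because every W(q_i) from an exact diagonalization is exactly
unitary, the operator-valued basis rotation

    U = sum_{n,j} W*_{jn}(Q_hat) (x) |n><j|

is exactly unitary, so full-rank Born-Huang propagation (N_BO = N_CSF) is a
pure change of basis from the pre-BO evolution -- the module's equivalence
oracle.  GBOA truncation keeps the first N_BO rotated blocks (all derivative
couplings among retained states included implicitly, couplings to discarded
states dropped).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .operator_algebra import HilbertLayout
from .propagation import Trajectory, require_hermitian
from .vibronic_hamiltonian import (
    IntegralExpansion,
    ModeSet,
    SecondQuantizedOperator,
    VibronicState,
    build_hamiltonian,
    fermion_string_matrix,
)


# ---------------------------------------------------------------------------
# electronic sectors

def determinant_basis(n_orbitals: int, n_electrons: int, sz: float | None = None,
                      spin_alternating: bool = False) -> list[int]:
    """Qubit-basis indices of determinants in a particle-number (and S_z) sector.

    Spin convention: orbitals 0..m-1 are spin-up, m..2m-1 spin-down (matching
    the model ordering a-up, b-up, a-down, b-down) unless ``spin_alternating``.
    """
    m = n_orbitals // 2
    indices = []
    for occ in itertools.combinations(range(n_orbitals), n_electrons):
        if sz is not None:
            if spin_alternating:
                ms = sum(0.5 if o % 2 == 0 else -0.5 for o in occ)
            else:
                ms = sum(0.5 if o < m else -0.5 for o in occ)
            if abs(ms - sz) > 1e-9:
                continue
        idx = 0
        for o in occ:
            idx |= 1 << (n_orbitals - 1 - o)
        indices.append(idx)
    return sorted(indices)


def spin_squared_matrix(n_orbitals: int) -> np.ndarray:
    """S^2 on the full Fock space (spin-up block first convention)."""
    m = n_orbitals // 2
    dim = 2 ** n_orbitals
    sp = np.zeros((dim, dim), dtype=complex)
    for j in range(m):
        sp += fermion_string_matrix(((j, True), (j + m, False)), n_orbitals)
    sm = sp.conj().T
    sz = np.zeros((dim, dim), dtype=complex)
    for j in range(m):
        sz += 0.5 * (fermion_string_matrix(((j, True), (j, False)), n_orbitals)
                     - fermion_string_matrix(((j + m, True), (j + m, False)), n_orbitals))
    return sm @ sp + sz @ sz + sz


def sector_projector(n_orbitals: int, n_electrons: int, *, sz: float | None = 0.0,
                     spin: float | None = None) -> np.ndarray:
    """Orthonormal columns spanning the requested electronic sector.

    With ``spin`` given, the spin-adapted (CSF) subspace with S(S+1) is taken
    inside the determinant sector.
    """
    dets = determinant_basis(n_orbitals, n_electrons, sz)
    dim = 2 ** n_orbitals
    S = np.zeros((dim, len(dets)))
    for col, idx in enumerate(dets):
        S[idx, col] = 1.0
    if spin is None:
        return S
    s2 = S.T @ spin_squared_matrix(n_orbitals).real @ S
    vals, vecs = np.linalg.eigh(s2)
    target = spin * (spin + 1.0)
    keep = np.abs(vals - target) < 1e-8
    if not keep.any():
        raise ValueError(f"no states with S = {spin} in this sector")
    return S @ vecs[:, keep]


# ---------------------------------------------------------------------------
# BO surfaces

def electronic_integrals_at(expansion: IntegralExpansion, dq: np.ndarray):
    """h_pq(Q) and v_pqrs(Q) from the Taylor tensors at displacement dq = Q - Q_0."""
    dq = np.atleast_1d(np.asarray(dq, dtype=float))
    h = expansion.h[0].copy()
    v = expansion.v[0].copy()
    for m in range(1, expansion.order + 1):
        hm, vm = expansion.h[m], expansion.v[m]
        for mi in itertools.product(range(expansion.n_modes), repeat=m):
            factor = np.prod([dq[nu] for nu in mi])
            h = h + factor * hm[mi]
            v = v + factor * vm[mi]
    return h, v


def electronic_matrix(expansion: IntegralExpansion, dq, sector: np.ndarray) -> np.ndarray:
    """H^e(Q) = (one- + two-electron terms) projected on sector columns."""
    no = expansion.n_orbitals
    h, v = electronic_integrals_at(expansion, dq)
    dim = 2 ** no
    H = np.zeros((dim, dim), dtype=complex)
    for p in range(no):
        for q in range(no):
            if abs(h[p, q]) > 1e-14:
                H += h[p, q] * fermion_string_matrix(((p, True), (q, False)), no)
    for p, q, r, s in itertools.product(range(no), repeat=4):
        if abs(v[p, q, r, s]) > 1e-14:
            H += 0.5 * v[p, q, r, s] * fermion_string_matrix(
                ((p, True), (q, True), (s, False), (r, False)), no)
    return sector.conj().T @ H @ sector


@dataclass
class BOBasis:
    """BO eigenpairs on a set of nuclear positions, phase-aligned along Q."""

    q_values: np.ndarray            # (n_Q,), ascending
    energies: np.ndarray            # (n_Q, n_states)
    W: np.ndarray                   # (n_Q, n_states, n_sector): rows = <det|state>*
    sector: np.ndarray              # (2^No, n_sector) projector columns

    @property
    def n_states(self) -> int:
        return self.W.shape[1]

    def derivative_couplings(self) -> np.ndarray:
        """First-derivative couplings D_jk(Q) = <Phi_j | d Phi_k / dQ> (finite diff).

        BO state j has determinant components W*_{jn}(Q).
        """
        dWc = np.gradient(self.W.conj(), self.q_values, axis=0)
        return np.einsum("qjn,qkn->qjk", self.W, dWc)


def diagonalize_bo(expansion: IntegralExpansion, q_values, sector: np.ndarray) -> BOBasis:
    """Eigen-decompose H^e at each Q with phase continuity along the sweep."""
    q_values = np.asarray(q_values, dtype=float)
    order = np.argsort(q_values)
    inverse = np.argsort(order)
    energies, rows = [], []
    prev = None
    for q in q_values[order]:
        He = electronic_matrix(expansion, [q], sector)
        vals, vecs = np.linalg.eigh(require_hermitian(He))
        W = vecs.conj().T  # rows satisfy E = W He W^dag
        if prev is not None:
            overlaps = W @ prev.conj().T
            for j in range(W.shape[0]):
                if overlaps[j, j].real < 0:
                    W[j] *= -1.0
        prev = W
        energies.append(vals)
        rows.append(W)
    energies = np.array(energies)[inverse]
    rows = np.array(rows)[inverse]
    return BOBasis(q_values, energies, rows, sector)


# ---------------------------------------------------------------------------
# Born-Huang propagation

@dataclass
class BornHuangSetup:
    """Operator-valued rotation between the pre-BO sector basis and BO blocks."""

    layout: HilbertLayout
    sector: np.ndarray
    basis: BOBasis
    rotation: np.ndarray            # U, (boson_dim*n_sector) square, exactly unitary
    h_sector: np.ndarray            # pre-BO H on (boson (x) sector)
    q_nodes: np.ndarray


def _position_nodes(modes: ModeSet, layout: HilbertLayout):
    cutoff = layout.mode_cutoffs[0]
    w = modes.omegas[0]
    b = np.diag(np.sqrt(np.arange(1, cutoff)), k=1)
    Q = (b + b.T) / np.sqrt(2.0 * w) + modes.q0[0] * np.eye(cutoff)
    return np.linalg.eigh(Q)


def born_huang_setup(expansion: IntegralExpansion, modes: ModeSet,
                     layout: HilbertLayout, *, spin: float | None = 0.0,
                     sz: float | None = 0.0, n_electrons: int = 2,
                     include_g: bool = True) -> BornHuangSetup:
    """Build the exactly unitary Born-Huang rotation for a single-mode model."""
    if modes.n_modes != 1:
        raise NotImplementedError("Born-Huang comparator is single-mode")
    sector = sector_projector(expansion.n_orbitals, n_electrons, sz=sz, spin=spin)
    sq = build_hamiltonian(expansion, modes, include_g=include_g)
    H_full = sq.to_matrix(layout)
    P = np.kron(np.eye(layout.boson_dim), sector)
    H_sector = P.conj().T @ H_full @ P
    leak = np.abs(H_full @ P - P @ (P.conj().T @ H_full @ P)).max()
    if leak > 1e-8:
        warnings.warn(f"Hamiltonian couples the sector to its complement ({leak:.2e})")

    qvals, V = _position_nodes(modes, layout)
    basis = diagonalize_bo(expansion, qvals, sector)
    n_sec = sector.shape[1]
    db = layout.boson_dim
    # U[(v, n), (v', j)] = sum_i V[v,i] W*_{jn}(q_i) V*[v',i]
    Wc = basis.W.conj()  # (n_nodes, j, n)
    U = np.einsum("vi,ijn,wi->vnwj", V, Wc, V.conj()).reshape(db * n_sec, db * n_sec)
    return BornHuangSetup(layout, sector, basis, U, H_sector, qvals)


def born_huang_propagate(setup: BornHuangSetup, psi0: VibronicState, times, *,
                         n_bo: int | None = None, bo_states=None) -> Trajectory:
    """Propagate in the (truncated) BO x Fock basis; return full-layout states.

    ``bo_states`` selects retained BO indices (default: the first n_bo).
    At full rank this is exactly the pre-BO evolution in a rotated basis.
    """
    layout = setup.layout
    db = layout.boson_dim
    n_sec = setup.sector.shape[1]
    if bo_states is None:
        bo_states = list(range(n_bo if n_bo is not None else n_sec))
    bo_states = list(bo_states)

    P = np.kron(np.eye(db), setup.sector)
    c_sector = P.conj().T @ psi0.amplitudes
    loss = 1.0 - np.linalg.norm(c_sector) ** 2
    if loss > 1e-10:
        warnings.warn(f"initial state leaks outside the electronic sector ({loss:.2e})")
    t0 = setup.rotation.conj().T @ c_sector

    # selection of retained (v, j) amplitudes
    keep = np.zeros((db, n_sec), dtype=bool)
    keep[:, bo_states] = True
    keep = keep.ravel()
    t_kept = t0[keep]
    trunc_loss = 1.0 - np.linalg.norm(t_kept) ** 2
    if trunc_loss > 1e-6:
        warnings.warn(f"initial state leaks outside retained BO states ({trunc_loss:.2e})")
    t_kept = t_kept / np.linalg.norm(t_kept)

    H_bh = setup.rotation.conj().T @ setup.h_sector @ setup.rotation
    H_red = H_bh[np.ix_(keep, keep)]
    vals, vecs = np.linalg.eigh(require_hermitian(H_red))
    coeffs = vecs.conj().T @ t_kept
    times = np.asarray(times, dtype=float)
    states = np.empty((times.size, layout.dim), dtype=complex)
    for i, t in enumerate(times):
        t_t = vecs @ (np.exp(-1j * vals * (t - psi0.time)) * coeffs)
        full_t = np.zeros(db * n_sec, dtype=complex)
        full_t[keep] = t_t
        states[i] = P @ (setup.rotation @ full_t)
    return Trajectory(times, states, layout, kind="pure",
                      metadata={"method": "born_huang", "bo_states": bo_states,
                                "truncation_loss": trunc_loss})
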