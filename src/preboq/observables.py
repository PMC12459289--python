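"""Measurement emulation: fidelities, reduced density matrices, and
characteristic-function tomography of real-space densities.

The nuclear density never needs the orbital functions: sampling the nuclear
characteristic function chi(k) = <exp(i k Q_hat)> on a symmetric momentum grid
and Fourier transforming gives rho_n(Q) directly (orthonormality of the spin
orbitals at every Q).  Joint electron-nuclear densities additionally weight
the Q-resolved one-electron reduced density matrix with orbital products
phi_p*(r; Q) phi_q(r; Q) evaluated on a position grid.

The 1RDM is available through two independent routes -- direct amplitude
contraction, and summed Pauli-string expectation values as a hardware
Hadamard-test protocol would measure them -- which must agree; their equality
is the central oracle for the Jordan-Wigner bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .operator_algebra import HilbertLayout, pauli_matrix
from .cmqb_mapping import jordan_wigner
from .vibronic_hamiltonian import ModeSet, VibronicState, fermion_string_matrix


# ---------------------------------------------------------------------------
# fidelity and RDMs

def _amplitudes(state) -> np.ndarray:
    return state.amplitudes if isinstance(state, VibronicState) else np.asarray(state)


def fidelity(state, reference) -> float:
    """|<psi|ref>|^2 for pure states; <ref|rho|ref> for a density operator."""
    ref = _amplitudes(reference).ravel()
    a = _amplitudes(state)
    if a.ndim == 2:
        if a.shape[0] != ref.size:
            raise ValueError("dimension mismatch")
        return float(np.real(np.vdot(ref, a @ ref)))
    if a.size != ref.size:
        raise ValueError("dimension mismatch")
    return float(abs(np.vdot(a, ref)) ** 2)


def _qubit_expectation(state, qubit_matrix: np.ndarray, layout: HilbertLayout) -> complex:
    """<I_boson (x) M> for a pure state vector or density operator."""
    a = _amplitudes(state)
    db, dq = layout.boson_dim, layout.qubit_dim
    if a.ndim == 1:
        psi = a.reshape(db, dq)
        return complex(np.vdot(psi, psi @ qubit_matrix.T))
    rho = a.reshape(db, dq, db, dq)
    return complex(np.einsum("bqbr,qr->", rho, qubit_matrix.T))


def one_rdm(state, layout: HilbertLayout) -> np.ndarray:
    """<a+_p a_q> by direct amplitude contraction on the Fock basis."""
    no = layout.n_qubits
    rdm = np.empty((no, no), dtype=complex)
    for p in range(no):
        for q in range(p, no):
            M = fermion_string_matrix(((p, True), (q, False)), no)
            rdm[p, q] = _qubit_expectation(state, M, layout)
            rdm[q, p] = np.conj(rdm[p, q])
    return rdm


def one_rdm_from_pauli(state, layout: HilbertLayout) -> np.ndarray:
    """<a+_p a_q> assembled from Pauli-string expectations (Hadamard-test route)."""
    no = layout.n_qubits
    rdm = np.zeros((no, no), dtype=complex)
    cache: dict[str, complex] = {}
    for p in range(no):
        for q in range(no):
            for string, coeff in jordan_wigner(((p, True), (q, False)), no):
                if string not in cache:
                    cache[string] = _qubit_expectation(state, pauli_matrix(string), layout)
                rdm[p, q] += coeff * cache[string]
    return rdm


def fractional_occupation(state, layout: HilbertLayout, p: int) -> float:
    """FON n_p = (1 - <Z_p>)/2 under the Jordan-Wigner encoding."""
    letters = "".join("Z" if q == p else "I" for q in range(layout.n_qubits))
    z = _qubit_expectation(state, pauli_matrix(letters), layout)
    return float(np.real(1.0 - z) / 2.0)


def sample_expectation(value: float, shots: int, rng) -> float:
    """Binomial shot noise for a Hadamard-test outcome in [-1, 1]."""
    p = min(max((1.0 + value) / 2.0, 0.0), 1.0)
    return 2.0 * rng.binomial(shots, p) / shots - 1.0


# ---------------------------------------------------------------------------
# measurement planning

@dataclass(frozen=True)
class MeasurementSetting:
    """One Hadamard-test configuration: Pauli group, displacement grid, part."""

    label: str
    pauli_group: tuple
    part: str  # "real" (no phase gate) or "imag" (with phase gate)


def plan_density_measurements(n_orbitals: int, overlap_pairs, *,
                              spin_symmetry: bool = False,
                              spin_partner=None) -> tuple[list, int]:
    """Measurement settings for density tomography via the Q-resolved 1RDM.

    Each diagonal RDM element and each orbital pair (p, q) with a
    non-vanishing spatial product forms one operator group, measured twice
    (real and imaginary Hadamard-test parts).  When the two spin components
    carry identical densities, spin-partner groups are redundant and the count
    halves.
    """
    pairs = sorted({(min(p, q), max(p, q)) for p, q in overlap_pairs if p != q})
    groups = [("diag", (p, p)) for p in range(n_orbitals)]
    groups += [("offdiag", pq) for pq in pairs]
    if spin_symmetry:
        if spin_partner is None:
            half = n_orbitals // 2
            spin_partner = lambda p: (p + half) % n_orbitals
        seen, kept = set(), []
        for kind, (p, q) in groups:
            partner = tuple(sorted((spin_partner(p), spin_partner(q))))
            if partner in seen:
                continue
            seen.add((p, q))
            kept.append((kind, (p, q)))
        groups = kept
    settings = [
        MeasurementSetting(f"{kind}{pq}", pq, part)
        for kind, pq in groups for part in ("real", "imag")
    ]
    return settings, len(settings)


# ---------------------------------------------------------------------------
# characteristic-function tomography

@dataclass
class DensityGrid:
    """Real-space density on coordinate axes, unit-normalized."""

    axes: dict
    values: np.ndarray
    resolution: float
    normalization: float  # raw integral before unit normalization

    def integral(self) -> float:
        out = self.values
        for name in reversed(list(self.axes)):
            out = np.trapezoid(out, self.axes[name], axis=-1)
        return float(out)


def momentum_grid(xi_spacing: float, n_points: int) -> np.ndarray:
    return (np.arange(n_points) - n_points // 2) * xi_spacing


def real_space_resolution(xi_spacing: float, n_points: int) -> float:
    """Conjugate-grid spacing 2 pi / (N xi) in mass-weighted units."""
    return 2.0 * np.pi / (n_points * xi_spacing)


def displacement_matrix(alpha: complex, cutoff: int) -> np.ndarray:
    """Exact Fock-basis matrix elements of D(alpha) = exp(alpha b^dag - alpha* b).

    Uses the closed Laguerre form of the infinite-dimensional displacement
    operator, so no truncation artifact enters the characteristic function
    (the emulated hardware mode is a genuine continuous oscillator).
    """
    from scipy.special import eval_genlaguerre, gammaln

    n = np.arange(cutoff)
    x = abs(alpha) ** 2
    out = np.zeros((cutoff, cutoff), dtype=complex)
    for d in range(cutoff):  # d = m - n >= 0 diagonal
        nn = n[: cutoff - d]
        # D_{n+d, n} = sqrt(n!/(n+d)!) alpha^d e^{-x/2} L_n^d(x)
        log_ratio = 0.5 * (gammaln(nn + 1) - gammaln(nn + d + 1))
        vals = np.exp(log_ratio - x / 2.0) * (alpha ** d) * eval_genlaguerre(nn, d, x)
        out[nn + d, nn] = vals
        if d > 0:
            # D_{n, n+d} = sqrt(n!/(n+d)!) (-alpha*)^d e^{-x/2} L_n^d(x)
            out[nn, nn + d] = np.exp(log_ratio - x / 2.0) * ((-np.conj(alpha)) ** d) \
                * eval_genlaguerre(nn, d, x)
    return out


def characteristic_function(state, layout: HilbertLayout, modes: ModeSet,
                            k_grid: np.ndarray, mode: int = 0,
                            qubit_matrix: np.ndarray | None = None) -> np.ndarray:
    """chi(k) = <exp(i k Q_hat_mode) (x) M_qubit> on the momentum grid.

    exp(i k Q_hat) = e^{i k Q_0} D(i k / sqrt(2 omega)) is evaluated through
    exact displacement-operator matrix elements.
    """
    a = _amplitudes(state)
    pre = int(np.prod(layout.mode_cutoffs[:mode])) if mode > 0 else 1
    cutoff = layout.mode_cutoffs[mode]
    post = layout.dim // (pre * cutoff)
    w = modes.omegas[mode]
    q0 = modes.q0[mode]
    chi = np.empty(k_grid.size, dtype=complex)
    if a.ndim == 1:
        psi = a.reshape(pre, cutoff, post)
        if qubit_matrix is not None:
            dq = layout.qubit_dim
            psi = psi.reshape(pre, cutoff, post // dq, dq)
    else:
        rho = a.reshape(pre, cutoff, post, pre, cutoff, post)
        if qubit_matrix is not None:
            dq = layout.qubit_dim
            rest = post // dq
            rho = rho.reshape(pre, cutoff, rest, dq, pre, cutoff, rest, dq)
    for i, k in enumerate(k_grid):
        D = displacement_matrix(1j * k / np.sqrt(2.0 * w), cutoff)
        phase = np.exp(1j * k * q0)
        if a.ndim == 1:
            if qubit_matrix is None:
                chi[i] = phase * np.einsum("pmk,mn,pnk->", psi.conj(), D, psi)
            else:
                chi[i] = phase * np.einsum("pmrq,mn,qs,pnrs->", psi.conj(), D,
                                           qubit_matrix, psi)
        else:
            if qubit_matrix is None:
                chi[i] = phase * np.einsum("pnkpmk,mn->", rho, D)
            else:
                chi[i] = phase * np.einsum("pnrqpmrs,mn,sq->", rho, D, qubit_matrix)
    return chi


def _inverse_fourier(k_grid: np.ndarray, chi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """rho(Q) = (dk / 2 pi) sum_j exp(-i k_j Q) chi(k_j) on the conjugate grid."""
    n = k_grid.size
    dk = k_grid[1] - k_grid[0]
    dq = 2.0 * np.pi / (n * dk)
    q_grid = (np.arange(n) - n // 2) * dq
    phases = np.exp(-1j * np.outer(q_grid, k_grid))
    rho = (dk / (2.0 * np.pi)) * (phases @ chi)
    return q_grid, rho


def nuclear_density(state, layout: HilbertLayout, modes: ModeSet, *,
                    xi_spacing: float, n_points: int, mode: int = 0,
                    coordinate: str = "Q", mass: float = 1.0) -> DensityGrid:
    """Reconstruct the nuclear density of one mode by characteristic tomography.

    ``coordinate="R"`` rescales the mass-weighted axis to the unweighted ion
    position R = Q / sqrt(M) for display.
    """
    k_grid = momentum_grid(xi_spacing, n_points)
    chi = characteristic_function(state, layout, modes, k_grid, mode=mode)
    q_grid, rho = _inverse_fourier(k_grid, chi)
    if np.abs(rho.imag).max() > 1e-6 * max(np.abs(rho.real).max(), 1e-30):
        warnings.warn("reconstructed density has a non-negligible imaginary part")
    rho = rho.real
    norm = float(np.trapezoid(rho, q_grid))
    if abs(norm - 1.0) > 0.01:
        warnings.warn(f"tomography norm loss: integral {norm:.4f} (grid aliasing?)")
    axis = q_grid
    values = rho / norm
    if coordinate == "R":
        axis = q_grid / np.sqrt(mass)
        values = values * np.sqrt(mass)
    return DensityGrid({coordinate: axis}, values,
                       real_space_resolution(xi_spacing, n_points), norm)


def q_resolved_rdm(state, layout: HilbertLayout, modes: ModeSet, *,
                   xi_spacing: float, n_points: int, mode: int = 0):
    """n_pq(Q): Fourier transform of <exp(i k Q_hat) a+_p a_q> per orbital pair."""
    no = layout.n_qubits
    k_grid = momentum_grid(xi_spacing, n_points)
    q_grid = None
    out = None
    for p in range(no):
        for q in range(no):
            M = fermion_string_matrix(((p, True), (q, False)), no)
            chi = characteristic_function(state, layout, modes, k_grid,
                                          mode=mode, qubit_matrix=M)
            q_grid, npq = _inverse_fourier(k_grid, chi)
            if out is None:
                out = np.zeros((no, no, q_grid.size), dtype=complex)
            out[p, q] = npq
    return q_grid, out


def joint_density(state, layout: HilbertLayout, modes: ModeSet, *,
                  orbital_fn, r_grid: np.ndarray, xi_spacing: float,
                  n_points: int, mass: float = 1.0, mode: int = 0) -> DensityGrid:
    """Joint electron-nuclear density rho(r, R) via Q-resolved 1RDM tomography.

    ``orbital_fn(r_grid, R)`` returns spin-orbital spatial values, shape
    (N_o, len(r_grid)); orbital pairs of opposite spin must return orthogonal
    (zero-product) values.
    """
    q_grid, rdm_q = q_resolved_rdm(state, layout, modes,
                                   xi_spacing=xi_spacing, n_points=n_points, mode=mode)
    r_axis = np.asarray(r_grid, dtype=float)
    values = np.zeros((r_axis.size, q_grid.size))
    sqrt_m = np.sqrt(mass)
    for iq, Q in enumerate(q_grid):
        phi = orbital_fn(r_axis, Q / sqrt_m)  # (N_o, n_r)
        dens = np.einsum("pr,pq,qr->r", np.conj(phi), rdm_q[:, :, iq], phi)
        values[:, iq] = dens.real
    R_axis = q_grid / sqrt_m
    values = values * sqrt_m  # Jacobian dQ -> dR
    norm = float(np.trapezoid(np.trapezoid(values, R_axis, axis=1), r_axis))
    if norm <= 0:
        raise ValueError("joint density reconstruction failed (non-positive norm)")
    return DensityGrid({"r": r_axis, "R": R_axis}, values / norm,
                       real_space_resolution(xi_spacing, n_points), norm)


def electron_density(joint: DensityGrid) -> DensityGrid:
    """Marginal electron density from a joint (r, R) grid."""
    r = joint.axes["r"]
    R = joint.axes["R"]
    values = np.trapezoid(joint.values, R, axis=1)
    norm = float(np.trapezoid(values, r))
    return DensityGrid({"r": r}, values / norm, joint.resolution, norm)
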