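"""Closed-system time evolution of vibronic states.

Exact propagation uses a dense eigendecomposition of the (Hermitian)
Hamiltonian.  Trotterized propagation applies first-order product-formula
factors exp(-i dt f_I (x) P^I) per step; each factor is evaluated exactly
through the spectral decomposition of the boson polynomial f_I and the +/-1
projectors of the Pauli string, so the emulation differs from a gate-level
simulation only by the (modelled, not emulated) hardware noise.

With base compensation on, the identity-Pauli term (harmonic base Hamiltonian
plus nuclear-only potential) is split symmetrically around the digital factors
of every step, emulating an always-on base drive compensated in the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .operator_algebra import HilbertLayout, pauli_matrix
from .cmqb_mapping import CMQBHamiltonian
from .vibronic_hamiltonian import ModeSet, SecondQuantizedOperator, VibronicState


@dataclass(frozen=True)
class TrotterSchedule:
    """Trotter schedule on the molecular time scale (a.u.).

    ``order`` selects the product formula: 1 applies each factor once per
    step (first order), 2 the symmetric (Strang) sequence -- forward sweep at
    dt/2, backward sweep at dt/2 -- whose error is O(dt^2) per unit time.
    """

    dt: float
    n_steps: int
    ordering: str = "descending_coeff"  # or "given"
    base_compensation: bool = True
    order: int = 2

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def total_time(self) -> float:
        return self.dt * self.n_steps


@dataclass
class Trajectory:
    """Time series of pure states (dim,) or density operators (dim, dim)."""

    times: np.ndarray
    states: np.ndarray
    layout: HilbertLayout
    kind: str = "pure"  # or "density"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("trajectory times must be monotone non-decreasing")

    def state(self, i: int):
        return self.states[i]

    def final(self):
        return self.states[-1]


def save_trajectory(path, trajectory: "Trajectory") -> None:
    """Write a trajectory (times, states, layout metadata) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=trajectory.times)
        fh.create_dataset("states", data=trajectory.states)
        fh.attrs["kind"] = trajectory.kind
        fh.attrs["n_qubits"] = trajectory.layout.n_qubits
        fh.attrs["mode_cutoffs"] = list(trajectory.layout.mode_cutoffs)
        for key, value in trajectory.metadata.items():
            fh.attrs[f"meta_{key}"] = value


def load_trajectory(path) -> "Trajectory":
    import h5py

    with h5py.File(path, "r") as fh:
        layout = HilbertLayout(int(fh.attrs["n_qubits"]),
                               tuple(int(c) for c in fh.attrs["mode_cutoffs"]))
        meta = {k[5:]: fh.attrs[k] for k in fh.attrs if k.startswith("meta_")}
        return Trajectory(fh["times"][...], fh["states"][...], layout,
                          kind=str(fh.attrs["kind"]), metadata=meta)


def _as_matrix(ham, layout: HilbertLayout) -> np.ndarray:
    if isinstance(ham, CMQBHamiltonian):
        return ham.to_matrix(layout)
    if isinstance(ham, SecondQuantizedOperator):
        return ham.to_matrix(layout)
    return np.asarray(ham, dtype=complex)


def require_hermitian(matrix: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    scale = max(1.0, np.abs(matrix).max())
    if np.abs(matrix - matrix.conj().T).max() > tol * scale:
        raise ValueError("Hamiltonian is not Hermitian")
    return matrix


def exact_evolve(ham, psi0: VibronicState, times) -> Trajectory:
    """psi(t) = exp(-i H t) psi0 via dense eigendecomposition."""
    layout = psi0.layout
    H = require_hermitian(_as_matrix(ham, layout))
    energies, vectors = np.linalg.eigh(H)
    c0 = vectors.conj().T @ psi0.amplitudes
    times = np.asarray(times, dtype=float)
    states = np.empty((times.size, layout.dim), dtype=complex)
    for i, t in enumerate(times):
        states[i] = vectors @ (np.exp(-1j * energies * (t - psi0.time)) * c0)
    return Trajectory(times, states, layout, kind="pure",
                      metadata={"method": "exact"})


class _TermPropagator:
    """Exact single-term factor exp(-i dt f (x) P) with reusable spectra."""

    def __init__(self, term, layout: HilbertLayout):
        B = term.poly.matrix(layout.mode_cutoffs)
        if np.abs(B - B.conj().T).max() > 1e-10 * max(1.0, np.abs(B).max()):
            raise ValueError(f"boson polynomial for term {term.pauli} is not Hermitian")
        self.w, self.U = np.linalg.eigh(B)
        self.identity_pauli = term.weight == 0
        if not self.identity_pauli:
            P = pauli_matrix(term.pauli)
            self.proj_plus = (np.eye(P.shape[0]) + P) / 2.0
            self.proj_minus = (np.eye(P.shape[0]) - P) / 2.0
        self._exp_cache: dict[float, np.ndarray] = {}

    def boson_exp(self, dt: float) -> np.ndarray:
        if dt not in self._exp_cache:
            self._exp_cache[dt] = (self.U * np.exp(-1j * dt * self.w)) @ self.U.conj().T
        return self._exp_cache[dt]

    def apply(self, psi: np.ndarray, dt: float) -> np.ndarray:
        """psi has shape (boson_dim, qubit_dim) or (boson_dim, qubit_dim, batch)."""
        E = self.boson_exp(dt)
        if self.identity_pauli:
            return np.tensordot(E, psi, axes=(1, 0))
        # (A (x) Q) vec -> apply Q on the qubit axis, A on the boson axis
        pp = np.einsum("rq,bq...->br...", self.proj_plus, psi)
        pm = np.einsum("rq,bq...->br...", self.proj_minus, psi)
        return np.tensordot(E, pp, axes=(1, 0)) + np.tensordot(E.conj().T, pm, axes=(1, 0))


def _step_sequence(ham: CMQBHamiltonian, schedule: TrotterSchedule):
    """The per-step factor list [(term, duration), ...] for the product formula."""
    terms = list(ham.terms)
    base_terms = [t for t in terms if t.weight == 0]
    digital_terms = [t for t in terms if t.weight > 0]
    if schedule.ordering == "descending_coeff":
        digital_terms.sort(key=lambda t: -t.max_coefficient())
    dt = schedule.dt
    if schedule.order == 2:
        forward = base_terms + digital_terms
        return [(t, dt / 2.0) for t in forward] + [(t, dt / 2.0) for t in reversed(forward)]
    if schedule.order != 1:
        raise ValueError("order must be 1 or 2")
    if schedule.base_compensation and base_terms:
        return ([(t, dt / 2.0) for t in base_terms]
                + [(t, dt) for t in digital_terms]
                + [(t, dt / 2.0) for t in base_terms])
    return [(t, dt) for t in base_terms + digital_terms]


def trotter_evolve(ham: CMQBHamiltonian, psi0: VibronicState,
                   schedule: TrotterSchedule, *, record_every: int = 1) -> Trajectory:
    """Product-formula evolution recording every `record_every` steps."""
    layout = psi0.layout
    sequence = _step_sequence(ham, schedule)
    props = {}
    for t, _ in sequence:
        if id(t) not in props:
            props[id(t)] = _TermPropagator(t, layout)

    psi = psi0.amplitudes.reshape(layout.boson_dim, layout.qubit_dim).copy()
    times = [psi0.time]
    states = [psi.ravel().copy()]
    for step in range(1, schedule.n_steps + 1):
        for t, dt in sequence:
            psi = props[id(t)].apply(psi, dt)
        if step % record_every == 0 or step == schedule.n_steps:
            times.append(psi0.time + step * schedule.dt)
            states.append(psi.ravel().copy())
    return Trajectory(np.array(times), np.array(states), layout, kind="pure",
                      metadata={"method": "trotter", "dt": schedule.dt,
                                "n_steps": schedule.n_steps,
                                "ordering": schedule.ordering,
                                "order": schedule.order,
                                "base_compensation": schedule.base_compensation,
                                "n_op": ham.n_op})


def trotter_step_unitary(ham: CMQBHamiltonian, schedule: TrotterSchedule,
                         layout: HilbertLayout) -> np.ndarray:
    """Dense unitary of a single Trotter step (product of all factors)."""
    sequence = _step_sequence(ham, schedule)
    props = {}
    for t, _ in sequence:
        if id(t) not in props:
            props[id(t)] = _TermPropagator(t, layout)
    dim = layout.dim
    U = np.eye(dim, dtype=complex).reshape(layout.boson_dim, layout.qubit_dim, dim)
    for t, dt in sequence:
        U = props[id(t)].apply(U, dt)
    return U.reshape(dim, dim)


def coherent_amplitudes(alpha: complex, cutoff: int) -> np.ndarray:
    """Truncated coherent state |alpha>, renormalized after truncation."""
    n = np.arange(cutoff)
    log_fact = np.cumsum(np.log(np.maximum(n, 1)))
    amps = np.exp(n * np.log(complex(alpha)) - 0.5 * log_fact) if alpha != 0 else \
        np.eye(cutoff, dtype=complex)[0]
    if alpha != 0:
        amps = amps * np.exp(-abs(alpha) ** 2 / 2.0)
        loss = 1.0 - np.linalg.norm(amps) ** 2
        if loss > 1e-6:
            import warnings
            warnings.warn(f"coherent-state truncation loss {loss:.2e}; raise the cutoff")
        amps = amps / np.linalg.norm(amps)
    return amps


def prepare_initial_state(onv, layout: HilbertLayout, modes: ModeSet | None = None,
                          nuclear="ground", displacements=None) -> VibronicState:
    """Product state: qubit ONV (x) per-mode ground or coherent nuclear state.

    ``displacements`` are mass-weighted offsets Q - Q_0 per mode; a coherent
    displacement Q maps to alpha = Q sqrt(omega/2).  A real-space displacement
    R_0 of an ion of mass M corresponds to Q = R_0 sqrt(M).
    """
    onv = tuple(int(b) for b in onv)
    if len(onv) != layout.n_qubits:
        raise ValueError("ONV length must equal qubit count")
    if any(b not in (0, 1) for b in onv):
        raise ValueError("ONV occupations must be 0 or 1")
    boson = np.array([1.0 + 0j])
    for nu, cutoff in enumerate(layout.mode_cutoffs):
        if nuclear == "ground":
            mode_state = np.eye(cutoff, dtype=complex)[0]
        elif nuclear == "coherent":
            if modes is None or displacements is None:
                raise ValueError("coherent preparation needs modes and displacements")
            alpha = displacements[nu] * np.sqrt(modes.omegas[nu] / 2.0)
            mode_state = coherent_amplitudes(alpha, cutoff)
        else:
            raise ValueError(f"unknown nuclear preparation {nuclear!r}")
        boson = np.kron(boson, mode_state)
    qubit = np.zeros(layout.qubit_dim, dtype=complex)
    index = 0
    for bit in onv:
        index = (index << 1) | bit
    qubit[index] = 1.0
    return VibronicState(np.kron(boson, qubit), layout)
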