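"""Lindblad-equation propagation with motional-decoherence noise scaling.

An ion-trap coupled qubit-boson simulator is dominated by dephasing of the
motional modes (jump operator b^dag b at native rate gamma_mot).  Modes that
encode molecular vibrations dephase for the whole experiment; qubits pick up
motional noise only while two-qubit entangling gates (through the bus mode)
act on them.  Scaling both exposures from laboratory time to molecular time
gives the molecular-frame rates

    gamma_vib_mol = gamma_mot_au * (dt_mol / F + N_CNOT * t_CNOT_au) / dt_mol
    gamma_q_mol   = gamma_mot_au * 2 * N_CNOT * t_CNOT_au / (N_q * dt_mol)

where F = H_sim / H_mol is the simulator energy-scale factor (the analog part
of a molecular step dt_mol takes laboratory time dt_mol/F), t_CNOT is the
entangling-gate time, N_CNOT the gate count per Trotter step, and the qubit
exposure is averaged over the N_q qubits (each CNOT involves two qubits).
Noise is applied directly in the molecular frame with these scaled rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .operator_algebra import HilbertLayout, pauli_matrix
from .cmqb_mapping import CMQBHamiltonian, total_cnot_count
from .propagation import (Trajectory, TrotterSchedule, _as_matrix,
                          require_hermitian, trotter_step_unitary)

#: one atomic unit of time in seconds
ATOMIC_TIME_S = 2.4188843265857e-17
#: one hartree in rad/s
HARTREE_RAD_S = 1.0 / ATOMIC_TIME_S


@dataclass(frozen=True)
class DeviceParameters:
    """Native ion-trap parameters (SI units)."""

    omega_rabi_hz: float = 1.0e6      # Rabi frequency Omega / 2 pi
    gamma_mot_per_s: float = 30.0     # native motional decoherence rate
    t_cnot_s: float = 1.0e-7          # two-qubit entangling gate time (fast-gate regime)

    @property
    def omega_rabi_au(self) -> float:
        return 2.0 * np.pi * self.omega_rabi_hz / HARTREE_RAD_S

    @property
    def t_cnot_au(self) -> float:
        return self.t_cnot_s / ATOMIC_TIME_S

    @property
    def gamma_mot_au(self) -> float:
        """Native rate per atomic unit of laboratory time."""
        return self.gamma_mot_per_s * ATOMIC_TIME_S


def simulator_scale_factor(ham: CMQBHamiltonian, device: DeviceParameters) -> float:
    """F = Omega / (sum of analog drive strengths), dimensionless.

    Each Trotter factor exp(-i theta_I dt f_I P^I) is driven at most at the
    Rabi rate, so the analog laboratory time for one molecular time unit is
    sum_I |theta_I| / Omega; its inverse is the energy-scale factor F.
    """
    total = sum(t.max_coefficient() for t in ham.terms)
    if total == 0:
        raise ValueError("Hamiltonian has no terms; scale factor undefined")
    return device.omega_rabi_au / total


def scale_noise_rates(gamma_mot_per_s: float, F: float, dt_mol: float,
                      t_cnot_s: float, n_cnot: int, n_qubits: int = 1
                      ) -> tuple[float, float]:
    """Molecular-frame (a.u.) vibrational and per-qubit dephasing rates."""
    if F == 0:
        raise ValueError("scale factor F must be non-zero")
    if dt_mol <= 0 or t_cnot_s < 0 or n_cnot < 0 or gamma_mot_per_s < 0:
        raise ValueError("invalid noise-scaling inputs")
    gamma_au = gamma_mot_per_s * ATOMIC_TIME_S
    t_cnot_au = t_cnot_s / ATOMIC_TIME_S
    gamma_vib = gamma_au * (dt_mol / F + n_cnot * t_cnot_au) / dt_mol
    gamma_q = gamma_au * 2.0 * n_cnot * t_cnot_au / (max(n_qubits, 1) * dt_mol)
    return gamma_vib, gamma_q


@dataclass(frozen=True)
class JumpOperator:
    """A Lindblad jump channel.

    kind: "mode_dephasing" (L = b^dag b on one mode), "qubit_z" (L = Z_q / 2),
    or "qubit_lower" (L = sigma^-_q).
    """

    kind: str
    index: int
    rate: float

    def matrix(self, layout: HilbertLayout) -> np.ndarray:
        if self.kind == "mode_dephasing":
            mats = []
            for nu, cutoff in enumerate(layout.mode_cutoffs):
                m = np.diag(np.arange(cutoff, dtype=float)) if nu == self.index \
                    else np.eye(cutoff)
                mats.append(m)
            bos = np.array([[1.0]])
            for m in mats:
                bos = np.kron(bos, m)
            return np.kron(bos, np.eye(layout.qubit_dim)).astype(complex)
        if self.kind == "qubit_z":
            letters = "".join("Z" if q == self.index else "I"
                              for q in range(layout.n_qubits))
            return 0.5 * np.kron(np.eye(layout.boson_dim), pauli_matrix(letters))
        if self.kind == "qubit_lower":
            sm = np.array([[0, 1], [0, 0]], dtype=complex)
            mat = np.array([[1.0 + 0j]])
            for q in range(layout.n_qubits):
                mat = np.kron(mat, sm if q == self.index else np.eye(2))
            return np.kron(np.eye(layout.boson_dim), mat)
        raise ValueError(f"unknown jump kind {self.kind!r}")

    def diagonal(self, layout: HilbertLayout) -> np.ndarray | None:
        """Eigenvalues if the jump is diagonal in the product basis, else None."""
        if self.kind in ("mode_dephasing", "qubit_z"):
            return np.real(np.diag(self.matrix(layout)))
        return None


@dataclass
class NoiseModel:
    """Jump channels plus the device bookkeeping that produced their rates."""

    jumps: list = field(default_factory=list)
    device: DeviceParameters | None = None
    scale_factor: float | None = None
    n_cnot: int = 0
    dt_mol: float | None = None

    @classmethod
    def from_device(cls, ham: CMQBHamiltonian, device: DeviceParameters,
                    dt_mol: float, *, qubit_jump: str = "qubit_z",
                    include_qubit_channel: bool = True) -> "NoiseModel":
        """Derive molecular-frame jump channels for a model + device + schedule."""
        F = simulator_scale_factor(ham, device)
        n_cnot = total_cnot_count(ham)
        gamma_vib, gamma_q = scale_noise_rates(
            device.gamma_mot_per_s, F, dt_mol, device.t_cnot_s, n_cnot, ham.n_qubits)
        jumps = [JumpOperator("mode_dephasing", nu, gamma_vib)
                 for nu in range(ham.n_modes)]
        if include_qubit_channel:
            jumps += [JumpOperator(qubit_jump.replace("sigma_minus", "qubit_lower"), q, gamma_q)
                      for q in range(ham.n_qubits)]
        return cls(jumps, device, F, n_cnot, dt_mol)


def _dissipator(rho: np.ndarray, jump_mats: list) -> np.ndarray:
    out = np.zeros_like(rho)
    for L, rate in jump_mats:
        LdL = L.conj().T @ L
        out += rate * (L @ rho @ L.conj().T - 0.5 * (LdL @ rho + rho @ LdL))
    return out


def lindblad_evolve(ham, rho0: np.ndarray, noise: NoiseModel, times,
                    layout: HilbertLayout, *, trotterized: bool = False,
                    schedule: TrotterSchedule | None = None,
                    rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Propagate a density operator under the Lindblad master equation.

    With ``trotterized=True`` the Hamiltonian part advances by the same exact
    per-term factors as the closed-system Trotter propagator and the (diagonal)
    dephasing channels are applied analytically between steps; ``ham`` must
    then be a CMQBHamiltonian and ``schedule`` given.  Otherwise an adaptive
    Runge-Kutta integrator propagates the full generator.
    """
    rho0 = np.asarray(rho0, dtype=complex)
    dim = layout.dim
    if rho0.shape != (dim, dim):
        raise ValueError("rho0 shape does not match layout")
    if abs(np.trace(rho0) - 1.0) > 1e-8:
        raise ValueError("rho0 must have unit trace")
    times = np.asarray(times, dtype=float)

    if trotterized:
        if not isinstance(ham, CMQBHamiltonian) or schedule is None:
            raise ValueError("trotterized Lindblad evolution needs a CMQBHamiltonian and schedule")
        return _lindblad_trotter(ham, rho0, noise, schedule, layout, times)

    H = require_hermitian(_as_matrix(ham, layout))
    jump_mats = [(j.matrix(layout), j.rate) for j in noise.jumps if j.rate > 0]

    def rhs(_t, y):
        rho = y.reshape(dim, dim)
        drho = -1j * (H @ rho - rho @ H) + _dissipator(rho, jump_mats)
        return drho.ravel()

    sol = solve_ivp(rhs, (times[0], times[-1]), rho0.ravel(), t_eval=times,
                    method="DOP853", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"Lindblad integration failed: {sol.message}")
    states = sol.y.T.reshape(len(times), dim, dim)
    states = 0.5 * (states + np.conj(np.swapaxes(states, 1, 2)))
    return Trajectory(times, states, layout, kind="density",
                      metadata={"method": "lindblad_rk"})


def _lindblad_trotter(ham: CMQBHamiltonian, rho0, noise: NoiseModel,
                      schedule: TrotterSchedule, layout: HilbertLayout,
                      record_times) -> Trajectory:
    diag_jumps = []
    for j in noise.jumps:
        if j.rate <= 0:
            continue
        diag = j.diagonal(layout)
        if diag is None:
            raise NotImplementedError(
                "trotterized Lindblad path supports diagonal jumps only; "
                "use the adaptive integrator for raising/lowering channels")
        diag_jumps.append((diag, j.rate))
    # elementwise damping over one Trotter step: exp(-rate*dt*(l_i - l_j)^2/2)
    damp = np.ones((layout.dim, layout.dim))
    for diag, rate in diag_jumps:
        delta = diag[:, None] - diag[None, :]
        damp *= np.exp(-0.5 * rate * schedule.dt * delta ** 2)

    U = trotter_step_unitary(ham, schedule, layout)
    Ud = U.conj().T
    rho = rho0.copy()
    n_steps = int(round((record_times[-1] - record_times[0]) / schedule.dt))
    times_out = [record_times[0]]
    states = [rho.copy()]
    record_set = {int(round((t - record_times[0]) / schedule.dt)) for t in record_times}
    for step in range(1, n_steps + 1):
        rho = (U @ rho @ Ud) * damp
        if step in record_set:
            times_out.append(record_times[0] + step * schedule.dt)
            states.append(rho.copy())
    return Trajectory(np.array(times_out), np.array(states), layout, kind="density",
                      metadata={"method": "lindblad_trotter", "dt": schedule.dt})


def purity(rho: np.ndarray) -> float:
    return float(np.real(np.trace(rho @ rho)))


def check_density(rho: np.ndarray, tol: float = 1e-8) -> None:
    """Trace-1, Hermitian, positive (eigenvalues >= -tol) or raise."""
    if abs(np.trace(rho) - 1.0) > tol:
        raise ValueError("density operator trace deviates from 1")
    if np.abs(rho - rho.conj().T).max() > tol:
        raise ValueError("density operator is not Hermitian")
    if np.linalg.eigvalsh(rho).min() < -tol:
        raise ValueError("density operator has a negative eigenvalue")
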