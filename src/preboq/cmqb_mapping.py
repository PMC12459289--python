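"""Jordan-Wigner mapping and assembly of the coupled multi-qubit-boson Hamiltonian.

The fermionic creation operator on spin orbital p (qubit p, 0-based) maps to
Z_0 ... Z_{p-1} (X_p - i Y_p)/2, the annihilator to its Hermitian conjugate.
The mapped Hamiltonian is a sum over Pauli strings P^I of terms f_I(b, b^dag)
(x) P^I, with terms merged by Pauli string, and an overall simulator scale
factor F multiplying the molecular Hamiltonian (H_sim = F H_mol).

Each qubit-boson term is decomposed into a digital Clifford (Hadamard, phase,
CNOT ladder) conjugating a single-qubit analog block, matching trapped-ion
digital-analog practice; only the CNOT count feeds the noise model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .operator_algebra import HilbertLayout, pauli_matrix
from .vibronic_hamiltonian import BosonPolynomial, SecondQuantizedOperator

# single-qubit Pauli multiplication table: (A, B) -> (phase, C) with A.B = phase*C
_PAULI_MUL = {
    ("I", "I"): (1, "I"), ("I", "X"): (1, "X"), ("I", "Y"): (1, "Y"), ("I", "Z"): (1, "Z"),
    ("X", "I"): (1, "X"), ("X", "X"): (1, "I"), ("X", "Y"): (1j, "Z"), ("X", "Z"): (-1j, "Y"),
    ("Y", "I"): (1, "Y"), ("Y", "X"): (-1j, "Z"), ("Y", "Y"): (1, "I"), ("Y", "Z"): (1j, "X"),
    ("Z", "I"): (1, "Z"), ("Z", "X"): (1j, "Y"), ("Z", "Y"): (-1j, "X"), ("Z", "Z"): (1, "I"),
}


def pauli_string_product(a: str, b: str) -> tuple[complex, str]:
    """Product of two Pauli strings: returns (phase, string)."""
    phase = 1.0 + 0j
    letters = []
    for la, lb in zip(a, b):
        ph, lc = _PAULI_MUL[(la, lb)]
        phase *= ph
        letters.append(lc)
    return phase, "".join(letters)


def jordan_wigner(fermion_ops, n_orbitals: int) -> list[tuple[str, complex]]:
    """Map a fermionic ladder string to a sum of weighted Pauli strings.

    ``fermion_ops`` is a tuple of (orbital, is_creation) applied left to right.
    """
    # running sum represented as dict string -> coeff
    total = {"I" * n_orbitals: 1.0 + 0j}
    for orbital, creation in fermion_ops:
        if not 0 <= orbital < n_orbitals:
            raise IndexError(f"orbital {orbital} outside 0..{n_orbitals - 1}")
        z_prefix = "Z" * orbital
        suffix = "I" * (n_orbitals - orbital - 1)
        sign = -1j if creation else 1j  # creation: (X - iY)/2
        factor = {
            z_prefix + "X" + suffix: 0.5,
            z_prefix + "Y" + suffix: 0.5 * sign,
        }
        new_total: dict[str, complex] = {}
        for sa, ca in total.items():
            for sb, cb in factor.items():
                phase, s = pauli_string_product(sa, sb)
                new_total[s] = new_total.get(s, 0.0) + ca * cb * phase
        total = {s: c for s, c in new_total.items() if abs(c) > 1e-15}
    return sorted(total.items())


@dataclass
class PauliTerm:
    """One cMQB Hamiltonian term: boson polynomial f_I coupled to Pauli string P^I."""

    pauli: str
    poly: BosonPolynomial

    @property
    def weight(self) -> int:
        return sum(1 for c in self.pauli if c != "I")

    def support(self) -> list[int]:
        return [k for k, c in enumerate(self.pauli) if c != "I"]

    def max_coefficient(self) -> float:
        return max((abs(c) for c in self.poly.terms.values()), default=0.0)

    def matrix(self, layout: HilbertLayout) -> np.ndarray:
        return np.kron(self.poly.matrix(layout.mode_cutoffs), pauli_matrix(self.pauli))


@dataclass
class CMQBHamiltonian:
    """Qubit-boson image of a second-quantized vibronic Hamiltonian."""

    n_qubits: int
    n_modes: int
    terms: list[PauliTerm] = field(default_factory=list)
    scale_factor: float = 1.0  # F, dimensionless simulator/molecular energy ratio

    def to_matrix(self, layout: HilbertLayout, *, simulator_scale: bool = False) -> np.ndarray:
        if layout.n_qubits != self.n_qubits:
            raise ValueError("layout qubit count mismatch")
        dim = layout.dim
        out = np.zeros((dim, dim), dtype=complex)
        for term in self.terms:
            out += term.matrix(layout)
        if simulator_scale:
            out = self.scale_factor * out
        return out

    @property
    def n_op(self) -> int:
        return len(self.terms)

    def scaled(self, factor: float) -> "CMQBHamiltonian":
        return CMQBHamiltonian(self.n_qubits, self.n_modes,
                               list(self.terms), self.scale_factor * factor)

    def term_table(self) -> pd.DataFrame:
        """Flat (pauli_string, monomial, coefficient) table for export."""
        rows = []
        for term in self.terms:
            for powers, coeff in sorted(term.poly.terms.items()):
                mono = " ".join(
                    f"bd{nu}^{c}" * (c > 0) + (" " if c and a else "") + f"b{nu}^{a}" * (a > 0)
                    for nu, (c, a) in enumerate(powers) if c or a
                ) or "1"
                rows.append({"pauli_string": term.pauli, "monomial": mono,
                             "coefficient_re": coeff.real, "coefficient_im": coeff.imag})
        return pd.DataFrame(rows, columns=["pauli_string", "monomial",
                                           "coefficient_re", "coefficient_im"])


def assemble_cmqb(op: SecondQuantizedOperator, *, scale_factor: float = 1.0,
                  coeff_tol: float = 1e-14) -> CMQBHamiltonian:
    """Jordan-Wigner map a SecondQuantizedOperator and merge by Pauli string."""
    merged: dict[str, BosonPolynomial] = {}
    nm = op.n_modes
    for fermion_ops, poly in op.terms:
        for string, coeff in jordan_wigner(fermion_ops, op.n_orbitals):
            contrib = poly * coeff
            if string in merged:
                merged[string] = merged[string] + contrib
            else:
                merged[string] = contrib
    terms = []
    for string in sorted(merged):
        poly = merged[string]
        poly.terms = {k: c for k, c in poly.terms.items() if abs(c) > coeff_tol}
        if not poly.is_zero:
            terms.append(PauliTerm(string, poly))
    return CMQBHamiltonian(op.n_orbitals, nm, terms, scale_factor)


# ---------------------------------------------------------------------------
# digital-analog gate decomposition

_H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)
_S = np.array([[1, 0], [0, 1j]], dtype=complex)

_GATE_1Q = {"H": _H, "S": _S, "Sdg": _S.conj().T}


@dataclass
class GateSequence:
    """Clifford conjugation circuit for one qubit-boson term.

    Applying ``clifford_matrix()`` as N in  N (f (x) P_{q0}^{axis}) N^dag
    reproduces f (x) P^I, where q0 is the lowest-index non-identity qubit.
    """

    n_qubits: int
    gates: list  # ("H"|"S"|"Sdg", qubit) or ("CNOT", control, target)
    anchor_qubit: int
    n_cnot: int

    def clifford_matrix(self) -> np.ndarray:
        dim = 2 ** self.n_qubits
        out = np.eye(dim, dtype=complex)
        for gate in self.gates:
            if gate[0] == "CNOT":
                mat = _cnot_matrix(gate[1], gate[2], self.n_qubits)
            else:
                mat = _embed_1q(_GATE_1Q[gate[0]], gate[1], self.n_qubits)
            out = mat @ out
        return out


def _embed_1q(gate: np.ndarray, qubit: int, n_qubits: int) -> np.ndarray:
    out = np.array([[1.0 + 0j]])
    for k in range(n_qubits):
        out = np.kron(out, gate if k == qubit else np.eye(2, dtype=complex))
    return out


def _cnot_matrix(control: int, target: int, n_qubits: int) -> np.ndarray:
    dim = 2 ** n_qubits
    out = np.zeros((dim, dim), dtype=complex)
    cbit = 1 << (n_qubits - 1 - control)
    tbit = 1 << (n_qubits - 1 - target)
    for j in range(dim):
        out[j ^ tbit if j & cbit else j, j] = 1.0
    return out


def decompose_term(term: PauliTerm, n_qubits: int | None = None) -> GateSequence:
    """Clifford + CNOT-ladder decomposition of a non-identity Pauli term.

    Single-qubit basis changes rotate each X/Y letter to Z, then a linear
    nearest-support CNOT ladder folds all Z letters onto the anchor qubit
    (lowest non-identity index); N_CNOT = 2 (weight - 1).
    """
    if n_qubits is None:
        n_qubits = len(term.pauli)
    support = term.support()
    if not support:
        raise ValueError("identity Pauli string: handled as boson-only evolution")
    anchor = support[0]
    # CNOT ladder first: conjugating Z_anchor gives a Z on every support qubit
    ladder = [("CNOT", q, anchor) for q in support[1:]]
    # then per-qubit basis rotations taking Z -> X (H) or Z -> Y (S H)
    basis: list = []
    for q in support:
        letter = term.pauli[q]
        if letter == "X":
            basis.append(("H", q))
        elif letter == "Y":
            basis.append(("H", q))
            basis.append(("S", q))
    gates = ladder + basis
    # N_CNOT counts the ladder both in N and in N^dag (down and back)
    return GateSequence(n_qubits, gates, anchor, n_cnot=2 * (len(support) - 1))


def total_cnot_count(ham: CMQBHamiltonian) -> int:
    """CNOTs per Trotter step: sum of 2(w-1) over non-identity Pauli terms."""
    return sum(2 * (t.weight - 1) for t in ham.terms if t.weight >= 1)


def gate_count_report(ham: CMQBHamiltonian) -> dict:
    weights = [t.weight for t in ham.terms]
    return {
        "n_qubits": ham.n_qubits,
        "n_modes": ham.n_modes,
        "n_op": ham.n_op,
        "n_boson_only_terms": sum(1 for w in weights if w == 0),
        "n_cnot_per_step": total_cnot_count(ham),
        "max_pauli_weight": max(weights, default=0),
    }


def export_term_table(ham: CMQBHamiltonian, csv_path: str, json_path: str | None = None) -> None:
    ham.term_table().to_csv(csv_path, index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(gate_count_report(ham), fh, indent=2)
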