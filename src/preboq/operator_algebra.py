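"""Operators and states on a tensor product of truncated bosonic modes and qubits.

The joint Hilbert space is ordered modes-first (slowest varying index), qubits
last, with qubit 0 (spin orbital 1) the leftmost / most significant bit of the
qubit index.  Every other module builds its matrices through this one, so the
ordering convention is fixed here once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod, sqrt

import numpy as np
import scipy.sparse as sp

#: total dimension above which operators are stored sparse by default
SPARSE_THRESHOLD = 2 ** 12

PAULI_MATRICES = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


class LayoutError(ValueError):
    """Raised for invalid or mismatched Hilbert-space layouts."""


@dataclass(frozen=True)
class HilbertLayout:
    """Index bookkeeping for N bosonic modes (Fock-truncated) and n qubits.

    Parameters
    ----------
    n_qubits : int
        Number of qubits (spin orbitals under the Jordan-Wigner encoding).
    mode_cutoffs : tuple of int
        Fock truncation per mode; occupations run 0 .. D_nu - 1.
    """

    n_qubits: int
    mode_cutoffs: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mode_cutoffs", tuple(int(c) for c in self.mode_cutoffs))
        if self.n_qubits < 0:
            raise LayoutError("n_qubits must be >= 0")
        if any(c < 2 for c in self.mode_cutoffs):
            raise LayoutError("every mode cutoff must be >= 2")

    @property
    def n_modes(self) -> int:
        return len(self.mode_cutoffs)

    @property
    def boson_dim(self) -> int:
        return prod(self.mode_cutoffs) if self.mode_cutoffs else 1

    @property
    def qubit_dim(self) -> int:
        return 2 ** self.n_qubits

    @property
    def dim(self) -> int:
        return self.boson_dim * self.qubit_dim

    def index_to_occupations(self, index: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Map a flat basis index to (mode occupations v, qubit occupations n)."""
        if not 0 <= index < self.dim:
            raise LayoutError(f"index {index} outside dimension {self.dim}")
        qubit_part = index % self.qubit_dim
        boson_part = index // self.qubit_dim
        occs = []
        for cutoff in reversed(self.mode_cutoffs):
            occs.append(boson_part % cutoff)
            boson_part //= cutoff
        v = tuple(reversed(occs))
        n = tuple((qubit_part >> (self.n_qubits - 1 - q)) & 1 for q in range(self.n_qubits))
        return v, n

    def occupations_to_index(self, v, n) -> int:
        """Inverse of :meth:`index_to_occupations`."""
        if len(v) != self.n_modes or len(n) != self.n_qubits:
            raise LayoutError("occupation vectors inconsistent with layout")
        boson_part = 0
        for occ, cutoff in zip(v, self.mode_cutoffs):
            if not 0 <= occ < cutoff:
                raise LayoutError(f"mode occupation {occ} outside cutoff {cutoff}")
            boson_part = boson_part * cutoff + occ
        qubit_part = 0
        for bit in n:
            if bit not in (0, 1):
                raise LayoutError("qubit occupations must be 0/1")
            qubit_part = (qubit_part << 1) | bit
        return boson_part * self.qubit_dim + qubit_part


@dataclass(frozen=True)
class LadderMonomial:
    """Normal-ordered product of ladder operators, creations left of annihilations.

    ``powers[nu] = (n_create, n_annihilate)`` for mode nu; a missing trailing
    mode means identity on it.
    """

    coefficient: complex
    powers: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if any(c < 0 or a < 0 for c, a in self.powers):
            raise ValueError("ladder powers must be non-negative")

    def dagger(self) -> "LadderMonomial":
        return LadderMonomial(
            np.conj(self.coefficient), tuple((a, c) for c, a in self.powers)
        )


@dataclass
class OperatorMatrix:
    """A matrix on a HilbertLayout with an optional Hermitian assertion."""

    matrix: object  # ndarray or scipy sparse
    layout: HilbertLayout
    hermitian: bool = False

    def __post_init__(self):
        d = self.matrix.shape
        if d != (self.layout.dim, self.layout.dim):
            raise LayoutError(f"matrix shape {d} does not match layout dim {self.layout.dim}")
        if self.hermitian:
            delta = self.matrix - self.matrix.conj().T
            err = abs(delta).max() if isinstance(delta, np.ndarray) else abs(delta.toarray()).max()
            if err > 1e-12:
                raise ValueError(f"operator declared Hermitian but ||A - A^dag|| = {err:.2e}")

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m if isinstance(m, np.ndarray) else m.toarray()


# ---------------------------------------------------------------------------
# single-mode building blocks

def annihilator(cutoff: int) -> np.ndarray:
    """Truncated matrix of b with <m|b|n> = sqrt(n) delta_{m,n-1}."""
    if cutoff < 2:
        raise LayoutError("cutoff must be >= 2")
    return np.diag(np.sqrt(np.arange(1, cutoff)), k=1).astype(complex)


def monomial_single_mode(n_create: int, n_annihilate: int, cutoff: int) -> np.ndarray:
    b = annihilator(cutoff)
    bdag = b.conj().T
    out = np.eye(cutoff, dtype=complex)
    out = out @ np.linalg.matrix_power(bdag, n_create)
    out = out @ np.linalg.matrix_power(b, n_annihilate)
    return out


def boson_matrix(monomials, cutoffs) -> np.ndarray:
    """Dense matrix of a sum of LadderMonomials on the boson factor only."""
    cutoffs = tuple(cutoffs)
    dim = prod(cutoffs) if cutoffs else 1
    out = np.zeros((dim, dim), dtype=complex)
    for mono in monomials:
        if len(mono.powers) > len(cutoffs):
            raise LayoutError("monomial touches more modes than the layout has")
        factors = []
        for nu, cutoff in enumerate(cutoffs):
            if nu < len(mono.powers):
                c, a = mono.powers[nu]
                factors.append(monomial_single_mode(c, a, cutoff))
            else:
                factors.append(np.eye(cutoff, dtype=complex))
        term = np.array([[mono.coefficient]], dtype=complex)
        for f in factors:
            term = np.kron(term, f)
        out += term
    return out


def pauli_matrix(letters: str) -> np.ndarray:
    """Dense matrix of a Pauli string on the qubit factor only (qubit 0 leftmost)."""
    out = np.array([[1.0 + 0j]])
    for letter in letters:
        try:
            out = np.kron(out, PAULI_MATRICES[letter])
        except KeyError:
            raise ValueError(f"unknown Pauli letter {letter!r}") from None
    return out


# ---------------------------------------------------------------------------
# full-space constructors

def _maybe_sparse(mat: np.ndarray, layout: HilbertLayout, sparse: bool | None):
    if sparse is None:
        sparse = layout.dim > SPARSE_THRESHOLD
    return sp.csr_matrix(mat) if sparse else mat


def build_boson_operator(monomials, layout: HilbertLayout, *, hermitian: bool = False,
                         sparse: bool | None = None) -> OperatorMatrix:
    """Sum of ladder monomials acting as identity on the qubit factor."""
    bos = boson_matrix(monomials, layout.mode_cutoffs)
    full = np.kron(bos, np.eye(layout.qubit_dim, dtype=complex))
    return OperatorMatrix(_maybe_sparse(full, layout, sparse), layout, hermitian=hermitian)


def build_pauli_operator(letters: str, layout: HilbertLayout, *,
                         sparse: bool | None = None) -> OperatorMatrix:
    """Pauli string (one letter per qubit) acting as identity on the modes."""
    if len(letters) != layout.n_qubits:
        raise LayoutError("need exactly one Pauli letter per qubit")
    full = np.kron(np.eye(layout.boson_dim, dtype=complex), pauli_matrix(letters))
    return OperatorMatrix(_maybe_sparse(full, layout, sparse), layout, hermitian=True)


def tensor_assemble(boson_part: np.ndarray, qubit_part: np.ndarray,
                    layout: HilbertLayout, *, hermitian: bool = False,
                    sparse: bool | None = None) -> OperatorMatrix:
    """Kronecker product (modes first) of factor matrices on one layout."""
    if boson_part.shape != (layout.boson_dim, layout.boson_dim):
        raise LayoutError("boson factor dimension mismatch")
    if qubit_part.shape != (layout.qubit_dim, layout.qubit_dim):
        raise LayoutError("qubit factor dimension mismatch")
    full = np.kron(boson_part, qubit_part)
    return OperatorMatrix(_maybe_sparse(full, layout, sparse), layout, hermitian=hermitian)


# ---------------------------------------------------------------------------
# serialization

def save_operator(group, name: str, op: OperatorMatrix) -> None:
    """Write an OperatorMatrix into an open h5py group."""
    dset = group.create_dataset(name, data=op.dense())
    dset.attrs["n_qubits"] = op.layout.n_qubits
    dset.attrs["mode_cutoffs"] = list(op.layout.mode_cutoffs)
    dset.attrs["hermitian"] = op.hermitian


def load_operator(group, name: str) -> OperatorMatrix:
    dset = group[name]
    layout = HilbertLayout(int(dset.attrs["n_qubits"]),
                           tuple(int(c) for c in dset.attrs["mode_cutoffs"]))
    return OperatorMatrix(dset[...], layout, hermitian=bool(dset.attrs["hermitian"]))


def save_state(group, name: str, amplitudes: np.ndarray, layout: HilbertLayout,
               time: float = 0.0) -> None:
    dset = group.create_dataset(name, data=np.asarray(amplitudes, dtype=complex))
    dset.attrs["n_qubits"] = layout.n_qubits
    dset.attrs["mode_cutoffs"] = list(layout.mode_cutoffs)
    dset.attrs["time"] = time
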