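"""Second-quantized pre-Born-Oppenheimer vibronic Hamiltonians.

The molecular Hamiltonian couples fermionic spin-orbital ladder operators to
polynomials in the nuclear normal-mode position and momentum operators.  All
electron integrals (one-electron h_pq, derivative couplings d_nu,pq, second
derivative couplings g_nu,pq, two-electron v_pqrs) are stored as Taylor
coefficient tensors about the reference geometry Q_0, and the Taylor variable
DQ = Q - Q_0 = (b + b^dag)/sqrt(2 omega) is expanded exactly at the operator
level into normal-ordered ladder monomials.

Conventions fixed here:
  * two-electron term: (1/2) sum_pqrs v_pqrs a+_p a+_q a_s a_r with
    v_pqrs = <pq|v|rs> (physicist ordering);
  * derivative coupling term Hermitian-symmetrized:
    -(i/2) sum_nu,pq {d_nu,pq(DQ), P_nu} a+_p a_q  (d real antisymmetric);
  * second-derivative term: +(1/2) sum_nu,pq g_nu,pq(DQ) a+_p a_q.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, factorial, prod, sqrt

import numpy as np

from .operator_algebra import (
    HilbertLayout,
    LadderMonomial,
    boson_matrix,
)


# ---------------------------------------------------------------------------
# boson polynomials

class BosonPolynomial:
    """Sum of normal-ordered ladder monomials over a fixed number of modes."""

    __slots__ = ("n_modes", "terms")

    def __init__(self, n_modes: int, terms: dict | None = None):
        self.n_modes = n_modes
        # key: tuple of (n_create, n_annihilate) per mode -> complex coeff
        self.terms: dict[tuple, complex] = dict(terms or {})

    @classmethod
    def constant(cls, n_modes: int, value: complex) -> "BosonPolynomial":
        key = tuple((0, 0) for _ in range(n_modes))
        return cls(n_modes, {key: complex(value)} if value != 0 else {})

    @classmethod
    def from_monomials(cls, n_modes: int, monomials) -> "BosonPolynomial":
        out = cls(n_modes)
        for m in monomials:
            powers = tuple(m.powers) + tuple((0, 0) for _ in range(n_modes - len(m.powers)))
            out.terms[powers] = out.terms.get(powers, 0.0) + m.coefficient
        return out._prune()

    def _prune(self) -> "BosonPolynomial":
        self.terms = {k: v for k, v in self.terms.items() if abs(v) > 1e-300}
        return self

    def copy(self) -> "BosonPolynomial":
        return BosonPolynomial(self.n_modes, dict(self.terms))

    def __add__(self, other):
        if isinstance(other, BosonPolynomial):
            out = self.copy()
            for k, v in other.terms.items():
                out.terms[k] = out.terms.get(k, 0.0) + v
            return out._prune()
        return self + BosonPolynomial.constant(self.n_modes, other)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, BosonPolynomial):
            out = BosonPolynomial(self.n_modes)
            for ka, va in self.terms.items():
                for kb, vb in other.terms.items():
                    for key, factor in _normal_order_product(ka, kb):
                        out.terms[key] = out.terms.get(key, 0.0) + va * vb * factor
            return out._prune()
        out = BosonPolynomial(self.n_modes, {k: v * other for k, v in self.terms.items()})
        return out._prune()

    def __rmul__(self, scalar):
        return self * scalar

    def __sub__(self, other):
        return self + (other * (-1.0) if isinstance(other, BosonPolynomial) else -other)

    def dagger(self) -> "BosonPolynomial":
        out = BosonPolynomial(self.n_modes)
        for k, v in self.terms.items():
            out.terms[tuple((a, c) for c, a in k)] = np.conj(v)
        return out

    def monomials(self) -> list[LadderMonomial]:
        return [LadderMonomial(v, k) for k, v in self.terms.items()]

    def matrix(self, cutoffs) -> np.ndarray:
        return boson_matrix(self.monomials(), cutoffs)

    @property
    def is_zero(self) -> bool:
        return not self.terms

    def __pow__(self, n: int):
        out = BosonPolynomial.constant(self.n_modes, 1.0)
        for _ in range(n):
            out = out * self
        return out


def _normal_order_product(ka, kb):
    """Normal-order the product of two multimode monomials.

    b^m b^dag^n = sum_k k! C(m,k) C(n,k) b^dag^(n-k) b^(m-k) per mode.
    Yields (key, combinatorial factor) pairs.
    """
    per_mode = []
    for (c1, a1), (c2, a2) in zip(ka, kb):
        options = []
        for k in range(min(a1, c2) + 1):
            factor = factorial(k) * comb(a1, k) * comb(c2, k)
            options.append(((c1 + c2 - k, a1 + a2 - k), factor))
        per_mode.append(options)
    for combo in itertools.product(*per_mode):
        key = tuple(powers for powers, _ in combo)
        factor = prod(f for _, f in combo)
        yield key, factor


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ModeSet:
    """Vibrational normal modes: frequencies, reference geometry, Fock cutoffs."""

    omegas: tuple[float, ...]
    q0: tuple[float, ...]
    cutoffs: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "omegas", tuple(float(w) for w in self.omegas))
        object.__setattr__(self, "q0", tuple(float(q) for q in self.q0))
        object.__setattr__(self, "cutoffs", tuple(int(c) for c in self.cutoffs))
        if not (len(self.omegas) == len(self.q0) == len(self.cutoffs)):
            raise ValueError("omegas, q0, cutoffs must have equal length")
        if any(w <= 0 for w in self.omegas):
            raise ValueError("mode frequencies must be positive")

    @property
    def n_modes(self) -> int:
        return len(self.omegas)

    def layout(self, n_qubits: int) -> HilbertLayout:
        return HilbertLayout(n_qubits, self.cutoffs)


def delta_position(nu: int, modes: ModeSet) -> BosonPolynomial:
    """DQ_nu = Q_nu - Q_0,nu = (b_nu + b^dag_nu)/sqrt(2 omega_nu)."""
    w = modes.omegas[nu]
    n = modes.n_modes
    s = 1.0 / sqrt(2.0 * w)
    key_b = tuple((0, 1) if m == nu else (0, 0) for m in range(n))
    key_bd = tuple((1, 0) if m == nu else (0, 0) for m in range(n))
    return BosonPolynomial(n, {key_b: s, key_bd: s})


def position_operator(nu: int, modes: ModeSet) -> BosonPolynomial:
    """Q_nu = (b + b^dag)/sqrt(2 omega) + Q_0,nu (mass-weighted a.u.)."""
    return delta_position(nu, modes) + modes.q0[nu]


def momentum_operator(nu: int, modes: ModeSet) -> BosonPolynomial:
    """P_nu = i sqrt(omega/2) (b^dag - b)."""
    w = modes.omegas[nu]
    n = modes.n_modes
    s = sqrt(w / 2.0)
    key_b = tuple((0, 1) if m == nu else (0, 0) for m in range(n))
    key_bd = tuple((1, 0) if m == nu else (0, 0) for m in range(n))
    return BosonPolynomial(n, {key_b: -1j * s, key_bd: 1j * s})


@dataclass
class IntegralExpansion:
    """Taylor coefficient tensors of the electron integrals about Q_0.

    ``h[m]`` has shape (N_mode,)*m + (N_o, N_o); ``d[m]`` and ``g[m]`` carry a
    leading mode index, shape (N_mode,) + (N_mode,)*m + (N_o, N_o); ``v[m]``
    has shape (N_mode,)*m + (N_o,)*4.  ``vnn`` is a polynomial in DQ given as
    {powers tuple per mode: coefficient} and holds V_nn + V_inact (plus any
    constant folded in by the active-space reduction).
    """

    n_orbitals: int
    n_modes: int
    order: int
    h: list = field(default_factory=list)
    d: list = field(default_factory=list)
    g: list = field(default_factory=list)
    v: list = field(default_factory=list)
    vnn: dict = field(default_factory=dict)
    real_orbitals: bool = True

    def __post_init__(self):
        no, nm, k = self.n_orbitals, self.n_modes, self.order
        if not self.h:
            self.h = [np.zeros((nm,) * m + (no, no)) for m in range(k + 1)]
        if not self.d:
            self.d = [np.zeros((nm,) + (nm,) * m + (no, no)) for m in range(k + 1)]
        if not self.g:
            self.g = [np.zeros((nm,) + (nm,) * m + (no, no)) for m in range(k + 1)]
        if not self.v:
            self.v = [np.zeros((nm,) * m + (no,) * 4) for m in range(k + 1)]
        self.h = [np.asarray(t, dtype=complex) for t in self.h]
        self.d = [np.asarray(t, dtype=complex) for t in self.d]
        self.g = [np.asarray(t, dtype=complex) for t in self.g]
        self.v = [np.asarray(t, dtype=complex) for t in self.v]

    def validate(self, atol: float = 1e-10) -> None:
        """Check Hermiticity / antisymmetry conventions of the stored tensors."""
        if self.n_orbitals == 0:
            return
        for m, t in enumerate(self.h):
            if np.abs(t - np.conj(np.swapaxes(t, -1, -2))).max() > atol:
                raise ValueError(f"h order {m} is not Hermitian")
        for m, t in enumerate(self.g):
            if np.abs(t - np.conj(np.swapaxes(t, -1, -2))).max() > atol:
                raise ValueError(f"g order {m} is not Hermitian")
        if self.real_orbitals:
            for m, t in enumerate(self.d):
                if np.abs(t + np.swapaxes(t, -1, -2)).max() > atol:
                    raise ValueError(f"d order {m} is not antisymmetric in (p, q)")
        for m, t in enumerate(self.v):
            # Hermiticity v_pqrs* = v_rspq and particle symmetry v_pqrs = v_qpsr
            tt = np.swapaxes(np.swapaxes(t, -4, -2), -3, -1)
            if np.abs(np.conj(tt) - t).max() > atol:
                raise ValueError(f"v order {m} violates v_pqrs* = v_rspq")


@dataclass
class SecondQuantizedOperator:
    """Sum of (fermionic ladder string, boson polynomial) terms.

    ``fermion_ops`` is a tuple of (orbital index, is_creation) applied left to
    right as written, e.g. ((0, True), (1, False)) is a+_0 a_1.
    """

    n_orbitals: int
    n_modes: int
    terms: list = field(default_factory=list)  # list of (fermion_ops, BosonPolynomial)

    def add(self, fermion_ops, poly: BosonPolynomial) -> None:
        if not poly.is_zero:
            self.terms.append((tuple(fermion_ops), poly))

    def to_matrix(self, layout: HilbertLayout) -> np.ndarray:
        """Dense matrix by direct fermionic construction (no qubit mapping)."""
        if layout.n_qubits != self.n_orbitals:
            raise ValueError("layout qubit count must equal orbital count")
        dim = layout.dim
        out = np.zeros((dim, dim), dtype=complex)
        cache: dict[tuple, np.ndarray] = {}
        for ops, poly in self.terms:
            if ops not in cache:
                cache[ops] = fermion_string_matrix(ops, self.n_orbitals)
            out += np.kron(poly.matrix(layout.mode_cutoffs), cache[ops])
        return out


def fermion_single_matrix(orbital: int, creation: bool, n_orbitals: int) -> np.ndarray:
    """Matrix of a_p^(dag) on the occupation-number basis (orbital 0 = leftmost bit).

    The sign is (-1)^(number of occupied orbitals with index < p); this is the
    direct antisymmetrized-Fock-space construction.
    """
    dim = 2 ** n_orbitals
    out = np.zeros((dim, dim), dtype=complex)
    bit = 1 << (n_orbitals - 1 - orbital)
    for j in range(dim):
        occupied = bool(j & bit)
        if creation == occupied:
            continue
        target = j | bit if creation else j & ~bit
        preceding = bin(j >> (n_orbitals - orbital)).count("1")
        out[target, j] = (-1.0) ** preceding
    return out


def fermion_string_matrix(ops, n_orbitals: int) -> np.ndarray:
    out = np.eye(2 ** n_orbitals, dtype=complex)
    for orbital, creation in ops:
        out = out @ fermion_single_matrix(orbital, creation, n_orbitals)
    return out


def number_operator_matrix(n_orbitals: int) -> np.ndarray:
    """Total electron number sum_p n_p on the ONV basis."""
    dim = 2 ** n_orbitals
    return np.diag([float(bin(j).count("1")) for j in range(dim)]).astype(complex)


# ---------------------------------------------------------------------------
# Hamiltonian assembly

def _taylor_polynomial(coeff_tensor_entry, mode_index: tuple, modes: ModeSet) -> BosonPolynomial:
    """coeff * prod_nu DQ_nu over a multi-index of Taylor modes."""
    poly = BosonPolynomial.constant(modes.n_modes, complex(coeff_tensor_entry))
    for nu in mode_index:
        poly = poly * delta_position(nu, modes)
    return poly


def build_hamiltonian(expansion: IntegralExpansion, modes: ModeSet, *,
                      include_g: bool = True, validate: bool = True,
                      coeff_tol: float = 1e-14) -> SecondQuantizedOperator:
    """Assemble the pre-BO vibronic Hamiltonian from Taylor-expanded integrals."""
    if validate:
        expansion.validate()
    if expansion.n_modes != modes.n_modes:
        raise ValueError("expansion/mode-set mode counts differ")
    no, nm = expansion.n_orbitals, expansion.n_modes
    op = SecondQuantizedOperator(no, nm)

    # nuclear kinetic energy (1/2) P_nu^2 and the nuclear-only potential
    nuc = BosonPolynomial(nm)
    for nu in range(nm):
        p = momentum_operator(nu, modes)
        nuc = nuc + 0.5 * (p * p)
    for powers, coeff in expansion.vnn.items():
        term = BosonPolynomial.constant(nm, complex(coeff))
        for nu, power in enumerate(powers):
            for _ in range(power):
                term = term * delta_position(nu, modes)
        nuc = nuc + term
    if not nuc.is_zero:
        op.add((), nuc)

    mode_indices = [list(itertools.product(range(nm), repeat=m))
                    for m in range(expansion.order + 1)]

    # one-electron + second-derivative terms: (h_pq + g_pq/2) a+_p a_q
    for p in range(no):
        for q in range(no):
            poly = BosonPolynomial(nm)
            for m in range(expansion.order + 1):
                for mi in mode_indices[m]:
                    c = expansion.h[m][mi + (p, q)]
                    if include_g:
                        for nu in range(nm):
                            c = c + 0.5 * expansion.g[m][(nu,) + mi + (p, q)]
                    if abs(c) > coeff_tol:
                        poly = poly + _taylor_polynomial(c, mi, modes)
            # derivative coupling: -(i/2) {d_pq(DQ), P_nu}
            for nu in range(nm):
                dpoly = BosonPolynomial(nm)
                for m in range(expansion.order + 1):
                    for mi in mode_indices[m]:
                        c = expansion.d[m][(nu,) + mi + (p, q)]
                        if abs(c) > coeff_tol:
                            dpoly = dpoly + _taylor_polynomial(c, mi, modes)
                if not dpoly.is_zero:
                    pmom = momentum_operator(nu, modes)
                    poly = poly + (-0.5j) * (dpoly * pmom + pmom * dpoly)
            op.add(((p, True), (q, False)), poly)

    # two-electron term: (1/2) v_pqrs a+_p a+_q a_s a_r
    for p, q, r, s in itertools.product(range(no), repeat=4):
        poly = BosonPolynomial(nm)
        for m in range(expansion.order + 1):
            for mi in mode_indices[m]:
                c = expansion.v[m][mi + (p, q, r, s)]
                if abs(c) > coeff_tol:
                    poly = poly + _taylor_polynomial(0.5 * c, mi, modes)
        op.add(((p, True), (q, True), (s, False), (r, False)), poly)

    return op


# ---------------------------------------------------------------------------
# active space

def apply_active_space(expansion: IntegralExpansion, active,
                       inactive_occupations: dict) -> IntegralExpansion:
    """Fold frozen orbitals into an expansion over the active orbitals only.

    Occupied inactive orbitals contribute a mean-field shift to the active
    one-electron integrals and a nuclear-only polynomial (frozen determinant
    energy as a function of DQ); cross active/inactive blocks vanish under the
    projection onto the frozen-occupation sector.
    """
    active = list(active)
    inactive = sorted(inactive_occupations)
    if set(active) & set(inactive):
        raise ValueError("active and inactive orbital sets overlap")
    if sorted(active + inactive) != list(range(expansion.n_orbitals)):
        raise ValueError("active + inactive must partition the orbitals")
    occ = [i for i in inactive if inactive_occupations[i] == 1]
    if any(inactive_occupations[i] not in (0, 1) for i in inactive):
        raise ValueError("inactive occupations must be 0 or 1")

    na, nm, k = len(active), expansion.n_modes, expansion.order
    out = IntegralExpansion(na, nm, k, real_orbitals=expansion.real_orbitals)
    amap = {orb: idx for idx, orb in enumerate(active)}

    for m in range(k + 1):
        hm = expansion.h[m]
        vm = expansion.v[m]
        dm = expansion.d[m]
        gm = expansion.g[m]
        # active blocks
        for x in active:
            for y in active:
                val = hm[..., x, y].copy()
                for i in occ:
                    val = val + 0.5 * (vm[..., x, i, y, i] + vm[..., i, x, i, y]
                                       - vm[..., x, i, i, y] - vm[..., i, x, y, i])
                out.h[m][..., amap[x], amap[y]] = val
                out.d[m][..., amap[x], amap[y]] = dm[..., x, y]
                out.g[m][..., amap[x], amap[y]] = gm[..., x, y]
        for x, y, z, w in itertools.product(active, repeat=4):
            out.v[m][..., amap[x], amap[y], amap[z], amap[w]] = vm[..., x, y, z, w]

        # frozen-determinant energy contribution at this Taylor order
        const = np.zeros(hm.shape[:-2], dtype=complex)
        for i in occ:
            const = const + hm[..., i, i]
            for nu in range(nm):
                const = const + 0.5 * gm[nu][..., i, i]
            for j in occ:
                const = const + 0.5 * (vm[..., i, j, i, j] - vm[..., i, j, j, i])
        _accumulate_polynomial(out.vnn, const, nm, m)

    # carry over the original nuclear-only polynomial
    for powers, coeff in expansion.vnn.items():
        out.vnn[powers] = out.vnn.get(powers, 0.0) + coeff
    out.vnn = {p: c for p, c in out.vnn.items() if abs(c) > 1e-300}
    return out


def _accumulate_polynomial(vnn: dict, coeff_tensor, n_modes: int, order: int) -> None:
    """Add an order-`order` Taylor coefficient tensor into a DQ-power dict."""
    if order == 0:
        c = complex(coeff_tensor)
        if c != 0:
            key = (0,) * n_modes
            vnn[key] = vnn.get(key, 0.0) + c.real if abs(c.imag) < 1e-12 else vnn.get(key, 0.0) + c
        return
    for mi in itertools.product(range(n_modes), repeat=order):
        c = complex(coeff_tensor[mi])
        if c == 0:
            continue
        powers = [0] * n_modes
        for nu in mi:
            powers[nu] += 1
        key = tuple(powers)
        vnn[key] = vnn.get(key, 0.0) + (c.real if abs(c.imag) < 1e-12 else c)


# ---------------------------------------------------------------------------
# states

@dataclass
class VibronicState:
    """Complex amplitude vector C_vn on a HilbertLayout."""

    amplitudes: np.ndarray
    layout: HilbertLayout
    time: float = 0.0

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex).ravel()
        if self.amplitudes.size != self.layout.dim:
            raise ValueError("amplitude vector size does not match layout")
        norm = np.linalg.norm(self.amplitudes)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"state norm {norm} deviates from 1 by more than 1e-10")

    def expectation(self, matrix) -> complex:
        return complex(np.vdot(self.amplitudes, matrix @ self.amplitudes))
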