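"""Resource and scaling estimates: CSF counts, qubit counts, operation scalings.

The classical cost of a Born-Oppenheimer-equivalent treatment scales with the
number of configuration state functions N_CSF, given exactly by the
Weyl-Paldus dimension formula; the qubit-boson orbital encoding needs one
qubit per spin orbital (N_q = N_o) and one bosonic mode per vibration.  All
counts use exact integer arithmetic (they get astronomically large).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, log2

import numpy as np
import pandas as pd


def weyl_count(n_spin_orbitals: int, n_electrons: int, spin: float) -> int:
    """Number of CSFs with N_e electrons and total spin S in N_o spin orbitals.

    Weyl-Paldus: (2S+1)/(n+1) C(n+1, N_e/2 - S) C(n+1, n - N_e/2 - S) with
    n = N_o/2 spatial orbitals.  Returns 0 for infeasible (N_e, S).
    """
    if n_spin_orbitals % 2:
        raise ValueError("spin-orbital count must be even (paired spatial orbitals)")
    n = n_spin_orbitals // 2
    two_s = int(round(2 * spin))
    if abs(2 * spin - two_s) > 1e-9 or two_s < 0:
        raise ValueError("spin must be a non-negative half-integer")
    if n_electrons < 0 or n_electrons > n_spin_orbitals:
        return 0
    a = n_electrons - two_s  # 2*(N_e/2 - S)
    if a < 0 or a % 2:
        return 0  # S infeasible for this electron count / parity
    a //= 2
    b = n - (n_electrons + two_s) // 2
    if b < 0:
        return 0
    return (two_s + 1) * comb(n + 1, a) * comb(n + 1, b) // (n + 1)


def brute_force_csf_count(n_spin_orbitals: int, n_electrons: int, spin: float) -> int:
    """Oracle: count S^2 eigenvectors with eigenvalue S(S+1) on the S_z = S sector.

    Spin orbitals alternate (up, down) per spatial orbital: orbital 2j is
    spatial j with spin up, 2j+1 with spin down.
    """
    n_spatial = n_spin_orbitals // 2
    two_s = int(round(2 * spin))
    dets = [occ for occ in itertools.combinations(range(n_spin_orbitals), n_electrons)
            if sum(1 if o % 2 == 0 else -1 for o in occ) == two_s]
    if not dets:
        return 0
    index = {d: i for i, d in enumerate(dets)}
    sz = two_s / 2.0
    s2 = _spin_squared_matrix(dets, index, n_spatial, sz)
    vals = np.linalg.eigvalsh(s2)
    target = spin * (spin + 1.0)
    return int(np.sum(np.abs(vals - target) < 1e-6))


def _fermion_phase(sorted_occ, remove, add) -> float:
    """Sign of a+_add a_remove acting on a sorted occupation tuple."""
    occ = list(sorted_occ)
    sign = (-1.0) ** occ.index(remove)
    occ.remove(remove)
    pos = sum(1 for o in occ if o < add)
    return sign * (-1.0) ** pos


def _spin_squared_matrix(dets, index, n_spatial, sz):
    dim = len(dets)
    s2 = np.zeros((dim, dim))
    for d, i in index.items():
        s2[i, i] += sz * (sz - 1.0)  # S_z^2 - S_z; S^2 = S-S+ + S_z^2 + S_z
        s2[i, i] += 2.0 * sz  # so total diagonal spin-z part is sz^2 + sz
        occ = set(d)
        for j in range(n_spatial):
            up_j, dn_j = 2 * j, 2 * j + 1
            # S+ = sum_j a+_up_j a_dn_j ; apply S+ then S-
            if dn_j not in occ or up_j in occ:
                continue
            sign_j = _fermion_phase(sorted(occ), dn_j, up_j)
            mid = sorted((occ - {dn_j}) | {up_j})
            mid_occ = set(mid)
            for k in range(n_spatial):
                up_k, dn_k = 2 * k, 2 * k + 1
                if up_k not in mid_occ or dn_k in mid_occ:
                    continue
                sign_k = _fermion_phase(mid, up_k, dn_k)
                new = tuple(sorted((mid_occ - {up_k}) | {dn_k}))
                s2[index[new], i] += sign_j * sign_k
    return s2


def qubit_counts(n_spin_orbitals: int, *, grid_qubits_per_dof: int = 10,
                 n_electrons: int | None = None, n_nuclei: int = 1) -> tuple[int, int]:
    """(orbital-encoding qubit count, first-quantized-grid qubit count).

    The orbital encoding needs N_o qubits; the real-space grid encoding needs
    3 n (N_n + N_e) qubits with n qubits per Cartesian degree of freedom.
    """
    if n_electrons is None:
        raise ValueError("n_electrons required for the grid comparison")
    return n_spin_orbitals, 3 * grid_qubits_per_dof * (n_nuclei + n_electrons)


def cmqb_term_count_scaling(n_spin_orbitals: int, n_modes: int, taylor_order: int) -> int:
    """Leading operation-count scaling N_o^4 N_mode^k of the orbital mapping."""
    return n_spin_orbitals ** 4 * n_modes ** taylor_order


@dataclass
class ResourceEstimate:
    n_spin_orbitals: int
    n_electrons: int
    spin: float
    n_modes: int = 1
    taylor_order: int = 1
    grid_qubits_per_dof: int = 10
    n_nuclei: int = 1

    def summary(self) -> dict:
        n_csf = weyl_count(self.n_spin_orbitals, self.n_electrons, self.spin)
        nq_cmqb, nq_grid = qubit_counts(self.n_spin_orbitals,
                                        grid_qubits_per_dof=self.grid_qubits_per_dof,
                                        n_electrons=self.n_electrons,
                                        n_nuclei=self.n_nuclei)
        return {
            "n_csf": n_csf,
            "log2_n_csf": log2(n_csf) if n_csf else float("-inf"),
            "n_qubits_cmqb": nq_cmqb,
            "n_qubits_grid": nq_grid,
            "n_op_cmqb_scaling": cmqb_term_count_scaling(
                self.n_spin_orbitals, self.n_modes, self.taylor_order),
            "n_op_bo_scaling": n_csf ** 2,
        }


def scaling_report(n_orbital_range, *, ratio: float = 6.0, spin: float = 0.0,
                   n_modes: int = 1, taylor_order: int = 1) -> pd.DataFrame:
    """Classical vs quantum resource curves over a range of spin-orbital counts.

    For each even N_o the table reports log2 of the CSF count at the minimum
    (N_e = 2), maximum (N_e = N_o/2 rounded to parity), and N_o/N_e = ratio
    branches, plus the orbital-encoding qubit count (a straight line N_o).
    """
    rows = []
    for no in n_orbital_range:
        if no % 2:
            continue
        ne_ratio = max(2, 2 * round(no / ratio / 2))
        ne_half = no // 2 if (no // 2) % 2 == 0 else no // 2 - 1
        row = {"n_spin_orbitals": no, "n_qubits_cmqb": no}
        for label, ne in (("min", 2), ("half_filling", max(ne_half, 2)),
                          ("ratio", ne_ratio)):
            count = weyl_count(no, ne, spin)
            row[f"n_e_{label}"] = ne
            row[f"log2_ncsf_{label}"] = log2(count) if count else float("nan")
        row["n_op_cmqb"] = cmqb_term_count_scaling(no, n_modes, taylor_order)
        rows.append(row)
    return pd.DataFrame(rows)
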