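"""One-dimensional two-electron Shin-Metiu charge-transfer model.

Two fixed ions sit at +/- L/2, a moving ion of mass M (harmonically bound,
frequency omega) sits between them at position R, and two electrons move in
softened-Coulomb potentials.  Two diabatic spatial orbitals eta_a (left) and
eta_b (right), each carrying both spins, span the electronic space: spin
orbitals are ordered (eta_a up, eta_b up, eta_a down, eta_b down).

The pipeline is: one-electron grid eigenstates at each R -> phase-fixed
adiabatic orbitals -> diabatization (integrating dc/dR + d c = 0) ->
one-/two-electron integrals over R by grid quadrature -> first-order Taylor
fit in the mass-weighted coordinate Q = R sqrt(M) -> qubit-boson model with
four qubits and one bosonic mode, plus the coherent initial state displaced
by R_0 with the closed-shell eta_a occupation (qubits 1 and 3).

All SI-quantity-like parameters (mass, omega, softening lengths, grids) are a
documented synthetic default profile; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eigh_tridiagonal, polar
from scipy.special import erf

from .cmqb_mapping import CMQBHamiltonian, assemble_cmqb
from .operator_algebra import HilbertLayout
from .propagation import prepare_initial_state
from .vibronic_hamiltonian import (
    IntegralExpansion,
    ModeSet,
    VibronicState,
    build_hamiltonian,
)


def _soft_coulomb(x: np.ndarray, softening: float) -> np.ndarray:
    """erf-screened Coulomb kernel 1/|x|, finite (2/(a sqrt(pi))) at x = 0."""
    ax = np.abs(x)
    out = np.empty_like(ax, dtype=float)
    small = ax < 1e-12
    out[~small] = erf(ax[~small] / softening) / ax[~small]
    out[small] = 2.0 / (softening * np.sqrt(np.pi))
    return out


@dataclass(frozen=True)
class ShinMetiuParameters:
    """Synthetic default profile of the single-mode charge-transfer model (a.u.)."""

    L: float = 5.4                 # fixed-ion separation
    mass: float = 1836.0           # moving-ion mass
    omega: float = 0.015           # harmonic V_nn frequency (mass-weighted)
    r0_displacement: float = -0.1  # initial displacement, |R_0| = 0.1, toward the
    #                                initially occupied left moiety (negative R)
    softening_fixed: float = 0.6   # erf screening length, electron-fixed-ion
    softening_moving: float = 1.5  # electron-moving-ion
    softening_ee: float = 20.0     # electron-electron (soft, nearly flat repulsion)
    r_extent: float = 8.0          # electron grid half-width
    n_r: int = 241                 # electron grid points
    R_well: float = 0.8            # half-width of the sampled nuclear well (R)
    n_R: int = 61                  # nuclear sample points for the Taylor fit
    cutoff: int = 32               # Fock truncation of the single mode
    include_g: bool = True
    symmetrize: bool = True        # enforce the exact mirror symmetry of the model
    shift_orbital_reference: bool = True  # remove the mean orbital energy (mu N_e term)

    @property
    def r_grid(self) -> np.ndarray:
        return np.linspace(-self.r_extent, self.r_extent, self.n_r)

    @property
    def R_grid(self) -> np.ndarray:
        return np.linspace(-self.R_well, self.R_well, self.n_R)

    def v_en(self, r: np.ndarray, R: float) -> np.ndarray:
        """Electron potential: attraction to both fixed ions and the moving ion."""
        return -(_soft_coulomb(r - self.L / 2.0, self.softening_fixed)
                 + _soft_coulomb(r + self.L / 2.0, self.softening_fixed)
                 + _soft_coulomb(r - R, self.softening_moving))

    def v_ee(self, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
        return _soft_coulomb(r1 - r2, self.softening_ee)

    def mode_set(self, cutoff: int | None = None) -> ModeSet:
        return ModeSet((self.omega,), (0.0,), (cutoff or self.cutoff,))


@dataclass
class OrbitalTable:
    """Orbitals on the (R, r) grid with diabatization bookkeeping."""

    params: ShinMetiuParameters
    R_grid: np.ndarray
    r_grid: np.ndarray
    orbitals: np.ndarray            # (n_R, n_orb, n_r), quadrature-normalized
    energies: np.ndarray            # (n_R, n_orb), adiabatic energies
    kind: str = "adiabatic"
    c: np.ndarray | None = None     # (n_R, n_orb, n_orb) adiabatic->diabatic
    couplings: np.ndarray | None = None  # (n_R, n_orb, n_orb) d(R)

    @property
    def dr(self) -> float:
        return self.r_grid[1] - self.r_grid[0]

    def overlap(self, i_R: int) -> np.ndarray:
        phi = self.orbitals[i_R]
        return phi @ phi.T * self.dr


def solve_one_electron(params: ShinMetiuParameters, R: float,
                       n_orbitals: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Lowest grid eigenstates of -1/2 d^2/dr^2 + v_en(r; R).

    Returns (energies, orbitals) with orbitals quadrature-normalized and the
    phase fixed so the leftmost significant lobe is positive.
    """
    r = params.r_grid
    dr = r[1] - r[0]
    diag = 1.0 / dr ** 2 + params.v_en(r, R)
    off = -0.5 / dr ** 2 * np.ones(r.size - 1)
    energies, vecs = eigh_tridiagonal(diag, off, select="i",
                                      select_range=(0, n_orbitals - 1))
    orbitals = vecs.T / np.sqrt(dr)
    for k in range(n_orbitals):
        significant = np.nonzero(np.abs(orbitals[k]) > 0.1 * np.abs(orbitals[k]).max())[0]
        if orbitals[k, significant[0]] < 0:
            orbitals[k] *= -1.0
    return energies, orbitals


def adiabatic_table(params: ShinMetiuParameters, n_orbitals: int = 2) -> OrbitalTable:
    """Phase-continuous adiabatic orbitals along the R grid."""
    R_grid = params.R_grid
    r = params.r_grid
    dr = r[1] - r[0]
    all_orbitals = np.empty((R_grid.size, n_orbitals, r.size))
    all_energies = np.empty((R_grid.size, n_orbitals))
    for i, R in enumerate(R_grid):
        e, phi = solve_one_electron(params, R, n_orbitals)
        if i > 0:
            # sign continuity with the previous geometry
            for k in range(n_orbitals):
                if np.dot(all_orbitals[i - 1, k], phi[k]) * dr < 0:
                    phi[k] *= -1.0
        all_orbitals[i] = phi
        all_energies[i] = e
    table = OrbitalTable(params, R_grid, r, all_orbitals, all_energies)
    table.couplings = derivative_couplings(table)
    return table


def derivative_couplings(table: OrbitalTable) -> np.ndarray:
    """d_ab(R) = <phi_a | d phi_b / dR> by central differences on the R grid."""
    R, phi, dr = table.R_grid, table.orbitals, table.dr
    dR = R[1] - R[0]
    dphi = np.gradient(phi, dR, axis=0)
    return np.einsum("iar,ibr->iab", phi, dphi) * dr


def diabatize(table: OrbitalTable, *, residual_tol: float = 0.05,
              reference: str = "edge") -> OrbitalTable:
    """Integrate the diabatization condition dc/dR + d c = 0 along the R grid.

    In one dimension a strict diabatization exists; c(R) stays unitary (polar
    re-orthogonalization guards against drift) and equals the identity at the
    reference geometry.  The default reference is the left grid edge, where
    the adiabats of a charge-transfer well are already localized, so the
    diabats inherit left/right character across the whole sweep (at the
    symmetric midpoint the adiabats are delocalized parity states and would
    anchor a delocalized diabatic basis).
    """
    if table.kind != "adiabatic":
        raise ValueError("diabatize expects an adiabatic table")
    R = table.R_grid
    m = table.orbitals.shape[1]
    d = table.couplings if table.couplings is not None else derivative_couplings(table)
    i_ref = 0 if reference == "edge" else int(np.argmin(np.abs(R)))
    c = np.empty((R.size, m, m))
    c[i_ref] = np.eye(m)

    def step(ci, i_from, i_to):
        h = R[i_to] - R[i_from]
        # midpoint rule on the antisymmetric generator
        d_mid = 0.5 * (d[i_from] + d[i_to])
        from scipy.linalg import expm
        cn = expm(-d_mid * h) @ ci
        u, _p = polar(cn)
        return u

    for i in range(i_ref + 1, R.size):
        c[i] = step(c[i - 1], i - 1, i)
    for i in range(i_ref - 1, -1, -1):
        c[i] = step(c[i + 1], i + 1, i)

    # eta_i(r; R) = sum_j phi_j(r; R) c[R]_{ji}
    diabatic = np.einsum("ijr,ijk->ikr", table.orbitals, c)
    out = OrbitalTable(table.params, R, table.r_grid, diabatic,
                       table.energies, kind="diabatic", c=c)
    out.couplings = derivative_couplings(out)
    residual = np.abs(out.couplings).max()
    scale = max(np.abs(d).max(), 1e-30)
    if residual > residual_tol * scale:
        warnings.warn(f"diabatization residual coupling {residual:.2e} "
                      f"(adiabatic max {scale:.2e}); refine the R grid")
    # order orbitals left/right by their density centroid at the reference R
    # (ties -- delocalized parity states -- keep the adiabatic order)
    centroid = (out.orbitals[i_ref] ** 2 @ out.r_grid) * out.dr
    order = np.argsort(np.round(centroid, 3), kind="stable")
    out.orbitals = out.orbitals[:, order]
    out.c = out.c[:, :, order]
    out.couplings = derivative_couplings(out)
    for i in range(R.size):  # keep the left orbital positive on its main lobe
        for k in range(m):
            peak = np.argmax(np.abs(out.orbitals[i, k]))
            if out.orbitals[i, k, peak] < 0:
                out.orbitals[i, k] *= -1.0
    return out


def symmetrize_diabats(table: OrbitalTable) -> OrbitalTable:
    """Enforce the model's mirror symmetry eta_b(r; R) = eta_a(-r; -R).

    The numerically integrated diabatization accumulates a small asymmetry
    between the left and right orbitals (the reference geometry treats them
    differently); since the Hamiltonian is exactly symmetric under
    (r, R) -> (-r, -R), the right orbital is replaced by the mirror image of
    the left one and the pair is Loewdin-orthonormalized at every R, which
    preserves the mirror relation.
    """
    if table.kind != "diabatic":
        raise ValueError("symmetrize_diabats expects a diabatic table")
    orbitals = table.orbitals.copy()
    mirrored = orbitals[::-1, 0, ::-1]  # eta_a(-r; -R)
    orbitals[:, 1, :] = mirrored
    dr = table.dr
    for i in range(table.R_grid.size):
        phi = orbitals[i]
        S = phi @ phi.T * dr
        vals, vecs = np.linalg.eigh(S)
        s_inv_half = vecs @ np.diag(vals ** -0.5) @ vecs.T
        orbitals[i] = s_inv_half @ phi
    out = OrbitalTable(table.params, table.R_grid, table.r_grid, orbitals,
                       table.energies, kind="diabatic", c=table.c)
    out.couplings = derivative_couplings(out)
    return out


def localization_fraction(table: OrbitalTable, i_R: int, orbital: int,
                          side: str = "left") -> float:
    """Fraction of the orbital density on one side of the origin."""
    r, dr = table.r_grid, table.dr
    mask = r < 0 if side == "left" else r > 0
    return float(np.sum(table.orbitals[i_R, orbital, mask] ** 2) * dr)


# ---------------------------------------------------------------------------
# integrals

def spatial_integral_tables(table: OrbitalTable) -> dict:
    """h, d, g, v spatial-orbital integrals at every sampled R (grid quadrature)."""
    if table.kind != "diabatic":
        warnings.warn("integrals are usually taken over diabatic orbitals")
    params = table.params
    R_grid, r, dr = table.R_grid, table.r_grid, table.dr
    nR, m, nr = table.orbitals.shape
    h = np.empty((nR, m, m))
    v = np.empty((nR, m, m, m, m))
    for i, R in enumerate(R_grid):
        phi = table.orbitals[i]
        vpot = params.v_en(r, R)
        # kinetic by central differences (matches the eigensolver stencil)
        lap = (np.roll(phi, -1, axis=1) - 2 * phi + np.roll(phi, 1, axis=1)) / dr ** 2
        lap[:, 0] = (phi[:, 1] - 2 * phi[:, 0]) / dr ** 2
        lap[:, -1] = (phi[:, -2] - 2 * phi[:, -1]) / dr ** 2
        hcore = (-0.5 * lap + vpot * phi)
        h[i] = phi @ hcore.T * dr
        h[i] = 0.5 * (h[i] + h[i].T)
        kernel = params.v_ee(r[:, None], r[None, :])
        pair = np.einsum("ar,cr->acr", phi, phi)  # density of orbital pair (a,c)
        contracted = np.einsum("acr,rs->acs", pair, kernel) * dr
        # physicist <ab|cd> = int phi_a(1) phi_b(2) K(1,2) phi_c(1) phi_d(2)
        v[i] = np.einsum("acr,bdr->abcd", contracted, pair) * dr
    dR = R_grid[1] - R_grid[0]
    dphi = np.gradient(table.orbitals, dR, axis=0)
    d = np.einsum("iar,ibr->iab", table.orbitals, dphi) * dr
    d = 0.5 * (d - np.swapaxes(d, 1, 2))  # enforce exact antisymmetry
    g = np.einsum("iar,ibr->iab", dphi, dphi) * dr
    return {"R": R_grid, "h": h, "d": d, "g": g, "v": v}


def taylor_fit(tables: dict, params: ShinMetiuParameters, *, order: int = 1,
               fit_report: dict | None = None) -> IntegralExpansion:
    """First-order Taylor expansion of the integrals in Q = R sqrt(M).

    Order 0 is the value at R = 0; order 1 is the central-difference slope,
    converted by dQ = sqrt(M) dR.  Derivative couplings transform as
    d_Q = d_R / sqrt(M) and g_Q = g_R / M (each nuclear derivative carries a
    1/sqrt(M)).  Spin structure duplicates each spatial orbital: spin orbitals
    (a up, b up, a down, b down).
    """
    if order != 1:
        raise NotImplementedError("the model pipeline implements first order")
    R = tables["R"]
    i0 = int(np.argmin(np.abs(R)))
    if abs(R[i0]) > 1e-12:
        raise ValueError("the R grid must contain the reference geometry R = 0")
    dR = R[1] - R[0]
    sqrt_m = np.sqrt(params.mass)

    def value_and_slope(arr):
        v0 = arr[i0]
        v1 = (arr[i0 + 1] - arr[i0 - 1]) / (2 * dR) / sqrt_m
        return v0, v1

    h0, h1 = value_and_slope(tables["h"])
    v0, v1 = value_and_slope(tables["v"])
    d0, d1 = value_and_slope(tables["d"] / sqrt_m)
    g0, g1 = value_and_slope(tables["g"] / params.mass)

    if fit_report is not None:
        # linear-fit residual over the well region (|R| <= 2 sigma of the
        # harmonic ground state), relative to the largest range any integral
        # element sweeps across that region
        sigma_R = 1.0 / np.sqrt(2.0 * params.mass * params.omega)
        well = np.abs(R) <= 2.0 * sigma_R + 1e-12
        Q = (R[well] - R[i0]) * sqrt_m
        for name in ("h", "v"):
            arr = tables[name]
            v0n, v1n = value_and_slope(arr)
            sub = arr[well]
            recon = v0n[None] + Q.reshape((-1,) + (1,) * v0n.ndim) * v1n[None]
            resid = np.abs(sub - recon).max()
            span = (sub.max(axis=0) - sub.min(axis=0)).max()
            scale = np.abs(sub).max()
            # residual relative to the swept range, or -- for integrals that
            # are essentially constant across the well -- to their magnitude
            fit_report[name] = float(min(resid / max(span, 1e-30),
                                         resid / max(scale, 1e-30)))

    m = h0.shape[0]
    no = 2 * m
    expansion = IntegralExpansion(no, 1, 1)
    spatial = [p % m for p in range(no)]
    spin = [p // m for p in range(no)]
    for p in range(no):
        for q in range(no):
            if spin[p] != spin[q]:
                continue
            a, b = spatial[p], spatial[q]
            expansion.h[0][p, q] = h0[a, b]
            expansion.h[1][0, p, q] = h1[a, b]
            expansion.d[0][0, p, q] = d0[a, b]
            expansion.d[1][0, 0, p, q] = d1[a, b]
            if params.include_g:
                expansion.g[0][0, p, q] = g0[a, b]
                expansion.g[1][0, 0, p, q] = g1[a, b]
    for p, q, rr, s in np.ndindex(no, no, no, no):
        if spin[p] != spin[rr] or spin[q] != spin[s]:
            continue
        expansion.v[0][p, q, rr, s] = v0[spatial[p], spatial[q], spatial[rr], spatial[s]]
        expansion.v[1][0, p, q, rr, s] = v1[spatial[p], spatial[q], spatial[rr], spatial[s]]
    # harmonic nuclear repulsion (1/2) omega^2 Q^2 about Q_0 = 0
    expansion.vnn = {(2,): 0.5 * params.omega ** 2}
    if params.shift_orbital_reference:
        # subtract the mean orbital energy; the removed part is mu * N_e, a
        # global phase within any fixed-electron-number sector, and shrinks
        # the coefficient spread that controls the Trotter step size
        mu = float(np.real(np.trace(expansion.h[0])) / no)
        expansion.h[0] -= mu * np.eye(no)
    return expansion


def compute_integrals(params: ShinMetiuParameters, *, order: int = 1,
                      fit_report: dict | None = None
                      ) -> tuple[IntegralExpansion, OrbitalTable]:
    """Full pipeline: adiabatic solve -> diabatize (+ mirror symmetrization)
    -> integrals -> Taylor fit."""
    diabatic = diabatize(adiabatic_table(params))
    if params.symmetrize:
        diabatic = symmetrize_diabats(diabatic)
    tables = spatial_integral_tables(diabatic)
    expansion = taylor_fit(tables, params, order=order, fit_report=fit_report)
    return expansion, diabatic


# ---------------------------------------------------------------------------
# model assembly

@dataclass
class ShinMetiuModel:
    params: ShinMetiuParameters
    expansion: IntegralExpansion
    modes: ModeSet
    hamiltonian: CMQBHamiltonian
    initial_state: VibronicState
    layout: HilbertLayout
    orbital_table: OrbitalTable | None = None

    def orbital_fn(self, r_grid: np.ndarray, R: float) -> np.ndarray:
        """Spin-orbital spatial values at (r, R) for joint-density tomography.

        Opposite-spin pairs are flagged by returning the values on disjoint
        spin channels: phi_p has its spatial function in channel spin(p).
        """
        table = self.orbital_table
        if table is None:
            raise ValueError("orbital table not attached")
        m = table.orbitals.shape[1]
        i = int(np.clip(np.searchsorted(table.R_grid, R), 0, table.R_grid.size - 1))
        spatial = np.empty((m, r_grid.size))
        for k in range(m):
            spatial[k] = np.interp(r_grid, table.r_grid, table.orbitals[i, k])
        no = 2 * m
        out = np.zeros((no, r_grid.size))
        for p in range(no):
            out[p] = spatial[p % m]
        return out


def build_model(params: ShinMetiuParameters | None = None, *,
                expansion: IntegralExpansion | None = None,
                orbital_table: OrbitalTable | None = None,
                cutoff: int | None = None) -> ShinMetiuModel:
    """Assemble the four-qubit, one-mode charge-transfer model + initial state."""
    params = params or ShinMetiuParameters()
    if expansion is None:
        expansion, orbital_table = compute_integrals(params)
    modes = params.mode_set(cutoff)
    sq = build_hamiltonian(expansion, modes, include_g=params.include_g)
    ham = assemble_cmqb(sq)
    layout = modes.layout(ham.n_qubits)
    q_displacement = params.r0_displacement * np.sqrt(params.mass)
    psi0 = prepare_initial_state((1, 0, 1, 0), layout, modes,
                                 nuclear="coherent",
                                 displacements=(q_displacement,))
    return ShinMetiuModel(params, expansion, modes, ham, psi0, layout, orbital_table)
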