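# Methods

This note records the model, the conventions, and the design choices behind
`preboq`, in the order the method runs. Everything is in Hartree atomic units
(ħ = m_e = e = 1) unless a device parameter is explicitly in SI units.

## State space and conventions

The joint Hilbert space is a tensor product of truncated bosonic modes
(Fock occupations 0..D_ν−1) and qubits, ordered **modes first (slowest
varying), qubits last**, with qubit 0 (spin orbital 1) the most significant
bit of the qubit index. One global ordering avoids Jordan–Wigner string sign
bugs; every matrix in the package is built through
`operator_algebra` with this convention. Operators above total dimension 2¹²
are stored sparse by default.

The Fock truncation is per mode and user-set. There is no universal safe
cutoff: the right value depends on how far the nuclear wavepacket travels.
The convergence check is operational — rebuild with `cutoff + 8` and compare
propagated-state fidelity (`tests/test_shin_metiu.py` does exactly this; the
default model passes at cutoff 32 with deficit < 1e−6).

## Second-quantized vibronic Hamiltonian

Electron integrals are stored as Taylor coefficient tensors about the
reference geometry Q₀, and the Taylor variable ΔQ̂ = (b + b†)/√(2ω) is
expanded exactly at the operator level into normal-ordered ladder monomials
(`BosonPolynomial`, with the exact reordering identity
b^m b†^n = Σ_k k!·C(m,k)·C(n,k)·b†^(n−k) b^(m−k)). Fixed conventions:

* two-electron term ½ Σ v_pqrs a†_p a†_q a_s a_r with v_pqrs = ⟨pq|v|rs⟩
  (physicist index order; only Hermiticity v*_pqrs = v_rspq and particle
  symmetry are assumed, the full 8-fold symmetry only for real orbitals);
* first-derivative vibronic coupling Hermitian-symmetrized,
  −(i/2) Σ {d_ν,pq(ΔQ̂), P̂_ν} a†_p a_q, with d real antisymmetric — the
  symmetrization order is not fixed by the structural description of the
  theory, so the Hermitian average is used and verified numerically;
* second-derivative coupling +½ Σ g_ν,pq(ΔQ̂) a†_p a_q, included by default
  and switchable (`include_g`).

Active-space reduction projects onto fixed occupations of the inactive
orbitals: occupied inactive orbitals fold into the active one-electron
integrals through the standard mean-field contraction
½(v_{xiyi} + v_{ixiy} − v_{xiiy} − v_{ixyi}) and into a nuclear-only
polynomial (the frozen-determinant energy as a function of ΔQ); cross
active/inactive blocks vanish identically under the projection, which makes
the reduced spectrum equal to the matching symmetry block of the full
operator (tested to 1e−10 on random fixtures).

## Qubit–boson mapping

Jordan–Wigner with the normalized convention
a†_p = Z_0 … Z_{p−1} (X_p − iY_p)/2 (creation maps |0⟩→|1⟩); the convention
is pinned by matrix-level anticommutation tests rather than trusted from any
printed form. Terms with identical Pauli strings are merged before gate
decomposition, which reduces both the Trotter factor count N_op and the
modelled noise. Each qubit–boson term is decomposed into a CNOT ladder
anchored at the lowest-index non-identity qubit plus single-qubit basis
rotations (H for X, S·H for Y); the contract is matrix equality of the
conjugated single-qubit–boson block with the full term exponential, and
N_CNOT = 2(w−1) for Pauli weight w (ladder down and back).

## Time evolution

*Exact* propagation uses a dense eigendecomposition. *Trotterized*
propagation applies each factor exp(−i dt f_I ⊗ P^I) exactly through the
spectral decomposition of the Hermitian boson matrix f_I and the ±1
projectors of P^I — the emulation equals the ideal gate sequence exactly;
hardware imperfections enter only through the noise model.

The always-on base Hamiltonian of the device (the identity-Pauli term:
nuclear kinetic + V_nn + nuclear-only electronic constants) is compensated by
symmetric splitting — half step before and half after the digital factors.

The default product formula is the **symmetric (Strang) sequence**
(`TrotterSchedule(order=2)`); first order is available and carries the
O(dt) state-error slope (property-tested). The choice is deliberate: under
the bundled model, a first-order product at Δt = 5.6 a.u. tops out near
fidelity 0.93 over the full window, short of the > 0.95 behaviour the method
is expected to deliver at its converged step; the symmetric sequence reaches
0.98 with the same factor set. A related numerical choice: the mean orbital
energy is subtracted from h_pq at model build (`shift_orbital_reference`).
The removed piece is μ·N̂_e — a global phase in any fixed-electron-number
sector — and the Trotter step size is controlled by the orbital energy
*range*, not its absolute scale. Digital factors are ordered by descending
coefficient magnitude (fixed for reproducibility; first-order error is
ordering-independent to leading order).

A practical stability limit worth knowing: when ω·Δt·n approaches 2π for
occupations n the wavepacket actually reaches, the base-factor phases alias
across the Fock ladder and the Trotterized dynamics heats catastrophically.
This is what collapses the Δt = 16.8 a.u. run (closed-system fidelity 0.32)
while Δt = 5.6 and 9.6 stay above 0.97.

## Noise model

Ion-trap qubit–boson simulators are dominated by motional dephasing
(jump operator b†b at native rate γ_mot ≈ 30 s⁻¹). Modes encoding molecular
vibrations dephase for the whole experiment; qubits acquire motional noise
only during entangling gates. Converting laboratory exposure to molecular
time gives

```
γ_vib^mol = γ_mot · (Δt_mol/F + N_CNOT·t_CNOT) / Δt_mol
γ_q^mol   = γ_mot · 2 N_CNOT·t_CNOT / (N_q · Δt_mol)
```

with F = H_sim/H_mol the simulator energy-scale factor. F is derived
operationally: every Trotter factor is driven at most at the Rabi rate Ω, so
one molecular time unit costs Σ_I |θ_I|/Ω of analog laboratory time, and
F = Ω / Σ_I max|f_I coefficients|. The qubit exposure is averaged over the
register (each CNOT involves two of the N_q qubits) into a constant rate; the
spin jump operator is configurable (σ_z/2 default, σ⁻ available through the
generic integrator).

Device defaults: Ω = 2π × 1.0 MHz, γ_mot = 30 s⁻¹, and t_CNOT = 100 ns. The
gate time is a deliberate fast-gate assumption: with it the digital and
analog exposures are comparable and the Trotter-error/noise trade-off is in
its interesting regime — the Δt = 9.6 a.u. run ends with higher fidelity
(0.29) than both Δt = 5.6 (0.20, more gates → more noise) and Δt = 16.8
(0.22, more Trotter error). With slow (10 μs) gates every run simply
decoheres; the trade-off structure, not the absolute rates, is the modelled
physics.

Both noise channels in scope are diagonal in the product basis, so the
Trotterized Lindblad propagator applies the exact per-step unitary followed
by analytic element-wise damping exp(−γ Δt (l_i − l_j)²/2); the generic path
is an adaptive high-order Runge–Kutta on the full generator (used for
non-diagonal jumps and as the cross-check oracle for the split-step path).

## Measurement emulation and tomography

Fractional occupations are n_p = (1 − ⟨Z_p⟩)/2; the 1RDM is available both
by direct amplitude contraction and by summing Jordan–Wigner Pauli-string
expectations (the Hadamard-test route a device would use) — their equality
to 1e−12 is the central bookkeeping oracle. An optional binomial layer adds
shot noise per setting.

Nuclear densities come from characteristic-function tomography:
χ(k) = ⟨exp(ik Q̂)⟩ sampled on a symmetric momentum grid and numerically
Fourier transformed, giving real-space resolution 2π/(N·ξ). Orbital
orthonormality at every Q makes the nuclear density independent of the
orbital functions; joint electron–nuclear densities weight the Q-resolved
1RDM with orbital products φ*_p(r;Q)φ_q(r;Q). Two numerical points matter:

* exp(ik Q̂) is evaluated through the **exact Laguerre closed form of the
  displacement operator matrix elements**, not by exponentiating the
  truncated position matrix — the truncated operator's characteristic
  function is an almost-periodic node comb that never decays and aliases
  spurious weight into fine k-grids, whereas the emulated hardware mode is a
  genuine continuous oscillator;
* tomography works in the mass-weighted coordinate Q and converts to the
  ion position R = Q/√M only for display.

Measurement planning counts one operator group per diagonal RDM element and
per orbital pair with a non-vanishing spatial product, times two
(real/imaginary Hadamard-test parts); spin symmetry identifies spin-partner
groups and halves the count (12 → 6 for the bundled model). Other readings of
the grouping are conceivable; this one is implemented uniformly and tested
for relabeling invariance.

## The charge-transfer model

The bundled model is a one-dimensional, two-electron charge-transfer system:
two fixed ions separated by L = 5.4 a.u., a moving ion of mass M = 1836
harmonically bound (frequency ω, replacing the bare Coulomb repulsion to
confine the wavefunction), two electrons in erf-screened soft-Coulomb
potentials. Two diabatic spatial orbitals η_a (left) and η_b (right), each
with both spins, give four spin orbitals ordered (a↑, b↑, a↓, b↓); the
initial state is the closed shell of η_a (qubits 1 and 3, prepared by
X₁X₃) with the nuclear coherent state displaced by |R₀| = 0.1 a.u. The
displacement is directed toward the occupied (left) moiety — the physically
prepared polaron-like configuration; the magnitude is the quoted model
parameter, the sign a documented convention of this profile.

Pipeline: finite-difference eigensolver for the one-electron grid
Hamiltonian at each R (phase fixed by sign continuity) → derivative
couplings by central differences → diabatization by integrating
∂c/∂R + d·c = 0 with midpoint exponentials and polar re-unitarization. The
boundary condition c = 1 is anchored at the **left edge** of the R sweep,
where the adiabats of a charge-transfer well are already localized; at the
symmetric midpoint they are parity eigenstates and would anchor a
delocalized diabatic basis. Because the numerically integrated rotation
accumulates a small left/right asymmetry, the right orbital is then replaced
by the exact mirror image of the left one, η_b(r;R) := η_a(−r;−R), and the
pair is Löwdin-orthonormalized (the Hamiltonian is exactly mirror-symmetric,
so this is a projection onto the model's true symmetry, not an
approximation). Integrals are grid quadratures (the two-electron kernel on
the product grid), Taylor-truncated at first order in Q = R√M by central
differences at R = 0; the fit residual over the well (|R| ≤ 2σ) is reported
relative to each integral's swept range or, for essentially constant
integrals, its magnitude.

All softening lengths and ω are a synthetic profile, chosen once:
(a_fixed, a_moving, a_ee) = (0.6, 1.5, 20.0) and ω = 0.015. This is the
regime where the model shows its intended phenomenology simultaneously:
diabats > 90 % localized; hopping t ≈ 0.015 with a vibronic tilt
∂h_aa/∂R ≈ 0.13 so that the occupied ionic configuration is dynamically
stabilized (polaron-like) in the exact dynamics; a very soft electron pair
repulsion that brings the ionic and covalent configurations close enough for
the ground BO state to participate strongly. Consequences, all computed by
the tests: the exact dynamics keeps the left-orbital occupation above 0.5 at
t = 56.1 a.u., the ground-state-excluding GBOA run (N_BO = 2) drops below
0.5 (spurious transfer — the excluded state carries a large share of the
initial state, which the propagator reports as a truncation-loss warning),
and Trotter/noise behave as described above. The profile emulates the
*mechanism* — GBOA failure through an excluded-state pathway, tunable
vibronic stiffness — not any particular molecule; quantitative features
(energy gaps, FON values, noise magnitudes) are properties of this profile
only, and passing tests certify the machinery and the qualitative
phenomenology, not real-molecule accuracy.

## Born–Huang comparator

The electronic Hamiltonian H^e(Q) (one- and two-electron terms at frozen Q)
is represented on a chosen sector — particle number, S_z, optionally total
spin (the spin-adapted singlet sector of the model has dimension 3). It is
diagonalized at the spectral nodes q_i of the truncated Q̂, with phase
alignment along the sweep. Since each W(q_i) is exactly unitary, the
operator-valued rotation U = Σ W*_{jn}(Q̂) ⊗ |n⟩⟨j| is exactly unitary, and
full-rank Born–Huang propagation is a pure change of basis from the pre-BO
evolution — the equivalence oracle holds to < 1e−8 in fidelity with no
finite-difference error. GBOA truncation keeps selected rotated blocks;
derivative couplings among retained states are included implicitly and
exactly, couplings to discarded states are dropped. Explicit
finite-difference derivative couplings are also computed (for export and for
the avoided-crossing diagnostics), with the known Lorentzian peak height
k/(2c) of the linear two-level model as their oracle.

## Resource estimates

CSF counts use the Weyl–Paldus dimension formula
(2S+1)/(n+1) · C(n+1, N_e/2−S) · C(n+1, n−N_e/2−S) on n spatial orbitals, in
exact integer arithmetic (the counts overflow floats quickly), cross-checked
by brute-force S² diagonalization for every feasible sector up to eight spin
orbitals. Qubit comparisons: orbital encoding N_q = N_o versus the
first-quantized grid encoding 3n(N_n + N_e) with n = 10 qubits per Cartesian
degree of freedom; the orbital encoding wins whenever N_o < 30·N_e. Scaling
curves (operation count O(N_o⁴·N_mode^k), minimum/half-filling/fixed-ratio
CSF branches) are descriptive tables, asserted only in the small-size oracle
range and as local slopes.

## Synthetic fixtures and their limits

`generate_fixture("random-vibronic")` draws seed-deterministic Hermitian
integral tensors with controlled coupling scales — it exercises every stage
of the mapping/propagation/noise/tomography machinery but has no spatial
orbitals, no diabatization step and no physically meaningful energy scales.
The two-level toy provides closed-form Rabi oracles. What the passing suite
shows about real data: the algebra, mappings and propagators are correct and
self-consistent, and the bundled model reproduces the intended qualitative
phenomenology; it does not validate grid convergence or integral accuracy
for any real molecular system.

## Problem sizes

Defaults keep everything at desk scale: the bundled model is 512-dimensional
(32 Fock × 16 qubit states), dense eigendecompositions throughout, noise
propagation by 512×512 matrix products; the full test suite (including the
three closed + three noisy full-window runs) completes in about a minute on
one core.
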