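# Methods

## Problem and model

`saptvqe` computes the first-order terms of symmetry-adapted perturbation
theory (SAPT) — the electrostatic energy E1_pol and the exchange repulsion
E1_exch in the single-exchange (S^2) approximation — for a dimer whose
monomer ground states are described by active-space wavefunctions. The
monomer solver can be restricted Hartree–Fock, exact diagonalization in the
active space (CASCI), or an ideal-statevector VQE with a k-layer modified
unitary cluster-Jastrow (k-muCJ) circuit. SAPT consumes nothing from the
solver except the spin-summed one- and two-particle reduced density matrices
(gamma, Gamma), so the interaction energy is obtained from direct expectation
values of the intermolecular operator rather than from a difference of large
total energies. That construction is the point of the method: errors in an
approximate monomer wavefunction largely cancel in the interaction
components, so a shallow circuit whose *total* energy is off by ten
kcal/mol can still deliver interaction components accurate to a few
hundredths of a kcal/mol. The package's acceptance script measures exactly
this contraction.

Assumptions baked in throughout: real orbitals, singlet (closed-shell or
low-spin biradical treated as singlet) monomers, monomer-centered basis sets,
no second-order terms (induction/dispersion), no counterpoise correction
(the perturbative route does not require one).

## First-order expressions

With the intermolecular operator distributed per electron pair,

    v(i,j) = 1/r_ij + v_B(r_i)/N_B + v_A(r_j)/N_A + V_nn/(N_A N_B),

E1_pol is the classical Coulomb energy of the two monomer charge clouds,
evaluated in the AO basis from the (AA|BB) cross repulsion integrals, the
two nuclear-attraction cross blocks and the internuclear term.

The S^2 exchange follows from the single-exchange operator
P = sum_{i in A, j in B} P_ij:

    E1_exch(S^2) = -<V P> + E1_pol <P>.

Expanding <V P> by electron coincidences and carrying out the singlet spin
algebra gives five pieces, each a contraction of at most the spin-summed
monomer 1- and 2-RDMs with overlap-dressed two-electron kernels:

* T1 — gamma_A x gamma_B through the mixed-distribution kernel (one AO from
  each monomer in both charge distributions);
* T2 — Gamma_A x gamma_B; T3 — its A<->B mirror;
* T4 — Gamma_A x Gamma_B;
* T5 — +E1_pol <P>, with <P> = 1/2 Tr(gamma_A S gamma_B S^T), a single
  matrix-product trace.

The reported `e1_exch_s2` is the sum; the breakdown is exposed for
inspection. Every coefficient of these contractions (including the spin
factors) was validated against a brute-force first-quantized enumeration of
all electron/permutation/spin assignments for four-electron dimers, at the
RHF level and with fully correlated (FCI) monomers; that enumeration lives
in the test suite as an oracle.

A note on what these expressions are *not*: for approximate monomer
wavefunctions the V-operator first-order energy differs from the
Heitler–London (antisymmetrized-product) interaction energy by zeroth-order
exchange-deformation terms, because an RHF or CASCI-in-a-basis monomer state
is not an eigenfunction of its monomer Hamiltonian. The test suite therefore
uses the Heitler–London determinant energy only as a sign-and-magnitude
consistency check, not as a tight oracle.

## Active-space structure and the optimized contraction path

Each monomer's canonical RHF orbitals are partitioned into N_c doubly
occupied core, N_a active, and virtual orbitals by an energy window
(e.g. (6e,6o) = HOMO-2..LUMO+2). Core electrons are folded into a
one-electron operator h~ = h + 2J_c - K_c in the AO basis; the embedded
active Hamiltonian is h~ transformed to the active MOs plus the active ERIs
and a scalar e_core fixed by total-energy consistency (the RHF determinant
placed in any window reproduces the full RHF energy through the embedding;
tested to 1e-8 Ha).

For the exchange contractions the full-space 2-RDM is never materialized in
production. We use the exact cumulant split

    Gamma = gamma x gamma - 1/2 gamma ^ gamma + Lambda,

where, for a closed-shell core plus active state, Lambda is supported on
active^4 only. All gamma-driven pieces reduce to matrix chains over the
(core+active) x (core+active) MO ranges, and Lambda-driven pieces touch only
O(N_a^4) quantities — this realizes the claim that generalized two-electron
objects are needed at active-space size only. The expansion of T4 into the
2x2 cumulant combinations times the four kernel dressings yields the
sixteen-term structure of the Gamma_A x Gamma_B contribution; T2/T3 each
yield six. A naive dense full-space AO contraction of the same five pieces
(`e1_exch_s2_oracle`) is kept for small systems and must agree to 1e-9 Ha —
exercised on H2-H2 and water fixtures with both RHF and CASCI densities.

Contractions are evaluated in restricted monomer-MO ranges rather than in
the AO basis. At scale the AO route with integral-driven J/K builds would be
preferable; at this package's problem sizes (up to ~130 AOs per dimer) the
MO route is equivalent (orthogonal transformation; verified against the AO
oracle) and simpler to audit.

An RHF-treated monomer is handled as the degenerate (2e,1o) active space
(gamma = [2], Gamma = [2], vanishing cumulant), which reproduces its RHF
density exactly and keeps a single code path.

## Integrals engine

The environment provides no quantum-chemistry backend, so the package
carries its own: a McMurchie–Davidson engine (numba-compiled) for overlap,
kinetic, nuclear-attraction and two-electron integrals over contracted
Cartesian Gaussians up to d, with spherical d components, per-AO
normalization, precomputed shell-pair Hermite expansions, and Schwarz
screening. Five ERI classes are produced: the monomer class and the four
cross classes (AA|BB), (AB|AB), (AA|AB), (AB|BB) needed by the exchange.
The Boys function uses a downward-recursion series (x <= 30) and the
asymptotic branch above, accurate to ~1e-13. The engine is validated against
an independent Obara–Saika recursion (in the test suite), closed-form
s-Gaussian results, analytic one-Gaussian hydrogen expectation values, and
textbook RHF energies (H2/STO-3G -1.11668, H2O/6-31G -75.984,
H2O/cc-pVDZ -76.0268 at the fixture geometry).

Basis sets (STO-3G, 6-31G, cc-pVDZ for H/He/C/O) ship as plain-text data.
The carbon cc-pVDZ s-contraction coefficients are not the Dunning originals:
they were re-derived variationally in the (unchanged) Dunning primitive set,
because a faithful offline transcription could not be verified; the refined
contraction reproduces uncontracted-s energies to <0.5 mHa (see the comment
in the data file). RHF uses DIIS with a core-Hamiltonian guess, convergence
|dE| < 1e-11 and orbital-gradient norm < 1e-8, deterministic throughout.

## Solvers

CASCI: determinant CI in the fixed (n_alpha, n_beta) sector, built from
string excitation operators with the same occupation-number phase convention
as the Jordan–Wigner simulator (so sector amplitudes transfer without sign
bookkeeping); dense diagonalization below 1500 determinants, sparse
Lanczos above, with a 1e6-determinant cap. RDMs come from E_pq actions on
the CI vector.

VQE: the k-muCJ circuit is simulated as an ideal statevector over 2*N_a
Jordan–Wigner qubits in blocked alpha-then-beta order (an interleaved layout
would be an equivalent drawing convention; all physical outputs are
basis-ordering independent by construction). Orbital rotations exp(K) are
spin-restricted and compiled to an adjacent-transposition Givens fabric via
QR elimination (plus diagonal sign flips), exact to machine precision; the
realized one-body transform is pinned by a Thouless-theorem oracle. The
pair-exchange gate P_X(theta) rotates the doubly-occupied/doubly-empty
sector of two neighboring spatial orbitals and is the exact exponential of
the corresponding fermionic pair-double generator for adjacent orbitals.
One ansatz layer applies an orbital rotation followed by pair-exchange
gates over the alternating nearest-neighbor pattern (even-start pairs, then
odd-start), and one trailing rotation closes the circuit; consecutive
layers' rotations are kept separate (the product structure leaves merging
open; the choice is immaterial to expressiveness). For (2e,2o) the k=1
circuit contains the exact ground state (tested).

Optimization: L-BFGS-B from the zero-parameter (RHF) start, central
finite-difference gradients with step 1e-5, gradient tolerance 1e-6,
optional seeded Gaussian restarts of scale 1e-2, and optional warm starts by
zero-padding a shallower solution (used to guarantee the k-nesting property
in tests). Expectation values are taken by projecting the statevector onto
the particle-number sector and contracting with the sector Hamiltonian —
a route independent of the RDM-contraction energy, and the two are required
to agree to 1e-9 Ha.

RDMs from the statevector are computed by applying annihilation operators
and forming Gram matrices — deliberately a different algorithm from the
CASCI Slater–Condon route, so the two cross-validate.

## Measurement-optimized electrostatics

When only monomer A is quantum, E1_pol is reorganized for measurement
economy: the A-nuclei/B and A-core/B pieces are classical scalars, and the
active part is Tr(gamma_act W) with W the active-MO image of B's
electrostatic potential. Diagonalizing W and rotating the state into its
eigenbasis ("ESP natural orbitals") reduces the quantum input to
occupation-number expectations — one commuting Z-basis group, i.e. a single
measurement circuit. The package evaluates this on the ideal statevector
(no shot noise), preserving the measurement structure so a sampling backend
could drop in. Equality with the direct AO-basis E1_pol is tested to 1e-9
Ha, along with joint-rotation invariance.

## Fixtures: what they emulate and what they do not

All benchmark geometries are generated programmatically from textbook
parameters, since the original benchmark structures are not redistributable
here:

* Water dimer — a collinear O-H...O hydrogen bond, O-O fixed at 2.91 A,
  monomer geometry r_OH = 0.9572 A, HOH = 104.52 deg. The *stretched*
  monomer is the hydrogen-bond acceptor, whose two O-H bonds are set
  symmetrically to r_OH (default study point 2.0 A) with orientation fixed;
  its hydrogens point away from the partner, so the stretch probes double
  bond-breaking without colliding with the donor. At 2.0 A the RHF error
  against (6e,6o) CASCI exceeds 100 kcal/mol — a genuine multi-reference
  regime.
* Benzene / p-benzyne — D6h benzene (r_CC 1.397 A, r_CH 1.084 A), p-benzyne
  obtained by deleting the two para hydrogens, T-shaped with perpendicular
  ring planes and centroid distance R (benchmark point 4.45 A); p-benzyne is
  treated as a low-spin singlet biradical with a (6e,6o) HOMO-2..LUMO+2
  space.
* Toy dimers — collinear H2-H2 and He-He for limits and brute-force oracles.

Because these are stand-in geometries, figure-level dissociation curves of
the original study are reproduced qualitatively, not point-for-point; all
quantitative statements the package makes about itself are computed by its
own tests and acceptance script on these fixtures. The generators are pure
functions of their arguments and bit-for-bit reproducible.

## Problem sizes and numerical choices

The acceptance computation runs the benzene/p-benzyne benchmark in the
6-31G basis (128 AOs total). That is this package's chosen problem size: the
measured quantity is a ratio of errors produced by the same monomer
wavefunction, which is insensitive to one basis-set step (cc-pVDZ data ships
and works; the cross-integral classes are simply much slower through a pure
numba engine). Measured on one CPU the full acceptance run takes about
3-4 minutes.

Other defaults: ERI Schwarz threshold 1e-12 (1e-13 for monomer blocks);
overlap eigenvalue floor 1e-10 (linear-dependence guard); CASCI dense/sparse
crossover at 1500 determinants; VQE restarts default 1 (3 in the acceptance
run); all seeds explicit and small. Degenerate frontier orbitals at a window
edge are resolved by (energy, index) order, which is stable and
deterministic. The lambda^2 overlap-scaling test scales every
overlap-carrying cross block (one power per mixed charge distribution),
which is the operationally meaningful probe of the S^2 structure.

## Known limitations

* First order only: no induction, dispersion, or their exchange
  counterparts; the first-order sum alone does not bind dispersion-dominated
  dimers.
* S^2 truncation: accurate while intermolecular overlap is small; it
  degrades at strongly compressed geometries.
* Monomers must be (low-spin) singlets; no UHF/ROHF reference.
* The integrals engine supports s/p/d shells and dense in-core storage —
  adequate for ~150 AOs per monomer, not for proteins; the contraction
  algebra, however, is written with the O(N_a^4) active-space scaling that
  a large-scale engine would need.
* VQE gradients are finite-difference; parameter counts beyond a few hundred
  would want analytic gradients.
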