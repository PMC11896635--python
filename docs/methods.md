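# Methods

`spinhop` simulates radiationless decay of photoexcited heavy-atom
chromophores — intersystem crossing (ISC) in particular — with mixed
quantum–classical trajectory surface hopping on model vibronic
Hamiltonians.  This note records the model, the numerical choices, and
what the synthetic systems do and do not establish.

## Model Hamiltonian

The electronic-structure provider is a linear vibronic coupling (LVC)
model.  Nuclear degrees of freedom are independent harmonic modes
(frequency ω in cm⁻¹, reduced mass m in amu); the diabatic potential
matrix over `n_S` singlets and `n_T` triplets is

    W_ii(x) = E_i + Σ_k κ_ik Δx_k + Σ_k ½ m_k ω_k² Δx_k²
    W_ij(x) = Σ_k λ_ijk Δx_k        (same-spin off-diagonal)

with Δx the displacement from the origin.  All states share the ground
state's curvature; crossings arise from the vertical energies `E_i` and
the state-specific gradients κ.  The *spin-diabatic* basis Θ used by the
dynamics consists of the eigenstates of the same-spin blocks of W
(singlets and the three M_S components −1, 0, +1 of each triplet,
ordered singlets first).  With all λ = 0 — true of every shipped
template — Θ coincides with the primitive diabatic basis.

Spin–orbit coupling (SOC) enters as complex matrix elements between
singlets and triplet components (cm⁻¹).  SOC magnitudes may depend on
geometry through per-coordinate linear/quadratic modulations (phases kept
fixed); this mimics the growth of SOC when a planar chromophore bends
out of plane.  The two-component Hamiltonian in the truncated
spin-diabatic basis is

    H(x; α) = diag(E_scalar(x)) + α · V_SOC(x)

where α ≥ 1 is the acceleration factor applied to SOC only — the
diagonal and any same-spin coupling are never scaled.  Diagonalizing
H U = U E yields the *spin-adiabatic* states Φ = Θ U in which trajectories
propagate; spin-diabatic amplitudes are recovered as b = U c, and
reported populations are ensemble averages of |b_i|² with triplet
components summed per triplet.

Internal units are Hartree atomic units; interfaces accept and emit
eV, cm⁻¹, fs, amu and degrees (CODATA 2018 conversion constants,
centralized in `spinhop.constants`).  Per-mode coordinates are in bohr;
the harmonic energy of a displaced mode is ½mω²Δx² exactly.

## Initial conditions

Coordinates and momenta are sampled from the Wigner distribution of a
canonical ensemble of independent quantum harmonic oscillators:
per-mode Gaussians with σ_q² = (ħ/2mω) coth(ħω/2k_BT) and
σ_p² = (mωħ/2) coth(ħω/2k_BT), independent of each other.  The default
temperature is 298 K.  Ensemble member i draws from a stream derived
deterministically from (seed, i).  Trajectories start in the
spin-adiabatic state with the largest squared overlap with the requested
spin-diabatic label (S1 by default), with the electronic coefficient
vector c set to that basis vector.

## Trajectory propagation

One nuclear step (default dt = 0.5 fs) is a three-stage cycle:

1. **Nuclei** — velocity Verlet on the active spin-adiabatic surface.
   The force is the exact Hellmann–Feynman expectation of the analytic
   diabatic-matrix gradient in the active eigenvector, including the
   α-scaled SOC-modulation gradient.
2. **Electronic structure** — diagonalization at the new geometry,
   followed by gauge alignment against the previous step: columns are
   matched by maximal |overlap| (linear-sum assignment over the
   *primitive-basis* overlap, so rotations of the scalar eigenbasis are
   included), each matched column's phase is rotated to make its overlap
   real non-negative, and eigenvalue clusters closer than 10⁻¹⁰ hartree
   are aligned jointly by a unitary Procrustes rotation (individual
   eigenvectors are arbitrary inside a degenerate subspace — the three
   components of an uncoupled triplet are the everyday example).
3. **Electrons + hops** — substepped unitary propagation (default 20
   substeps, 0.025 fs) and a single hop decision per nuclear step.

**Electronic propagator.** The trajectory driver propagates the
coefficients in locally diabatized form: the end-of-step Hamiltonian is
rotated into the frame of the step-start eigenstates with the (exactly
unitary) eigenvector overlap O, the Hamiltonian is interpolated linearly
across the substeps, each substep applies an exact matrix exponential,
and the result is rotated into the new basis with O†.  In the adiabatic
(slow) limit this is equivalent to integrating i ċ = (E − iħT) c with
finite-difference time-derivative couplings T; that equivalent form is
exposed as `electronic_propagate` and `tdc_estimate`.  The locally
diabatized form was chosen because it remains exact in the *sudden*
limit: a weakly avoided crossing whose mixing region is traversed within
a single step ("trivial crossing") rotates the adiabatic basis by π/2 no
matter how small the coupling, and a finite-difference T sampled on the
step grid then mis-transfers amplitude by orders of magnitude.  Against
an exact two-level time-dependent Schrödinger oracle driven along the
same nuclear path, single-passage transfer probabilities agree within a
few percent from the deeply diabatic (10⁻⁴ transfer) to the adiabatic
(0.7 transfer) regime.

**Hopping.**  Fewest-switches probabilities are evaluated once per
nuclear step from the total step propagator P (c' = P c):

    g_j = (1 − |c'_k|²/|c_k|²) · max(0, Re(c'_j P*_jk c*_k)) / Σ_l max(0, …)

with k the active state — the active-state population loss, distributed
over the states that coherently received it.  A drawn hop is accepted
only if the kinetic energy covers the electronic gap; accepted hops
rescale the *full momentum vector* by a single scalar so total energy is
conserved exactly (to < 10⁻⁸ hartree).  Insufficient kinetic energy
makes the hop "frustrated": it is rejected and logged, momenta unchanged
(no velocity reversal).  Uniform rescaling and no-reversal are
deliberate choices: they are well defined for model Hamiltonians of any
dimensionality and keep the acceptance test purely energetic; rescaling
along a nonadiabatic coupling vector is not implemented.

**No decoherence correction** is applied anywhere; the coefficients
evolve strictly unitarily between hops.  Decoherence corrections were
designed for localized, quickly damped couplings and are of uncertain
benefit when SOC is included.

## Accelerated ISC and kinetics

Golden-rule rates are proportional to the squared coupling, so scaling
SOC by α accelerates ISC by α² and τ_α = τ₁ α⁻².  The production recipe
runs ensembles at several α > 1 (protocol default: α ∈ {2, 3.5, 5},
20 trajectories each, 200 fs horizon — 100 fs at α = 5 — at 298 K),
fits the population curves, and extrapolates the fitted lifetimes back
to α = 1.

Fits: triplet growth p(t) = A(1 − e^{−(t−t₀)/τ}) with A ∈ [0, 1];
singlet decay p(t) = B + A e^{−(t−t₀)/τ} with B ≥ 0.  In the decay form
A and t₀ are degenerate (only A e^{t₀/τ} is identifiable), so t₀ is
pinned to the first time point and A absorbs the shift.  Initial guesses
come from the curve's fractional crossing times; degenerate (flat) input
raises an error rather than returning a number.

Extrapolation: an *unweighted free-slope* least-squares line of log₁₀ τ
vs log₁₀ α, τ₁ = 10^intercept, with the fitted slope reported for
comparison with the theoretical −2.  The free slope is deliberate:
fitted lifetimes from finite ensembles deviate from the exact α⁻² law,
and the free-slope line is the reproducible convention.  Applied to the
published fitted time-constant triples at α = (2, 3.5, 5) this yields
τ₁ = 6.06 ps (triplet growth; fitted slope ≈ −3.98), 1.73 ps (S1 decay)
and 1.93 ps (overall singlet decay).  Note an inconsistency surfaced by
the strict inverse k = 1/τ: 1/6.06 ps = 1.650×10¹¹ s⁻¹, whereas the
value printed alongside that lifetime in the source study is
1.73×10¹¹ s⁻¹; the package implements k = 1/τ and leaves the discrepancy
to the reader.

Rate formulas: the fluorescence rate is the Einstein spontaneous-emission
coefficient k_F = 2π e² E_F² f / (h² ε₀ m c³) (E_F the emission energy, f
the oscillator strength; at E_F = 2.56 eV, f = 0.58 it evaluates to
1.649×10⁸ s⁻¹), and the triplet quantum yield is
Φ_T = k_ISC/(k_ISC + k_IC + k_F).

## Spectra and curve metrics

The nuclear ensemble approach (NEA) averages, over a geometry ensemble,
the sum over excited states of oscillator strength × a unit-area
Gaussian centered at the vertical excitation energy.  Cross-sections are
reported in arbitrary units (the energy-dependent prefactor is dropped),
sufficient for peak positions and shift comparisons; vibrational fine
structure is absent by construction.  Default broadening width 0.05 eV
(a user parameter).

Non-parallelity of two curves on a shared grid:
NP(f, g) = max|f−g| − min|f−g|; symmetric, zero under constant shifts,
no interpolation (grids must match).

## Hop analysis and SOC rules

A hop's spin-diabatic character is weight(i, j) = |U_i,from|²·|U_j,to|²,
triplet components merged; each accepted hop contributes total weight 1.
Hop-based counting misses diabatic-character transfer that occurs
continuously within one active spin-adiabatic state, and partial mixing
produces artifact diagonal entries — both are inherent limitations of
the bookkeeping, flagged in the API (`diagnostic` mode).  Frustrated
hops are excluded from aggregation by default.  Dihedral angles use the
standard two-plane-normal construction mapped to [0°, 360°) with
trans-planar = 180°; occurrence histograms default to 1° bins.

The qualitative SOC classifier encodes the one-center Slater–Condon
selection rules: large SOC requires the two states to differ in a single
MO pair whose members carry strong admixtures of *different* (mutually
perpendicular) valence p orbitals of the *same* heavy atom.  Four
magnitude categories are anchored at ~1–9 ("units"), ~10–99 ("tens"),
~100–2000 cm⁻¹, and ~2300 cm⁻¹ (the atomic-like value when both MOs are
essentially iodine p orbitals, e.g. a closed shell against an (n,σ*)
state).  Borderline cases — e.g. (π,π*) vs (π,σ*) sharing the source π —
are encoded as "tens" with a "moderate, text-derived" rationale, since
the qualitative wording does not pin them more precisely.  The
classifier is a transparent rule table used for fixture design and
report annotation; it computes no integrals.

## Synthetic model systems

`two_manifold_golden_rule` is constructed to *be* in the golden-rule
regime: a bright donor singlet at 3.0 eV over six triplet acceptors
detuned by 0.01–0.07 eV, three modes (450/750/1100 cm⁻¹), slope
differences of ~0.4–0.7 eV/bohr, and per-component SOC of
(default) 15/√3 cm⁻¹.  The construction logic, in Landau–Zener terms:
thermal+zero-point motion modulates each singlet–triplet gap by roughly
0.1 eV, sweeping every gap through zero once or twice per vibrational
period (≈ 0.1–0.2 passages/fs in total), while the per-passage transfer
probability 2πV²/(ħ|dΔE/dt|) stays small (a few percent) even at α = 3,
so the ensemble decay is near-exponential with lifetime ∝ α⁻².  At much
larger coupling the per-passage probability saturates (1 − e^{−2πΓ})
and the apparent acceleration law flattens — that regime is outside the
template's design envelope and of the α² recipe generally.

`bodipy_like_37state` is a surrogate heavy-atom chromophore: 7 singlets
+ 10 triplets (spin-basis dimension 37), singlet ladder anchored at
published vertical excitation energies of an iodinated BODIPY dye
(S1 2.96 eV / f 0.74, then 3.66/0.10, 3.93/0.08, 4.37, 4.54 eV), SOC
magnitudes drawn per state-character pair from the selection-rule
categories, and a soft 25 cm⁻¹ out-of-plane mode with a quadratic SOC
modulation.  It exercises the full pipeline at realistic dimension; its
dynamics is *not* a reproduction of any molecule's photophysics — the
system-specific quantities of the source study (triplet saturation
levels near 60–82%, Φ_T = 0.85, ab initio excitation energies and SOC
tables) require a quantum-chemical backend and are out of scope here.

## Measuring the acceleration exponent

Ensemble decays of hopping simulations are near- but not strictly
single-exponential (trajectories carry heterogeneous effective rates),
so a fitted "lifetime" depends on the observation window.  Two protocol
rules make the α-scaling measurement well defined: (i) the per-α
horizon scales as α⁻², so every ensemble is observed over the same span
in units of its expected lifetime and the window bias cancels in the
lifetime *ratios* the law is about (the production recipe's shorter
horizon at its largest α embodies the same logic); (ii) the lifetime is
taken from a log-linear fit of ln p vs t (`fit_rate_loglinear`), which
has no amplitude/offset degeneracy — the nonlinear offset fit is
unidentifiable on windows of ≲ 1 lifetime and can latch onto the early
coherent transient.  The first 10% of each window is excluded as that
transient.

The in-suite α² study runs 200 trajectories per α at α ∈ {1, 2, 3} with
6 electronic substeps per 0.5 fs nuclear step (substep convergence
checked against the 20-substep default: ensemble rates agree to all
printed digits) and horizons of 1000/250/111 fs.

## Known limitations

- FSSH without decoherence overestimates coherence; ensemble decays on
  dense manifolds equilibrate toward the microcanonical distribution of
  the included states rather than decaying to zero (fits use a floor
  offset for this reason).
- The α² acceleration law is exact only in the perturbative regime.  On
  the golden-rule template the transfer rate follows V² cleanly
  (measured exponent 1.98–2.08) for total SOC up to ~6–10 cm⁻¹; at the
  couplings needed to make the unaccelerated decay directly simulatable
  within minutes (≈ 16 cm⁻¹, so 48 cm⁻¹ at α = 3) the scaled coupling
  approaches the acceptor-manifold level spacing and the measured
  acceleration exponent softens to ≈ −1.7 (a further ≈ 0.07 of which is
  finite-time-step bias at 0.5 fs).  Practitioners extrapolating from
  large α should expect — and the source methodology itself observes —
  free-slope fits that deviate from the ideal −2.
- Hellmann–Feynman forces are not unique at exact eigenvalue
  degeneracies; no regularization is applied in the model layer (the
  gauge machinery handles the adjacent near-degenerate cases).
- Uniform momentum rescaling and frustrated-hop non-reversal are
  conventions, not derived; sensitivity studies can use the hop log.
- The LVC family with shared curvature cannot represent anharmonicity,
  Duschinsky rotation, or true conical-intersection topographies beyond
  linear coupling.
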