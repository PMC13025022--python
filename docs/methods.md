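# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic test systems do and do not show about real
protein data.

## Units and constants

GROMACS molecular units throughout: length nm, time ps, mass amu, energy
kJ/mol, temperature K. In these units 1 kJ/mol = 1 amu nm²/ps² exactly, so no
conversion factors appear in kinetic energies or spring constants;
k_B = 0.008314462618 kJ/mol/K. Frequencies are wavenumbers ν in cm⁻¹ with
ω = 2πcν, c = 0.0299792458 cm/ps. TRR input (Å, Å/ps via MDAnalysis) is
converted to nm, nm/ps on read.

## Coarse-graining

One bead per glycine; two beads per other residue. The backbone bead takes
{N, H(N-H variants), CA, HA*, C, O, OXT/OT*}; the side-chain bead takes every
remaining atom, hydrogens included. This partition is a package choice (the
standard backbone/side-chain split); it is configurable through the
`backbone_atoms` argument. Bead position and velocity are mass-weighted means
of the member atoms, so bead mass, total mass and total momentum are
conserved exactly — the momentum-conserving velocity map is required for the
mass-weighted correlation formalism to preserve kinetic-energy bookkeeping.
A non-glycine residue with no side-chain atoms collapses to one bead with a
warning. Atom masses come from an element table keyed on the atom-name
convention; unknown elements need an explicit fallback mass.

## Reference-frame alignment

Weighted Kabsch superposition (SVD with a determinant guard, so rotations are
always proper). Default alignment weights are the bead masses over all beads;
backbone-only weighting is available by passing custom weights. Velocities
are rotated by the frame's rotation; the rigid-body velocity components are
*not* subtracted — they are signal (zero-frequency modes 1–6). At the Kabsch
optimum the cross-covariance with the reference is symmetric, which is the
Eckart-like condition the tests verify. Alignment is idempotent.

## Velocity-correlation spectrum

`C_ab(t) = ⟨√(m_a m_b) v_a(0) v_b(t)⟩` is estimated with every frame as a
time origin (configurable stride) up to t_max = 2 ps at the 20 fs sampling
interval (101 lags), then time-symmetrized, C ← (C + Cᵀ)/2.

Transform convention (documented so the Parseval check is exact): the lag
series is multiplied by a time-domain Gaussian `exp(−t²/2σ_t²)` with
σ_t = 2√(2 ln 2)/(2πc·FWHM), which makes the implied spectral smoothing a
Gaussian of the configured full width at half maximum (default 10 cm⁻¹ — the
"10 cm⁻¹ Gaussian window" is interpreted as an FWHM; σ-parameterisation is a
one-line change via `gaussian_taper`). The windowed, symmetric lag series is
zero-padded to 4× its length (configurable) and cosine-transformed; the
one-sided spectrum per cm⁻¹ doubles every bin except ν = 0 and Nyquist. With
this convention `Σ_j S(ν_j) Δν = C(0)` holds exactly because the taper is 1
at t = 0; the test suite checks it to 1%. Only relative intensities matter
for mode ranking, so the overall normalisation is a bookkeeping choice.

"Zero frequency" is grid point 0 exactly. Eigen-decomposition uses the
symmetric solver; modes are sorted by eigenvalue descending with a
reproducible sign convention (largest-magnitude component positive) and ties
broken stably. Eigenvalues are the per-mode VDoS contributions; their sum
equals the trace of C̃(ν). Per-mode projected spectra use the same estimator
normalisation as the matrix path, so summing them over a complete mode set
reproduces the total VDoS to machine precision.

## Mode comparison

Pairwise mode correlation is |a·b| in mass-weighted space (sign-invariant;
Cartesian comparison available by supplying unweighted vectors). Subspace
correlation is the RMSIP, √((1/k)Σ(a_i·b_j)²), which is invariant under any
orthogonal remixing within either set — a swap or mixing of modes 8 and 9
between replicas cannot change it. A geometric-mean-of-singular-values
alternative is selectable. Rigid-body classification projects each mode on
six orthonormalised mass-weighted vectors (3 uniform translations, 3 `r×ê`
rotations about the mass-weighted centroid, Gram–Schmidt against the
translations); the default rigid threshold is a projection norm of 0.8.
The quasiharmonic baseline diagonalises the mass-weighted displacement
covariance of the aligned trajectory.

## Collective variables

`evaluate_cv` aligns the (bead) frame to the CV's reference with the CV's
weights, takes displacements, and projects. The default projects mass-weighted
displacements √m_i Δr_i onto the eigenvector — consistent with the space the
eigenproblem lives in (units nm·amu^½); a plain-Cartesian option exists. For
a mode orthogonal to the rigid-body subspace the alignment is exactly the
identity for frames displaced along that mode, which makes the CV exactly
linear there; alignment makes it invariant under rigid motion of the input
(verified to 1e-8). The PLUMED writer emits one valid realization of the same
recipe — FIT_TO_TEMPLATE alignment, CENTER beads, COMBINE with the projection
coefficients and reference parameters, and a METAD action over exactly two
CVs. Metadynamics parameters have no defaults in the writer: all five
(height, sigma, pace, bias factor, temperature) must be supplied explicitly,
so production inputs cannot inherit silent values. Correctness of bias forces
propagated through the alignment Jacobian is the external engine's concern.

Mode files are text: metadata, then hex-float payload lines guarded by a
sha256 checksum. Hex floats make the round trip bit-exact and the format
endianness-neutral; truncation errors report the byte offset.

## Toy metadynamics and reweighting

The generator runs BAOAB Langevin dynamics on an analytic potential
(double well `B((x/a)²−1)²`, harmonic valley, or a Müller–Brown-like sum of
Gaussians scaled to molecular energies) and deposits Gaussians every `pace`
steps with the well-tempered height `h·exp(−V_bias/((γ−1)k_BT))`. Biased CVs
are rows of an optional linear map of the coordinates, so a run can be biased
along one combination and analysed along another; COLVAR always records the
raw coordinates. Output follows the PLUMED text dialect (`#! FIELDS …`),
floats written with shortest-round-trip precision.

Reweighting: default "final-bias" weights `w ∝ exp(+V(s, t_end)/k_BT)` with
the first 20% of the deposition period discarded (configurable); a
Tiwary–Parrinello time-dependent estimator (c(t) evaluated on a CV grid) is
selectable. Both recover the analytic double well to < 1 k_BT in the tests.

## Free-energy surfaces and metrics

Histograms default to 50 bins per axis over the data range padded by 5%;
bins with fewer than 5 effective samples (Kish count (Σw)²/Σw² per bin) are
masked. F = −k_BT ln P, gauge-fixed to min 0. Replica averaging averages the
*probability* distributions, then transforms; per-bin std across replicas is
computed on per-replica F after shifting each to min 0, and SEM = std/√R.
S₂ = −Σ p log₂ p (bits) over the normalised occupied-bin distribution — the
entropy therefore depends on the binning, which must be shared between any
two surfaces being compared, as the Bhattacharyya coefficient Σ√(p_a p_b)
already requires. State ΔF = −k_BT ln(P_B/P_A) over rectangle/ellipse/callable
regions; an empty region yields a signalled infinity rather than a number.
Microstates come from seeded k-means (scikit-learn) with sample weights. The
minimum free-energy path is the lowest-maximum (minimax) path on the
8-connected bin graph via a Dijkstra-style search — it reports the profile
with propagated per-bin std/SEM; a steepest-descent string method is out of
scope.

## Synthetic systems: what they emulate, and what they don't

* `HarmonicNetwork` — pairwise springs, analytic Hessian, rotation-invariant.
* `QuadraticNetwork` — a prescribed mass-weighted eigen-spectrum. Used where a
  test needs exact control of mode frequencies. Its quadratic form is *not*
  rotation-invariant, so linearized rigid rotations must either be confined
  (default 70 cm⁻¹ in `soft_mode_network`) or supplied by composition:
  `diffusing_network_trajectory` superimposes exact rigid-body diffusion
  (Ornstein–Uhlenbeck centre-of-mass and principal-axis angular velocities,
  exact one-step covariances) on the internal Langevin dynamics. Neglecting
  rotation–vibration coupling is precisely the approximation an aligned-frame
  analysis assumes, so this composite is the appropriate oracle for it.
* `two_state_system` — a quartic double well of configurable barrier along
  one known mass-weighted direction, one soft harmonic direction (10 cm⁻¹)
  and a stiff remainder; pinned (no free rigid modes), minima and transition
  mode known analytically. At a 7 k_BT barrier a ~2 ns replica crosses
  zero-to-few times (the measured rate, not a Kramers estimate, chose this
  value): displacement covariances become seed-dependent while velocity
  correlations do not, which is how the suite reproduces the qualitative
  PCA-vs-velocity-mode reproducibility ordering.
* The Langevin integrator is BAOAB with a stability guard
  (dt·ν_max·c < 0.05), Maxwell–Boltzmann initial velocities, 10% burn-in by
  default, and a kinetic-energy divergence check. At the default 20 fs step
  the kinetic temperature of an 80 cm⁻¹ mode is biased by about −1%, well
  inside the 3% equipartition tolerance used in tests.

Problem sizes in the test suite (10-bead systems, 10⁵–4.4×10⁵ frames,
six metadynamics replicas of 2.4 ns) are the package's desk-scale study
conditions; the replica-reproducibility fixture spans ≥ 2000 periods of its
slowest designed mode. Passing tests show the estimators and the protocol are
correct on systems where ground truth is analytic. They do not show that
20 ns of all-atom MD suffices for a given real protein, that a particular
backbone/side-chain split is optimal, or how the modes behave under force
field or solvation changes — those are properties of real data the synthetic
generators deliberately idealise (no solvent friction spectrum, no
anharmonic coupling between modes, no conformational heterogeneity beyond
the designed double well).

## Known limitations

* FRESEAN analysis here targets coarse-grained beads; all-atom scale is out
  of scope, as are temperature-dependent spectra and quantum corrections.
* The PLUMED input is one realization of the CV recipe; the package never
  executes PLUMED/GROMACS.
* Free-energy machinery is limited to 1D/2D grids; no block-averaging error
  analysis or multi-walker support.
* `read_topology` guesses elements from atom names; exotic naming schemes
  need the fallback-mass escape hatch.
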