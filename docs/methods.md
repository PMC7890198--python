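# Methods

This document records the models implemented in `nmakit`, the assumptions
behind them, every tunable parameter with its units and default, what the
synthetic generators do and do not emulate, and the numerical choices and
limitations a user should know about. Nothing here is an empirical claim
beyond what the test suite and `scripts/acceptance.py` compute.

## Units and constants

Internal units are kcal/mol (energy), Å (length), amu (mass), degrees
(angles), kelvin (temperature). All physical constants are derived from
scipy's CODATA table at import time, not hard-coded:

- Boltzmann constant: k_B = 0.0019872042586408316 kcal/mol/K.
- Coulomb constant: 332.0637 kcal·Å/mol/e².
- Eigenvalue→wavenumber conversion: with λ in kcal/mol/Å²/amu,
  ν[cm⁻¹] = √λ × 108.59135853528242. Negative eigenvalues (saddle
  directions) are reported as negated magnitudes, the conventional flag
  for imaginary frequencies, rather than raised as errors.

## Structure model

Structures are flat ordered atom lists with PDB-style fields; atom order
always follows the source file. Parsing is delegated to gemmi; masses come
from standard atomic weights keyed on the element. Alternate locations are
resolved per atom name (`keep-highest-occupancy` default, ties going to
altloc `A`; `keep-first` available). Selections are immutable strictly
increasing index tuples produced by a small grammar
(`chain`, `resid` ranges, `name`, `element`, `resname`, `heavy`,
`protein`, `water`, `ion`, `all`, combined with `and`/`or`/`not` and
parentheses).

Superposition is the Kabsch SVD algorithm with the determinant correction
that guarantees a proper rotation. Difference vectors superpose the second
structure onto the first over the paired selection before subtracting, so
rigid-body offsets never contaminate a transition vector. Residue pairing
between two structures takes the intersection of shared
(chain, resid, insertion-code) keys and refuses silently reordered
correspondences.

## Energy models

### Anisotropic network model (ANM)

Nodes are the selected atoms; every pair within the cutoff is joined by a
Hookean spring of constant γ. The off-diagonal 3×3 super-element for pair
(i,j) is −γ (d⊗d)/|d|² with d the equilibrium separation; diagonal blocks
are the negative sums of the row's off-diagonal blocks, which makes the
Hessian exactly translation invariant (and rotation invariant at the
equilibrium geometry) by construction.

Parameters:

| parameter | default | units | why |
| --- | --- | --- | --- |
| `cutoff` | 15.0 | Å | conventional Cα-network value; large enough that typical protein networks are rigid (exactly 6 zero modes) |
| `gamma` | 1.0 | kcal/mol/Å² | ANM frequencies scale as √γ, so a unit spring is the natural reference; absolute scale is unknowable without calibration |
| `masses` | uniform 1 | amu | Cα networks are conventionally analyzed with uniform masses; per-node masses can be supplied |

A node with no neighbor inside the cutoff leaves the network disconnected
(more than 6 zero modes); this is reported as a warning, not an error,
because partially connected networks are sometimes intentional.

### Generic potentials and numerical Hessians

`PotentialModel` wraps arbitrary energy/gradient callables with an
optional per-atom frozen mask. `numerical_hessian` central-differences the
gradient (step 10⁻⁴ Å) and symmetrizes as (H + Hᵀ)/2; rows and columns of
fixed atoms are removed. The ANM Hessian is cross-checked in the tests
against finite differences of the explicit network energy
0.5 γ Σ (|r_ij| − |r⁰_ij|)².

### Switched pair energy

For explicit electrostatics/van-der-Waals evaluation the package provides
a Coulomb + Lennard-Jones pair term multiplied by the C¹ cubic switching
function S(r) = (r_off² − r²)²(r_off² + 2r² − 3 r_on²)/(r_off² − r_on²)³
over a 6–10 Å window (1 below, 0 above). The Coulomb term is divided by a
relative dielectric (default 3, a common implicit-screening choice for
analyses without explicit solvent). Lennard-Jones parameters are given in
the well-depth/minimum-position (ε, r_min) convention.

### Minimization

Two stages: adaptive steepest descent (initial step 0.02 Å, grown ×1.2 on
an accepted downhill step, halved and rejected on an uphill one) for up to
`sd_steps` (default 1000), then Polak–Ribière conjugate gradient with
automatic restarts until the gradient RMS over free coordinates drops
below 10⁻⁴ kcal/mol/Å (default) or the step budget is exhausted. The
recorded energy trace is non-increasing by construction (uphill trial
steps are rejected). This mirrors the classic minimize-then-analyze NMA
protocol; the tolerance matters because normal modes assume a stationary
point — residual gradient shows up as slightly imaginary soft modes.

## Mode computation

`diagonalize_full` computes all 3N eigenpairs of the mass-weighted Hessian
with LAPACK (`scipy.linalg.eigh`) — the reference method, used wherever
3N is manageable.

The iterative scheme (`dimb_diagonalize`) targets the lowest `n_modes`
nontrivial modes of Hessians too large for full diagonalization, in the
spirit of mixed-basis block iteration methods:

1. The six rigid-body vectors (translations plus rotations about the
   mass-weighted centroid, orthonormalized; five for collinear systems)
   are projected out of the Hessian, P H P.
2. The coordinate space is split into contiguous blocks (default block
   size ≈ one quarter of the degrees of freedom). An initial guess comes
   from Rayleigh–Ritz over the union of each block's lowest local
   eigenvectors.
3. Sweeps over blocks diagonalize in the mixed basis of current Ritz
   vectors ⊕ the block's Cartesian unit vectors, updating the Ritz set.
4. Convergence is per-mode: 1 − |q_new·q_old| < `conv_tol` (default 0.03)
   for all requested modes.

Two design choices matter for accuracy and are deliberate:

- The working subspace is wider than requested —
  n_work = n_modes + max(10, n_modes/2) Ritz vectors are retained between
  sweeps and only the first n_modes reported. Without the buffer,
  information leaks out of the retained subspace each sweep and the
  iteration stalls far from the true eigenvectors.
- The per-mode overlap criterion cannot converge when *exactly* degenerate
  pairs rotate freely between sweeps; the spanned subspace is still
  correct (verified by principal-angle tests). For symmetric systems,
  judge convergence by subspace angles, not the flag.

## Transition analysis

Overlap percentage between two equally sized vectors is
p = [v₁·v₂/(‖v₁‖‖v₂‖)]² × 100 — symmetric, sign-invariant and
scale-invariant. Mode-difference scans compare Cartesian
(de-mass-weighted) mode shapes against coordinate difference vectors by
default, because ΔR is a Cartesian object; mass-weighted comparison is
available via `cartesian=False`. Over a complete orthonormal basis the
overlaps sum to exactly 100 (Parseval). Cumulative overlaps of
*selection-restricted* modes can exceed 100 because restricted modes are
not orthogonal on the subspace; sums above 100 are capped at 100 with a
warning rather than reported as pseudo-probabilities.

## Flexibility

Mode-sum fluctuations use classical equipartition per mode:
f_i = √( (k_B T/m_i) Σ_m a_im²/λ_m ), with a_im the atom's mass-weighted
eigenvector components. In internal units this yields Å directly. The
same quantity equals the diagonal of the pseudo-inverse covariance
k_B T · H⁺ (verified to 10⁻⁸ in the acceptance suite). A zero or negative
eigenvalue inside the requested mode range raises immediately — including
a rigid-body mode in the sum is always a mistake.

The default display temperature is T = 1300 K. This is **not** a claim
about physical temperature: elastic-network spring constants are
uncalibrated, so the absolute fluctuation scale is arbitrary, and a
conventional inflated temperature makes profile features visible on
plots. Everything temperature-dependent scales exactly as √T, so
comparisons are unaffected; pass `T=300` for physical-convention values.

B-factor conversion is the isotropic harmonic relation B = 8π²f²/3 in
both directions. Fluctuation difference profiles flag positions with
|Δf| above a threshold (default 0.2 Å — the scale at which localized
flexibility changes stand out against typical profile noise; tunable).
Group averages over named atom sets ship with a table of the transport-
site chelating oxygens of a P-type Ca²⁺ pump (carboxyl O of
E309/E771/D800/E908, T799 hydroxyl, N768/N796 amide O, V304/A305/I307
backbone carbonyls).

Per-mode correlation maps are C_ij = cosine of the angle between atoms i
and j's 3-component displacement sub-vectors — mass-weighting cancels, so
Cartesian and mass-weighted versions coincide. Atoms with exactly zero
displacement in the mode are masked (NaN row/column) with a warning.

## Helix geometry

Hydrogen bonds: with hydrogens present, donor–H···acceptor distance
≤ 2.5 Å and D–H···A angle ≥ 120°; without hydrogens, heavy-atom
donor–acceptor distance ≤ 3.5 Å. Hydrogens are associated to their donor
by covalent distance (≤ 1.25 Å within the same residue).

Helix classification labels residue i by its carbonyl's acceptor:
O(i)→N(i+3) ⇒ 3₁₀, O(i)→N(i+4) ⇒ α, O(i)→N(i+5) ⇒ π, priority α > π > 3₁₀
when several coexist (all patterns are recorded in `alternates`).
Segments are maximal runs of ≥ 3 identical labels.
**Known limitation:** without hydrogens, an ideal π-helix also satisfies
the heavy-atom i→i+4 distance criterion and the priority rule labels it
α; π-helices are only distinguished reliably when amide hydrogens are
present (the geometric angle criterion then rejects the spurious i+4
bond).

Helix axes are polylines of sliding-window Cα centroids (window 4 — one
helix turn, which cancels the helical wobble). The kink angle is the
angle between the SVD best-fit directions of two residue ranges;
curvature is the mean turning angle between consecutive axis segments.
Constructed 30° kinks are recovered within ±2° (acceptance suite).

## Synthetic generators

All generators are pure functions of their arguments and a seed
(numpy `default_rng`). What they emulate — and what they do not:

- `harmonic_chain`: a 1-D chain of longitudinal springs embedded in 3-D,
  with stiff *absolute* transverse restraints that exactly decouple the x
  spectrum. The returned analytic tridiagonal eigenvalues are the
  independent oracle for the whole Hessian→modes pipeline. Because the
  transverse restraints break translational/rotational invariance, this
  fixture is *not* a valid input for the rigid-body-projecting iterative
  diagonalizer.
- `ideal_helix` / `bent_helix`: poly-alanine backbones (N, CA, C, O,
  optional amide H) built by internal-coordinate (NeRF) placement with
  ideal bond lengths/angles and canonical dihedrals α(−57,−47),
  3₁₀(−49,−26), π(−57,−70). No sidechains and no thermal disorder; the bent variant rigidly rotates the second half about a
  perpendicular axis through the junction Cα without repairing the
  junction's backbone geometry (only the Cα trace is meaningful there).
- `hinge_pair`: two jittered cubic-lattice Cα pseudo-domains joined by a
  3-bead linker; the closed form rigidly rotates the second domain about
  the hinge. It emulates a clean two-state domain motion with an exact
  ground truth, not protein topology. The shipped defaults
  (spacing 3.8 Å, jitter 0.3 Å) with an analysis cutoff of 12 Å give an
  argmax hinge mode among the lowest nontrivial modes; the generator
  parameters were frozen before the committed-seed reference assertions.
- `folded_chain_structure`: a compact fixed-step (3.8 Å) random walk —
  connected at any cutoff ≥ the step, unlike a uniform point cloud, which
  is why it is the standard network fixture here.
- `decorated_structure` / `perturbed_copy` / `random_cloud_structure`:
  plumbing (B-factor columns, Gaussian coordinate noise, generic
  geometry clouds).

## Pipeline

`run_transition_report` executes load → modes → per-target overlap scans
→ top-mode export (NMD + correlation map) → fluctuations (+ difference
profile when a comparison system is given). The config is serialized
verbatim into the output directory; the log is one JSON object per stage
with wall time and SHA-256 input prefixes. Any failure aborts with the
stage name, preserving partial outputs. Coordinate differences below PDB
format precision (10⁻⁶ Å RMS) are rejected as identical endpoints rather
than scanned.

## Numerical choices

- Hessian symmetry is validated at construction (10⁻⁹ relative).
- Trivial-mode count is detected from the eigenvalue magnitude relative
  to the largest eigenvalue, not assumed to be six.
- Eigenvector sign convention for exported displacements: the
  largest-magnitude Cartesian component is made positive.
- NMD export stores per-mode scale λ^(−1/2); a round trip preserves
  eigenvectors to ~10⁻⁹ and eigenvalues to ~10⁻⁸ (text precision).
- Seeded child generators use `numpy.random.SeedSequence` spawning, with
  derived seeds reduced below 2³¹.

## Open design decisions and limitations

- The ANM spring constant is uncalibrated; all absolute frequencies and
  fluctuation amplitudes from network models are meaningful only up to a
  global scale. Ratios, mode shapes, overlaps and rankings are the robust
  outputs.
- The iterative diagonalizer's block size default (dof/4) trades memory
  against sweep count; it has not been tuned per system size.
- Helix classification ignores bifurcated hydrogen bonds beyond recording
  alternates, and the π-vs-α ambiguity without hydrogens (above) is
  unresolved by design — adding hydrogens is the supported fix.
- The pipeline analyzes one reference system's modes; a two-sided
  analysis (modes of both endpoints) is composable from the library but
  not a pipeline stage.
- Problem sizes in tests and examples (≈100-node networks, ≈20-residue
  helices) are the package's own choice for fast deterministic runs, not
  a statement about applicability limits; the algorithms are O(N³) for
  full diagonalization and the iterative path exists precisely for larger
  systems.
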