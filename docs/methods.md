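# Methods

`remcdock` implements enhanced-sampling Monte Carlo refinement of two-partner
complex geometries: a Metropolis–Hastings engine over rigid-body and
side-chain degrees of freedom, coupled replicas across temperature and a
softened-repulsion Hamiltonian ladder, and a well-tempered ensemble (WTE)
metadynamics bias on the potential energy.  This note records the model, the
parameters that matter, and the numerical and design choices made where the
problem left them open.

## Degrees of freedom and the pose model

A `ComplexPose` holds a fixed receptor, a mobile ligand, and continuous
side-chain χ angles on both partners.  The ligand's placement is a proper
rigid transform — unit-quaternion rotation applied **about the ligand's base
centroid**, then a translation.  The rotation centre is a genuine choice (a
rigid-body mover only needs *some* centre); the centroid makes the
translation component equal the displacement of the ligand's centre, so the
sampling-space restriction decomposes cleanly into a translation norm and a
rotation angle.  Angles are degrees at every API boundary and radians
internally; coordinates are Å; hydrogens are discarded at parse time
(the score assumes an extended heavy-atom parameterization).

χ angles are realized through a per-residue *chi topology*: an ordered list
of dihedral quadruples plus the atom set each χ rotates.  A built-in table
covers the standard amino acids (χ1–χ4 where defined; Gly/Ala have none and
proline is never moved); toy residues carry a one-χ topology supplied by the
fixture module.

## Docking score

The score keeps exactly the ingredients the sampling protocols manipulate:

* **Split Lennard-Jones.**  Base pair potential
  `E(r) = ε[(σ/r)¹² − 2(σ/r)⁶]`, minimum −ε at `r = σ = r_i + r_j`,
  `ε = √(ε_i ε_j)`.  For `r ≥ σ` the energy is attractive; inside the
  minimum the attraction is clamped at −ε and the excess is the repulsive
  term; below a switch distance `f·σ` the repulsion continues as the tangent
  line at the switch (value- and slope-continuous, so the potential is C¹
  everywhere).  All pair terms taper to zero with a C¹ cosine ramp of width
  1 Å ending at `σ + 6 Å`.
* **Softness ladder.**  A level λ ∈ [0, 1] linearly interpolates per-atom
  radii between the hard set and a soft set in which nonpolar radii are
  inflated by 1.07, and interpolates the switch fraction between the hard
  value 0.6 and the soft value **0.8**.  The soft switch must sit higher
  than the hard one: radius inflation alone *raises* the linear-branch
  repulsion at a fixed clash distance, and 0.8 is the smallest round value
  for which the repulsion is verified (numerically, over the full clash
  region) to be monotone non-increasing in λ — the property that makes the
  ladder a genuine softening.  The ladder used by the 2-D protocol is
  hard_rep, soft 50 %, 55 %, 60 %, 65 %.
* **Intra-partner clash term.**  Repulsion-only pairs between the side-chain
  atoms of χ-bearing residues and all atoms of other residues of the same
  partner, so side-chain moves cannot bury atoms into their own backbone
  for free.
* **Encounter restraint.**  Flat-bottom harmonic on the distance between the
  partners' centres: zero up to `d_max`, then `k(d − d_max)²` with
  `k = 1 score·Å⁻²`.  By default `d_max` is resolved at run start as the
  starting pose's centre separation + 5 Å — everything from the start
  inward is free, dissociation is penalized.
* **Optional Coulomb.**  Distance-dependent dielectric (`ε(r) = r`), off by
  default; the parameter table may carry a charge column.

The **interaction score** `I_sc` is the score of the complex minus the score
with the ligand rigidly displaced 500 Å (internal degrees of freedom fixed,
encounter restraint excluded from both sides).  Any displacement beyond the
cutoff is equivalent; invariance is tested.  Solvation, hydrogen bonding,
statistical pair potentials and rotamer self-energies of full docking force
fields are deliberately absent: the sampling machinery, not the force field,
is the contribution, and the score is weighted so individual terms can be
zeroed.

## Movers and proposal densities

Four kernels, drawn with weights 0.5 / 4 / 6 / 10 (rigid body, jump rotamer,
perturb rotamer, perturb χ) at the reference level:

* **Rigid body** — independent Gaussian translations on all three axes
  (σ = 0.1 Å at the reference) composed with a rotation by a Gaussian angle
  (σ = 1°) about a uniform random axis.  Symmetric, so the Hastings ratio
  is 1.
* **Jump rotamer** — pick a residue uniformly among eligible residues of
  both partners, a rotamer by library probability, then each χ from a
  Gaussian around the rotamer's means.  Forward and reverse densities are
  the full rotamer-marginalized mixtures evaluated at the new and old χ.
* **Perturb rotamer** — select the rotamer maximizing
  `p(rot)·Π N(χ_old; mean, σ)` (ties broken by lowest index,
  deterministically) and redraw χ around its means; densities are the
  single selected components, the reverse computed with the argmax under the
  *new* χ.
* **Perturb χ** — symmetric Gaussian (default, magnitude 10°) or uniform
  increments on all χ of one residue, wrapped to (−180°, 180°].

Gaussian χ densities include the ±360° wrap images, making every kernel a
proper density on the circle; on a flat energy surface the stationary law is
then exactly uniform, which the test-suite verifies per kernel.  Eligible
residues are all χ-bearing residues except proline; Gly/Ala drop out by
having no χ.

**Restriction.**  Rigid proposals leaving the closed ball of 20 Å
translation / 90° rotation around the immutable start transform are rejected
before any energy evaluation and counted as rejected steps.  A symmetric
kernel truncated this way still satisfies detailed balance on the restricted
space.  The chain's position inside the ball is asserted every step.

**Level-dependent schedules.**  Hotter/softer replicas use a linear blend
from the reference schedule toward a hot end (weights 4/2/3/5, steps
1.0 Å / 10°); the blend fraction is the mean of the replica's normalized
temperature and level indices.  The reference replica always runs the exact
reference schedule.

## Sampling protocols

All four protocols share the step kernel: select mover → propose → enforce
restriction → Metropolis–Hastings on the **total** energy (force field +
bias) → deposit WTE bias (stride 1) → periodic exchange and snapshots.

| protocol | replicas | temperatures | Hamiltonian | WTE |
|---|---|---|---|---|
| MC | 1 | 0.15 | hard_rep | – |
| REMC | 13 | geometric 0.15–0.31 | hard_rep | – |
| WTE-REMC | 5 | geometric 0.15–0.31 | hard_rep | per replica |
| WTE-H-REMC | 25 | 5 × geometric 0.15–0.30 | 5 levels | per replica |

Exchanges are attempted every 1,000 steps between neighbours; in two
dimensions the temperature and level dimensions alternate between epochs,
with even/odd pair offsets alternating within a dimension.  The exchange
test swaps *configurations* with probability `min(1, e^{−Δ})`,
`Δ = [U_i(x_j) − U_i(x_i)]/T_i + [U_j(x_i) − U_j(x_j)]/T_j`, where `U_k`
is the force-field energy under replica *k*'s Hamiltonian plus replica *k*'s
own bias at that energy.  Temperatures, Hamiltonians, biases and schedules
stay with the replica.

Snapshots are taken every 1,000 steps from the reference replica (coldest
temperature, hard_rep) and store force-field-only scores; the bias
exists to drive the walk, not to be reported.

**WTE bias.**  Binned over energy (`floor(E/width)`, width 2 score units for
docking runs, dynamically extended, never clamped), deposition height
`W = ω·τ·exp(−V_old/ΔT)` with γ = 5, ω = 1 by default and deposition stride
τ = 1.  We take `ΔT = (γ−1)T`, under which heights decay geometrically and
the bias converges; the opposite sign convention, under which deposits would
grow with accumulated bias, is available behind `delta_t_sign=-1` for
fidelity experiments but is not the default because it diverges.  Deposition
runs from step 0 (no burn-in exclusion).  For analytically small systems
(e.g. the harmonic validation system whose energy scale is ~T) the bin width
and ω must be scaled to the system's energy scale — the validation suite
uses width 0.1 and ω 0.05 there; the docking defaults are on the
docking-score scale.

**Asynchronous semantics, serially.**  The original scheme lets fast
replicas keep stepping rather than wait at the exchange barrier, ending when
the slowest replica exhausts its budget.  Executed serially here, replicas
advance round-robin one step per round, pairs exchange when both have
crossed their next stride multiple, and the run ends at the per-replica
budget — the same semantics without concurrency.  One master seed spawns
independent per-replica RNG streams plus one for exchanges; runs are
bit-identical for a fixed seed.

## Decoy analysis

* `L_rmsd`: Kabsch superposition (own SVD implementation with the
  determinant guard; never a reflection) of the decoy receptor backbone
  (N, CA, C, O; all atoms when a topology lacks those names) onto the
  reference, the transform applied to the decoy ligand, then backbone RMSD
  against the reference ligand with no further fitting.
* `f_nat`: fraction of native residue pairs (any heavy-atom pair ≤ 5 Å,
  the community contact criterion, configurable) whose minimal heavy-atom
  distance in the decoy is still ≤ 5 Å.
* Quality classes: high if `f_nat ≥ 0.5` and `L_rmsd ≤ 1 Å`; medium if
  (`f_nat ≥ 0.5` and `L_rmsd > 1 Å`) or (`0.3 ≤ f_nat < 0.5` and
  `L_rmsd ≤ 5 Å`); else none.  The first medium clause carries no upper
  L_rmsd bound and interface RMSD is not consulted; this two-class predicate
  is implemented verbatim and is more permissive than the official CAPRI
  scheme, which also ranks by interface RMSD.
* Efficiency curves: at each checkpoint, the mean of the 10 lowest
  interaction scores so far minus the overall minimum (mean over what is
  available below 10 snapshots — the curve is only guaranteed non-increasing
  once 10 exist), and the running minimum L_rmsd.

## Synthetic toy complexes

The fixture module builds miniature two-partner systems whose bound pose is
the global minimum of the package's own score *by construction*: the
receptor pocket is a triangular lattice of beads with lattice constant equal
to the contact distance σ = 4 Å, and each ligand anchor bead sits in an
"up-triangle" hollow at height `√(σ² − s²/3) ≈ 3.27 Å`, touching all three
vertex beads at exactly σ.  The hollow is the single-bead optimum on such a
patch (an on-top placement reaches one contact where the hollow reaches
three), so the bound arrangement maximizes contacts; a 10⁴-pose random scan
certifies the minimum in the test-suite and via `remcdock make-toy`.
Receptors additionally carry low-ε support beads below the plane and one
four-bead side-chain residue; ligands with ≥ 5 atoms carry one too, so all
three side-chain movers are exercised.  An optional *decoy trap* adds a
shallower, laterally displaced triangle patch (trap well depth must be less
than the funnel depth; anything else is rejected as infeasible), producing a
competing local minimum.

Start geometries follow the refinement-benchmark convention: the ligand is
displaced by exactly 15 Å in a uniform random direction and rotated by
exactly 60° about a uniform random axis through its centroid,
rejection-sampled until no inter-partner pair exceeds a hard-repulsion
threshold of 10 score units (the displacement sits strictly inside the
20 Å / 90° restriction ball).  Defaults: 16 receptor atoms, 8 ligand atoms,
funnel well depth 2 score units per contact bead.

What the toys do **not** emulate: protein topology, backbone flexibility,
realistic rotamer statistics, solvation or electrostatics, or the size of
real interfaces (hundreds of residues).  Passing tests certify the
samplers, the score implementation and the analysis — not docking accuracy
on real complexes.

## Numerical choices and problem sizes

* Kabsch rejects < 3 points and collinear sets (second singular value
  ≤ 10⁻¹⁰ of the first); quaternion extraction uses Shepperd's method.
* Angle wrap convention is (−180°, 180°] with −180 mapping to +180.
* Mixture log-densities use the log-sum-exp guard; an all-zero mixture
  evaluates to −∞ and is handled.
* Statistical validations run at fixed seeds: Boltzmann recovery on a
  harmonic single-bead system (10⁵ steps, 5,000 burn-in, thinning 20,
  KS p > 0.01), flat-energy stationarity per side-chain kernel (10⁵ steps,
  thinning 20, χ² over 18 bins, p > 0.01 — thinning is required because χ²
  assumes independent draws and the chains are autocorrelated), WTE
  broadening over 10 seeds (2×10⁴ steps each, one-sided Wilcoxon), and the
  efficiency comparison over 10 starts with a per-replica budget of 10⁴
  steps, chosen so the whole suite completes in a few minutes on one CPU.
* The sampler's inner loop precomputes per-level pair matrices (σ, ε,
  switch constants) once per topology; a brute-force double-loop oracle
  pins the vectorized path to 1 in 10⁹.

## Known limitations

* Serial execution only; wall-clock speed-ups of replica exchange are not
  modelled, only step-count efficiency.
* WTE-biased ensembles are not reweighted back to canonical averages;
  analysis uses force-field scores of reference-replica snapshots only.
* The rotamer library is a miniature stand-in with the same shape as a
  backbone-independent rotamer table; no backbone-dependent statistics.
* PDB support covers ATOM/HETATM records with chain selection; mmCIF,
  altlocs and insertion-code semantics beyond pass-through are out of scope.
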