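# Methods

## Scope and model

`ktnkit` analyses kinetic transition networks (KTNs) of peptide energy
landscapes: graphs whose nodes are local minima of a potential energy
surface and whose edges are transition states (index-1 saddles).  The
package covers the full analysis chain used for amyloid-beta monomer
landscapes — rates, first-passage kinetics, network reduction, funnel
topology, ensemble structural descriptors, hydration thermodynamics and a
graph-network solubility scorer — and ships synthetic generators that plant
every ground truth the analyses are supposed to recover.

## Rates and the master equation

Transfer rates use harmonic transition-state theory under a
uniform-frequency approximation: every minimum and saddle is assigned the
same average frequency factor nu_av, so

    k(j -> i) = nu_av * exp(-(V_ts - V_j) / (k_B T)),

with k_B = 0.0019872041 kcal/(mol K), T defaulting to 300 K, and all times
in reduced units of 1/nu_av (`RateModel.to_seconds` converts).  Energies
are kcal/mol throughout.  The rate matrix follows the column convention
K[i, j] = rate from j to i; the transition matrix Q = K − D (D the diagonal
of column sums) has zero column sums on a closed network.  Point-group
degeneracies are carried in the data model but default to 1: the
uniform-frequency estimate ignores them.  Harmonic rates satisfy detailed
balance exactly, so Q is symmetrizable — the property all kinetics here
rely on.

Equilibrium occupations are Boltzmann weights of the minimum energies,
computed with a max-shift to avoid overflow.

## First-passage-time distributions

Making a sink absorbing removes its rows/columns while the diagonal of the
reduced matrix keeps the escape rates into it.  The FPT density from an
initial occupation p0 is a sum over eigenmodes of the reduced matrix,
p(t) = Σ_l A_l |λ_l| e^{λ_l t} with A_l = (1·x_l)(y_l·p0); in log time
y = ln t each mode peaks at y* = −ln|λ_l| with height A_l/e.  Amplitudes
sum to 1 whenever the sink absorbs all probability.

Numerically the eigenproblem is solved in symmetrized form: off-diagonal
entries become geometric means sqrt(K_ij K_ji) (bounded even when Boltzmann
weights span hundreds of orders of magnitude) and eigenvectors are
transformed back with square-root Boltzmann weights recovered from rate
ratios in log space.  This guarantees a real spectrum and is the single
biggest conditioning win over a general dense solver.  Eigenvalues are
sorted slowest first; a non-negative eigenvalue beyond 1e-12·max|λ| raises
a conditioning error that points at graph-transformation reduction.

The mean first passage time is computed two independent ways — the linear
solve Q̃ᵀτ = −1 and the eigenmode sum Σ A_l/|λ_l| — and the test suite
asserts their agreement (1e-8 relative) on random networks drawn from the
well-conditioned regime (barriers 1–4 kcal/mol over a 5 kcal/mol energy
spread).  Outside that regime double-precision linear algebra on the full
matrix is *not* trustworthy, which is precisely the pGT use case below;
tests there compare against exact rational arithmetic instead.

Distributions are evaluated on a 2048-point log-time grid spanning 5 units
beyond the extreme mode peaks, with trapezoid quadrature; per-mode analytic
peaks and empirical local maxima of the summed density are both reported,
and modes with |A_l| < 0.01 are dropped from attribution reports.  Small
negative amplitudes (>-1e-10) are clipped as round-off; larger ones are
legitimate and preserved.  Per-state attribution of a mode uses normalized
magnitudes of the right-eigenvector components.

## Partial graph transformation

States are eliminated in a branching-probability / waiting-time
representation (P[i,j] = K_ij/D_jj, τ_j = 1/D_jj) with the direct
sink-escape probability ε_j carried explicitly.  Eliminating x reroutes
flux through its neighbours with denominator 1 − P_xx *always formed as the
sum of exit probabilities* Σ_{i≠x} P_ix + ε_x — never by subtraction from
1.  This is the crucial numerical point: with a deep kinetic trap the
self-return probability sits within machine epsilon of 1, and the naive
subtraction loses all significant digits (we measured 50% MFPT errors on a
20 kcal/mol-barrier landscape; the stable form agrees with exact rational
arithmetic to 3e-16).  Every update is an addition or multiplication of
positive quantities, so mean first-passage statistics of the retained
states are preserved to full relative precision regardless of conditioning.

`pgt_reduce` eliminates non-retained states in min-degree order (fewest
current branching partners, ties by id; order configurable), then converts
back to rates by resumming self-loops.  `gt_mfpt` pushes the reduction all
the way to a single source state, returning τ/ε — an MFPT route that never
performs a linear solve and is the reference implementation for
ill-conditioned networks.  FPT *distribution* preservation holds exactly
for the first moment and for the slow spectrum of the retained subspace;
exact transplantation of higher moments through accumulated waiting-time
distributions is out of scope and documented as such.

## Funnel clustering and disconnectivity graphs

Superbasins at ceiling E are union-find blocks over transition states with
energy ≤ E; minima whose own energy exceeds the ceiling are flagged
inactive.  Threshold funnel clusters ("sets of minima that can interconvert
without exceeding a threshold above their lowest member") are grown
greedily from seeds in ascending energy order, which makes the seed
provably the lowest member and the partition unique; flood-fill may
traverse already-claimed minima (interconversion paths are physical even
through claimed states) but claims only unassigned ones.  Ties on energy
break by smaller database id.  The partition provably satisfies: every
member's minimax barrier to its seed is within the threshold, and every
excluded minimum either exceeds it or was claimed by an earlier (lower)
seed — both asserted against a Floyd–Warshall minimax oracle in tests.
Cluster representatives ("selected minima") are the seeds.

The disconnectivity tree stacks superbasin partitions at a descending
ladder of ceilings (spacing is a user parameter; nothing canonical exists),
recording only merge events; leaves are minima attached at their own
energies.  A minimal matplotlib renderer is included.

## Structural descriptors

Superposition uses the Kabsch SVD algorithm with a proper-rotation
determinant correction; the default atom selection is main-chain N, CA, C,
O plus side-chain carbons (the selection used for ensemble RMSF), with
pure-CA and all-heavy alternatives.  RMSF aligns every member to the
reference and reports per-residue RMS deviation of selected-atom centroids
about the ensemble mean.  Radius of gyration is mass-weighted by default.
Distance/contact maps use C-beta positions with C-alpha for glycine;
contacts are inclusive at 8 Å and the contact matrix carries unit diagonal
(self-connections), as the graph network expects.

SASA is a Shrake–Rupley quadrature over deterministic golden-spiral sphere
points (960 by default, ~0.5% accuracy on an isolated sphere; configurable)
with Bondi radii and a 1.4 Å probe.  Polar/hydrophobic totals partition the
per-residue sums exactly.

The hydrophobic residue class is {G, A, V, L, I, P, F, M, W}: it is the
unique standard assignment reproducing the printed counts 11/23/25 for the
28-, 40- and 42-residue amyloid-beta chains.  Formal charges use fixed
values at neutral pH (D, E: −1; K, R: +1; H: 0) with free termini
cancelling — the simplest model giving each chain's net charge of −3.

## Ensemble thermodynamics

Per-structure free energies in two phases (computed externally at
force-field or semiempirical level) are combined with
G = −kT ln Σ e^{−G_i/kT} (max-shifted), the hydration free energy is the
solvated-minus-gas difference, and per-residue normalization divides by
chain length to remove the size dependence of hydrophobic surface energy.
The weighting temperature defaults to 300 K (an assumption; the source
protocols do not state it) and the same quantity is weighted and
aggregated.  Hartree inputs convert at 627.509 kcal/mol.

## GCN solubility scorer

Residue graphs carry a 91-wide feature matrix in fixed blocks: BLOSUM62 row
(20, scaled by 1/10), PSSM (20) and HMM (30) evolutionary blocks
(zero-filled here — no alignment pipeline), seven Meiler physicochemical
descriptors (scaled to comparable magnitude), secondary-structure one-hot
(3, from externally computed DSSP labels collapsed to helix/sheet/coil),
SASA min-max scaled per chain (1), and ten further sequence-predicted
structural features (zero-filled).  The published feature budget for this
model family is quoted as 94 while its enumerated blocks total 91; we
implement the enumerated 91 and note the discrepancy.

The model is two propagation layers H^{l+1} = ReLU(D⁻¹A H^l W^l) over the
binary contact adjacency with self-connections, four-head additive
attention pooling (score v_h·tanh(W_h h_i), softmax over nodes, heads
concatenated) and a final linear map + sigmoid.  The final map is linear so
the pre-sigmoid logit decomposes additively over residues as
Σ_h α_{h,i}(w_h·h_i); contributions plus bias equal the logit exactly, and
the monotone sigmoid carries attribution signs to the solubility direction.
The exact attention parametrization and output head of the published model
are not printed; ours is declared, not claimed identical.

Training is full numpy (hand-written backprop), Adam on squared error,
deterministic per seed, with 1e-4 weight decay on the weight matrices.  A
single run's held-out accuracy varies noticeably with the initialization
seed, so `train` fits a small ensemble (3 members by default, seeds derived
from the master seed) and averages pre-sigmoid logits; the average of
additive attributors is additive, so every attribution guarantee carries
over, and the seed-to-seed variance largely cancels.  Pretrained weights of
the published model and its experimental training set are external and not
reproduced; the deliverable is the architecture, attribution machinery and
the synthetic training harness.

## Synthetic generators

* **Funnel KTNs**: each funnel is a random tree of minima with energies
  rising up to 3 kcal/mol above its bottom and saddle barriers drawn from a
  stated range (default 1–5 kcal/mol); funnels join bottom-to-bottom
  through saddles at the planted inter-funnel barrier (default 20, always
  required to exceed the intra-funnel scale so the planted partition is
  recoverable).  Trees, not dense graphs, guarantee the minimax-barrier
  structure needed for exact planted-cluster recovery.  Energy magnitudes
  (bottoms near −50 kcal/mol, barriers 1–20, thresholds 5–14) match the
  real use case so numerical behaviour transfers.
* **Toy peptides**: C-alpha traces as ideal alpha-helix (1.5 Å rise,
  100°/residue, 2.3 Å radius; (i, i+4) contacts near 6.2 Å), extended chain
  (3.5 Å/residue) or self-avoiding random coil (3.8 Å virtual bonds), with
  C-beta pseudo-atoms 1.53 Å off the local chain direction and optional
  Gaussian jitter.  These exercise superposition, maps and SASA; they do
  not have physical side chains, hydrogens or realistic secondary-structure
  energetics, so passing tests show correctness of the descriptors, not
  realism of the structures.
* **Solubility datasets**: random-sequence graphs (band adjacency |i−j| ≤ 2
  plus a few long-range contacts) labelled sigmoid(Σ_i c(aa_i)) + clipped
  N(0, 0.05) noise, with planted per-residue contributions c = −0.25 for
  hydrophobic and +0.12 for polar residues — hydrophobicity depressing
  solubility, the signature the attribution analysis must recover.  Chain
  length 15–30 varies, so part of the label variance (the length factor in
  the sum) is irreducible for a mean-pooling model; a perfect oracle reaches
  R² ≈ 0.90 against the noisy labels and a composition-only predictor
  ≈ 0.83, which frames the acceptance bar of 0.8.

All generators are bit-reproducible given their seed.

## Problem sizes and numerical choices

Test-suite and acceptance-script sizes are chosen for desk-scale runs:
1000-minimum landscapes for master-equation checks, ≤100-state networks
for dual-route MFPT agreement, ≤30 states for stiff-ODE oracle comparisons,
200 random elimination trials for graph-transformation exactness, a
22-funnel planted landscape mirroring the real clustering analysis, and
500-graph training with a 500-graph held-out set for the GCN (a larger
held-out set halves the sampling noise of the R² estimate).  Exact-rational
oracles (Fraction-based Gaussian elimination and inverse power iteration)
replace floating-point references wherever conditioning makes the latter
meaningless.

## Known limitations

* Rates use uniform frequencies: no normal-mode prefactors, no
  entropic/degeneracy corrections; absolute time scales are in reduced
  units.
* pGT preserves MFPT and the slow spectrum of retained states; full
  phase-type waiting-time propagation is not implemented.
* The KTN file dialect is the whitespace min.data/ts.data convention;
  binary stationary-point formats are not read.
* DSSP labels are consumed, never computed; hydrogens are never placed.
* The solubility scorer is a desk-scale surrogate trained on synthetic
  labels; it makes no claim about experimental solubility data.
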