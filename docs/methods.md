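# Methods

## The model

`caterpillar` implements a residue-level protein model in which each amino
acid contributes one interaction sphere centred on its CA atom, while the
backbone amide (N–H) and carbonyl (C=O) groups are represented explicitly so
that hydrogen bonds can be directional.  The only degrees of freedom are the
backbone torsions (phi, psi); every bond length, bond angle and the peptide
torsion omega are fixed at standard peptide-unit values shared by all
residues (N–CA 1.458 Å, CA–C' 1.525 Å, C'–N 1.329 Å, C'=O 1.231 Å, N–H
1.000 Å; angles N–CA–C' 111.0°, CA–C'–N 116.6°, C'–N–CA 121.9°; omega =
180°, trans only).  Chains are built by sequential internal-to-Cartesian
construction in a canonical frame (first N at the origin); the carbonyl O
and amide H are placed in the peptide plane anti to the bisector of their
neighbouring backbone bonds.  The last residue has no psi; its carbonyl O
is placed with a virtual trans psi.  The first residue has no amide H and
never donates a hydrogen bond.

All energies are in reduced model units with k_B = 1; temperatures are
quoted in the same units.

### Pair term

Non-consecutive residues (|i−j| ≥ 2) interact through a continuous square
well between their CA spheres,

    E_pair = k · Σ_{|i−j|≥2} ε(a_i, a_j) · S(r_ij),
    S(r) = ½ [1 − tanh((r − r_cut) / w)],

with interaction range `r_cut = 12 Å`, switch width `w = 0.5 Å` and pair
scale `k` (see calibration below).  ε is a symmetric 20×20 contact-energy
matrix.  The matrix shipped with the package is a **synthetic stand-in** in
the family of PDB-derived statistical contact potentials: it is constructed
from the Kyte–Doolittle hydropathy scale through the
additive+multiplicative decomposition e(a,b) = c0 + c1(h_a + h_b) +
c2·h_a·h_b (h rescaled to [−1, 1]; c0 = −0.30, c1 = −0.275, c2 = −0.35),
which is known to capture the dominant component of such matrices.  Its
entries range from −1.2 (Ile–Ile) to +0.05 (hydrophobic–charged mismatch).
Because the matrix is nearly additive in hydropathy, the design stage tunes
overall composition more than specific pair patterns; a fully statistical
matrix would give the designer more pair-specific leverage.

Self-avoidance is a hard core between non-consecutive CA spheres: any pair
closer than twice the sphere radius receives an infinite-energy sentinel
and the conformation is rejected outright by every sampler.  Consecutive
CA–CA distances are fixed at 3.81 Å by construction and are exempt.  The
default sphere radius is 2.4 Å (hard-core diameter 4.8 Å): thick enough
that an ideal helix (closest non-consecutive CA pair 5.2 Å) clears it while
over-compact disordered globules are excluded — the backbone thickness does
real work in pre-sculpting the landscape.

### Hydrogen bond

Each donor H (residue i ≥ 1) and acceptor O (residue j, |i−j| ≥ 2)
interact through a 10–12 Lennard-Jones radial form modulated by the
bond-linearity angles,

    E_hb = ε_hb [5 (σ/r)¹² − 6 (σ/r)¹⁰] · A(α) · A(β),
    A(θ) = cos^m(θ − π)  for θ > 90°, else 0,

where r is the O···H distance, α the C'–O···H angle at the acceptor and β
the O···H–N angle at the donor.  Defaults: σ = 2.0 Å, ε_hb = 3.0, cutoff
4.5 Å, angular exponent m = 4.  A perfectly linear bond at r = σ scores
exactly −ε_hb, and no geometry can score below it.  The exponent was set by
refolding calibration: m = 2 is permissive enough that compact disordered
states accumulate bifurcated bonds (one acceptor serving several donors)
and compete with regular secondary structure; m = 4 suppresses them.

### Solvation (optional)

Hydrophobic residues pay for exposure in proportion to their shortfall of
CA contacts below the burial threshold:

    E_solv = k_s · Σ_i max(0, h_i) · max(0, n_c − n_i) / n_c,

with h the Kyte–Doolittle hydropathy, n_i the number of non-consecutive CA
neighbours within r_cut, burial threshold n_c = 24 and scale k_s = 1.  The
term is off by default (matching the main design protocol) and exact zero
when every hydrophobic residue is buried.

### Balance of the terms

The pair scale k balances the pair and hydrogen-bond contributions per
particle.  `calibrate_hb_balance` returns the k that equalizes |k·E_pair|
and |E_hb| on a reference structure+sequence; the shipped default was then
fixed by the refolding criterion (below), because the balance point depends
strongly on the reference sequence's hydrophobicity — with the synthetic
near-additive matrix, balancing on a hydrophobic homopolymer or on a mixed
sequence differ by a factor of ~4.

## Sequence design

Design is Metropolis Monte Carlo in sequence space on a fixed target
backbone.  A single-point mutation (uniform position, uniform new type) is
accepted with probability

    min{1, exp(−ΔE / T_design + λ · Δ ln N_perm)},

where N_perm = N! / Π_a n_a! is the multinomial permutation count of the
composition (computed through log-gamma).  The λ term rewards
compositional heterogeneity and prevents the collapse onto low-energy
homopolymers; λ = 1 by default.  Mutation energy deltas are computed
incrementally from the precomputed switch matrix of the fixed backbone and
agree with full recomputation to 1e-9.

A replica ladder of design temperatures (default: 8 replicas, geometric
from 0.05 to 2.0) is coupled by neighbour swaps after every sweep.
Because λ multiplies a temperature-independent term, it cancels exactly
from the swap detailed-balance ratio; the swap acceptance is
min{1, exp[(1/T_i − 1/T_j)(E_i − E_j)]}.

The ensemble is summarized by the Landau free-energy surface F(E, ln
N_perm) = −T ln H over the normalized 2D histogram of samples collected at
one analysis temperature (default: the rung nearest T = 0.25).  "LowF"
sequences are drawn from the occupied bins of minimal F (ties broken by
lower E, then first-seen order) — the most probable, robust designs.  The
"LowE" selector returns the raw energy minimum over the whole ladder
(including the coldest rungs) regardless of F; with the ladder reaching
T = 0.05 this control is nearly homopolymeric (poly-Ile-like), exactly the
kind of design the heterogeneity term exists to avoid.

## Folding validation

Folding is replica-exchange Metropolis Monte Carlo over torsions for a
fixed sequence, from the fully extended chain (phi = psi = 180°) by
default.  Moves perturb one torsion: a local displacement uniform in
[−Δ, +Δ] (Δ = 0.3 rad default) or, with probability 0.2, a full-circle
redraw (a pivot of the downstream tail).  Both proposals are symmetric, so
plain Metropolis acceptance is exact; hard-core overlaps auto-reject.  One
sweep = one attempted move per movable torsion; neighbour swaps follow
every sweep in an alternating even/odd pattern.  Stored energies are
revalidated against full recomputation periodically (tolerance 1e-6) to
guard against accumulation drift.

The order parameter is the DRMSD to the target: the root-mean-square
difference of all |i−j| ≥ 2 CA pair distances (rigid-motion invariant; the
|i−j| = 1 distances are fixed by construction and would only dilute the
signal).  Per-temperature DRMSD histograms (bin width 0.1 Å) give free
energy profiles F(DRMSD) = −T ln P, min-shifted to zero, with empty bins
masked, never imputed.  `refold_assessment` reports the bin centre of the
global F minimum and the largest downhill barrier encountered walking in
from the unfolded side.  A multiple-histogram (WHAM) combiner across
temperatures is provided as an optional refinement; the acceptance study
uses the single lowest-temperature histogram.

Kabsch RMSD (SVD superposition restricted to proper rotations) is reported
alongside DRMSD for best-snapshot structures; mirror-image topologies are
deliberately not superposable.

## Calibration by refolding

Four constants are not printed anywhere authoritative and were treated as
calibration targets, fixed once by the requirement that designed sequences
refold to a 16-residue helical target while the raw-energy control does
not: the sphere radius (2.4 Å), the hydrogen-bond angular exponent (4),
the pair scale default (k = 0.05), and the folding temperature ladder
(default 0.25, 0.4, 0.6, 0.9, with profiles measured at the coldest
rung).  The
calibration logic: the model's relaxed helix is the ground state of the
hydrogen-bond term alone; increasing the pair scale deepens compact
disordered ("glassy") alternatives roughly in proportion to the sequence's
total hydrophobicity.  The pair scale therefore sets a sequence-dependent
crossover — heterogeneous designed sequences still fold while maximally
hydrophobic homopolymer-like sequences become kinetically and
thermodynamically glass-bound.  The shipped defaults put typical LowF
designs on the folding side of that crossover and the LowE control on the
other.

## The scaled-down study

The full-size experiments this package's workflow mirrors (design and
refolding of ~60-residue PDB domains) are far beyond a desk budget, so the
shipped study is scaled down: a 16-residue ideal-helix target, 8 design
replicas × 1000 sweeps, 3 LowF selections, and refolding with 4 replicas ×
2×10⁵ sweeps each.  Problem sizes were chosen as the smallest at which the
design/selection/refolding contrast is meaningful.  What passing shows:
the samplers target their stationary distributions exactly (verified
against exhaustive enumeration and quadrature), the energy kernels match
brute-force oracles, and the design-then-refold loop closes at small scale.
What it does not show: transferability to real PDB backbones and
sequences, sheet-dominated topologies at scale, or quantitative agreement
with any particular published free-energy profile.

## Numerical choices and degenerate inputs

* Dihedrals use the atan2 form with the IUPAC sign convention; colinear
  triplets raise an error naming the residue.
* Terminal torsions are reported as NaN markers, never as 0.
* Masked (empty) histogram bins stay masked through every downstream
  computation.
* The design toy system for exact enumeration (6-mer, 3-letter alphabet
  A/E/I on a compact helical backbone) lives in `fixtures` and is shared
  by all sampler-correctness tests.
* RNG: one master integer seed; per-replica streams are spawned
  deterministically; every output file echoes the seed.
* Chi-squared sampler tests thin the chain (every ~20 sweeps, matched to
  the measured autocorrelation) because the statistic assumes independent
  draws; states with expected count < 5 are pooled.

### Mirror degeneracy

The backbone geometry carries no chiral centre (there are no side-chain
atoms), so the energy is exactly invariant under sign reversal of all
torsions — every conformation and its mirror image are degenerate, and a
refolding chain reaches the right- or left-handed helix with equal
probability.  DRMSD, built from internal distances, is mirror-blind and
treats both as the native basin; Kabsch RMSD, restricted to proper
rotations, is not.  A run that folds into the mirror basin therefore shows
a small argmin-F DRMSD together with a best-snapshot RMSD of several Å.
Both numbers are reported deliberately; breaking the degeneracy would
require a chirality term the model does not contain.

## Known limitations

* The synthetic contact matrix is nearly additive in hydropathy, which
  weakens pair-specific design pressure relative to a fully statistical
  matrix; design consequently controls composition more than contact
  patterns.
* Helix nucleation from the extended state is slow under single-torsion
  moves; refolding runs at the shipped sweep budgets fold reliably only
  for small chains.  Production-size targets would need larger budgets or
  collective moves.
* No side chains, no electrostatics, no explicit solvent, single chains
  only, trans peptide bonds only.
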