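# Methods

## Scope and model

`pepjunction` implements the computational side of a two-state picture of
peptide single-molecule junctions: methionine-anchored tetra- and
pentapeptides held between gold electrodes fold into beta-turn / 3_10
helical conformers (short anchor separations, high conductance) or
extended conformers (large separations, low conductance).  The package
covers five linked stages: (1) idealized all-atom peptide construction,
(2) junction-restrained conformational sampling, (3) backbone H-bond and
distance-matrix PCA analysis of the ensembles, (4) unsupervised analysis
of synthetic break-junction conductance traces, and (5) a bond-counting
tunneling-pathway estimate of how an i -> i+3 H-bond shortens the
electronic coupling route.

Electronic-structure transport (NEGF-DFT transmissions, PDOS) is out of
scope; the pathway model is the only transport estimator included.

## Peptide builder

Conformations are generated from ideal internal coordinates by NeRF
chain extension.  Backbone bond lengths and angles are standard
(N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A; tetrahedral/planar angles from
amino-acid geometry tables); omega defaults to 180 deg (trans).  Termini
are always zwitterionic: an N-terminal ammonium (H1-H3) and a C-terminal
carboxylate (O + OXT), matching measurements in water at neutral pH.
Aromatic side chains (Tyr, Trp) are embedded as planar ring templates
(regular hexagon; regular pentagon-hexagon fusion for the indole); the
proline ring is closed by side-chain torsions solved so the N-CD closure
bond is exactly 1.47 A, independent of phi.  Built backbone dihedrals
round-trip through measurement to < 1e-6 deg; all covalent bonds stay
within 15% of ideal lengths.

The shared backbone subgraph used by the PCA featurization is defined as
N, CA, C, O of each residue plus the C-terminal OXT — the unique
backbone-heavy-atom set giving 17 atoms for tetrapeptides and 21 for
pentapeptides (4n + 1 in general).  This OXT-inclusive definition is an
inference from those two counts, not an enumerated list from any source.

Backbone i -> i+3 H-bond pairs are (carbonyl O of residue i, amide H of
residue i+3); pairs whose donor residue is proline are omitted (no amide
H).  The canonical pair is 1 -> 4 for tetrapeptides and 2 -> 5 for
pentapeptides.

## Implicit-gold restraints

Three potentials replace the electrodes (kcal/mol, A, e, V):

* U1 = 1/2 k1 (z_S2 - z_S1 - z0)^2 with k1 = 1 kcal/mol/A^2 and z0 the
  holding stage (6, 9, 12 A).  The *signed* z-projection is restrained,
  which confines each sulfur to a plane, as a gold surface would.
* U2 = sum_i -q_i E z_i, E = V/(z0 + 2 l_S_Au), converting eV to
  kcal/mol via 23.0605.  l_S_Au defaults to 2.4 A (a typical Au-S dative
  bond length; chosen here, config-exposed).  The default charge set is
  a minimal zwitterion (+1 on the N-terminal N, -0.5 on each carboxylate
  O); full force-field charges may be supplied.  The default set is
  net-neutral, so U2 couples only to the molecular dipole.
* U3 = sum_i k3 (p_hat_i . z_hat)(-1)^i with k3 = 10 kcal/mol, where
  p_i = (r_S - r_CG) + (r_S - r_CE) is a surrogate for the sulfur
  lone-pair direction.  Bounded in [-2 k3, +2 k3].

All forces are analytic (including the normalization Jacobian of U3) and
verified against central finite differences to 1e-6 relative error.

## Conformational sampler

The explicit-solvent MD of the study design (16 replicates x 200 ns per
sequence and stage) is emulated by a Metropolis Monte Carlo sampler whose
energy is U1 + U2 + U3 plus a coarse intramolecular term:

* soft-sphere sterics, k_clash (r_min - d)^2 for heavy-atom pairs more
  than 4 bonds apart (k_clash = 10 kcal/mol/A^2; contact radii C 1.60,
  N 1.45, O 1.40, S 1.70 A — reduced vs van der Waals so that H-bond
  contact geometries are not penalized, and with a 1-5 exclusion because
  nearer contacts are fixed by the rigid ideal internal coordinates);
* a Gaussian H-bond well, -eps exp(-(d_OH - d_opt)^2 / 2 w^2) on every
  backbone i -> i+3 O...H distance, with d_opt = 2.0 A, eps = 3.5
  kcal/mol and w = 0.6 A.  eps is an *effective free-energy-scale*
  strength: it must out-compete the conformational entropy of the open
  ensemble at kT = 0.6 kcal/mol.  With a bare-enthalpy-like 2 kcal/mol
  and a narrow 0.3 A well the turn basin's equilibrium occupancy is ~2%
  even at the 6 A stage, which contradicts the consistent short-stage
  turn formation the sampler exists to emulate.  The well is kept wide
  and moderately deep rather than narrow and deep: a narrow 5 kcal/mol
  well gives a similar equilibrium occupancy but a kinetic barrier so
  large that chains freeze into or out of the basin for entire runs
  (and replica-exchange swaps out of the deep bound state are
  suppressed by the resulting energy gap); the wide 3.5 kcal/mol well
  yields the same stage profile with tractable bind/unbind kinetics.

The sampler state comprises (a) per-residue backbone (phi, psi), (b) the
methionine chi1/chi2/chi3 torsions, and (c) a rigid-body rotation of the
whole molecule.  (b) and (c) are essential, not optional: the builder
pins residue 1's frame, so without a rotational degree of freedom the
molecule cannot reorient relative to the z-axis restraints, and without
flexible Met side chains the sulfur anchors cannot satisfy U1/U3 while
the backbone folds.  Moves are symmetric: single-torsion Gaussian steps
(15 deg), occasional full uniform redraws (10%), rigid rotations about a
random axis (20%); proline phi is confined to [-80, -50] deg.
Initial dihedrals are drawn uniformly ((-180, 180]; proline phi in
[-80, -50] deg), matching the randomized-initial-structure protocol of
the study design.

Because the H-bond well is several kT deep, a single-temperature chain is
quasi-nonergodic at the run lengths used here (it freezes into or out of
the turn basin for an entire run).  Sampling therefore uses parallel
tempering: a geometric temperature ladder (factors 1, 1.8, 3.24 by
default), one replica per rung, replica-exchange attempts every 5
sweeps, with only cold-rung frames retained after burn-in (default
20,000 sweeps, 6,000 burn-in, thinning 20).  Tests use 12,000 sweeps
with 4 replicates per condition; these problem sizes are the package's
own choice of desk-scale defaults, and ensemble statistics are always
aggregated over replicates.

What the sampler reproduces: the analyzable *structure* of the study's
ensembles — anchor-displacement distributions centered on the stage
(variance ~ kT/k1), consistent i -> i+3 H-bonding at 6 A, depopulation
with stage and near-abolition at 12 A, and junction-orientation bias of
the S-S axis toward the pulling direction.  What it does not reproduce:
kinetics and timescales, solvent structure, force-field energetics,
side-chain rotamer statistics beyond the Met chis, and any
sequence-specific electronic effect.  Passing tests therefore validate
the analysis pipeline on ensembles with the right structure, not the
underlying MD physics.

## Trace generator

Synthetic STM break-junction traces are log10(G/G0) series on a uniform
displacement grid (0.01 A step, 3 A span).  Molecular traces (fraction
0.90 by default) carry sequentially: a contact-rupture decay from +0.3,
a high plateau at mu_H = -2.85 (mean length 0.5 A), a drop, a low
plateau at mu_L = -4.2 (mean length 0.8 A — the low state persists to
larger displacements), and a fall to a noise floor at -5.5; plateau
noise is 0.15 decades.  Background traces decay at 4 decades/A.  Both
plateaus in the same trace makes the generated ensemble dynamically
heterogeneous by construction; a "single" plateau mode (one level per
trace, 50/50) provides the static-heterogeneity contrast scenario.
Plateau levels are the two conductance states reported for these
peptides; trace shape, lengths, slopes and noise are generator
conventions.

## Trace analysis

Traces are featurized as per-trace normalized logG histograms
([-6.5, 0.5], 0.1-decade bins); the clustering literature for
break-junction data offers no single canonical featurization, so this
standard choice is config-exposed.  Cluster count is chosen by mean
silhouette score over seeded full-covariance GMM fits (k = 2..6, n_init
= 5, reg 1e-6; empty-cluster k scores -1; ties to smaller k).  Most
probable conductances come from an unweighted least-squares fit of a sum
of Lorentzians to the pooled 1D histogram, initialized at the
highest-prominence local maxima.  2D histograms re-origin each trace at
its first crossing below logG = -0.3.

Heterogeneity classification: a plateau is a run of >= 10 consecutive
points within +/-0.3 decades of a fitted level.  The ensemble is
"dynamic" if >= 60% of plateau-bearing traces contain both levels with
the high-level run first, "static" if >= 60% carry exactly one level and
the levels segregate across clusters, else "inconclusive".

## Distance-matrix PCA

Frames are represented by the upper triangle of the Euclidean distance
matrix over the shared subgraph (136 / 210 dimensions), concatenated
across sequences and stages per peptide length, Z-score standardized,
and decomposed with whitened PCA (scores rescaled to unit variance per
component; "whitening" here is defined as unit projected variance).
Zero-variance columns are dropped before standardization.  Because the
subgraph contains heavy atoms only, the O_i...N_{i+3} distances serve as
the H-bond proxy columns when ranking loadings.  The depopulation metric
is the per-stage fraction of frames with canonical O...H distance below
3.0 A.

## Pathway model

Tunneling decay is estimated by bond counting: covalent edges weigh 1,
H-bond edges weigh 2 covalent equivalents (decay through an H-bond twice
that through a covalent bond), and the best route between the sulfur
anchors minimizes L = n_cov + 2 n_hyd, with relative decay eps_C^L and
eps_C = 0.6 per covalent bond (standard pathway-model decay; config
exposed).  H-bond edges connect O to H when the O...H distance is below
2.5 A in the conformer under analysis.  Through-space jumps are not
implemented.  Ties between equal-length routes resolve to the
lexicographically smallest node sequence.

## Numerical conventions and degenerate inputs

* Dihedrals live in (-180, 180]; uniform draws map the boundary point
  accordingly.  phi/omega of residue 1 are undefined (NaN on
  measurement); psi of the last residue is defined against OXT.
* H-bond "presence" is O...H < 2.5 A (the violin-plot distance is the
  O...H Euclidean distance; the presence cutoff is a package default,
  config-exposed).  Conformer selection histograms use 0.1 A bins; mode
  ties break toward smaller distance (the structured state), then lowest
  frame index.
* Ramachandran surfaces report -kT ln p shifted to min 0 with +inf for
  empty bins; flatness checks must size bins so Poisson noise keeps
  kT ln(N_max/N_min) inside the tolerance band.
* Split-half convergence uses the Jensen-Shannon divergence (natural
  log, range [0, ln 2]) between half-chain H-bond distance histograms.
* Junction orientation folds theta into [0, 90] deg; "orthogonal" means
  theta < 30 deg (the alignment threshold is a package choice).
* U3 rejects conformations with |p| < 1e-8 A (collinear S/C atoms).
* The GMM retries once with 10x covariance regularization on
  singularity, then fails loudly; silhouette selection requires >= 10
  traces.

## Known limitations

* The sampler's coarse energy has no torsional potentials, no
  electrostatics beyond the applied field, and rigid bond angles; its
  ensembles are structurally, not thermodynamically, faithful.
* Replicate-to-replicate variance of H-bond fractions remains sizable at
  desk-scale run lengths even with tempering; ensemble statistics should
  be aggregated over replicates, as the pipeline does.
* Proline phi clamping biases the boundary of its allowed range rather
  than re-proposing, a deliberate simplification for a generator.
* The trace generator's background and contact slopes are conventions;
  real instrument artifacts (snap-back, drift, multi-molecule events)
  are not modeled.
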