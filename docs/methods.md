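# Methods

This package analyzes the dimerization free-energy landscape of a 35-residue
transmembrane helix (surfactant protein C, SP-C) from biased simulations:
two-dimensional umbrella sampling over a pair of interface dihedrals combined
with well-tempered metadynamics on the monomer separation, reweighted into
one equilibrium ensemble from which potentials of mean force, bound-state
populations, dimer-topology clusters and interface descriptors are computed.
Because no molecular-dynamics engine is part of the package, a synthetic-data
module provides a *planted* free-energy surface with exactly known answers
and a toy bead-helix geometry, so every stage of the analysis can be
validated end to end at desk scale.

## Collective variables and descriptors

The reaction coordinates follow the production setup for the membrane
system:

* **phi1, phi2** — interface dihedrals built from the centers of mass of
  three anchor groups per monomer: upper A = residues 31–33, middle
  B = 17–19, lower C = 8–10.  phi1 = dihedral(A, B, C, C′) and
  phi2 = dihedral(A′, B′, C′, C), primes denoting the partner monomer.
  Because the anchors lie close to the helix axis, each dihedral effectively
  measures which helix face points at the partner — the interface azimuth.
  The fourth point is the partner's lower anchor (the figure-caption
  definition; the ambiguous prose label "D" is read as the same point).
* **d** — distance between whole-monomer centers of mass (association
  coordinate).
* **d_min** — minimum inter-monomer bead distance over the helical segment
  (residues 9–33); `d_min <= 0.60 nm` defines the bound dimer.  The
  selection is exposed as a parameter because the figure text describes an
  any-bead minimum while the analysis text restricts it to the segment; the
  segment is the default.
* **region distances** — minimum bead distances between the N-terminal
  (8–10), middle (17–19) and C-terminal (31–33) regions of the two monomers.
* **crossing angle Psi** — angle between the two helix axes (backbone COM of
  residues 8–11 to that of 30–33), reported unsigned in [0°, 180°]: the
  production analysis reports small positive averages and defines only an
  axis vector, so no handedness convention is attached.
* **contacts** — two residues are in contact when any bead pair is closer
  than 6 Å; per-cluster contact probabilities are weighted means of the
  per-frame boolean maps, symmetrized under the monomer swap.

Angles are radians internally (the umbrella constant is per rad²) and
degrees at I/O boundaries.  Minimum-image corrections apply when a box is
given; the synthetic box is effectively infinite, so images never matter.

## Bias model

Each window `w` restrains (phi1, phi2) harmonically (production: k = 500
kJ mol⁻¹ rad⁻² on a 10° grid, 36 × 36 = 1296 windows) and runs its own
well-tempered metadynamics on d (bias factor γ = 50, hill width σ = 0.05 nm,
initial height h₀ = 0.1 kJ/mol) accumulated on a grid over [0.5, 4.5] nm
with 0.01 nm spacing (401 nodes), plus a half-harmonic wall at 5 nm with
500 kJ mol⁻¹ nm⁻².  Hills centered outside the deposition interval are
skipped; the stored bias never extends outside it.  Hill heights are
evaluated from the grid at the hill center (grid-stored bias semantics).

## Reweighting

The estimator is binless multistate reweighting (the MBAR fixed point) over
the per-window static bias

    B_w(x) = umbrella_w(phi1, phi2) + V_w(d) + wall(d),

where `V_w` is the *final* accumulated metadynamics grid of window `w`
(final-bias approximation).  The self-consistent equations are solved by
damped Newton on the convex multistate objective and certified by direct
iteration to max |Δf_w| < 1e-8 kT.  The reweighting formula is not printed
in the source study (it cites an external description); the binless
multistate estimator with the final-bias approximation is the standard
practice for combining umbrella windows that each carry a converged
well-tempered bias, and with γ = 50 the un-flattened residual F/γ is at the
2% level.  Each window keeps its own hill log and grid ("the distance was
sampled continuously in each window"); pooling hills across windows is the
untested alternative.

Profiles are F(bin) = −kT ln(Σ weights / bin width); the reference zero is
the mean over a dissociated plateau window (default d_min in [2.0, 3.5] nm),
matching a profile whose monomeric plateau sits at zero.  Empty bins are
flagged, never zeroed.  The bound/unbound difference is
ΔF = −kT ln(W_bound/W_unbound) (negative = bound favored).

## Uncertainties

All weighted estimates carry Bayesian block-bootstrap errors: one block per
window, 100 replicates by default, each replicate drawing a flat Dirichlet
weight vector over blocks (scaled so the mean factor is 1), multiplying the
effective window counts and *re-solving the full fixed point* before
re-evaluating the statistic.  Errors therefore propagate through the offset
estimation, not only through final binning.  Two known properties at desk
scale: (i) the error scales with the number of windows (blocks), not with
frames within a window — correlated frames add little information; (ii)
when the bound-state weight is carried by a handful of windows, the
Dirichlet dispersion is large and the reported error is conservative
relative to seed-to-seed scatter.

## Clustering and descriptors

Bound dimers are clustered by average-linkage agglomerative clustering
(criterion configurable; average linkage is the common default for
precomputed distance matrices and is duplication-stable) on the pairwise
monomer-swap-symmetric RMSD: the minimum over the two monomer labelings of
the least-squares-superposed (Kabsch) RMSD of the helical-segment beads.
Superposition removes the rigid in-membrane diffusion that would otherwise
dominate the metric.  The RMSD matrix is unweighted; statistical weights
enter only the per-cluster estimates (free energies, means, contact
probabilities), exactly as in the production analysis.

The pipeline clusters an importance-resampled subsample (systematic
resampling by weight, 400 frames by default) of the bound ensemble rather
than the raw bound pool: at desk scale the raw pool is numerically dominated
by near-zero-weight contact frames from umbrella windows far from any
favorable orientation (any orientation pushed to contact satisfies
d_min <= 0.6 nm), which carry no statistical weight but would swamp an
unweighted partition.  The resampled subsample represents the equilibrium
bound ensemble the clusters are meant to describe.

The cluster count defaults to 3 and the dendrogram merge heights are always
written out so the choice is auditable.  The automatic choice takes the
largest merge-height gap on a log scale (ratio of successive merge heights):
the two V-like topologies are genuinely more similar to each other than
either is to the parallel dimer, so absolute gaps overweight the top split,
while the ratio criterion is invariant to the overall RMSD scale and
corresponds to where one visually cuts a dendrogram.  Both criteria are
available.

Distribution "maxima" are histogram modes at 0.05 nm (distances) and 2°
(angles) bin widths, which reproduces two-decimal modes at comparable
resolution.  Centroids are weighted medoids (ties to the lowest frame
index).  The per-residue contact profile is the probability that a residue
touches *any* partner residue (configurable to the maximum pair
probability); the interface motif renders the contiguous span of
above-threshold residues with residue letters at interface positions and
'x' elsewhere.

## Synthetic data: what is emulated and what is not

The sampler works directly in CV space: an overdamped Langevin
(Euler–Maruyama) walker per window on the planted surface plus the full
bias stack, angles wrapped, hills deposited at the stated stride, fully
reproducible from one seed.  Bead frames are reconstructed afterwards from
the CVs, which keeps the ground truth exact while still exercising every
piece of geometry code.

**Planted surface.**  F(phi1, phi2, d) is a sum of three Gaussian basins
(one per dimer topology, centered at each topology's canonical CVs), a flat
dissociated plateau, and a steric contact wall whose location depends on
orientation: under each basin it sits 0.02 nm below that basin's separation
and is blended between basins with angular Gaussian weights — no
orientation can reach separations where the reconstructed helices would
interpenetrate.  Basin widths are σ_phi = 0.25 rad and σ_d = 0.20 nm; the
width in d and the wall stiffness (800 kJ mol⁻¹ nm⁻²) were chosen so the
stiffest curvature on the surface admits a stable Euler–Maruyama step of
dt = 8e-5 while keeping bound-state thermal fluctuations (±0.04 nm in d,
±4° in the angles) small enough that descriptor modes stay within one
histogram bin of the planted values.

**Depth calibration.**  Basin depths are solved (by bracketing on each
depth, iterated to joint consistency) so the planted per-topology free
energies match the production values −10.4, −5.0, −2.4 kJ/mol up to a
uniform shift chosen so the *total* bound/unbound difference equals
10.14 kJ/mol — the production numbers are mutually inconsistent by
~0.7 kJ/mol, and the uniform shift (+0.66 kJ/mol on each cluster value)
preserves the stability ordering, which is the recovered property.  All
planted observables (ΔF, cluster ΔFs, the d_min PMF) are evaluated by
importance sampling of the planted Boltzmann distribution with an analytic
mixture proposal — a route completely independent of the biased sampler and
of the reweighting estimator being validated.  The ground truth recorded in
a campaign manifest comes from a sample independent of the calibration
sample.

**Toy helices.**  Each monomer is an ideal α-helix of one backbone
(r = 0.23 nm) and one side bead (r = 0.41 nm) per residue, 100°/residue
twist and 0.15 nm/residue axial rise (the α-helical rise; with a longer
rise the production descriptor targets are geometrically unreachable), with
a gentle quadratic axis bend that co-rotates with the helix spin (a rigid
bent rod).  Each topology template's placement (tilts, bends, vertical
offset, separation, spins) is solved once by least squares against its
descriptor targets — the region-distance modes, mean crossing angle and
typical contact distance of the three production topologies — under two
steric constraints (no pair undercuts the segment contact distance; the
flexible terminal tails, residues 1–7/34–35, stay out of the interface) and
a mutual-separation constraint on the canonical CVs of different templates
(≥ ~69° apart, so planted basins never overlap).  The solved placements are
frozen as package constants and re-validated by the test suite.  Per frame,
`pose_from_cvs` adjusts only the two spins and the separation: each
dihedral is a winding-1 circle map of its own monomer's spin, solved by
bracketed bisection plus Newton polish to < 1e-9, so reconstructed frames
match their CVs to machine precision.

**What the toy does not emulate.**  No lipids, no force field, no kinetics,
no internal helix flexibility beyond the fixed bend, no palmitoylation.
Contacts within a cluster are nearly deterministic (rigid poses with small
thermal jitter), so contact probabilities are more binary than in real
ensembles; passing tests demonstrate that the *analysis* recovers planted
truth, not that the toy reproduces membrane physics.

## Scaled campaign

The default campaign is scaled for a single CPU: 30° window spacing (144
windows) with the umbrella constant scaled to k = 55 kJ mol⁻¹ rad⁻² so the
spacing-to-width ratio of the production layout (10°, k = 500) is
preserved; 6e5 Langevin steps per window (dt = 8e-5, friction 1); hills
every 150 steps with deposition *frozen after 35% of the run*, and the
deposition grid extended to [0.5, 5.3] nm, past the wall.

The freeze and the extended grid are the two adaptations that make the
final-bias approximation exact rather than approximate at this scale.
Without the freeze, the bias keeps evolving through the retained frames
(the well-tempered tempering scale k_B(γ−1)T = 126 kJ/mol barely decays
hills over 30–40 kJ/mol basins), which systematically over-weights whatever
region was filled last; frames recorded during deposition are discarded
(default equilibration fraction 0.4 in the pipeline; the library default
for user campaigns remains 0.1).  Without the grid extension, the unbiased
pocket between the production deposition edge (4.5 nm) and the wall (5 nm)
becomes an absorbing trap once the grid region fills.  The hill stride
keeps per-dwell deposition near kT so the basin/plateau balance at freeze
is within a couple of kT, leaving both states exchange-accessible.  With
these settings one seeded campaign recovers the planted bound/unbound
difference to a few tenths of kJ/mol (seed-to-seed spread ~0.6 kJ/mol) and
the planted d_min profile within 0.5 kT over the sampled range.

Frames for analysis are strided (subsample 10 after the equilibration
discard, ~360 frames per window); the reweighting matrix then holds ~52k
frames × 144 windows.

## Degenerate inputs and numerical choices

k_B = 0.0083144621 kJ mol⁻¹ K⁻¹ (reproduces the printed 2.58 kJ/mol at
310 K).  Dihedrals with collinear triples raise; empty selections raise;
negative d_min raises; windows with zero frames after the discard raise;
non-finite forces abort the sampler with a diagnostic.  A reflective floor
at d = 0.05 nm protects the integrator and is never reached in practice.
Ties in the medoid search and in histogram modes resolve to the lowest
index/bin.  The Kabsch RMSD uses the singular-value form for the O(n²)
matrix and the explicit-rotation form (no cancellation) for single pairs,
cross-checked against an independent superposition routine in the tests.

## Known limitations

* The final-bias approximation is exact here only because deposition is
  frozen; analyzing a user campaign whose bias evolved through the retained
  frames reintroduces the approximation error.
* Bound-state information concentrates in the few windows nearest each
  basin, so block-bootstrap errors on bound-state quantities are
  conservative at desk scale (they shrink with window count, per the
  production layout's 1296+ windows).
* The cluster-count gap criterion is reliable when clusters are tight and
  separated; for diffuse ensembles the dendrogram should be inspected, and
  the merge heights are always written out for that purpose.
* Time-dependent metadynamics reweighting (c(t) variants) and kinetics are
  out of scope by design.
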