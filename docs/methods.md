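# Methods

Model, conventions and parameter defaults for every analysis in the
package. All coordinates are handled internally in nanometres; PDB
files are converted at the I/O boundary (1 nm = 10 Å). All energies are
in kcal/mol with R = 1.987 × 10⁻³ kcal/(mol K).

## System model

A system is declared explicitly as a `Topology`: chains → residues →
atoms, where every atom carries an element, an *atom class*
(`main_chain`, `side_chain`, `ligand`, `hydrogen`) and optionally a
named aromatic *ring group* or cationic *charged group*. The
declaration deliberately carries more chemistry than a PDB file,
because the analyses (main-chain clustering, side-chain contacts,
stacking, cation–π) need these partitions to be unambiguous. The first
two chains may be declared a homodimer, which requires identical
residue/atom naming and enables chain-label-independent RMSD.

An `Ensemble` is an ordered list of frames over one topology with
per-frame weights (normalised to sum to 1; uniform by default) and a
temperature tag used by free-energy surfaces (default 310 K).

## Secondary structure (Kabsch–Sander)

Backbone hydrogen bonds are scored with the Kabsch–Sander
electrostatic model,

E = 27.888 · (1/r(N,O) + 1/r(H,C) − 1/r(H,O) − 1/r(N,C)) kcal/mol

(distances in Å, clamped below at 0.5 Å), with a bond assigned when
E < −0.5 kcal/mol. Amide hydrogens are taken from the topology when
declared and otherwise reconstructed as H = N + 1 Å · unit(C_prev −
O_prev); prolines and chain-start residues without a declared H never
donate. Self-pairs and same-chain neighbours (|i−j| < 2) are excluded;
inter-chain bonds are allowed, so β-bridges across the dimer interface
are detected.

From the bond matrix the standard patterns are assigned: n-turns
(n = 3, 4, 5), minimal helices (G/H/I from two consecutive turns),
parallel and antiparallel bridges (B), ladders extended residue by
residue and merged across β-bulges (gap ≤ 1 on one strand and ≤ 4 on
the other, same chain) into sheets (E), hydrogen-bonded turns (T) and
bends (S, Cα virtual angle κ > 70°). The 8 classes are collapsed for
reporting: helix = {H,G,I}, sheet = {E}, bridge = {B}, turn = {T},
bend = {S}, coil = {C}.

Strand-length distributions count maximal runs of E per chain per
frame; the default normalisation is the expected number of strands of
each length per chain per frame.

## Clustering

Pairwise distance is the main-chain (N, CA, C, O) RMSD after optimal
superposition (Kabsch SVD with a determinant guard so reflections are
never returned). For homodimers the RMSD is the minimum over the two
chain-label assignments, making the metric invariant to an arbitrary
A/B swap. Clustering follows the greedy neighbour-count rule: the
frame with the most neighbours within the cutoff (default 0.35 nm)
seeds a cluster, seed and neighbours are removed, and the rule repeats;
ties resolve to the lowest frame index and final clusters are ordered
by decreasing size.

## Contacts, hydrogen bonds, stacking

* **Contacts.** Two residues are in contact when the minimum distance
  between their selected heavy atoms (main-chain–main-chain or
  side-chain–side-chain) is ≤ 0.50 nm (default; a two-tier preset
  0.54/0.46 nm is provided). Inter-chain maps are symmetrised for
  homodimers; intra-chain maps are averaged over the two chains.
* **Hydrogen bonds (geometric).** Donor–acceptor N(H)···O pairs with
  d(N,O) ≤ 0.35 nm and ∠(H–N···O) ≤ 30°. Ligand oxygens can be included
  as acceptors. Note this geometric criterion is stricter than the
  Kabsch–Sander energy criterion: idealised rigid templates (e.g. the
  built hairpin) can satisfy E < −0.5 while failing the angular test,
  so geometric counts are conservative on synthetic structures.
* **Stacking.** Ring planes are least-squares fits (SVD); the plane
  angle is folded to [0°, 90°]. A residue-ring/ligand-ring pair is
  *parallel* when centroid distance ≤ 0.55 nm and angle ≤ 30°,
  *perpendicular* (T-shaped) when distance ≤ 0.75 nm and angle ≥ 60°.
  These thresholds bracket the canonical π-stacking geometries
  (~0.4 nm/small angle and ~0.6 nm/near-90°) and are configurable.
* **Cation–π.** Distance from the mean position of a declared charged
  group (e.g. the three guanidinium nitrogens) to ligand ring
  centroids, histogrammed to a unit-area PDF over 0.2–2.0 nm.
* **Ligand inter-ring torsions.** The angle between the oriented
  normals of two rings of the same molecule, unfolded over [0°, 180°]
  (orientation fixed by the declared atom ordering).

## Free-energy surfaces and diagnostics

G(x,y) = −RT ln P(x,y) on a weighted 2-D histogram, shifted so the
lowest occupied bin is 0; empty bins are masked. Basins are persistent
local minima found by watershed flooding in order of increasing G: a
minimum is kept when the lowest saddle connecting it to a deeper basin
lies at least `depth_threshold` above it. Empty bins are treated as
passable barriers at the height of the worst sampled bin, so sampling
islands separated only by empty bins are not spurious basins. The
default pipeline surface uses radius of gyration (0.02 nm bins) against
the geometric hydrogen-bond count (unit bins).

Split-half convergence compares first- and second-half histograms of
any scalar metric with the base-2 Jensen–Shannon distance (0 identical,
1 disjoint). Replica-ladder utilities provide the geometric ladder
T_i = T_min (T_max/T_min)^{i/(n−1)} (constant neighbour ratio, exact
endpoints) and a state-machine count of completed bottom→top→bottom
round trips.

## Collision cross section

Projection approximation: the CCS is the average over uniformly random
orientations (quaternion-sampled, seeded) of the area of the union of
the atoms' projected hard disks (radii: H 2.2, C/N/O 2.7, S 3.1 Å).
The union area uses an importance-sampled Monte Carlo estimator —
sample a disk with probability ∝ its area, sample a point in it, and
weight by 1/multiplicity — which is exact for non-overlapping disks and
can never exceed Σπr², so the union bound holds deterministically, not
just in expectation. Defaults: 300 orientations × 5000 points
(pipeline: 100 × 2000). The projection approximation systematically
underestimates trajectory-method CCS values for proteins; a linear
calibration factor is exposed (default 1).

## Synthetic generators

Backbones are built from per-residue (φ, ψ, ω) internal coordinates by
natural-extension-of-reference-frame placement with ideal geometry
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles 111.2°/116.2°/121.7°;
ω = 180°). Side chains are minimal: CB for all non-glycine residues,
ideal hexagonal rings for PHE/TYR (+OH), guanidinium (ARG) and ammonium
(LYS) charged groups — enough to exercise every analysis without
claiming rotamer realism.

Presets: ideal helix (−57°, −47°), extended strand (−139°, 135°),
random coil (seeded draws from broad Ramachandran boxes: β/PPII 45%,
α 35%, left-handed α 20%). The β-hairpin uses strand/flank dihedrals
(−130°, 128°) and a type-II′-like two-residue turn centre
((60°, −120°), (−80°, 0°)); these values were selected so that the
rigid template actually closes into a hydrogen-bonded antiparallel
ladder under the Kabsch–Sander criteria, which the textbook ideal
strand values alone do not achieve. Hairpin frames are jittered by a
rigid-body wobble rather than dihedral noise, since dihedral jitter
unzips the hydrogen-bond register.

Dimers place a second, independently generated chain by a rigid
transform with a clash check (minimum heavy-atom distance 0.15 nm,
retried with growing separation). Mixtures draw each frame from named
component generators by seeded categorical sampling and return the true
labels. The three-ring ligand is a rigid simplified polyphenol (two
benzene rings and a gallate-like third ring on one-carbon linkers) with
the two inter-ring torsions as its only degrees of freedom;
`place_ligand_ring` plants a chosen ligand ring at an exact centroid
distance and plane angle relative to a target residue ring, with seeded
azimuth and spin.

What the generators do *not* emulate: solvent, realistic side-chain
packing, ligand chemistry (hydroxyls, esters), thermal backbone
fluctuations within a basin, or any force field. They provide exact,
seeded ground truth for recovery tests, not physical realism.

## Pipeline

`run_full_analysis` executes every stage on one ensemble and writes TSV
tables plus cluster centres as a multi-model PDB; ligand-dependent
tables are skipped (with a log entry) when the topology declares no
ligand. A `manifest.json` records the configuration and SHA-256
checksums of every output; all stochastic stages are seeded from the
config, so reruns are byte-identical. `compare_conditions` emits
difference tables between two completed runs and refuses mismatched
binnings or shapes.

## Limitations

* The DSSP implementation targets residue-level agreement ≥ 95% with
  reference implementations; known divergence is confined to π-helix
  boundary conventions and isolated bridge/edge cases.
* CCS values are projection-approximation numbers; compare to
  trajectory-method data only after calibration.
* The geometric H-bond count and the Kabsch–Sander energy criterion
  intentionally differ (see above); choose the one appropriate to the
  question.
* Synthetic ensembles are caricatures with exact ground truth, not
  samples from a physical Boltzmann distribution.
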