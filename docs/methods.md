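# Methods

This note records the models, conventions and numerical choices behind
`doubletlattice`, and what the synthetic tests do and do not establish about
real data.

## Coordinate and map conventions

All coordinates are Å. Maps are MRC2014 mode 2, normalised on read to
`(z, y, x)` value order regardless of the file's axis permutation; the world
position of voxel `(i, j, k)` is `origin + voxel_size · (k, j, i)`. The
origin comes from the MRC ORIGIN words with fallback to `nstart · voxel`.
Anisotropic voxels are rejected — every map this package targets is
isotropic. Residue numbering is preserved verbatim from the source file
(interface residues are cited by deposited numbering, e.g. R308, E414).
Hydrogens are excluded from SASA/clash work by default because deposited
lattice models are heavy-atom. vdW radii: C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20, P 1.80 Å; unknown elements default to 1.70 Å with a warning.

## Lattice geometry

**Superposition** is Kabsch/SVD with a reflection guard; pairing is by atom
order or by `(chain, residue, atom name)` key. Collinear pairings are
rejected (rank check on the centred cloud).

**Axis estimation.** The longitudinal axis is taken from the orientation
tensor of nearest-neighbour difference vectors between monomer centroids:
within a PF the nearest neighbour of a monomer is its axial neighbour
(40 Å monomer rise versus ≳48 Å lateral spacing), so the dominant
eigenvector of those directions is the tube axis. A plain principal-
component axis is *not* used: for a short, wide ring (two 8-nm repeats,
~200 Å diameter) the axial and lateral variances nearly coincide and the
principal axis is undefined in practice. The estimator requires a clear
dominant direction (eigenvalue ratio ≥ 2) and at least 4 chains. The sign
is fixed so β→α within a dimer points along the axis (plus end up) when
subunit labels are available, otherwise deterministically by the largest
component.

**Twist–swing decomposition.** The quaternion of the rotation is projected
onto the axis (swing–twist split); twist is reported in (−180°, 180°], the
screw translation along the axis is referred to the axis point, and the
deviation is the acute angle between the transform's own rotation axis and
the lattice axis. Rotations below 1e-6° report twist 0 with deviation 0.
Rows with deviation > 20° are flagged unreliable rather than re-fitted
under an axis constraint: the unconstrained number plus a diagnostic is
reproducible and debuggable. Positive twist is counterclockwise viewed from
the plus end; the convention is ours (published tables use magnitudes).

**PF assignment.** Chain centroids are projected into the plane normal to
the axis and clustered by single linkage (15 Å cutoff; a silhouette below
0.6 is an error rather than a guess). The closed A-ring is separated from
the open B-arc by a deterministic consensus circle: all centroid triples
are scanned, each circumcircle scored by inliers within an absolute 8 Å
radial tolerance, and the best refined by least squares. The absolute
tolerance matters — a proportional one lets oversized circles graze many
points. A radial k-means split was considered and rejected: with the global
axis through the combined centroid, A- and B-PF radii overlap heavily and
k-means cannot separate the tubules. PF labels are anchored at the outer
junction (arc PF nearest the A-ring surface = B1; its two A partners are
A10/A11, with A11 the one nearer B2, i.e. on the side the arc extends
over); a singlet gets A1..An from a deterministic arbitrary anchor. PF
identity is always derived geometrically, never from chain ids.

**Seam classification.** For each adjacent pair, the α→α axial offset is
folded into [−rise/2, rise/2) (rise estimated from within-PF α spacing,
fallback 80 Å) and each subunit votes `seam` when its folded offset exceeds
rise/4 — i.e. α sits nearer the neighbour's β than its α. The fold makes
the call independent of axial truncation of the wall (a plain
nearest-neighbour test fails at the wrap-around pair of a 2-repeat model);
the per-subunit vote avoids sign cancellation exactly at the ±rise/2
boundary. `pf_class` rounds half away from zero.

## Synthetic lattices

The generator is the package's study condition, not a tuning knob: monomer
rise 40 Å, dimer rise 80 Å (the 8-nm repeat; real tubulin's ~81.6 Å is
configurable), default stagger 3·40/n_pf (3-start monomer helix, giving the
canonical single seam in a closed ring), ring radius 100 Å, two axial
repeats. The bundled pseudo-monomer is a fixed 50-atom asymmetric blob
(constant internal seed) spanning ±15 Å laterally and ±17 Å axially; the β
variant displaces a quarter of the atoms and changes some elements so α and
β render distinguishably. The doublet grafts a 10-of-15-PF arc outside the
ring between two designated A-PFs at a 48 Å radial clearance, with overlap
detection at the graft. Ground truth (tubule/PF/repeat/subunit per chain,
twists, stagger, junction pair, planted-MIP masks) is recorded in model
metadata and scores every downstream stage.

What the generator does *not* emulate: tubulin's real shape and chemistry
(no charged residues — synthetic junction grafts can never form salt
bridges), lattice defects, supertwist, GTP/GDP states, inner-junction
closure of the arc onto the ring. Passing tests therefore demonstrate the
correctness of the measurements and their conventions, not biological
realism of the inputs.

## Interface analysis

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å). Exact duplicate atoms are counted once
(the shared surface belongs to the first), so two coincident spheres bury
each other into exactly one sphere's area. BSA is reported in both
conventions; the full sum `SASA_A + SASA_B − SASA_AB` is the headline, and
the union model is built in source atom order so BSA(A,B) = BSA(B,A)
bitwise. Salt bridges use a 4.0 Å charged-group heavy-atom cutoff with His
assumed protonated (required for His–Asp bridges), deduplicated to one
record per residue pair at minimum distance. Clashes are cross-partition
vdW overlaps > 0.4 Å, a common severe-clash criterion. The nonbonded score
places formal charges on side-chain group centroids
(Coulomb constant 332.06, shift function `(1 − (r/r_c)²)²` vanishing
exactly at 8.5 Å) and element-level Lennard-Jones parameters under a
CHARMM-style cubic switching function between 6.5 and 8.5 Å. The score is a
comparator between interfaces; its unit is arbitrary and no desolvation,
minimisation or pKa handling is attempted.

## Junction modelling

The outer-junction test divides the junction into the A10 dimer and the
rigid A11/B1 complex (their relative position is assumed fixed, as if
bridged by MIP7). For each adjacent A-pair, A10 is superposed onto the
first host PF and the complex onto the second using only its A11-region
atoms (Cα-level dimers); B1 rides along rigidly, preserving internal
distances to 1e-9 Å. Scoring uses the shared bridge/clash thresholds, and
the verdict rule is: any clash → `clash`; clash-free but bridge-free →
`no-bridge-gap`; otherwise `compatible`. Grafts are scored rigid — no
relaxation before evaluation.

## Density tools

Atoms render as isotropic Gaussians with σ = resolution/(π√2), truncated at
5σ, integral (voxel sum) equal to the atomic number; an independent
Fourier-space renderer in the tests guards the convention (real-space
correlation ≥ 0.99). Rendering requires resolution ≥ 2·voxel. Difference
maps subtract `gain·sim + offset` with the affine fit restricted to the
model footprint (sim > 2% of max) so MIP densities cannot bias the
scaling; subtracting a map from itself is bitwise zero. Voxel-size
calibration scans ±3% in 0.1% steps, re-rendering the model in each
reinterpreted frame (the origin scales with the voxel relabel) and refining
the correlation maximum parabolically; a maximum at the scan edge warns.
Register assignment renders each PF's first fitted dimer at its modelled
position and 40 Å (4 nm) up-axis, and compares masked correlations over the
union footprint; the confidence is |cc₀ − cc₄| and near-ties are flagged
ambiguous. Subvolumes are boxed out around dimer centres and resampled
into a common frame by trilinear interpolation; averaging is a plain
voxel-wise mean, optionally preceded by a local rigid re-alignment of each
subvolume to the running average (±5° about each axis in 2.5° steps,
integer shifts to ±3 voxels with parabolic sub-voxel refinement). No
missing-wedge weighting is applied, and no resolution estimation is
performed anywhere — resolution figures are accepted as map metadata.

## Conservation

The conservation score is the normalised Shannon-entropy complement
1 − H/log 20 per column and group, gaps excluded from the counts (a
fraction-identity-to-reference metric is available behind a flag for
sensitivity checks). Columns with > 50% gaps in a group are flagged;
all-gap columns are undefined, not zero. Region reports average scores over
reference-numbered residue windows; each bundled region carries its
expected reference subsequence and any mismatch is a hard error, because
silent numbering drift is the dominant failure mode of residue-window
analyses. One bundled region's published range label disagrees with its
printed motif by one residue; the motif (10 residues, 362–371) is taken as
authoritative since the subsequence check anchors on it. The
ciliated/non-ciliated partition is user input — no taxon database ships
with the package. Scores map onto structures through the B-factor column,
scaled to [0, 100].

## Problem sizes and determinism

Synthetic analyses run at desk scale: 13+10 PF doublets with two 8-nm
repeats (~4,600 pseudo-atoms), maps at 3 Å voxels (~2.7M voxels), 20-seed
noise ensembles for register accuracy, 16 subvolumes for averaging, and
80k-sample Monte-Carlo SASA oracles. Every stochastic step takes an
explicit seed; identical inputs give bitwise-identical reports, and the CLI
echoes its parameters as YAML beside each output.

## Known limitations

Deposited-model workflows (`reproduce-5ubq`) require a user-supplied local
coordinate file. The seam test assumes at least one α subunit per PF with a
lateral α counterpart. The junction scan on pseudo-tubulin cannot produce
salt bridges (no charged residues), so synthetic verdicts exercise the
clash/gap logic only. Subvolume refinement searches small rotations
sequentially per axis and will not recover large misorientations.
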