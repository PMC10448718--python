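# Methods

## Scope and model

`chpi` implements an empirical model of CH–π interactions for protein–ligand
scoring.  The chain is: geometric detection of contacts in 3-D structures →
a pairwise CH–π energy term layered on a re-implemented empirical docking
base score → grid-search fitting of the term's three constants against
dimer energy curves → torsion grid-search pose validation.  Quantum-chemical
reference calculations themselves, PDB-wide data mining, and the stochastic
docking search engine are out of scope; the package builds idealized
methane–benzene dimers and synthetic binding sites internally so every
result here is reproducible from nothing but the code.

## Contact detection

A CH–π contact exists when an aliphatic hydrogen lies ≤ 3.5 Å from an
aromatic ring centroid.  Filters mirror crystallographic practice: residues
with any partial-occupancy atom or an average B-factor above 40 Å² are
excluded (the ligand counts as a single residue), and methyl hydrogens are
excluded from *detection* because their torsional positions are not
experimentally determined (they still contribute to *energies*, where the
model, not the crystal, places them).  Rings come from residue templates for
PHE/TYR/HIS/TRP — the tryptophan indole is treated as two independent rings,
5- and 6-membered, each with its own centroid, since fused-ring centroids
are otherwise ill-defined — and from cycle perception plus a planarity test
(max out-of-plane deviation 0.2 Å) for ligands.  rdkit-style aromaticity
perception was deliberately not used: docking inputs lack the bond orders
and protonation a sanitizer needs, whereas planarity of a 5/6-cycle is
directly observable.

Descriptors: R, θ, ω, θ₁, θ₂, horizontal/vertical offsets of both the
carbon and the hydrogen, and the carbon–centroid distance.  θ₁ and θ₂ are
reported folded into [0°, 90°] (the sign of a ring normal is not
observable), and ω is the folded angle between the ring plane and the plane
of the H with its nearest *adjacent* ring-atom pair — restricting to ring
edges keeps the choice stable when an on-axis hydrogen is equidistant from
all ring atoms.  "Strong" contacts satisfy θ₁ < 35° and θ₂ < 35°.

## Base score

The base term re-implements the published empirical pairwise docking score:
steric attraction as two Gaussians in the surface distance
d = r − R_i − R_j (widths 0.5 and 2 Å, the second offset by 3 Å), quadratic
soft repulsion for d < 0, a piecewise-linear hydrophobic term between
carbon-only atoms, and a non-directional donor–acceptor hydrogen-bond term,
with the published weights and van der Waals radii stored in
`data/base_score.json`.  The 8 Å cutoff applies to the interatomic distance.
Conformation-independent constants and the rotatable-bond affinity rescaling
are omitted because only pose-dependent energies matter here.  Hydrogens are
never scored by the base term.

## The CH–π term

Each aliphatic proton interacts with each aromatic ring **carbon** (ring
nitrogens contribute zero, which is what makes imidazole stacking weak in
this model; hooks exist for assigning other ring-atom types):

    E_pair = −E · ½ · exp(−(R − R0)² / c) · f(θ₂),   f(θ₂) = max(cos θ₂, 0)

* θ₂ is measured against the ring normal oriented *through* the ring away
  from the aliphatic carbon, so a C–H pointing at the ring face has θ₂ = 0
  and hydrogens pointing away are clamped to zero — the pairwise sum then
  needs no explicit nearest-hydrogen selection.
* The ½ is a π-lobe occupancy factor: each ring carbon's π density has two
  lobes and only the one facing the proton is engaged.
* The published constants are E_HC = 0.29 kcal/mol, R⁰_HC = 3.58 Å,
  C_HC = 0.85 (hydrogen-dependent) and E_CC = 0.26, R⁰_CC = 4.49 Å,
  c_CC = 0.75 (hydrogen-independent, no angular factor, aliphatic-carbon to
  ring-carbon distances).
* The exact exponent arrangement and the ½ factor are implementation
  constants fixed by calibration: with the published parameter values they
  reproduce the four desk-scale dimer anchors (base-only trace ≈ −0.4
  kcal/mol, combined trace ≈ −1.0 kcal/mol and flat across the ring face at
  3.8 Å, averaged vertical optimum 3.7 ± 0.2 Å at −1.2 ± 0.2 kcal/mol).
  Without the ½, no single-well radial arrangement meets those anchors: the
  six-pair sum at E_HC = 0.29 roughly doubles the combined well depth and
  pushes the optimum out to ≈ 4.4 Å.  This calibration was done once, over
  an enumerated design space of exponent arrangements, hydrogen conventions
  and orientation conventions, before the anchors were frozen into tests.
* The term shares the base score's 8 Å neighbor cutoff (the Gaussian is
  ≈ e⁻²³ there, so no discontinuity of practical size).

The combined score is E_base + w·E_CHπ with w ∈ [0, 1]; w = 1 during
fitting, and w = 0.3 as the recommended general-purpose weighting (pose
prediction improves steeply up to ≈ 0.3 and only marginally beyond).
At w = 0 the combined score equals the base score bit-for-bit.

## Dimer laboratory

Monomers are idealized rather than quantum-optimized: benzene as a planar
D6h hexagon (C–C 1.391 Å, C–H 1.087 Å) and methane as a Td tetrahedron
(C–H 1.091 Å); the ≤ 0.01 Å differences from optimized geometries are far
inside the ± 0.2 tolerances of the anchor quantities.  Six dimer
orientations are defined (implementation constants, since tetrahedral
symmetry leaves three distinct axis-aligned orientations plus azimuth):
A/D/E place one C–H on the ring axis pointing at the centroid (azimuths
0°/20°/40°) — the family whose ring-facing C–H has f(θ₂) = 1, used for
fitting the hydrogen-independent form — and B/C/F present the face (tripod),
edge, and rotated-face orientations.  Scans follow the stated grids:
vertical 3.0–4.2 Å in 0.1 Å steps then 4.4–6.0 Å in 0.2 Å steps (22
points); horizontal 0.1 Å steps to 1.4 Å toward a ring carbon or 1.2 Å
toward a bond midpoint, extendable to 6.0 Å.  Curve minima are refined by a
parabola through the three bracketing points; monotone or flat curves
return a no-minimum flag; ties break to the smallest abscissa.

## Parameter fitting

Two-stage exhaustive grid search, as in the original derivation: stage 1
scans E 0.10–0.50, R0 1.50–4.55, c 0.05–2.00 at 0.05 intervals (22,320
combinations for the hydrogen-dependent form); stage 2 refines each
parameter ± 0.05 at 0.01 intervals around the stage-1 winner, run once
(iterating the refinement is available to the caller and can only improve
the objective).  The objective is the mean over curves of the rmsd between
the *combined* model (w = 1) and the reference within each curve's fit
range, which starts at the first grid point where the reference energy is
negative — the soft quadratic repulsion cannot reproduce steep
quantum-mechanical walls, so the repulsive branch is excluded — and ends at
6.0 Å, bounds inclusive, no interpolation.  Ties break to the
lexicographically smallest (E, R0, c).  No quantum-chemical tables are
shipped (none are printed in machine-readable form anywhere to take them
from); reference curves are user-supplied or generated from known
parameters, which turns the default path into a parameter-recovery check:
noiseless curves are recovered exactly, and with 0.05 kcal/mol Gaussian
noise R0 is recovered to ≈ 0.1 Å.

## Rotamer grid search

Up to two rotatable bonds are scanned 0–360° in 3° increments (120ⁿ
conformations, streamed lazily).  Because the base score has no
intramolecular term, rotamers with severe internal clashes are discarded
first, using inclusive thresholds: ≤ 2.0 Å heavy–heavy, ≤ 1.75 Å heavy–H,
≤ 1.40 Å H–H, with 1-2 and 1-3 pairs exempt (1-4 pairs are checked).
Surviving rotamers are scored with the combined energy; "highest predicted
affinity" means the most negative total, ties break to the first (smallest)
angle tuple.  Accuracy versus a reference pose is the heavy-atom rmsd of
the moving set with no re-superposition (the receptor frame is fixed) plus
per-bond angle deviations wrapped to (−180°, 180°].  Receptor-internal
interactions are not rescored — a deliberate mirror of the scoring model's
limitation, which is also its known failure mode (an aromatic side chain
can flip into the ligand's CH–π embrace at the cost of an unmodeled
side-chain/side-chain contact).

## Synthetic binding sites

`make_synthetic_site` emulates the curated crystallographic contact sets at
fixture scale: phenylalanine-like fragments (template-named benzene side
chains on a protonated Cβ stub) spaced 25 Å apart, each with a methane
posed so the ring-facing hydrogen realizes an exactly sampled H–centroid
distance (default N(3.0, 0.2) Å, clipped to ≤ 3.4) and tilt (default
N(20°, 10°), clipped to [0°, 30°] so sibling hydrogens stay outside the
detection cutoff and the returned ground truth is exhaustive).  What it
does *not* emulate: real B-factor/occupancy noise, ring chemical diversity
(TRP/TYR/HIS environments), crowded pockets where contacts overlap, or
lattice artifacts — so passing tests demonstrate correctness of the
detector and scorer on well-posed geometry, not robustness to
crystallographic pathology.

## Numerical choices and limitations

* Hydrogens are built at 1.09 Å with ideal tetrahedral geometry; methyl
  rotors are staggered against the heaviest vicinal substituent.  Carbons
  with a < 1.30 Å bond to N/O are treated as sp2 and left unprotonated.
* Bonds are inferred by distance (1.9 Å cutoff, 2.2 Å with sulfur, 1.25 Å
  for hydrogens, nearest-partner only) unless given; aromatic rings of
  standard residues are located by name template, in ring-path order.
* ω is reported folded to [0°, 90°]; surveys that distinguish inside/outside
  edge displacement report values up to ~180°, which this convention maps
  onto its mirror image.
* The B-factor filter averages over all atoms of a residue; the ligand is
  one residue.
* Degenerate inputs: empty contact lists summarize to an explicit empty
  flag; flat/monotone scan curves return a no-minimum flag; an all-positive
  reference curve has no fit range and raises; a fully clashing rotamer
  stream raises rather than returning a winner.
* Energies are reported in kcal/mol and distances in Å, 4 decimals in all
  file output.
* Problem sizes used throughout the tests and the acceptance script —
  single dimers, ≤ 50-contact synthetic sites, 6 × 22-point scans, one
  22,320-point stage-1 grid, 120-rotamer searches — were chosen so the whole
  suite is a desk-scale computation; the statistical claims of large-scale
  structure mining (contact tallies, rmsd-vs-w curves over hundreds of
  complexes, docking benchmark percentages) require external structure sets
  and a docking engine, and are explicitly not reproduced.
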