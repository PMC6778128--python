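# Methods

This note records the models, numerical choices and limitations behind
`coronastat`, in the spirit of the methods documentation of analysis
packages like mdtraj or statsmodels.

## Data model and units

All quantities are GROMACS-like: nm, kJ/mol, ps, elementary charges.
PDB input (Å) is converted on read. Atom indexing is 0-based
internally, but each atom keeps its source `res_seq`, so residue
ranges quoted against the deposited numbering (an active site
"136–150") address the right residues regardless of gaps. Waters and
monatomic ions are dropped on PDB read; missing residues are *not*
rebuilt — the structure is analysed as deposited. Hydrogens are kept
when present but never required: every distance-based metric (contact
census, assembly gap) uses heavy atoms only, so results do not depend
on whether a model was protonated.

## SASA and contact surface area

SASA uses the Shrake–Rupley construction: each atom's sphere is
inflated by the probe radius (default 0.14 nm, water) and sampled
with a deterministic golden-spiral point set (default 960 points), a
point being accessible when it lies outside every neighbour's inflated
sphere. The spiral is quasi-uniform and involves no RNG, so SASA and
CSA are bit-reproducible at fixed parameters. Neighbour lookup uses a
k-d tree; the result is identical to the all-pairs scan (asserted in
tests). Radii: Bondi values when hydrogens are present, a united-atom
set (C 0.187, N 0.165, O 0.150, S 0.185 nm) when they are not.

CSA = (SASA_pro + SASA_sur − SASA_complex)/2 with all three
evaluations at identical probe and point count. Quadrature noise can
produce slightly negative CSA for disjoint bodies; values in
(−0.01, 0) nm² are clamped to zero. Time-series aggregation defaults
to the final 25 % of frames (`window="last:0.25"`), mean ± s.e.m.
over frames, and over replicas when several trajectories are given
(replica counts are explicit, never assumed).

Accuracy anchors: a single sphere reproduces 4π(r+probe)² to ~1e-13
relative at 960 points; a two-sphere overlap matches the closed-form
spherical-cap area within 2 %; an independent Shrake–Rupley
implementation (mdtraj) agrees within a few percent on peptides.

## Contact census

A residue is adsorbed when the minimum heavy-atom distance to any
surface atom is ≤ 0.5 nm. Classes: hydrophobic {ALA VAL LEU ILE PRO
PHE MET TRP}, charged {ASP GLU LYS ARG}, everything else non-charged
hydrophilic — HIS is treated as neutral at pH 7, giving three disjoint
classes aligned with the sign structure of the Eisenberg scale.
Censuses are computed per frame and averaged arithmetically over the
window; no contact-persistence threshold is applied. Both the
final-frame census and the window average are reported, since printed
adsorption counts in the literature are usually final-snapshot values.

## Energy decomposition

Direct intermolecular sum over (protein atom, surface atom) pairs
within 1.2 nm: 4ε[(σ/r)¹² − (σ/r)⁶] plus f·qᵢqⱼ/(ε_r·r) with
f = 138.935 kJ·mol⁻¹·nm·e⁻², geometric combination for both σ and ε,
ε_r = 1, no 1-4 exclusions (all pairs are intermolecular), and the
minimum-image convention when a box is present. This is deliberately
*not* PME: the module quantifies the direct protein–surface term only,
with no reciprocal-space or solvent screening contribution, so its
magnitudes are not comparable to ensemble-averaged interaction
energies from explicit-solvent MD — only orderings and structural
trends are.

The shipped force-field table (`data/forcefield.tsv`) is a minimal
OPLS-like set: protein heavy atoms typed by element, with coarse
formal charges on charged side-chain terminal atoms (±0.5 e per
carboxylate oxygen and arginine NH, +1 e on lysine NZ); graphene
carbons neutral; hydroxyl O/H/ipso-C at phenol-like partial charges
(−0.585/+0.400/+0.185 e); gold and thiol atoms neutral. It is an
editable plain-text file, not a topology generator — analyses needing
full per-atom OPLS-AA charges should supply their own table.

## Secondary structure

A simplified Kabsch–Sander assignment: backbone H-bond energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (distances
in Å), bond iff E < −0.5; two consecutive n→n+4 bonds mark a helix,
bridge patterns mark strand, lone n→n+3/4/5 turns mark T, priority
H > E > T > C. 3₁₀ and π helices fold into H and there is no bend
category, giving the four classes that adsorption studies report.
Amide hydrogens are reconstructed at 0.10 nm from N along the
anti-bisector of C(prev)–N and CA–N when absent. Chains shorter than
three residues, and residues missing backbone atoms, are coil (the
latter flagged). The assignment is a pure function of interatomic
distances, hence rigid-motion (and mirror) invariant. Agreement with
mdtraj's DSSP on the ideal-geometry fixtures is exact; ≥90 % is the
tested bound.

Free-vs-adsorbed content changes are reported as free − adsorbed, so
a positive helix delta means helix lost upon adsorption. Both entry
points exist: content of a single structure (the deposited
coordinates) or a window average over a free-protein trajectory.

## Hydrophobic moment

µH = |Σₙ hₙ·exp(i·n·δ)|/N per helix, δ = 100°/residue, on the
Eisenberg consensus normalized scale — the combination under which
the conventional 0.5 amphipathicity threshold is meaningful. All
three (scale, δ, normalization) are overridable. Helices are maximal
H-runs of the package's own assignment with length ≥ 6 (PDB HELIX
records are not consulted, keeping the pipeline self-contained); the
protein mean is unweighted over helices, with a length-weighted mean
reported alongside since the aggregation convention varies across the
literature.

## Flexibility

RMSF is computed per CA (optionally per-residue heavy-atom mean)
after Kabsch superposition of every frame onto the window-average
structure, iterated twice so the reference is self-consistent. Under
isotropic Gaussian jitter with per-coordinate σ the expectation is
RMSF = σ√3; superposition removes six rigid degrees of freedom, which
biases small systems low by ≈ √(1 − 6/(3N)) — negligible for N ≳ 50
selected atoms and the reason recovery tests use a 60-residue fixture.

ΔRMSF = RMSF(adsorbed) − RMSF(free), so negative values mean
rigidified. The active-site verdict operationalizes qualitative
language into explicit thresholds: *compromised* when more than 2/3
of the span is rigidified, *preserved* when positive and negative
counts balance within ±2, else *indeterminate*. Both thresholds are
keyword arguments.

## Surface builders

Graphene: honeycomb lattice, C–C 0.142 nm, filling the requested
basal dims; hydroxyls at ±0.149 nm along the normal (O–H 0.096 nm,
along the normal) on a fraction of (carbon, face) sites. The sheet
stays flat — the sp²→sp³ pyramidalization of a real grafted carbon is
ignored, a geometric simplification. Patterns share one global count
round(oh_fraction × sites), so Janus/striped/random sheets at equal
fraction are controlled comparisons differing only in placement:
random draws sites uniformly (seeded), Janus restricts to one
half-plane along the long axis, stripes restrict to alternating bands
of width *d* starting modified at the origin edge. The default
coverage (1.8 % of carbon sites per face, "half"; 3.6 %, "full") was
set so that the mean nearest-neighbour OH spacing at half coverage is
≈ 0.6 nm via the 2-D Poisson nearest-neighbour relation
E[d] = 1/(2√ρ); absolute hydroxyl density is otherwise a free
parameter of the chemistry, exposed as `oh_fraction`.

Gold: three fcc(111) layers (nearest-neighbour 0.2885 nm) — deeper
layers contribute negligibly inside a 1.2 nm cutoff — with thiols on
a √3×√3 R30° sublattice (0.497 nm), each an all-trans chain standing
along the normal, methyl- (SC) or hydroxyl-terminated (SO) with the
SO fraction given by `chain_ratio`. Curvature is ignored: a 50-nm
particle is locally flat on the nm scale of a protein footprint.

Assembly places the protein so its minimum heavy-atom height above
the top decoration plane equals the gap (default 1.0 nm, the
conventional initial separation), centred laterally; a protein wider
than the sheet is a warning, not an error.

## Synthetic data

Generators are pure functions of (arguments, seed). Ideal helices and
hairpins are built from canonical backbone internal coordinates by
natural-extension (NeRF) chaining: helix φ/ψ = −57°/−47°, strand
−139°/+135°. The hairpin's second strand is the 180°-rotated partner
of the first, with the rotation axis and (Δx, y₀) offset chosen by a
deterministic grid search maximizing the total Kabsch–Sander
inter-strand bond energy; the 2-residue turn is a Bézier-interpolated
backbone whose labels are only required to be non-helix/non-strand.
Jitter trajectories add i.i.d. Gaussian displacements per atom, frame
and coordinate — not dynamics, but the choice that gives every
downstream statistic a closed form. Adsorption paths translate the
protein rigidly along −z in equal steps.

What passing tests therefore show: the *metrics* are correct on
geometries with known answers. What they do not show: anything about
conformational relaxation, solvent, or the adsorption kinetics of
real proteins — those require the cluster-scale MD this package
analyses but does not perform. Printed ensemble results from such
simulations (CSA of tens of nm², energies of hundreds of kJ/mol)
arise from full-size proteins after long equilibration and are not
reproduced by the rigid desk-scale toys.

## Determinism and degenerate inputs

Every stochastic element takes an explicit seed; reports serialize
with sorted keys at six significant digits, so identical configs give
byte-identical output. Degenerate cases are errors with context:
coincident atoms in SASA, collinear point sets in Kabsch, atom-count
mismatches naming the offending frame, untyped atoms naming the atom.
Problem sizes in the shipped tests and the acceptance script (sheets
up to ~10 nm, proteins up to 60 residues, ≤ 2000 frames) were chosen
so the whole suite runs in well under a minute of CPU per module
while keeping every estimate's sampling error far below its test
tolerance.
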