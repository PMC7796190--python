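# Methods

This note documents the models, conventions and numerical choices behind
`mirrorhh`, in the order the pipeline uses them.

## Residue templates and the pair frame

Heavy atoms only; hydrogens are never modelled. Base heavy-atom counts are
A=10, G=11, C=8, U=8; the sugar–phosphate moiety has 12 heavy atoms with a
5′-phosphate and 9 for a free 5′-OH terminus. Chains default to 5′-OH
termini, which is what makes the 14-nt substrate, 33-nt ribozyme and their
complex come to 289, 711 and 1000 heavy atoms.

Base ring geometry comes from the Chemical Component Dictionary bundled
with biotite and is flattened onto its best-fit plane (max displacement
~10⁻³ Å). Treating bases as exactly planar is what makes two properties
exact rather than approximate: base-pair planarity restraints have a true
zero, and a mirrored base superposes onto its original by a proper
rotation (planar objects are achiral), which underlies the base-anchored
enantiomerization below. Sugar and phosphate internal coordinates are
pinned constants in `templates.py` (standard ribonucleotide geometry).

The ideal Watson–Crick pair frame places both C1′ anchors 10.906 Å apart
with both glycosidic bonds at λ = 52.45° to the C1′–C1′ axis, and solves
the two in-plane base rotations so that every canonical donor–acceptor
contact sits at 2.90 Å while each base keeps its CCD glycosidic-bond
orientation. λ and the C1′–C1′ span were themselves solved once, jointly
over G·C and A·U with the flattened CCD bases, and then frozen; because
the anchor scaffold is shared, all four pair orientations are *exactly*
isosteric, and the two orientations of one pair are exact images under the
pair dyad (180° about the in-plane axis bisecting the pair).

## Ribose rings from (P, νmax)

The five ring torsions are νⱼ = νmax·cos(P + 144°(j−2)) (so ν₂ = νmax·cos P,
N-type ≈ C3′-endo near P = 0°, S-type ≈ C2′-endo near P = 180°). A closed
five-ring cannot satisfy five ideal bond lengths, five ideal angles and
five prescribed torsions simultaneously, so the builder seeds a ring
sequentially from ν₀, ν₁ and polishes it by weighted least squares
(weights 100 Å⁻¹ bonds : 10 rad⁻¹ angles : 30 rad⁻¹ torsions). At νmax =
38° the achieved phase matches the request to ≲0.2° and the amplitude to
~1.5%; requests the ring cannot realise (νmax ≳ 80° with these bond
lengths) raise an explicit infeasibility error. Pseudorotation is read
back with the atan2 form of the Altona–Sundaralingam formula (the signed
denominator realises the usual "add 180° when ν₂ < 0" rule), with an
amplitude floor of 5° below which P is reported undefined. Pucker classes:
N for P ∈ [315°, 45°), S for [135°, 225°), otherwise "other"; conformer
names follow the standard 20-bin (18°) envelope/twist wheel centred at
P = 0°, 18°, … so that P = 18° is C3′-endo and P = 162° C2′-endo.

## Ideal helices by exact symmetry

A duplex is one solved nucleotide template propagated by the helical
operator S (twist Ω about z, rise h) with the partner strand generated by
the pair dyad. The dyad axis is kept perpendicular to and intersecting the
helix axis, which makes the two-fold symmetry exact and guarantees that
solving backbone closure for one strand closes the other. Free parameters
of the solve are the sugar roll about the glycosidic bond, γ, β, the dyad
displacement dx and the inclination ψ; hard residuals are the O3′–P(next)
bond (1.595 Å), its two flanking angles, and the adjacent P–P distance;
soft residuals keep χ, γ, β near canonical values to select the physical
branch. Pinned fibre parameters: A-form Ω = 32.7°, h = 2.81 Å, C3′-endo
(P = 18°); B-form Ω = 36.0°, h = 3.38 Å, C2′-endo (P = 162°). The P–P
targets (5.9 Å A-form/N, 7.0 Å B-form/S) are part of that calibration, so
generated helices reproduce them to ≲10⁻⁶ Å by construction; the solved
A-form template lands at χ ≈ −161.4° (anti) and γ ≈ +44.7° (gauche+),
which are frozen as regression values in the tests.

## The hammerhead scaffold

`build_hammerhead_scaffold` is an analysis test scaffold, not a fold
prediction. Helices 1 and 3 are laid out quasi-coaxially (the substrate
runs through both, as in the coaxial stacking of real hammerheads) with
helix 2 branching at 80°; arm rolls come from a deterministic grid search
keeping junction-facing strand ends at arc-able distances. Unpaired core
and loop residues are set down on quadratic arcs (evenly resampled in arc
length, ~6–7 Å per step) with bases rolled outward, the bow direction
chosen greedily to stay farthest from everything already placed, followed
by a rigid-residue repulsion pass until no non-bonded contact is closer
than the 2.5 Å clash floor. Its contract is exactly: correct topology,
1000 heavy atoms, all-D chirality, every mapped Watson–Crick pair
detectable in 3D, no clashes. Backbone O3′–P continuity across the
unpaired stretches is established by the refinement stage, not by the
layout.

## Watson–Crick detection and restrained refinement

A pair is detected when all type-specific donor–acceptor distances (G·C:
O6·N4, N1·N3, N2·O2; A·U: N6·O4, N1·N3) are ≤ 3.5 Å, the base normals
agree within 35°, and the partner base centroid lies within 2.0 Å of the
base plane — the last criterion rejects stacked neighbours that satisfy
the distance cutoffs edge-on.

Refinement is plain gradient descent with backtracking (monotone
non-increasing energy by construction) on a purely harmonic restraint
energy: bonds 300 kcal/mol/Å² and angles 50 kcal/mol/rad² toward
template-measured ideals, Watson–Crick H-bonds 10 kcal/mol/Å² toward the
ideal-pair per-contact distances (≈2.9 Å), base-pair coplanarity
5·(1−(n̂₁·n̂₂)²), chirality-enforcing improper-volume terms
5·(V−V₀)² on the four sugar stereocentres (V the substituent scalar
triple product, V₀ signed by the residue's current hand — these are the
restraint-level counterpart of the force field's chirality impropers, and
without them large junction-closing forces can invert a sugar), and
optional 0.5 kcal/mol/Å² position anchors on paired-base heavy atoms.
Because restraint targets are measured on the same templates the builders
use, an ideal duplex is already at the energy minimum (verified to
ΔE < 10⁻⁶, max move < 10⁻³ Å). All gradients are analytic and checked
against finite differences in the tests.

## Heterochiral construction

To enantiomerize one strand, each of its residues is mirrored (z → −z)
and rigidly re-superposed by a proper rotation so its base heavy atoms
coincide with the pre-mirror base position. Planar bases make this fit
essentially exact (<0.1 Å on as-built structures), so the pairing
interface survives while the sugar–phosphate backbone changes hand; the
broken backbone is re-joined by the restrained refinement with base
anchors on all residues of inter-strand pairs. Applying the operation
twice restores the all-homochiral complex. The resulting L-RNA/D-Rz model
keeps 11/11 helix-1/3 pairs geometrically Watson–Crick and heterochiral,
with helix 2 homochiral — the package-level restatement of the
heterochiral-pairing claim. L/L and D/L are pure mirror images of D/D and
L/D; their conformational summaries are mirror-symmetric to ~10⁻¹³ °.

## Force-field enantiomerization

Only torsions and impropers are modelled; bonds, angles and non-bonded
terms are achiral and identical for D and L. Proper torsions
E = k(1+cos(nφ−δ)) enantiomerize by δ → −δ (mod 360°; 0° and 180° are
fixed points), giving exact invariance of the energy under simultaneous
structure mirroring, since φ → −φ. Chirality-enforcing impropers are
harmonic, E = k(ξ−ξ₀)², and enantiomerize by ξ₀ → −ξ₀ — again exactly
invariant. Periodic impropers carry a signed k that flips under
enantiomerization together with the phase; note that for the 1+cos form a
k sign flip negates the term rather than preserving it, so periodic
impropers sit outside the invariance guarantee — the guarantee (and its
test) covers torsions plus harmonic impropers, which is where chirality
actually lives.

## Ensembles and circular statistics

`generate_ensemble` redraws each residue's P and χ from wrapped normal
distributions (defaults: the structure's own values as means; amplitude
νmax = 38°), rebuilds the sugar ring at the drawn phase (anchored on the
old ring by a proper Kabsch fit; P quantized to a 0.25° cache grid,
negligible next to any prescribed spread), re-places the exocyclic atoms
with the old γ/β, and rolls the rigid base about the glycosidic bond to
the drawn χ, optionally adding i.i.d. Cartesian noise. One integer seed
drives everything; identical seeds give bit-identical ensembles.

Ensemble summaries use the wrapped median (the sample angle minimising the
mean circular deviation). Exact ties — e.g. the two central values of an
even-sized sample — resolve to the circular mean of the tied candidates;
this is the analogue of the ordinary even-n median convention and, unlike
picking the smallest representative, is equivariant under mirroring, so a
mirrored ensemble has exactly negated χ medians and P medians shifted by
180°. Quartiles are taken on deviations around the median.

Superposition is Kabsch via SVD. With reflections disallowed the rotation
determinant is forced to +1; heterochiral comparisons default to
proper-only, since a reflection-allowed fit overlays enantiomers at RMSD 0
and erases the property under study. Region RMSD series use the
ribose–phosphate backbone (O2′ excluded by default, configurable).

## What the synthetic data does and does not show

The generators emulate ideal geometry: perfect helices, exactly isosteric
pairs, prescribed pucker/χ statistics, Gaussian noise. They contain no
electrostatics, stacking energetics, ions or solvent, and the scaffold's
junction layout is a documented heuristic. Passing tests therefore
demonstrate that the *operations* — mirroring, enantiomerization,
restrained refinement, detection and the conformational analyses — behave
exactly as specified on controlled inputs; they do not constitute evidence
about the physical stability of heterochiral complexes, which is an
experimental and simulation question. Published RMSD values that depend on
undeposited model coordinates are deliberately not reproduced; the
comparison *protocol* (selections, atom counts, proper-rotation policy)
is.

## Problem sizes

Default analyses run on the full 47-residue complex; ensemble analyses use
60 frames in the analysis scripts and 200 frames (on a 2-bp duplex) for
the parameter-recovery check, sizes at which the wrapped-median sampling
error (~1.25·σ/√n) is well below the asserted tolerances.

## Known limitations

- The scaffold core is topologically valid but not physically folded; the
  catalytic-core geometry of a real hammerhead (from a crystal structure)
  is out of scope.
- B-form parameters applied to RNA residues (2′-OH present) are a
  geometric fixture for the S-pucker/P–P contrast, not a claim that RNA
  adopts B-form.
- The refinement is restraint-only; it has no notion of sterics beyond
  the builder's clash floor, and converges to the nearest restrained
  minimum.
- Detection thresholds (3.5 Å, 35°, 2 Å plane offset) are conventions;
  values near the boundary flip classification discretely.
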