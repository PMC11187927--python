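# Methods

This note records how `gpcrsel` defines and computes its quantities, the
conventions and numerical choices behind them, and what the synthetic
studies can and cannot show.

## Coordinate frame and superposition

All angular descriptors are defined in a membrane frame whose +Z axis is
the membrane normal pointing extracellular. The frame is carried by a
reference receptor assumed pre-oriented (for deposited structures, an
H3R-type model placed on the bilayer; for synthetic work, the generated
reference stub, which is born in-frame). Every other structure is placed
by rigid Kabsch superposition of Cα atoms of GRN-matched residues.

The default superposition set is TM1–TM4 plus TM7. These helices align
closely between Gs- and Gi/o-coupled complexes, so the frame is not biased
by the TM5/TM6 geometry being measured; the set is configurable
(`{"helices": [...], "atom": "CA"}`, or an explicit GRN list). The Kabsch
solve goes through `scipy`'s `Rotation.align_vectors`, which guarantees a
proper rotation; collinear correspondence sets are refused rather than
returning an arbitrary in-plane orientation, and fewer than three matched
atoms is an error. Gα-side comparisons (e.g. α5 displacement) use the same
receptor-defined frame.

## Helix lengths

`tm5_len`/`tm6_len` count residues from the conserved x.50 anchor
(exclusive) to the cytosolic tip, **by GRN position**: length =
|position(tip) − 50|. The tip is the modeled residue of the segment whose
Cα sits deepest on the −Z side; it must also lie intracellular of the
anchor in GRN terms, else the segment is flagged as inverted/mis-framed.
Counting by position makes lengths robust to unmodeled gaps: a helix with
two disordered residues in the middle is not two residues "shorter". This
convention reproduces the anchor correspondences used throughout the
analysis (tip 5.75 ⇒ length 25; tip 5.69 ⇒ length 19, the shortest "long"
TM5 of Gs receptors; a 5.67→5.75 extension spans nine residues).

Segment boundaries come from the manifest/config (per-receptor GRN
ranges); absent explicit bounds, the full GRN-annotated helix is used.
The tip of a built model is taken as modeled — no attempt is made to
distinguish "last modeled" from "last helical" residues of unwound
C-terminal extensions; users who need that distinction should pass
explicit bounds.

## Helix orientations

The cytosolic orientation of a helix is estimated from its backbone
carbonyls: unit C→O vectors are averaged over a window of 11 residues
(≈3 turns at 3.6 residues/turn, so components perpendicular to the helix
axis nearly cancel) taken from the cytosolic tip inward; residues missing
C, O, or Cα are skipped and the window extends one residue deeper until 11
usable residues or the segment is exhausted (minimum 4, else an error).
The residual perpendicular component of the mean is removed by projecting
onto a helix-axis estimate of the window, and the axis is oriented toward
the cytosolic tip.

The window's helix axis is estimated by the bisector-cross construction:
for consecutive Cα triples, `p[i−1] + p[i+1] − 2·p[i]` is exactly radial
on an ideal helix, so cross products of successive bisectors are exactly
axial and their normalized mean recovers the screw axis to machine
precision on ideal geometry, degrading gracefully on real helices. The
first principal axis of the window's Cα cloud was evaluated and rejected
for this role: on an exact helix whose window does not span a whole number
of turns, the principal axis is biased by several degrees (≈6° for an
11-residue window), which would dominate the tilt measurements.

* `tm5_tilt` is the angle between a receptor's TM5 orientation
  (11-residue window) and the reference receptor's TM5 orientation
  computed once with a 22-residue window. The reference's own tilt is
  computed with the ordinary 11-residue window, not defined as zero, so
  reference and non-reference receptors are treated identically (for an
  ideal reference both windows coincide and the self-tilt is ≈0).
* `tm6_outward` is the angle between the TM6 orientation and −Z, the
  receptor central axis.

Angles are reported unsigned in [0, 180); no in-plane direction ("toward
TM6") is encoded — the classifier uses magnitudes.

## Classification stack

TM6 length is measured but excluded from classification (its Gs and Gi/o
distributions are indistinguishable). The remaining three features are
standardized (population SD, ddof = 0 by default; configurable — and the
projection model can be built directly from the published constants, so
downstream results do not hinge on this choice), decomposed by PCA
(sklearn, full SVD), and the top two components kept. SVD sign ambiguity
is fixed to the published convention: positive TM5-length loading on PC1,
positive TM6-outward loading on PC2. The decision rule is Gs iff the PC1
score exceeds 0.7 strictly; the boundary value itself is called Gi/o.

The stump forest is the in-package implementation of the constrained
ensemble: 15 trees, each a depth-1 stump trained on ⌈0.7·n⌉ rows drawn
with replacement, choosing one random candidate feature and the
class-weighted Gini-optimal threshold (ties broken toward the smallest
threshold; a single-class or constant-valued bag yields a majority-vote
stump). Class weights {Gs: 74, Gi/o: 24} invert the 24:74 training
composition so both classes carry equal total weight; they enter the
impurity and the leaf votes. The ensemble score is the fraction of stumps
voting Gs; the exact 50:50 tie goes to the majority class Gi/o. All
randomness flows through one `numpy` generator seed, so a fixed seed
reproduces the model bit-for-bit *within this package*; reproducing a
third-party library's internal RNG stream is out of scope.

Validation uses stratified k-fold CV (k = 10, reduced with a warning when
the rarer class has fewer members), pooling out-of-fold predictions so
every row is tested exactly once. Metrics: accuracy, F1 with Gs positive,
rank-statistic AUC on the Gs-vote fraction (midrank ties), MCC, and the
(Gs, Gi/o)-ordered confusion matrix. Group comparisons use the two-sided
Mann–Whitney U with midrank ties: exact enumeration for tie-free samples
of ≤8, normal approximation with tie correction otherwise; a fully tied
comparison reports p = 1.

## Interface areas

"Contact area" is half the buried solvent-accessible surface area,
`(SASA(A) + SASA(B) − SASA(A∪B))/2`, probe radius 1.4 Å, Bondi-type
element radii (fallback 1.8 Å with a warning); SASA is Shrake–Rupley
sampling on a deterministic golden-spiral lattice (960 points/atom by
default) via `biotite`. The half-ΔSASA convention, probe, and radii set
are recorded in every interface report's metadata and are configurable;
the halved convention matches the magnitude scale of receptor–Gα
interfaces (~1100–1600 Ų). Interface residues are those with any atom
within 4.0 Å of the partner selection, symmetric in both directions.

Extended TMs are GRN-position subsets: TM5 residues at or past 5.69
toward the cytosol for Gs-coupled receptors, TM6 residues at or past 6.29
for Gi/o-coupled ones (so a TM5 tip at 5.75 carries a 7-residue
extension). The additional contact area is regressed on the extended
residue count by ordinary least squares; the slope's uncertainty is its
standard error.

## Synthetic data

The generator provides every input the pipeline needs.

*Helix stubs.* Backbones (N, Cα, C, O) are chain-extended from internal
coordinates: bond lengths N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231 Å,
ω = 180°, and φ = −57° with ψ = −47.61° / ∠N-Cα-C = 109.77°, the last two
solved once so the helix realizes exactly the standard helical parameters
of 1.5 Å rise and 100°/residue twist (3.6 residues/turn). Carbonyl
orientations are therefore physically realistic — the property the
axis-estimation code actually consumes, and one a Cα-trace fixture could
not test. The screw axis is aligned exactly to the requested
(tilt, azimuth) direction; the free roll about the axis is fixed so the
terminal residue sits at the bottom of its turn, making the constructed
tip coincide with the measured (minimum-Z) tip at any tilt. Receptor
stubs combine TM5, TM6 (16 Å apart, leaning into separate lanes by
default) and short TM1–4/7 scaffold helices on a wide ring for
superposition; overlapping placements are rejected.

*Feature tables.* Labeled rows are drawn from per-group Gaussians at the
group summaries (Gs: TM5 length 23.1 ± 4.6, tilt 12.3 ± 7.1°, TM6 outward
23.8 ± 8.4°; Gi/o: 18.9 ± 3.1, 5.90 ± 2.9°, 19.7 ± 7.6°). TM6 length uses
the group medians (20.5 / 22) with an SD of 3.0 chosen as realistic for
helix-length spread; it never enters the classifier. Features are
independent by default, with an optional TM5 length/tilt correlation hook
for correlation studies. Lengths are rounded to integers (floor 4),
angles floored at 0. The 24 Gs : 74 Gi/o training composition is the
default study condition.

*Toy complexes.* A helix laid horizontally over a planar slab of pseudo-Gα
carbon atoms at a controlled gap exercises the interface code; a slab is
geometry enough for SASA behavior, so no Gα fold is modeled.

What passing synthetic tests shows: the measurement pipeline recovers
constructed geometry essentially exactly, the classifier algebra matches
its closed form, and the ensemble behaves sensibly under the stated group
models. What it does not show: performance on real structures, where
helices kink, fray, and deviate from ideal geometry, where GRN tables and
segment bounds carry curation error, and where features correlate. The
diagonal-Gaussian mixture is a simplified stand-in for the real feature
distributions; measured on it, the constrained stump forest's pooled
10-fold CV accuracy lands near 0.9 and exceeds the 74/98 majority-class
baseline in roughly 92% of seed replicates (the acceptance script reports
the rate for its own seed).

## Degenerate inputs and tie-breaks

Alternate locations resolve to the highest-occupancy conformer (first on
ties); waters are dropped on load. Duplicate GRNs within a chain are
rejected on every mutation path. Zero-variance features refuse
standardization. Collinear atom sets refuse superposition. Stump threshold
ties break toward the smaller threshold; the forest's 50:50 vote goes to
Gi/o; X exactly at 0.7 goes to Gi/o. SASA needs no seed (deterministic
lattice). PDB round-trips preserve coordinates to the 10⁻³ Å column
precision.

## Known limitations

* GRN maps are consumed, never computed: no alignment-based numbering.
* No secondary-structure assignment; segment ends are annotation-driven.
* The membrane frame comes from superposition onto a pre-oriented
  reference, not from implicit-membrane optimization.
* The published trained forest (and hence its exact confusion matrix on
  the 54 experimental structures) is not reproduced: that would require
  the original per-receptor feature tables and a third-party RNG stream;
  the validation here is against deposited structures the user supplies
  plus the synthetic property suite.
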