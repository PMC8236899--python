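# Methods

This note records the models, conventions and numerical choices behind each
stage of the package, what the synthetic fixtures do and do not emulate, and
the design decisions taken where more than one reasonable convention exists.

## Structural model and numbering

Coordinate files (PDB/mmCIF, parsed with gemmi) are flattened to chains of
residues of heavy atoms with author numbering and insertion codes.  For each
altloc group the highest-occupancy conformer is kept, ties broken by altloc
letter, so downstream geometry is deterministic.  Waters are held apart from
polymer residues and participate only where explicitly enabled (water-bridged
polar contacts; SASA occlusion behind a flag, off by default).

Canonical numbering — the cross-class scheme rooted in the classic HLA-A2
α1/β₂-m convention, with insertion codes such as p62b in loop regions — is
*configuration, not inference*.  Per-structure configs give, per domain
class (pa, pb, ia, ib), the author chain and inclusive residue range(s), an
optional author→canonical offset, and an insertion-code table; the peptide
is anchored by the author number of P1, every other register following
arithmetically (overhang residues get registers ≤ 0, i.e. P-1, P-2…).  The
map is checked to be a bijection; unmapped polymer residues are reported,
never dropped.  Curated numbering of loop regions is genuinely uncertain in
parts of the MHC family, which is exactly why it is supplied as reviewable
configuration rather than recomputed by alignment at run time.  The same
reasoning applies to the peptide register: which residue sits in the P1
pocket comes from the crystallographic literature, and inferring it (a hard
problem for class II) is out of scope.

## Hydrogen bonds and secondary structure

Backbone H-bonds use the Kabsch–Sander electrostatic model,
`E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, accepted
below −0.5 kcal/mol.  Crystal structures lack hydrogens; the amide H is
placed 1.01 Å from N opposite the bisector of the C(i−1)–N–CA angle (one of
the two classic reconstructions; at the −0.5 kcal/mol threshold it gives
the same accepted set as the carbonyl-direction variant on all fixtures
tested).  Prolines donate nothing; chain-start residues have no H; donors
and acceptors closer than two positions in sequence are excluded.  A 9 Å
CA–CA prefilter bounds the pair scan; tests verify it is lossless against
an exhaustive scan.

States follow the DSSP pattern rules: n-turns from i→i+n bonds (n = 3, 4,
5), minimal helices from two consecutive turns (lengths ≥ 3/4/5 for
3₁₀/α/π), bridges from the parallel/antiparallel bond patterns, ladders
from runs of bridges.  Two or more consecutive bridges make a strand;
singleton bridges remain bridges and are not labelled strand.  Where helix
patterns overlap, a complete π pattern (≥ 5 residues) overrides α — the
behaviour of modern DSSP releases that report π-helices — otherwise
α > 3₁₀ > π.  On ideal fixtures the assignment matches mdtraj's DSSP
implementation residue-for-residue; mdtraj serves only as an independent
oracle, never as the implementation.

Strand labels are assigned per domain in sequence order (S1–S4 expected for
p-domains, S1–S7 with the conventional A–G aliases for IgSF domains);
unexpected counts are labelled best-effort with a warning.

## β-bulge and S2-S3-cleft detectors

Both detectors consume only main-chain hydrogen-bond topology — never CA
distances — because that is what defines the features.

A **classic β-bulge** appears in the rung sequence of an antiparallel
ladder as the bulged strand skipping exactly one residue more than its
partner between two accepted rungs: with `skip_a` partner residues and
`skip_a + 1` bulge-strand residues skipped (`skip_a` ∈ {0, 1}), the two
consecutive residues after the inner flanking rung form the bulge pair and
the single partner residue between the rungs is the opposite residue.  The
skipped region must be genuinely unpaired and chain-continuous.  Sidechain
direction is the sign of the summed (CB−CA) projections onto the local
sheet-plane normal (least-squares plane of the rung-neighbourhood CAs),
oriented toward the mean helix-CA centroid — "up" is out of the groove.
For pure-sheet inputs with no helix the fallback orientation is the
majority sidechain side of the remaining strand residues; direction is only
asserted in tests when a helix reference exists.

The **S2-S3 cleft** is decided from the outermost accepted rung between the
strands labelled S2 and S3 of one p-domain: present exactly when that rung
is the canonical p24–p36 pair, absent when pairing extends outward (e.g. to
p22–p38), undetermined (neither true nor false) when S2/S3 cannot be
identified.

## Superposition

Standard Kabsch: SVD of the cross-covariance with sign-correction of the
smallest singular vector, so reflections are excluded; inputs must be ≥ 3
non-collinear points.  Domain superposition matches residues by canonical
label (CA-only by default, other atom sets by argument), drops residues
with missing atoms from the correspondence, and errors below three pairs
naming the selector.  Using the curated numbering as the correspondence —
rather than a sequence-independent structural aligner — makes fits
deterministic and reviewable; absolute RMSDs can differ slightly from
aligner-based values, but orientation comparisons (the intended use, e.g.
residual ib-domain displacement after a pab fit) are unaffected.

## Contacts, SASA and interfaces

Contacts: any heavy-atom pair ≤ 4.0 Å between disjoint residue groups
(hydrogens excluded even when present); polar contacts: N/O/S pairs ≤
3.5 Å, with waters bridging both groups when requested; disulfides: SG–SG
≤ 2.5 Å.  A kd-tree accelerates the scans; tests pin them to O(n²)
brute-force equality.

SASA is Shrake–Rupley with a deterministic golden-spiral point set (960
points by default), probe 1.4 Å, and a single element-keyed van der Waals
radii table (C 1.70, N 1.55, O 1.52, S 1.80 …) shipped in code; unknown
elements fall back to the carbon radius with a warning.  Absolute areas
carry the usual few-percent method variance between radii tables, so no
asserted quantity depends on absolute SASA — scores are ratios or
differences computed within one table.  Because the sphere-point grid is
fixed in space, rotational invariance holds to quadrature accuracy (≈1% at
960 points, <0.5% at 4000); the invariance test uses 4000.

Interface summaries report per-residue ΔSASA (isolated part vs complex),
interface residues as those burying > 0.1 Ų (any-burial, the convention of
interface servers; configurable), and the symmetric buried area
½(SASA_a + SASA_b − SASA_ab).  Peptide exposed surface is the peptide's
SASA within the complex, which equals its isolated area minus the buried
part; an internal-consistency test ties the two routes together.

## Peptide-register geometry and the knob score

Register distances are plain CA distances between canonical registers.
Bulge height is the maximum CA deviation from the straight P1→PΩ axis (an
end-anchored axis, not a fitted line, matching how bulging is described
for groove-bound ligands); note an extended β chain has an intrinsic
pleat of ~1.5 Å, so only differences well above that are meaningful.
Sidechain orientation is sign((CB−CA)·n̂) with n̂ the pab sheet normal
oriented toward the groove helices, and a ±0.3 cosine dead-band reported
as "lateral" to avoid flip-flopping near the plane.

The knob-insertion score takes the ia-domain knob residues (default
canonical ia56 and ia60) and computes the fractional burial of their
sidechain atoms against the pab domain:
`1 − SASA_sidechain(residue + pab) / SASA_sidechain(residue alone)`,
averaged over the knob residues.  The inserted flag applies a 0.6
threshold; the continuous score is always reported beside it, and the
threshold is an explicit, documented parameter because the underlying
quantity is continuous.  Glycine at a knob position yields NaN for that
residue rather than a silent 0.  The score is monotone non-increasing as
the ia domain is pulled away (a tested property).

## Conservation classification

Identity between two sequences over a domain block is
100 × matches / (columns where both are non-gap); `X` counts as mismatch,
never as gap.  The denominator convention (shared non-gap columns rather
than block length) is stated because published identity percentages rarely
specify it; the two conventions differ by at most a point or two on
typical MHC domain blocks.

The column classifier evaluates labels in fixed precedence —
MHC-characteristic (conserved across both MHC lineage groups, absent from
a non-MHC outgroup), ancestral (conserved across both lineage groups),
a-lineage, b-lineage, then class-specific tiers — where a label applies
when some residue-type set reaches the support threshold (default 0.8) in
every required group while staying below it in every excluded group.
Residue-types are configurable sets (acidic/amide, aromatic, aliphatic …)
plus singletons.  Support in [0.5, threshold) yields the same label
flagged low-confidence, mirroring the small-font uncertainty tier of
curated alignment figures.  Curated shadings of this kind are partly
subjective; the classifier is deterministic given its configuration, and
disagreements with a curated figure should be read as properties of the
configuration, not hidden.

## Synthetic fixtures: what they do and do not show

Backbones are grown by internal-coordinate (NeRF) construction from ideal
bond lengths/angles (Engh–Huber-like values), so requested φ/ψ are exact
and measured dihedrals recover them to numerical precision.  The flat
antiparallel sheet uses the repeating (φ, ψ) near (−139°, 135°) solved so
the per-residue screw is exactly 2₁ (flat, untwisted), with the partner
strand placed by a once-solved rigid offset that puts narrow-pair N···O
distances at 2.9 Å; the pairing register is forced by strand-length parity
(offset 1 for even lengths).  Engineered bulges insert one residue arcing
2+ Å above the plane with real ~1.33 Å peptide bonds to its neighbours;
all three bulge-window sidechains point off-plane, as in the conserved
p33/p34 feature.

The toy complexes are geometric caricatures assembled from these parts: an
eight-strand floor (four strands per p-domain), poly-glycine wall helices,
a registered peptide, an ia-like strand beneath the floor and an ib-like
helical appendage on a programmable hinge.  Class-typical features are
engineered so the detectors have known answers: the cleft domain's S3
outer end bends off the sheet so its outermost surviving rung is the
canonical p24–p36 pair (pb for class I, pa for class II); the class I
peptide is bent into a circular arc of 6 Å sagitta (chosen to contract the
P1–P9 span by ~15%, the magnitude separating real class I from class II
9-mer cores) with P1 engineered up and PΩ down, while the class II peptide
stays extended with both anchors down and optional overhang beyond the
walls; the class I ia strand carries two long pseudo-sidechains placed
into floor openings (the knob), whereas the class II ia sits lower with
short sidechains.  Toy layout constants (wall offsets, knob reach) were
chosen once so the fixtures are free of steric clashes below 2.2 Å while
preserving 4 Å contacts.

Passing on these fixtures demonstrates that the detectors recover
engineered ground truth from geometry alone.  It does not demonstrate
robustness to the messiness of real crystal structures — missing atoms,
distorted strands, alternative conformations, register ambiguity — beyond
the specific degradations the tests exercise (altlocs, missing backbone
atoms, absent registers).  Real-structure analyses additionally depend on
the correctness of the shipped per-accession numbering configs, whose
loop-region entries are best-effort transcriptions.

## Problem sizes and determinism

Default analysis sizes: 960 sphere points for free-standing SASA calls, 240
for the pipeline's interface sections (differences against the 960-point
values are within the method's few-percent variance), toy floors of 8 × 9
residues, 100 randomized bulge placements and 100 planted conservation
columns in the property checks.  Every generator is deterministic under a
fixed seed, and the pipeline's report bundle is byte-identical across
reruns of the same configuration (timestamps are isolated in provenance).
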