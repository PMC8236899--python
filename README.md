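# pmhckit

Comparative structural analysis of peptide-loaded MHC class I and class II
complexes, for molecular-evolution work on antigen presentation.

Classical pMHC-I (heavy chain + β₂-microglobulin) and pMHC-II (α + β chain)
ectodomains are built from four homologous domains.  This package adopts the
unified nomenclature used in cross-class comparisons — **pa** (I-α1/II-α1) and
**pb** (I-α2/II-β1) form the peptide-binding superdomain **pab**; **ia**
(β₂-m/II-α2) and **ib** (I-α3/II-β2) are the membrane-proximal IgSF domains —
and makes the structural features that distinguish the two classes
*computable*:

* **Canonical numbering** — per-structure configs map author chains/residues
  to canonical domain positions (with insertion codes) and the peptide
  register P1…P9/PΩ.
* **Secondary structure & β-topology** — Kabsch–Sander hydrogen bonds
  (`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`, bond below −0.5
  kcal/mol; amide H reconstructed on the C(i−1)–N–CA bisector), DSSP-style
  states, strand labelling (S1–S4 per p-domain, S1–S7/A–G for IgSF), and two
  rule-based detectors: the classic **β-bulge** (two consecutive residues
  opposite one partner residue, conserved at p33/p34 of strand S3) and the
  **S2-S3 cleft** (main-chain pairing truncated at the p24–p36 rung instead
  of extending to p22–p38).
* **Superposition** — Kabsch least-squares fits over canonical-numbering
  correspondences (CA by default), used for cross-structure domain-orientation
  comparisons.
* **Contacts, surfaces, interfaces** — residue contacts at 4.0 Å, polar
  contacts at 3.5 Å (optionally water-bridged), disulfides, Shrake–Rupley
  SASA, per-residue ΔSASA interface summaries with symmetric buried area
  `BSA = ½(SASA_a + SASA_b − SASA_ab)`, and peptide exposed surface
  (accessible minus buried).
* **Peptide-register geometry** — P1–P9/P2–P9/P1–PΩ CA spans, bulge height
  off the P1→PΩ axis, per-register sidechain orientation (up/down/lateral in
  the groove frame), and the **knob-insertion score**: fractional SASA burial
  of the ia-domain hydrophobic knob (canonically iaF56+iaW60) against the
  pab sheet floor.
* **Conservation** — per-domain percent identity on curated gapped
  alignments and a rule-based residue-type/lineage classifier (ancestral,
  a/b-lineage, class-specific, MHC-characteristic tiers with support values).
* **Synthetic fixtures** — ideal α/3₁₀/π helices, antiparallel sheets with
  engineered bulges, and toy class I / class II groove complexes whose
  contacts, cleft, knob and register geometry are known by construction, so
  the whole pipeline is testable offline.

## Worked example

```sh
python examples/groove_geometry.py
```

```
class I: P1-P9 = 24.0 A, bulge height = 7.1 A, P1 sidechain up, P9 down, knob burial = 0.79 (inserted=True), peptide exposed = 547 A^2
class II: P1-P9 = 27.8 A, bulge height = 1.6 A, P1 sidechain down, P9 down, knob burial = 0.19 (inserted=False), peptide exposed = 834 A^2
```

The two lines contrast the binding modes on the synthetic complexes: the
class I toy binds its 9-mer core in a closed groove as a bulged arc — the
P1–P9 CA span contracts by ~15%, the P1 sidechain rotates out of the groove,
the β₂-m-like knob buries ~80% of its sidechain surface in the sheet floor —
while the class II toy holds an extended chain in an open groove (long span,
flat chain, P1 and P9 both pointing down, no knob insertion, and roughly 50%
more peptide surface left solvent-exposed).

Other examples, one per capability: `secondary_structure.py`,
`bulge_and_cleft.py`, `superpose_domains.py`, `conservation_classes.py`,
`run_pipeline.py`.

A thin CLI wraps the pipeline:

```sh
pmhckit analyze configs/toy_suite.yaml      # per-structure reports (JSON)
pmhckit fixtures --out fixtures/            # regenerate the synthetic suite
```

Per-accession numbering configs for the reference crystal structures
(HLA-A2, HLA-DR1, shark and carp class I) are shipped under
`configs/accessions/`; coordinate files themselves are fetched by the user
(no download machinery is included) and placed under `data/structures/`.

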