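"""Assign DSSP-style secondary structure to ideal helices and a β-sheet.

Builds poly-alanine fixtures with exact backbone dihedrals, computes
Kabsch–Sander hydrogen bonds, and prints the per-residue state string.
"""
from pmhckit.secondary import assign_secondary_structure, compute_backbone_hbonds
from pmhckit.synthetic import HelixSpec, SheetSpec, make_beta_sheet, make_ideal_helix

CODE = {"alpha": "H", "310": "G", "pi": "I", "strand": "E", "turn": "T", "coil": "-"}

for kind in ("alpha", "310", "pi"):
    st = make_ideal_helix(HelixSpec(n_residues=12, kind=kind))
    bonds = compute_backbone_hbonds(st)
    ss = assign_secondary_structure(bonds, st)
    states = "".join(CODE[s] for _, s in ss.as_rows())
    seps = sorted({b.donor[1] - b.acceptor[1] for b in bonds})
    print(f"{kind:>5} helix: {states}   (N-H...O=C donors bond i -> i{-seps[0]:+d})")

st, _ = make_beta_sheet(SheetSpec(n_strands=2, strand_length=8))
ss = assign_secondary_structure(compute_backbone_hbonds(st), st)
print("2-strand antiparallel sheet:",
      "".join(CODE[s] for _, s in ss.as_rows()),
      "  (E = strand; chain ends cannot complete bridge patterns)")
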