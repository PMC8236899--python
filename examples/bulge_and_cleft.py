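"""Detect a β-bulge and an S2-S3 cleft from hydrogen-bond topology alone.

An extra residue is engineered into one strand of an ideal sheet; the
detector must localise it from the ladder pairing.  The toy class I complex
carries the class-typical truncated S2-S3 pairing in its pb domain.
"""
from pmhckit.secondary import (build_beta_topology, compute_backbone_hbonds,
                               detect_beta_bulges, detect_s2s3_cleft)
from pmhckit.synthetic import SheetSpec, ToyComplexSpec, make_beta_sheet, make_toy_pmhc
from pmhckit.numbering import assign_domains
from pmhckit.secondary import assign_secondary_structure

st, truth = make_beta_sheet(SheetSpec(n_strands=2, strand_length=9, bulge_at=(0, 4)))
topo = build_beta_topology(compute_backbone_hbonds(st), st)
for b in detect_beta_bulges(topo, st):
    pair = "+".join(f"{c}{n}" for c, n, _ in b.bulge_pair)
    opp = "{}{}".format(*b.opposite_residue[:2])
    print(f"bulge: residues {pair} oppose {opp} "
          f"(inserted residue was {truth.bulge_inserted[0]}{truth.bulge_inserted[1]})")

st, nmap, truth = make_toy_pmhc(ToyComplexSpec(class_type="I"))
domains = assign_domains(st, nmap)
hb = compute_backbone_hbonds(st)
topo = build_beta_topology(hb, st, assign_secondary_structure(hb, st),
                           domains=domains, nmap=nmap)
for d in ("pa", "pb"):
    s = detect_s2s3_cleft(topo, d, nmap)
    print(f"class I toy, {d} domain: cleft_present={s.cleft_present} "
          f"outermost S2-S3 pair=p{s.last_pair[0]}-p{s.last_pair[1]}")
print("(cleft present = pairing stops at p24-p36; absent = extends to p22-p38)")
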