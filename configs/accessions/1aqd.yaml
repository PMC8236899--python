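# HLA-DR1 (pMHC-II reference structure, PDB 1AQD).
# alpha chain: alpha1 = pa, alpha2 = ia; beta chain: beta1 = pb, beta2 = ib.
# The peptide register anchor (author number of P1) comes from the
# crystallographic literature for the bound endogenous peptide; verify the
# chain identifiers and peptide numbering against the retrieved file.
id: 1AQD
class_label: MHC-II
domains:
  pa: {chain: A, range: [1, 84]}
  ia: {chain: A, range: [85, 180], offset: -84}
  pb: {chain: B, range: [1, 94]}
  ib: {chain: B, range: [95, 190], offset: -94}
peptide: {chain: C, p1: 3}   # overhanging N-terminal residues map to P-1, P-2
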