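# HLA-A2 (pMHC-I reference structure, PDB 3PWN).
# Canonical numbering follows the classic HLA-A2 heavy-chain / human beta-2-
# microglobulin convention: alpha1 = pa 1-90, alpha2 = pb (author 91-182),
# alpha3 = ib (author 183-276), beta-2-m = ia.  Loop-region positions with
# insertion codes are alignment-curated and not encoded here; verify chain
# roles against the retrieved file before use.
id: 3PWN
class_label: MHC-I
domains:
  pa: {chain: A, range: [1, 90]}
  pb: {chain: A, range: [91, 182], offset: -90}
  ib: {chain: A, range: [183, 276], offset: -182}
  ia: {chain: B, range: [1, 99]}
peptide: {chain: C, p1: 1}   # 9-mer; P1 = author residue 1
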