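# Grass carp UAA (pMHC-I, PDB 5Y91); class I domain layout.
id: 5Y91
class_label: MHC-I
domains:
  pa: {chain: A, range: [1, 90]}
  pb: {chain: A, range: [91, 182], offset: -90}
  ib: {chain: A, range: [183, 276], offset: -182}
  ia: {chain: B, range: [1, 99]}
peptide: {chain: C, p1: 1}
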