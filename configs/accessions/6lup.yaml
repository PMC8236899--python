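# Nurse shark UAA*01 (pMHC-I, PDB 6LUP).  Same domain layout as other
# class I structures: heavy chain pa/pb/ib, beta-2-m-like chain ia.
# Note the recombinant beta-2-m carries iaS3 instead of the natural iaG3.
id: 6LUP
class_label: MHC-I
domains:
  pa: {chain: A, range: [1, 90]}
  pb: {chain: A, range: [91, 182], offset: -90}
  ib: {chain: A, range: [183, 276], offset: -182}
  ia: {chain: B, range: [1, 99]}
peptide: {chain: C, p1: 1}
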