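"""Superpose two complexes over their peptide-binding superdomain.

Two toys differing only in the programmed ib-domain hinge angle are fitted
over pab; the residual ib displacement is the orientation difference the
fit is designed to reveal.
"""
import numpy as np
from pmhckit.superpose import superpose_by_domain
from pmhckit.synthetic import ToyComplexSpec, make_toy_pmhc

ref, ref_map, _ = make_toy_pmhc(ToyComplexSpec(class_type="I"))
mob, mob_map, _ = make_toy_pmhc(ToyComplexSpec(class_type="I", ib_hinge_angle=20.0))
fit = superpose_by_domain(mob, mob_map, ref, ref_map, selector="pab")

def ib_centroid(st):
    return np.mean([r.coord("CA") for r in st.chains["D"]], axis=0)

disp = np.linalg.norm(ib_centroid(fit.transformed) - ib_centroid(ref))
print(f"pab fit: rmsd = {fit.rmsd:.2e} A over {fit.n_fitted} CA positions")
print(f"residual ib centroid displacement = {disp:.2f} A "
      "(the programmed 20-degree hinge, untouched by the pab fit)")
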