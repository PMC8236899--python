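"""Run the full analysis pipeline on the synthetic suite and summarise it.

Equivalent to `pmhckit analyze configs/toy_suite.yaml`; prints the
class-discriminating calls from the report bundle.
"""
from pmhckit.pipeline import run_pipeline

bundle = run_pipeline({
    "structures": [
        {"id": "toy-I", "synthetic": {"kind": "toy_pmhc", "class_type": "I"}},
        {"id": "toy-II", "synthetic": {"kind": "toy_pmhc", "class_type": "II",
                                       "peptide_overhang": 2}},
    ],
    "thresholds": {"sasa_points": 240},
})
assert not bundle["errors"], bundle["errors"]
for sid, section in bundle["structures"].items():
    cleft = {d: v["present"] for d, v in section["topology"]["cleft"].items()}
    print(f"{sid}: cleft={cleft}, knob inserted={section['knob']['inserted']}, "
          f"P1-P9={section['peptide_geometry']['register_distances']['P1-P9']} A, "
          f"peptide exposed={section['peptide_exposed_surface']} A^2, "
          f"{len(section['peptide_contacts'])} peptide-receptor contacts")
print("superpositions:", bundle.get("superpositions"))
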