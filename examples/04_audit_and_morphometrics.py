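"""The bundled autapomorphy audit and vertebral elongation indices.

Loads the bundled table of proposed autapomorphies of the four Winton
Formation sauropod species crossed with 25 specimens, prints one row of
the O/X/- grid, the rule-based referral suggestions, and an elongation
index (aEI = centrum length / mean of posterior articular width and
height).
"""

from morphotax import (
    VertebraMeasurement,
    aei,
    audit,
    limb_ratio,
    load_bundled_diagnostics,
    load_bundled_specimens,
    suggest_referral,
)

diagnostics = load_bundled_diagnostics()
specimens = load_bundled_specimens()
result = audit(specimens, diagnostics)

row = result["symbols"]["AODF 2296"]
print("AODF 2296 audit row (O possesses / X lacks / - not assessable):")
print("  " + " ".join(f"{d.id}:{row[d.id]}" for d in diagnostics))

for sid in ("AODF 2854", "AODF 0656", "AODF 2296"):
    sp = next(s for s in specimens if s.id == sid)
    ref = suggest_referral(sp, diagnostics)
    print(f"{sid}: {ref['referred_to']}  ({ref['rationale']})")

m = VertebraMeasurement("example", "caudal centrum",
                        length=120.0, width=95.0, height=105.0)
print(f"aEI of a 120 x (95, 105) mm centrum: {aei(m)['aei']:.2f} "
      "(1.0 means as long as tall/wide; >1 elongate)")
print(f"tibia/femur ratio 590/1000 mm: {limb_ratio(590.0, 1000.0):.2f}")
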