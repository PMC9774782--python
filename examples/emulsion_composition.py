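"""Map surfactant mass fractions to interfacial volume fractions.

A 1:9 v/v oil-in-water emulsion (10 mL) stabilized by Tween 20
(density 1.11 g/mL) at the mass fractions of the reference design.
"""

from pseudophase import composition_from_surfactant

for wt in (0.005, 0.01, 0.02, 0.04):
    comp = composition_from_surfactant(wt)
    print(f"Tween 20 {100 * wt:4.1f}% w/w -> Phi_I = {comp.phi_I:.4f}  "
          f"(Phi_O = {comp.phi_O:.2f}, Phi_W = {comp.phi_W:.4f})")
# 0.5-4% w/w maps to Phi_I ~ 0.0045-0.036, spanning the nominal
# 0.005-0.04 design range of the kinetic experiments.
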