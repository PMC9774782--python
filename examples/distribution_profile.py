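"""Antioxidant distribution and interfacial enrichment across surfactant levels.

Uses P_O^I = 5 (the value implied by a 20% interfacial fraction at
Phi_I = 0.005 in a 1:9 v/v emulsion) and [AO_T] = 0.004 M.
"""

from pseudophase import distribution_profile

prof = distribution_profile(
    P_O_I=5.0, AO_T=0.004, phi_I_grid=[0.005, 0.01, 0.02, 0.04], phi_O=0.1
)
print(prof.to_dataframe().to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(f"\npct_I rises {prof.pct_I[-1] / prof.pct_I[0]:.2f}-fold across the grid "
      f"while conc_I falls {prof.conc_I[0] / prof.conc_I[-1]:.2f}-fold "
      f"(dilution with surfactant: {prof.dilution_with_surfactant})")
# The interfacial percentage climbs from 20% to 67%, yet the effective
# interfacial concentration drops from 0.16 M to 0.067 M: the interface
# volume grows faster than its antioxidant load. fold_I is the enrichment
# over the stoichiometric 0.004 M (40x down to ~17x here).
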