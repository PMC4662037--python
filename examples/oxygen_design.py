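"""Closed-form oxygen design chain for a perforated-MEA sandwich.

Computes how much oxygen tension the perfusate must present at the MEA
surface so a dark-adapted retina clipped between two perforated arrays stays
above its survival tensions, using only the flux-balance design equations.
"""

from mtmkit import (
    default_mea_design,
    effective_oar,
    henry_tension,
    membrane_conductance,
    required_gradient,
    required_surface_tension,
)

design = default_mea_design()
oar = effective_oar(design)
print(f"whole-surface open-area ratio:      {100 * oar:.1f} %")

# gradient the 170 um retina demands through two perforated supply surfaces
grad = required_gradient(q_nr=3.5, tissue_thickness_cm=0.017, oar=oar, n_surfaces=2)
print(f"required tension gradient:          {grad:,.0f} mmHg/cm")

# tension step across the 20 um array on top of the 45 mmHg arterial target
p_smea = required_surface_tension(p_sr=45.0, dPdz=grad, mea_thickness_cm=0.002)
print(f"required MEA-surface tension:       {p_smea:.0f} mmHg")

g = membrane_conductance(oar, dk_fluid=2.84e-6, thickness_cm=0.002)
print(f"homogenized MEA conductance:        {g:.3e} ml O2 cm^-2 min^-1 mmHg^-1")

p_inlet = henry_tension(0.018, 3.09e-5)
print(f"inlet tension from 18 mg/l reading: {p_inlet:.0f} mmHg")

print(
    "\nThe perfusate must hold roughly "
    f"{p_smea:.0f} mmHg at the array surface; the {p_inlet:.0f} mmHg "
    "hyperoxic inlet leaves ample margin for the drop across the fluid film."
)
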