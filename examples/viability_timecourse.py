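"""Viability monitoring: firing-rate time course with decline detection.

Simulates a 72-minute session (24 blocks of 1 min pulse train + 2 min rest)
from a Type III cell whose evoked yield starts decaying 55 minutes in, then
recovers the decline onset from the block-wise firing rates alone.
"""

from dataclasses import replace

from mtmkit import StimulusProtocol, generate_session, rate_timecourse, type_iii_response

protocol = StimulusProtocol(n_blocks=24)
response = replace(type_iii_response(), decline_onset_min=55.0, decline_tau_min=5.0)
train, _ = generate_session(response, protocol, seed=1)

tc = rate_timecourse(train, protocol)
for t, r in zip(tc.block_times_min, tc.rates_hz):
    bar = "#" * int(round(r))
    print(f"{t:5.0f} min  {r:5.1f} Hz  {bar}")

print(f"\ngenerator decline onset: 55 min")
print(f"detected decline onset:  {tc.decline_onset_min:.0f} min")
print(
    "\nRates hold a ~15 Hz plateau while the tissue is well supplied, then "
    "collapse; the change point localizes the viability loss to within one "
    "stimulation block."
)
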