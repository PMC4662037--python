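"""Evoked-response typing from synthetic ganglion-cell recordings.

Generates one Type I session (20 stimulus repeats) and one Type III session
(32 repeats) at the 1.5 Hz / 5 ms pulse protocol, builds 10 ms-bin
peri-stimulus histograms and classifies the burst structure.
"""

from mtmkit import (
    StimulusProtocol,
    align_and_bin,
    classify_response,
    generate_session,
    type_i_response,
    type_iii_response,
)

for maker, n_repeats in ((type_i_response, 20), (type_iii_response, 32)):
    protocol = StimulusProtocol.single_train(n_repeats)
    train, _ = generate_session(maker(), protocol, seed=1)
    psth, raster = align_and_bin(train, protocol)
    label = classify_response(psth)
    head = " ".join(f"{c:3d}" for c in psth.counts[:10])
    print(f"cell generated as Type {maker().cell_type}, {n_repeats} repeats:")
    print(f"  first ten 10-ms bins: {head}")
    print(f"  classified as: Type {label}\n")

print(
    "Type I shows one early bin cluster (single burst < 20 ms after the "
    "stimulus); Type III shows two clusters (a second burst near 45 ms), "
    "matching the electrically evoked taxonomy the platform records."
)
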