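# mtmkit

Oxygen-transport design and spike-train analysis for perforated
MEA–tissue–MEA ("sandwich") platforms.

Clipping a live retina between a stimulation microelectrode array (facing the
photoreceptors) and a recording array (facing the ganglion cells) enables
point-to-point stimulation/recording of the retinal circuit — but the retina
consumes oxygen about as fast as the brain, and two slabs pressed against the
tissue block its supply. The engineering answer is to perforate both arrays
with diffusion holes and perfuse oxygenated medium over them. `mtmkit`
implements the computational side of that platform for neuroengineers:

* **Design equations.** Fick flux `J = D·k · dP/dz`, the consumption–flux
  balance `Q_NR · A · L = D·k · (dP/dz) · 2A · OAR` for a retina of thickness
  `L` supplied through two perforated surfaces of open-area ratio OAR, the
  thin-array step `dP/dz ≈ (P_SMEA − P_SR)/t_MEA`, and Henry's law
  `P = c / k_H` for converting dissolved-oxygen meter readings to tension.
* **Transport solver.** A finite-volume steady convection–diffusion–reaction
  solver over the layered stack (perfused chamber / MEA / outer retina /
  inner retina / MEA / chamber), with perforated arrays homogenized to
  effective conductance layers (`OAR · D·k_fluid / t`), zero-order tissue
  consumption with a hypoxic shut-off, and extraction of the three design
  check points: outer MEA surface (P_SMEA), retina–MEA interface (P_SR) and
  retina mid-plane (P_IR). A 2D plane-symmetric mode resolves the streamwise
  flow explicitly.
* **Spike pipeline.** Threshold-crossing spike detection with a 1 ms
  refractory, peri-stimulus time histograms (10 ms bins) and rasters aligned
  to a 1.5 Hz / 5 ms pulse-train protocol delivered in 3-minute blocks
  (1 min train + 2 min rest), burst-structure classification into the
  electrically evoked Type I (one burst within 20 ms) and Type III (two–three
  bursts) patterns, and block-wise firing-rate time courses with automatic
  detection of the viability decline onset.
* **Synthetic data.** A seeded generator producing ground-truth spike trains
  (and optionally rendered noisy traces) with the platform's response
  structure and plateau-then-decline viability dynamics, plus a battery of
  solver scenario configs — so the whole pipeline is testable without any
  recordings.

## Worked example

```bash
python examples/simulate_oxygen.py
```

```
              checkpoint  required_mmHg  simulated_mmHg  pass
   1 (outer MEA surface)          156.0      260.365626  True
2 (retina-MEA interface)           45.0      149.515339  True
    3 (retina mid-plane)           17.4      104.995092  True

conservation imbalance: 1.54e-14 (relative)
```

Reading: the perfusate enters at 583 mmHg (18 mg/l through Henry's law); the
concentration film over the array drops it to ~260 mmHg at the MEA surface;
diffusion through the 18.9 %-open perforations costs another ~110 mmHg; and
consumption inside the 170 µm retina sags the profile by a further
~45 mmHg to its mid-plane minimum — comfortably above the 17.4 mmHg
dark-adapted survival floor, which is the design claim the platform rests on.
The steady solution conserves oxygen to machine precision.

The other examples follow the same pattern: `examples/oxygen_design.py`
(closed-form sizing chain, reproducing the 156 mmHg surface requirement),
`examples/spike_classification.py` (Type I/III typing from synthetic PSTHs)
and `examples/viability_timecourse.py` (a ~15 Hz plateau collapsing after
55 min, with the change point recovered at 57 min, one block later).

A thin CLI wraps the same functions:

```bash
mtmkit scenarios --out scenarios/
mtmkit simulate --scenario scenarios/mtm_default.yaml --out out/
mtmkit synth --cell-type III --n-blocks 24 --seed 1 --out spikes.tsv
mtmkit timecourse --spikes spikes.tsv --n-blocks 24
```

## Layout

```
src/mtmkit/
  params.py    physical constants, Henry/flow conversions, config I/O
  mea.py       hole layouts, open-area ratios, homogenized conductance
  core.py      closed-form design equations + consuming-slab oracle
  solver.py    finite-volume transport solver (1D film model, 2D mode)
  spikes.py    detection, PSTH/raster, response typing, viability
  synth.py     seeded synthetic sessions and scenario configs
  pipeline.py  scenario runner, end-to-end pipeline, run manifest
  cli.py       thin click CLI over the above
docs/methods.md  model assumptions, parameter choices, limitations
```
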