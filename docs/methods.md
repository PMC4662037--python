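# Methods

This note records the models behind `mtmkit`, the parameter choices that
matter, and what the synthetic tests do and do not demonstrate.

## Unit convention

Lengths in cm, time in minutes, tension in mmHg, oxygen amounts in ml O₂.
The literature states both the retinal consumption rate
(Q_NR = 3.5 ml O₂/(100 g·min)) and the Krogh diffusion coefficient
(D·k = 2.84 × 10⁻⁶) with a per-100 g normalization; with tissue density taken
as 1 g/cm³ the normalization cancels in every ratio the models use (required
gradients, slab profiles, conductances), so both constants are kept in their
printed forms and never mixed with per-cm³ quantities. The printed unit
string for D·k ("ml cm²/(100 g min mmHg)") is not dimensionally consistent
with a flux law as written; we read it as ml O₂ cm⁻¹ min⁻¹ mmHg⁻¹ per 100 g,
the only reading under which the published 156 mmHg surface-tension
requirement follows from the balance equation.

Two Henry-type coefficients exist and are deliberately kept apart: `dk`
(tissue/fluid Krogh coefficient, drives fluxes) and `k_h`
(medium solubility, 3.09 × 10⁻⁵ mg ml⁻¹ mmHg⁻¹ at 37 °C, converts
dissolved-oxygen readings to tension). They are never substituted for one
another.

## Oxygen transport model

**Stack.** Upper perfused chamber (2.5 mm), stimulation MEA (20 µm), outer
retina (85 µm), inner retina (85 µm), recording MEA (20 µm), lower chamber
(2.5 mm). Perforated arrays are homogenized into effective conductance
layers with diffusivity `OAR_eff · dk_fluid`: resolving thousands of
10–100 µm holes in a mm-scale chamber would add nothing at the axis where
the check points sit, and the published balance equation is itself
OAR-homogenized. The three fabricated hole regions (10/50/100 µm at
10/20/20 % OAR) enter through their area-weighted average; the region
footprint areas are not published, so the concentric area fractions
(11 % / 25 % / 64 % of the 1 mm window) were solved once so that the average
equals the published 18.9 % whole-surface figure.

**Fluid side.** The default 1D axial model treats the perfused bulk as well
mixed at the inlet tension (583 mmHg from the 18 mg/l reading; supply at
100 ml/h exceeds total tissue consumption by ~4000×, so depletion of the
bulk is negligible) separated from each array by a stagnant diffusion film.
The film thickness defaults to 0.3 mm — the platform's own reported extent
of the near-MEA gradient zone — and is a config value. Flow runs transverse
to the solved axis, so the 1D model carries no advection term; the mean
velocity (100 ml/h over a 0.25 cm² section → 6.67 cm/min) is reported as
field metadata. The optional 2D plane-symmetric mode drops the film and
resolves the streamwise direction instead: upwind advection with a plug or
plane-Poiseuille profile, molecular O₂ diffusivity of the medium
(1.8 × 10⁻³ cm²/min) splitting `dk_fluid` into diffusivity × solubility for
the advective flux, inlet Dirichlet at x = 0 and advective outflow at the
far end. The concentration boundary layer then develops from the flow
itself.

**Tissue.** Zero-order consumption Q_NR in the retina, zero elsewhere. The
governing transport-reaction equation is implemented with consumption as a
sink (a source sign would violate conservation), and no extra prefactor on
the diffusion term: dual-surface supply is carried explicitly by the
geometry, not by a factor inside the operator. Because a constant sink can
drive tension negative in starved configurations, consumption ramps linearly
to zero below P_crit = 2 mmHg. This clamp is inactive in the default
scenario (minimum tension ≈ 105 mmHg) and exists for the low-OAR and
single-sided sweeps.

**Discretization.** Cell-centered finite volumes; harmonic-mean interface
conductances; per-layer grids (2.5 µm targets in MEA/retina, 20 µm in
fluid, ~336 cells for the default stack); sparse direct solves. The clamp is
handled by an active-set iteration: cells below P_crit move their (linear in
P) sink onto the matrix diagonal, which keeps the operator an M-matrix, so
the solution stays non-negative by construction; iteration stops when the
active set is stable and the relative step is below 10⁻⁸ (cap 200). Face
tensions at material interfaces are reconstructed flux-continuously for
check-point extraction. Verified properties: ≤ 0.5 % error against the
closed-form consuming slab at 200 nodes with second-order grid convergence,
and global conservation (sink = boundary influx) at machine precision.

**Check points.** P_SMEA at the fluid-side face of the supply array, P_SR at
its tissue-side face, P_IR at the retina mid-plane, compared against the
requirements (156 / 45 / 17.4 mmHg). The default scenario yields
≈ (260, 150, 105) mmHg: all requirements pass. The first two agree with the
published simulation values (244, 144) to ~10 %; the mid-retina value does
not reproduce the published 37 mmHg and cannot under the published
constants — with dual-sided supply the center-to-surface drop is pinned at
Q_NR·L²/(8·D·k) ≈ 44.5 mmHg, whereas the published (144, 37) pair implies a
107 mmHg drop. We follow the printed constants rather than invent a lower
tissue diffusivity to match the figure, and flag the discrepancy rather than
hide it.

## Spike pipeline

**Detection** is negative-going threshold crossing at 4.5 × a
median-absolute-deviation noise estimate (falling back to half the peak
excursion on noiseless traces), timestamped at the trough within 0.5 ms of
the crossing, with a 1 ms refractory enforced on trough times (one sample of
slack absorbs quantization). No spike sorting is attempted: the platform
analyzes per-electrode responses near single-cell resolution, and multi-unit
separation is out of scope.

**PSTH/raster.** Spikes are aligned to every pulse of the protocol
(1.5 Hz, 5 ms width, 1 min trains in 3 min blocks), binned at 10 ms over the
full 666.7 ms inter-stimulus interval. Spikes inside the stimulus-artifact
window (default = the 5 ms pulse width) are blanked; configurable.

**Typing.** Counts are first normalized to a reference repeat count (20),
which makes the classifier exactly invariant under jointly scaling counts
and repeats; bins are burst candidates when they exceed the Poisson-motivated
baseline + 3·√baseline (baseline = mean of the final quarter of the window)
*and* reach 20 % of the global peak — the prominence filter keeps stray
background coincidences from counting as bursts, without which a few percent
of single-burst sessions sprout spurious second bursts. Contiguous candidate
bins form a burst; two bursts must be separated by at least one sub-threshold
bin. Exactly one burst with onset < 20 ms → Type I; two or three bursts →
Type III; anything else unclassified.

**Viability.** The firing rate of block *b* is the spike count in its
1-minute train window divided by the train duration (the published "~15 Hz"
and "~5 Hz" figures do not state their denominator; we adopt the
train-minute). The decline onset is the start of the first block from which
all later rates stay below 50 % of the plateau median (plateau = blocks
after the first, before the drop), stepped back one block when the preceding
block is itself already more than three robust standard deviations below the
plateau. The back-correction matters: a plateau that starts decaying
mid-block leaves one intermediate-rate block above the 50 % line, and
without the correction the estimate lands a full block late. With it, a
55 min onset with a 5 min decay constant is detected at 57 min — within one
3-minute block — in every seeded trial; an abrupt silence after the first
block is still reported at the second block.

## Synthetic generator

Per stimulus, burst spike counts are Poisson with means scaled so plateau
firing matches the target rate (defaults: Type I one burst at 5 ms,
5 Hz; Type III bursts at 5 and 45 ms with an occasional third burst,
probability 0.15, 15 Hz — the platform's narrative values). Burst onsets get
Gaussian jitter (2 ms); burst spikes are placed inside a 12 ms envelope with
at least the 1 ms refractory between them, so a Type I response stays inside
the 20 ms short-latency window by construction. Background activity is
homogeneous Poisson at 1 Hz. After a configurable onset the per-stimulus
yield decays as exp(−Δt/τ), τ = 5 min by default. Traces render each spike
as a ~0.8 ms biphasic template (short enough that refractory-spaced spikes
remain separable) in Gaussian noise. Identical seeds give bit-identical
outputs.

What this does *not* emulate: overlapping units on one electrode, stimulus
artifacts beyond a blanking window, electrode drift, bursting variability
beyond Poisson counts, or any biophysical membrane dynamics. Passing tests
therefore demonstrate the pipeline's correctness on its stated model — not
robustness to every pathology of real extracellular recordings.

## Problem sizes and determinism

Default runs: ~336 axial cells (1D), 24 × ~130 cells (2D smoke
configurations), 100 sessions per response type for classification, 200
sessions for change-point recovery, 50 rendered traces per detection
condition. All stochastic stages take a single integer seed; the acceptance
script derives its stage seeds from `--seed` and is exactly reproducible.

## Known limitations

* The fluid side of the 1D model stands or falls with the film thickness;
  0.3 mm is adopted from the platform's reported profile, not derived from a
  flow correlation. The 2D mode with the default molecular diffusivity
  develops a thinner (~0.1 mm) boundary layer and accordingly higher
  check-point tensions.
* Regional OARs enter only through their area-weighted mean; the lateral
  variation across the 1 mm window (10 % center vs 20 % annulus) is not
  resolved on the axis.
* Steady state only; no transient start-up mode.
* The mid-retina published value is not reproducible under the published
  constants (see above); the solver makes no attempt to match it.
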