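"""Synthetic recordings and oxygen-scenario configs for end-to-end testing.

The generator emulates the two electrically evoked ganglion-cell response
patterns seen on the platform — Type I (one short-latency burst per
stimulus) and Type III (two, occasionally three, bursts) — driven by the
1.5 Hz / 5 ms pulse protocol delivered in 3-minute blocks, plus the
viability signature: a constant-rate plateau followed by an exponential
decline once the tissue starts failing.  Spike times are exact ground truth;
optionally they are rendered into a noisy voltage trace for the detector.

Everything is seeded: identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InvalidParameterError, params_to_config, PhysicalParams, GeometryParams, CheckpointRequirements
from .spikes import REFRACTORY_MS, SpikeTrain, StimulusProtocol

__all__ = [
    "ResponseModel",
    "NoiseModel",
    "type_i_response",
    "type_iii_response",
    "generate_session",
    "render_trace",
    "default_spike_template",
    "generate_scenarios",
]


@dataclass(frozen=True)
class ResponseModel:
    """Stochastic evoked-response model for one ganglion cell.

    ``burst_latencies_ms`` / ``burst_weights`` describe the obligatory bursts
    (one for Type I, two for Type III); an optional third burst fires with
    probability ``third_burst_prob`` at ``third_burst_latency_ms``.  Expected
    evoked spikes per stimulus are scaled so the train-minute firing rate on
    the plateau equals ``plateau_rate_hz``.  After ``decline_onset_min`` the
    per-stimulus yield decays as exp(-(t - onset)/tau).
    """

    cell_type: str  # 'I' | 'III'
    burst_latencies_ms: tuple[float, ...]
    burst_weights: tuple[float, ...]
    jitter_sd_ms: float = 2.0
    #: envelope of a single burst; all its spikes fall within this many ms of
    #: the (jittered) burst onset, so Type I responses stay inside the 20 ms
    #: short-latency window by construction
    burst_duration_ms: float = 12.0
    baseline_rate_hz: float = 1.0
    plateau_rate_hz: float = 15.0
    decline_onset_min: float | None = None
    decline_tau_min: float = 5.0
    third_burst_prob: float = 0.0
    third_burst_latency_ms: float = 85.0

    def __post_init__(self) -> None:
        if self.cell_type not in ("I", "III"):
            raise InvalidParameterError("cell_type must be 'I' or 'III'")
        n = len(self.burst_latencies_ms)
        if self.cell_type == "I":
            if n != 1 or self.burst_latencies_ms[0] >= 20.0:
                raise InvalidParameterError(
                    "Type I has a single burst with latency < 20 ms"
                )
        else:
            if n not in (2, 3):
                raise InvalidParameterError("Type III has two or three bursts")
        if len(self.burst_weights) != n:
            raise InvalidParameterError("one weight per burst required")
        for r in (self.baseline_rate_hz, self.plateau_rate_hz):
            if r < 0:
                raise InvalidParameterError("rates must be non-negative")
        if not 0 <= self.third_burst_prob <= 1:
            raise InvalidParameterError("third_burst_prob must be in [0, 1]")

    def mean_spikes_per_stimulus(self, pulse_rate_hz: float) -> float:
        return self.plateau_rate_hz / pulse_rate_hz


def type_i_response(plateau_rate_hz: float = 5.0, **kwargs) -> ResponseModel:
    """Default Type I cell: one burst at 5 ms, ~5 Hz plateau firing."""
    return ResponseModel(
        cell_type="I",
        burst_latencies_ms=(5.0,),
        burst_weights=(1.0,),
        plateau_rate_hz=plateau_rate_hz,
        **kwargs,
    )


def type_iii_response(plateau_rate_hz: float = 15.0, **kwargs) -> ResponseModel:
    """Default Type III cell: bursts at 5 and 45 ms, occasional third burst
    (probability 0.15), ~15 Hz plateau firing."""
    kwargs.setdefault("third_burst_prob", 0.15)
    return ResponseModel(
        cell_type="III",
        burst_latencies_ms=(5.0, 45.0),
        burst_weights=(1.0, 1.0),
        plateau_rate_hz=plateau_rate_hz,
        **kwargs,
    )


def default_spike_template(sampling_rate_khz: float = 25.0) -> np.ndarray:
    """A biphasic extracellular spike waveform, ~0.8 ms, unit negative peak.

    Short enough that spikes separated by the 1 ms refractory floor remain
    individually resolvable by threshold crossing.
    """
    t = np.arange(int(round(0.8 * sampling_rate_khz))) / sampling_rate_khz  # ms
    wave = -np.exp(-(((t - 0.2) / 0.08) ** 2)) + 0.3 * np.exp(
        -(((t - 0.42) / 0.12) ** 2)
    )
    return wave / np.abs(wave).max()


@dataclass(frozen=True)
class NoiseModel:
    """Recording-noise and waveform model for trace rendering."""

    noise_sd: float = 0.1
    spike_amplitude: float = 1.0
    sampling_rate_khz: float = 25.0
    seed: int = 0
    spike_template: np.ndarray | None = None

    def template(self) -> np.ndarray:
        if self.spike_template is not None:
            return np.asarray(self.spike_template, dtype=float)
        return default_spike_template(self.sampling_rate_khz)


def _draw_burst_times(
    rng: np.random.Generator,
    t_stim: float,
    latency_ms: float,
    n_spikes: int,
    jitter_sd_ms: float,
    duration_ms: float,
) -> np.ndarray:
    """Spike times of one burst.

    The burst onset gets Gaussian jitter; its spikes are then placed inside a
    fixed envelope of ``duration_ms`` with at least the refractory interval
    between them (sorted uniforms plus minimum gaps), which bounds the burst
    extent deterministically.  Spike counts above the envelope capacity are
    truncated to it.
    """
    if n_spikes <= 0:
        return np.empty(0)
    n_spikes = min(n_spikes, int(duration_ms // REFRACTORY_MS))
    onset = t_stim + latency_ms + rng.normal(0.0, jitter_sd_ms)
    if n_spikes == 1:
        return np.array([onset])
    slack = duration_ms - (n_spikes - 1) * REFRACTORY_MS
    offsets = np.sort(rng.uniform(0.0, slack, size=n_spikes - 1))
    offsets += np.arange(1, n_spikes) * REFRACTORY_MS
    return onset + np.concatenate(([0.0], offsets))


def generate_session(
    response: ResponseModel,
    protocol: StimulusProtocol,
    noise: NoiseModel | None = None,
    *,
    seed: int | None = None,
    channel: str = "ch0",
    render: bool = False,
) -> tuple[SpikeTrain, np.ndarray | None]:
    """Simulate one recording session; returns ground truth and optional trace.

    Per stimulus, burst spike counts are Poisson with means set by the burst
    weights (normalized so plateau firing matches ``plateau_rate_hz``),
    scaled by the viability multiplier exp(-(t - onset)/tau) after the
    decline onset; spike times get Gaussian latency jitter and
    refractory-floored intra-burst intervals.  Background activity is a
    homogeneous Poisson process at ``baseline_rate_hz``.  The global 1 ms
    refractory floor is enforced on the merged train.  With ``render=True``
    the train is drawn as spike templates in Gaussian noise.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    session_ms = protocol.session_length_ms
    stim_times = protocol.stimulus_times_ms()

    weights = np.asarray(response.burst_weights, dtype=float)
    lat = list(response.burst_latencies_ms)
    if response.third_burst_prob > 0 and len(lat) == 2:
        weights = np.append(weights, 0.4 * weights.mean())
        lat = lat + [response.third_burst_latency_ms]
    mean_total = response.mean_spikes_per_stimulus(protocol.pulse_rate_hz)
    # obligatory bursts carry the plateau rate; the occasional burst adds on top
    n_oblig = len(response.burst_latencies_ms)
    means = weights / weights[:n_oblig].sum() * mean_total

    times = []
    for t0 in stim_times:
        t_min = t0 / 60_000.0
        mult = 1.0
        if response.decline_onset_min is not None and t_min >= response.decline_onset_min:
            mult = float(
                np.exp(-(t_min - response.decline_onset_min) / response.decline_tau_min)
            )
        for k, latency in enumerate(lat):
            is_occasional = k >= n_oblig
            if is_occasional and rng.random() >= response.third_burst_prob:
                continue
            n_sp = rng.poisson(means[k] * mult)
            times.append(
                _draw_burst_times(
                    rng, t0, latency, n_sp, response.jitter_sd_ms,
                    response.burst_duration_ms,
                )
            )

    if response.baseline_rate_hz > 0:
        n_bg = rng.poisson(response.baseline_rate_hz * session_ms / 1000.0)
        times.append(rng.uniform(0.0, session_ms, size=n_bg))

    all_times = np.sort(np.concatenate(times)) if times else np.empty(0)
    all_times = all_times[(all_times >= 0) & (all_times < session_ms)]
    # enforce the refractory floor on the merged train
    kept = []
    last = -np.inf
    for t in all_times:
        if t - last >= REFRACTORY_MS:
            kept.append(t)
            last = t
    train = SpikeTrain(channel, np.asarray(kept), session_ms)

    trace = render_trace(train, noise, rng) if render else None
    return train, trace


def render_trace(
    train: SpikeTrain, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Render a spike train as templates in Gaussian noise.

    Each ground-truth timestamp is placed at the template's negative peak, so
    detector timestamps are directly comparable to the truth.
    """
    fs = noise.sampling_rate_khz
    n = int(round(train.session_length_ms * fs))
    trace = rng.normal(0.0, noise.noise_sd, size=n) if noise.noise_sd > 0 else np.zeros(n)
    template = noise.template() * noise.spike_amplitude
    peak_offset = int(np.argmin(template))
    for t in train.timestamps_ms:
        start = int(round(t * fs)) - peak_offset
        a = max(start, 0)
        b = min(start + template.size, n)
        if b > a:
            trace[a:b] += template[a - start : b - start]
    return trace


# ---------------------------------------------------------------------------
# oxygen scenario configs
# ---------------------------------------------------------------------------


def generate_scenarios() -> dict[str, dict]:
    """Complete solver configs for the standard scenario battery.

    Emits the default sandwich scenario, a single-sided supply variant, a
    uniform-OAR sweep (1-30%), and the bare consuming-slab oracle case.
    Each value is a flat config dict consumable by the pipeline runner.
    """
    base = params_to_config(PhysicalParams(), GeometryParams(), CheckpointRequirements())
    base.update(
        {
            "inlet_o2_mg_per_l": 18.0,
            "mode": "1d",
            "fluid_model": "film",
            "film_thickness_mm": 0.3,
            "grid_refine": 1.0,
        }
    )

    scenarios: dict[str, dict] = {}
    cfg = dict(base)
    cfg.update({"scenario": "mtm_default", "stack": "mtm", "mea_design": "default"})
    scenarios["mtm_default"] = cfg

    cfg = dict(base)
    cfg.update({"scenario": "single_mea", "stack": "single_mea", "mea_design": "default"})
    scenarios["single_mea"] = cfg

    for oar in (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30):
        cfg = dict(base)
        cfg.update(
            {
                "scenario": f"oar_sweep_{oar:.2f}",
                "stack": "mtm",
                "mea_design": "uniform",
                "mea_uniform_oar": oar,
            }
        )
        scenarios[cfg["scenario"]] = cfg

    cfg = dict(base)
    cfg.update(
        {
            "scenario": "slab_oracle",
            "stack": "slab",
            "slab_length_um": 170.0,
            "slab_p_left_mmHg": 100.0,
            "slab_p_right_mmHg": 100.0,
            "slab_n_cells": 400,
        }
    )
    scenarios["slab_oracle"] = cfg
    return scenarios
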