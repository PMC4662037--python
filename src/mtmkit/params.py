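"""Physical constants, geometry and unit-safe conversions.

Internal unit convention (used throughout the package):

* length: cm (config keys may use um / mm and are converted on load)
* time: min
* oxygen amount: ml O2 (volume at standard conditions)
* tension (partial pressure): mmHg
* mass: the literature normalizes tissue quantities "per 100 g"; with tissue
  density taken as 1 g/cm^3 this normalization cancels between the consumption
  rate ``q_nr`` and the Krogh diffusion coefficient ``dk`` as long as both are
  kept in their printed per-100 g forms.  The package keeps them that way and
  never mixes them with per-cm^3 quantities.

Two Henry-type coefficients appear in the field and must not be confused:

``dk``
    The Krogh diffusion coefficient of tissue/fluid, the product of the oxygen
    diffusion constant and the solubility, in
    ml O2 cm^-1 min^-1 mmHg^-1 (per 100 g).  It converts a tension gradient
    into an oxygen flux (Fick's law).
``k_h``
    The Henry solubility of the perfusion medium at 37 degC, in
    mg ml^-1 mmHg^-1.  It converts a dissolved-oxygen concentration reading
    (mg/ml) into a tension (mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = [
    "PhysicalParams",
    "GeometryParams",
    "CheckpointRequirements",
    "henry_tension",
    "tension_to_concentration",
    "convert_flow",
    "load_config",
    "save_config",
]


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (sign/range)."""


@dataclass(frozen=True)
class PhysicalParams:
    """Transport and consumption constants of the perfused retina chamber.

    Defaults are the dark-adapted mammalian retina values used throughout the
    platform design: ``dk = 2.84e-6`` ml O2 cm^-1 min^-1 mmHg^-1 (per 100 g),
    ``k_h = 3.09e-5`` mg ml^-1 mmHg^-1 at 37 degC, ``q_nr = 3.5``
    ml O2/(100 g min), perfusion ``flow_rate = 100`` ml/h.
    """

    dk: float = 2.84e-6
    k_h: float = 3.09e-5
    q_nr: float = 3.5
    flow_rate: float = 100.0
    temperature: float = 37.0
    #: Krogh coefficient of the perfusion fluid; defaults to ``dk`` (the paper
    #: uses a single coefficient for both phases).
    dk_fluid: float | None = None

    def __post_init__(self) -> None:
        for name in ("dk", "k_h", "q_nr", "flow_rate", "temperature"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.dk_fluid is not None and not self.dk_fluid > 0:
            raise InvalidParameterError("dk_fluid must be strictly positive")

    @property
    def dk_fluid_effective(self) -> float:
        return self.dk if self.dk_fluid is None else self.dk_fluid


@dataclass(frozen=True)
class GeometryParams:
    """Chamber / MEA / retina stack dimensions.

    ``half_retina_um`` is derived: the inner and outer retina are each half of
    the full thickness (85 um of a 170 um retina by default).
    """

    retina_thickness_um: float = 170.0
    mea_thickness_um: float = 20.0
    chamber_height_mm: float = 2.5
    window_diameter_mm: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "retina_thickness_um",
            "mea_thickness_um",
            "chamber_height_mm",
            "window_diameter_mm",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    @property
    def half_retina_um(self) -> float:
        return self.retina_thickness_um / 2.0

    # convenience cm accessors used by the solver
    @property
    def retina_thickness_cm(self) -> float:
        return self.retina_thickness_um * 1e-4

    @property
    def mea_thickness_cm(self) -> float:
        return self.mea_thickness_um * 1e-4

    @property
    def chamber_height_cm(self) -> float:
        return self.chamber_height_mm * 0.1

    @property
    def window_area_cm2(self) -> float:
        import math

        r = self.window_diameter_mm * 0.1 / 2.0
        return math.pi * r * r


@dataclass(frozen=True)
class CheckpointRequirements:
    """Minimum oxygen tensions at the three design check points (mmHg).

    Check point 1: outer surface of the MEA (``p_smea_req``, hyperoxic-medium
    target).  Check point 2: MEA-retina interface (``p_sr_req``, the arterial
    tension below which ganglion-cell firing degrades).  Check point 3: retina
    mid-plane (``p_ir_req``, the dark-adapted minimum measured in rat retina).
    """

    p_smea_req: float = 156.0
    p_sr_req: float = 45.0
    p_ir_req: float = 17.4

    def __post_init__(self) -> None:
        if not (self.p_smea_req > self.p_sr_req > self.p_ir_req > 0):
            raise InvalidParameterError(
                "requirements must satisfy p_smea_req > p_sr_req > p_ir_req > 0"
            )


def henry_tension(concentration: float, k_h: float) -> float:
    """Convert dissolved O2 concentration (mg/ml) to tension (mmHg).

    Henry's law: ``p = c / k_h`` with ``k_h`` in mg ml^-1 mmHg^-1.
    The default medium coefficient at 37 degC converts the 18 mg/l inlet
    reading to ~583 mmHg.
    """
    if not k_h > 0:
        raise InvalidParameterError("k_h must be strictly positive")
    if concentration < 0:
        raise InvalidParameterError("concentration must be non-negative")
    return concentration / k_h


def tension_to_concentration(tension: float, k_h: float) -> float:
    """Inverse of :func:`henry_tension`: tension (mmHg) to mg/ml."""
    if not k_h > 0:
        raise InvalidParameterError("k_h must be strictly positive")
    if tension < 0:
        raise InvalidParameterError("tension must be non-negative")
    return tension * k_h


def convert_flow(flow_rate_ml_per_h: float, cross_section_cm2: float) -> float:
    """Mean flow velocity (cm/min) from a volume rate (ml/h) and section (cm^2)."""
    if not cross_section_cm2 > 0:
        raise InvalidParameterError("cross_section must be strictly positive")
    if flow_rate_ml_per_h < 0:
        raise InvalidParameterError("flow_rate must be non-negative")
    return flow_rate_ml_per_h / 60.0 / cross_section_cm2


# ---------------------------------------------------------------------------
# flat key:value config files
# ---------------------------------------------------------------------------

_PHYS_KEYS = {
    "dk_ml_per_cm_min_mmHg": "dk",
    "k_h_mg_per_ml_mmHg": "k_h",
    "q_nr_ml_per_100g_min": "q_nr",
    "flow_rate_ml_per_h": "flow_rate",
    "temperature_c": "temperature",
    "dk_fluid_ml_per_cm_min_mmHg": "dk_fluid",
}

_GEOM_KEYS = {
    "retina_thickness_um": "retina_thickness_um",
    "mea_thickness_um": "mea_thickness_um",
    "chamber_height_mm": "chamber_height_mm",
    "window_diameter_mm": "window_diameter_mm",
}

_REQ_KEYS = {
    "p_smea_req_mmHg": "p_smea_req",
    "p_sr_req_mmHg": "p_sr_req",
    "p_ir_req_mmHg": "p_ir_req",
}


def load_config(path: str | Path) -> dict:
    """Read a flat key:value YAML config file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidParameterError(f"config {path} is not a flat mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    """Write a flat config dict as YAML (sorted keys, round-trip stable)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)


def _from_config(cls, keymap: dict[str, str], cfg: dict):
    kwargs = {attr: cfg[key] for key, attr in keymap.items() if key in cfg}
    return cls(**kwargs)


def physical_params_from_config(cfg: dict) -> PhysicalParams:
    return _from_config(PhysicalParams, _PHYS_KEYS, cfg)


def geometry_params_from_config(cfg: dict) -> GeometryParams:
    return _from_config(GeometryParams, _GEOM_KEYS, cfg)


def requirements_from_config(cfg: dict) -> CheckpointRequirements:
    return _from_config(CheckpointRequirements, _REQ_KEYS, cfg)


def params_to_config(
    phys: PhysicalParams | None = None,
    geom: GeometryParams | None = None,
    reqs: CheckpointRequirements | None = None,
) -> dict:
    """Serialize parameter objects into the flat config key space."""
    cfg: dict = {}
    for obj, keymap in ((phys, _PHYS_KEYS), (geom, _GEOM_KEYS), (reqs, _REQ_KEYS)):
        if obj is None:
            continue
        values = asdict(obj)
        for key, attr in keymap.items():
            if values.get(attr) is not None:
                cfg[key] = values[attr]
    return cfg
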