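"""Closed-form oxygen design equations and the consuming-slab solution.

These are the back-of-envelope relations used to size the perforated MEA
before any numerical simulation, plus the exact steady profile of a uniformly
consuming slab, which doubles as the analytic oracle for the numerical solver:

* Fick's law for the diffusive flux across a tension gradient,
* the consumption-flux balance that fixes the gradient a retina of given
  thickness demands through perforated surfaces of given OAR,
* the thin-MEA gradient approximation converting that gradient into a
  required tension step across the array,
* the quadratic steady profile of a slab with zero-order consumption and
  Dirichlet faces.

Units follow the package convention (cm, min, mmHg, ml O2 per 100 g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InvalidParameterError

__all__ = [
    "SlabProblem",
    "fick_flux",
    "required_gradient",
    "required_surface_tension",
    "slab_profile",
    "slab_min",
]


class InfeasibleDesignError(ValueError):
    """A design parameter makes the required supply impossible (e.g. OAR 0)."""


@dataclass(frozen=True)
class SlabProblem:
    """Steady 1D slab with zero-order consumption and fixed face tensions.

    ``q`` is the volumetric consumption in ml O2 (100 g)^-1 min^-1 scaled by
    tissue density 1 g/cm^3; ``dk`` the matching Krogh coefficient.
    """

    length_cm: float
    p_left: float
    p_right: float
    q: float
    dk: float

    def __post_init__(self) -> None:
        if not self.length_cm > 0:
            raise InvalidParameterError("slab length must be positive")
        if not self.dk > 0:
            raise InvalidParameterError("dk must be positive")
        if self.q < 0:
            raise InvalidParameterError("consumption q must be non-negative")
        if self.p_left < 0 or self.p_right < 0:
            raise InvalidParameterError("boundary tensions must be non-negative")


def fick_flux(dk: float, dPdz: float) -> float:
    """Diffusive oxygen flux J = dk * dP/dz (signed), Fick's first law."""
    if not dk > 0:
        raise InvalidParameterError("dk must be positive")
    return dk * dPdz


def required_gradient(
    q_nr: float,
    tissue_thickness_cm: float,
    oar: float,
    dk: float = 2.84e-6,
    n_surfaces: int = 2,
) -> float:
    """Tension gradient (mmHg/cm) needed to feed a consuming tissue slab.

    Balance of total consumption against flux through the perforated supply
    surfaces: q_nr * A * L = dk * (dP/dz) * n_surfaces * A * OAR, with the
    footprint A cancelling.  ``n_surfaces`` is 1 for single-sided supply and
    2 for the sandwich's dual supply.
    """
    if n_surfaces not in (1, 2):
        raise InvalidParameterError("n_surfaces must be 1 or 2")
    if q_nr < 0:
        raise InvalidParameterError("q_nr must be non-negative")
    if not tissue_thickness_cm > 0:
        raise InvalidParameterError("tissue thickness must be positive")
    if not dk > 0:
        raise InvalidParameterError("dk must be positive")
    if not oar > 0:
        raise InfeasibleDesignError("OAR of 0 blocks all supply (infeasible)")
    return q_nr * tissue_thickness_cm / (dk * n_surfaces * oar)


def required_surface_tension(
    p_sr: float, dPdz: float, mea_thickness_cm: float
) -> float:
    """Outer-MEA tension implied by a gradient across a thin MEA.

    Thin-slab approximation dP/dz ~ (P_SMEA - P_SR) / t rearranged to
    P_SMEA = P_SR + dPdz * t.  With the default retina/OAR parameters and
    P_SR = 45 mmHg this reproduces the ~156 mmHg design requirement.
    """
    if not mea_thickness_cm > 0:
        raise InvalidParameterError("mea thickness must be positive")
    if not np.isfinite(p_sr) or not np.isfinite(dPdz):
        raise InvalidParameterError("inputs must be finite")
    return p_sr + dPdz * mea_thickness_cm


def slab_profile(problem: SlabProblem, z) -> np.ndarray | float:
    """Exact steady tension profile of the consuming slab at position(s) z.

    P(z) = p_left + (p_right - p_left) z/L - (q / (2 dk)) z (L - z),
    the solution of dk P'' = q with Dirichlet faces.
    """
    z_arr = np.asarray(z, dtype=float)
    L = problem.length_cm
    if np.any(z_arr < -1e-12 * L) or np.any(z_arr > L * (1 + 1e-12)):
        raise InvalidParameterError("z outside the slab [0, L]")
    p = (
        problem.p_left
        + (problem.p_right - problem.p_left) * z_arr / L
        - (problem.q / (2.0 * problem.dk)) * z_arr * (L - z_arr)
    )
    return p if isinstance(z, np.ndarray) else float(p)


def slab_min(problem: SlabProblem) -> tuple[float, float]:
    """Location and value of the global tension minimum over [0, L].

    The profile is a downward-sagging parabola (or a line for q = 0); the
    minimum is the vertex when it lies inside the slab, else a boundary.
    """
    L = problem.length_cm
    candidates = [0.0, L]
    if problem.q > 0:
        # vertex of the quadratic: P'(z) = 0
        z_star = L / 2.0 - problem.dk * (problem.p_right - problem.p_left) / (
            problem.q * L
        )
        if 0.0 < z_star < L:
            candidates.append(z_star)
    values = [slab_profile(problem, z) for z in candidates]
    i = int(np.argmin(values))
    return candidates[i], values[i]
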