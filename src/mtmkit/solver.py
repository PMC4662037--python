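"""Steady convection-diffusion-reaction solver for the layered MEA chamber.

The chamber is a vertical stack: perfused fluid above, a perforated
stimulation MEA, the retina (outer + inner halves), a perforated recording
MEA, perfused fluid below.  Oxygen enters with the perfusate, diffuses
through the MEA holes (homogenized to an effective conductance layer,
dk_fluid * OAR) and is consumed in the tissue at a constant dark-adapted rate
with a linear shut-off below a critical tension (so deep hypoxia cannot drive
the solution negative).

Two fluid representations are provided:

``film`` (default, 1D axial)
    The perfused bulk is well mixed at the inlet tension; only a stagnant
    diffusion film of configurable thickness (default 0.3 mm, the observed
    extent of the near-MEA gradient zone) separates the bulk from each MEA.
    Bulk cells are pinned to the inlet tension; film, MEA and tissue cells are
    solved by finite volumes.  Flow never crosses the MEAs, so the axial model
    carries no advection term; the transverse mean velocity is reported as
    metadata.

``resolved`` (optional, 2D plane-symmetric)
    The flow direction x is resolved: upwind advection with a plug or
    plane-Poiseuille velocity profile in the fluid layers, diffusion in both
    directions, inlet Dirichlet at x = 0, advective outflow at x = L.  The
    concentration boundary layer over the MEA then develops from the flow
    itself instead of being imposed.

Discretization: cell-centered finite volumes, harmonic-mean interface
conductances, first-order upwind advection, sparse direct solves with Picard
iteration only when the consumption clamp activates (relative tolerance 1e-8,
cap 200 iterations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import SlabProblem
from .mea import MEADesign, effective_oar
from .params import (
    CheckpointRequirements,
    GeometryParams,
    InvalidParameterError,
    PhysicalParams,
    convert_flow,
)

__all__ = [
    "Layer",
    "StackGeometry",
    "OxygenField",
    "CheckpointReport",
    "paper_stack",
    "single_mea_stack",
    "build_stack",
    "build_slab_problem",
    "velocity_profile",
    "solve_steady",
    "conservation_error",
    "extract_checkpoints",
    "axial_profile",
    "iso_crossings",
    "solve_steady_2d",
]

MATERIALS = ("fluid", "mea", "retina")

#: default grid targets per material, cm
_DZ_TARGET = {"fluid": 20e-4, "mea": 2.5e-4, "retina": 2.5e-4}
_MIN_CELLS = {"fluid": 6, "mea": 6, "retina": 12}


class ConfigurationError(ValueError):
    """Stack geometry and MEA designs are inconsistent."""


class SolverError(RuntimeError):
    """The nonlinear iteration failed to converge."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass(frozen=True)
class Layer:
    name: str
    thickness_cm: float
    material: str

    def __post_init__(self) -> None:
        if not self.thickness_cm > 0:
            raise ConfigurationError(f"layer {self.name}: thickness must be positive")
        if self.material not in MATERIALS:
            raise ConfigurationError(f"layer {self.name}: unknown material {self.material!r}")


@dataclass(frozen=True)
class StackGeometry:
    """Ordered layer stack (top to bottom) plus lateral extent."""

    layers: tuple[Layer, ...]
    lateral_extent_cm: float = 1.0
    symmetry: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ConfigurationError("stack needs at least one layer")
        # exactly one contiguous retina block
        mats = [lay.material for lay in self.layers]
        in_block, n_blocks = False, 0
        for m in mats:
            if m == "retina" and not in_block:
                n_blocks += 1
                in_block = True
            elif m != "retina":
                in_block = False
        if n_blocks > 1:
            raise ConfigurationError("retina layers must form one contiguous block")


def paper_stack(geom: GeometryParams | None = None) -> StackGeometry:
    """The sandwich scenario: fluid / sMEA / outer+inner retina / rMEA / fluid."""
    geom = geom or GeometryParams()
    half = geom.retina_thickness_cm / 2.0
    layers = (
        Layer("upper fluid", geom.chamber_height_cm, "fluid"),
        Layer("sMEA", geom.mea_thickness_cm, "mea"),
        Layer("outer retina", half, "retina"),
        Layer("inner retina", half, "retina"),
        Layer("rMEA", geom.mea_thickness_cm, "mea"),
        Layer("lower fluid", geom.chamber_height_cm, "fluid"),
    )
    return StackGeometry(layers=layers)


def single_mea_stack(geom: GeometryParams | None = None) -> StackGeometry:
    """Single-sided supply: sealed top, retina on one perforated MEA."""
    geom = geom or GeometryParams()
    half = geom.retina_thickness_cm / 2.0
    layers = (
        Layer("outer retina", half, "retina"),
        Layer("inner retina", half, "retina"),
        Layer("rMEA", geom.mea_thickness_cm, "mea"),
        Layer("lower fluid", geom.chamber_height_cm, "fluid"),
    )
    return StackGeometry(layers=layers)


@dataclass
class Problem1D:
    """Discretized axial problem (cell-centered grid over the stack)."""

    z_faces: np.ndarray
    z_centers: np.ndarray
    h: np.ndarray
    dk: np.ndarray
    q: np.ndarray
    material: np.ndarray  # str per cell
    mixed: np.ndarray  # bool per cell: pinned to bulk tension
    velocity: np.ndarray  # transverse speed, cm/min, fluid cells only
    p_top: float | None  # Dirichlet at top face (None = no-flux)
    p_bottom: float | None
    p_bulk: float
    p_crit: float
    layer_bounds: list[tuple[str, str, float, float]]  # (name, material, z0, z1)

    @property
    def n_cells(self) -> int:
        return self.z_centers.size


@dataclass
class OxygenField:
    """Solved tension field on the axial grid."""

    problem: Problem1D
    tension: np.ndarray
    q_eff: np.ndarray
    residual_history: list[float] = field(default_factory=list)

    @property
    def z_centers(self) -> np.ndarray:
        return self.problem.z_centers

    @property
    def velocity(self) -> np.ndarray:
        return self.problem.velocity


@dataclass
class CheckpointReport:
    """Simulated tensions at the three design check points vs requirements."""

    p_smea: float
    p_sr: float
    p_ir: float
    requirements: CheckpointRequirements
    pass_flags: tuple[bool, bool, bool]

    def to_frame(self) -> pd.DataFrame:
        req = self.requirements
        return pd.DataFrame(
            {
                "checkpoint": [
                    "1 (outer MEA surface)",
                    "2 (retina-MEA interface)",
                    "3 (retina mid-plane)",
                ],
                "required_mmHg": [req.p_smea_req, req.p_sr_req, req.p_ir_req],
                "simulated_mmHg": [self.p_smea, self.p_sr, self.p_ir],
                "pass": list(self.pass_flags),
            }
        )

    @property
    def all_pass(self) -> bool:
        return all(self.pass_flags)


# ---------------------------------------------------------------------------
# grid and problem assembly
# ---------------------------------------------------------------------------


def _layer_grid(stack: StackGeometry, grid_refine: float) -> tuple[np.ndarray, list[int]]:
    """Face coordinates for the whole stack; cells per layer."""
    faces = [0.0]
    counts = []
    z = 0.0
    for lay in stack.layers:
        n = max(
            _MIN_CELLS[lay.material],
            int(math.ceil(lay.thickness_cm / _DZ_TARGET[lay.material] * grid_refine)),
        )
        # even cell count keeps layer midplanes on faces
        n += n % 2
        counts.append(n)
        edges = z + np.linspace(0.0, lay.thickness_cm, n + 1)[1:]
        faces.extend(edges.tolist())
        z += lay.thickness_cm
    return np.asarray(faces), counts


def build_stack(
    stack: StackGeometry,
    designs: list[MEADesign],
    params: PhysicalParams | None = None,
    *,
    inlet_tension: float | None = None,
    fluid_model: str = "film",
    film_thickness_cm: float = 0.03,
    grid_refine: float = 1.0,
    p_crit: float = 2.0,
) -> Problem1D:
    """Assemble the discretized axial problem from geometry + MEA designs.

    ``designs`` must provide one :class:`MEADesign` per ``mea`` layer, in
    stack order; each MEA becomes a conductance layer with diffusivity
    ``effective_oar * dk_fluid``.  ``inlet_tension`` defaults to the Henry
    conversion of the 18 mg/l inlet reading (~583 mmHg).
    """
    params = params or PhysicalParams()
    if inlet_tension is None:
        from .params import henry_tension

        inlet_tension = henry_tension(0.018, params.k_h)
    n_mea = sum(1 for lay in stack.layers if lay.material == "mea")
    if n_mea != len(designs):
        raise ConfigurationError(
            f"stack has {n_mea} MEA layer(s) but {len(designs)} design(s) given"
        )
    if fluid_model not in ("film", "resolved"):
        raise ConfigurationError(f"unknown fluid model {fluid_model!r}")

    faces, counts = _layer_grid(stack, grid_refine)
    centers = 0.5 * (faces[:-1] + faces[1:])
    h = np.diff(faces)
    n = centers.size

    dk = np.empty(n)
    q = np.zeros(n)
    material = np.empty(n, dtype=object)
    velocity = np.zeros(n)
    layer_bounds: list[tuple[str, str, float, float]] = []

    u_mean = convert_flow(
        params.flow_rate,
        _flow_cross_section_cm2(stack),
    )

    idx = 0
    mea_iter = iter(designs)
    z0 = 0.0
    for lay, cnt in zip(stack.layers, counts):
        sl = slice(idx, idx + cnt)
        material[sl] = lay.material
        if lay.material == "fluid":
            dk[sl] = params.dk_fluid_effective
            velocity[sl] = u_mean
        elif lay.material == "retina":
            dk[sl] = params.dk
            q[sl] = params.q_nr
        else:  # mea
            design = next(mea_iter)
            dk[sl] = effective_oar(design) * params.dk_fluid_effective
        layer_bounds.append((lay.name, lay.material, z0, z0 + lay.thickness_cm))
        z0 += lay.thickness_cm
        idx += cnt

    # film model: fluid cells farther than the film thickness from the nearest
    # non-fluid material are well mixed (pinned to the bulk/inlet tension)
    mixed = np.zeros(n, dtype=bool)
    if fluid_model == "film":
        non_fluid_faces = [
            b for (_, m, a, b) in layer_bounds if m != "fluid"
        ] + [a for (_, m, a, b) in layer_bounds if m != "fluid"]
        for i in range(n):
            if material[i] != "fluid":
                continue
            if not non_fluid_faces:
                mixed[i] = True
                continue
            dist = min(abs(centers[i] - zf) for zf in non_fluid_faces)
            if dist > film_thickness_cm:
                mixed[i] = True

    # boundary conditions: perfused (fluid) ends are held at the inlet
    # tension; solid ends are no-flux walls
    p_top = inlet_tension if stack.layers[0].material == "fluid" else None
    p_bottom = inlet_tension if stack.layers[-1].material == "fluid" else None

    return Problem1D(
        z_faces=faces,
        z_centers=centers,
        h=h,
        dk=dk,
        q=q,
        material=material,
        mixed=mixed,
        velocity=velocity,
        p_top=p_top,
        p_bottom=p_bottom,
        p_bulk=inlet_tension,
        p_crit=p_crit,
        layer_bounds=layer_bounds,
    )


def _flow_cross_section_cm2(stack: StackGeometry) -> float:
    """Cross-section seen by the perfusate: chamber height x lateral extent."""
    heights = [lay.thickness_cm for lay in stack.layers if lay.material == "fluid"]
    h = max(heights) if heights else 1.0
    return h * stack.lateral_extent_cm


def build_slab_problem(slab: SlabProblem, n_cells: int = 200) -> Problem1D:
    """Discretize a bare consuming slab with Dirichlet faces (oracle case)."""
    faces = np.linspace(0.0, slab.length_cm, n_cells + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    h = np.diff(faces)
    n = centers.size
    return Problem1D(
        z_faces=faces,
        z_centers=centers,
        h=h,
        dk=np.full(n, slab.dk),
        q=np.full(n, slab.q),
        material=np.array(["retina"] * n, dtype=object),
        mixed=np.zeros(n, dtype=bool),
        velocity=np.zeros(n),
        p_top=slab.p_left,
        p_bottom=slab.p_right,
        p_bulk=max(slab.p_left, slab.p_right),
        p_crit=2.0,
        layer_bounds=[("slab", "retina", 0.0, slab.length_cm)],
    )


def velocity_profile(
    flow_rate_ml_per_h: float,
    channel_height_cm: float,
    width_cm: float,
    model: str = "plug",
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Streamwise velocity (cm/min) at heights ``y`` within a channel.

    ``plug``: uniform mean velocity Q/(h w).  ``poiseuille``: plane-Poiseuille
    parabola u(y) = 6 u_mean (y/h)(1 - y/h) with the same mean (peak 1.5x).
    Both integrate to the volume rate.
    """
    if not channel_height_cm > 0 or not width_cm > 0:
        raise InvalidParameterError("channel dimensions must be positive")
    if y is None:
        y = np.linspace(0.0, channel_height_cm, 51)
    y = np.asarray(y, dtype=float)
    u_mean = convert_flow(flow_rate_ml_per_h, channel_height_cm * width_cm)
    if model == "plug":
        return np.full_like(y, u_mean)
    if model == "poiseuille":
        eta = y / channel_height_cm
        return 6.0 * u_mean * eta * (1.0 - eta)
    raise InvalidParameterError(f"unknown velocity model {model!r}")


# ---------------------------------------------------------------------------
# steady solve (1D)
# ---------------------------------------------------------------------------


def _face_conductances(problem: Problem1D) -> tuple[np.ndarray, float, float]:
    """Interior face conductances + Dirichlet half-cell conductances."""
    h, dk = problem.h, problem.dk
    g = 1.0 / (h[:-1] / (2.0 * dk[:-1]) + h[1:] / (2.0 * dk[1:]))
    g_top = 2.0 * dk[0] / h[0]
    g_bot = 2.0 * dk[-1] / h[-1]
    return g, g_top, g_bot


def _clamp_factor(p: np.ndarray, p_crit: float) -> np.ndarray:
    """Consumption multiplier: 1 above p_crit, linear ramp to 0 at 0 mmHg."""
    return np.clip(p / p_crit, 0.0, 1.0)


def _assemble(problem: Problem1D, ramp: np.ndarray):
    """Linear system for the steady state.

    Cells flagged in ``ramp`` are in the hypoxic shut-off regime: there the
    sink q * P / p_crit is linear in P and goes on the matrix diagonal, which
    keeps the operator an M-matrix and the solution non-negative.
    """
    n = problem.n_cells
    g, g_top, g_bot = _face_conductances(problem)
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    b = np.where(ramp, 0.0, -problem.q * problem.h)
    main += np.where(ramp, problem.q * problem.h / problem.p_crit, 0.0)

    main[:-1] += g
    main[1:] += g
    lower -= g
    upper -= g
    if problem.p_top is not None:
        main[0] += g_top
        b[0] += g_top * problem.p_top
    if problem.p_bottom is not None:
        main[-1] += g_bot
        b[-1] += g_bot * problem.p_bottom

    A = sp.diags([lower, main, upper], [-1, 0, 1], format="lil")
    # pinned (well-mixed) cells: identity rows at the bulk tension
    for i in np.flatnonzero(problem.mixed):
        A.rows[i] = [i]
        A.data[i] = [1.0]
        b[i] = problem.p_bulk
    return A.tocsr(), b


def solve_steady(
    problem: Problem1D, tol: float = 1e-8, max_iter: int = 200
) -> OxygenField:
    """Solve the steady problem; Picard iteration only if the clamp engages.

    Raises :class:`SolverError` (with the residual history attached) if the
    nonlinear iteration does not converge within ``max_iter``.
    """
    ramp = np.zeros(problem.n_cells, dtype=bool)
    A, b = _assemble(problem, ramp)
    p = spla.spsolve(A, b)
    history: list[float] = []

    consuming = problem.q > 0
    if np.any(consuming) and p[consuming].min() < problem.p_crit:
        # active-set iteration on the shut-off region: cells below p_crit
        # switch to the linear-in-P sink, cells above switch back
        for _ in range(max_iter):
            ramp_new = consuming & (p < problem.p_crit)
            A, b = _assemble(problem, ramp_new)
            p_new = spla.spsolve(A, b)
            scale = max(np.abs(p_new).max(), 1.0)
            delta = np.abs(p_new - p).max() / scale
            history.append(delta)
            changed = np.any(ramp_new != ramp)
            ramp, p = ramp_new, p_new
            if delta < tol and not changed:
                break
        else:
            raise SolverError("consumption-clamp iteration did not converge", history)
    q_eff = np.where(
        ramp, problem.q * _clamp_factor(p, problem.p_crit), problem.q
    )
    return OxygenField(problem=problem, tension=p, q_eff=q_eff, residual_history=history)


def conservation_error(field: OxygenField) -> float:
    """Relative imbalance between total consumption and net influx.

    The control volume is the set of freely solved cells (film, MEA, tissue);
    influx counts diffusion across Dirichlet boundaries and across faces from
    pinned well-mixed cells (the advective supply in the film model).
    """
    prob = field.problem
    p = field.tension
    g, g_top, g_bot = _face_conductances(prob)
    free = ~prob.mixed

    sink = float(np.sum(field.q_eff[free] * prob.h[free]))
    influx = 0.0
    if prob.p_top is not None and free[0]:
        influx += g_top * (prob.p_top - p[0])
    if prob.p_bottom is not None and free[-1]:
        influx += g_bot * (prob.p_bottom - p[-1])
    for i in range(prob.n_cells - 1):
        if prob.mixed[i] and free[i + 1]:
            influx += g[i] * (p[i] - p[i + 1])
        elif free[i] and prob.mixed[i + 1]:
            influx += g[i] * (p[i + 1] - p[i])
    if sink == 0.0 and abs(influx) < 1e-300:
        return 0.0
    return abs(influx - sink) / max(abs(sink), abs(influx))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def _face_value(field: OxygenField, z: float) -> float:
    """Tension at an arbitrary axial position.

    At faces between cells the flux-continuous reconstruction
    P_f = (a P_i + b P_j)/(a + b) with a = dk_i/h_i, b = dk_j/h_j is used;
    elsewhere linear interpolation between cell centers.
    """
    prob = field.problem
    faces = prob.z_faces
    j = int(np.argmin(np.abs(faces - z)))
    if abs(faces[j] - z) < 1e-12 and 0 < j < faces.size - 1:
        i = j - 1
        a = prob.dk[i] / prob.h[i]
        b = prob.dk[j] / prob.h[j]
        return float((a * field.tension[i] + b * field.tension[j]) / (a + b))
    return float(np.interp(z, prob.z_centers, field.tension))


def extract_checkpoints(
    field: OxygenField,
    reqs: CheckpointRequirements | None = None,
) -> CheckpointReport:
    """Sample the three design check points on the central axis.

    Check point 1: fluid-side face of the supply MEA; check point 2: its
    tissue-side face; check point 3: mid-plane of the retina block.
    """
    reqs = reqs or CheckpointRequirements()
    bounds = field.problem.layer_bounds
    z_min, z_max = field.problem.z_faces[0], field.problem.z_faces[-1]

    mea_layers = [(i, b) for i, b in enumerate(bounds) if b[1] == "mea"]
    retina = [b for b in bounds if b[1] == "retina"]
    if not mea_layers or not retina:
        raise ConfigurationError("checkpoints need at least one MEA and a retina block")

    # supply MEA: the first MEA that touches a fluid layer
    chosen = None
    for i, (name, mat, z0, z1) in mea_layers:
        above = bounds[i - 1][1] if i > 0 else None
        below = bounds[i + 1][1] if i + 1 < len(bounds) else None
        if above == "fluid":
            chosen = (z0, z1)  # fluid side up
            break
        if below == "fluid":
            chosen = (z1, z0)  # fluid side down
            break
    if chosen is None:
        raise ConfigurationError("no MEA adjacent to a fluid layer")
    z_cp1, z_cp2 = chosen
    z_cp3 = 0.5 * (min(b[2] for b in retina) + max(b[3] for b in retina))
    for z in (z_cp1, z_cp2, z_cp3):
        if z < z_min - 1e-12 or z > z_max + 1e-12:
            raise ConfigurationError("checkpoint coordinate outside the grid")

    p_smea = _face_value(field, z_cp1)
    p_sr = _face_value(field, z_cp2)
    p_ir = _face_value(field, z_cp3)
    flags = (p_smea >= reqs.p_smea_req, p_sr >= reqs.p_sr_req, p_ir >= reqs.p_ir_req)
    return CheckpointReport(p_smea, p_sr, p_ir, reqs, flags)


def axial_profile(field: OxygenField) -> pd.DataFrame:
    """Central-axis tension profile as a table (z in cm and mm)."""
    prob = field.problem
    return pd.DataFrame(
        {
            "z_cm": prob.z_centers,
            "z_mm": prob.z_centers * 10.0,
            "tension_mmHg": field.tension,
            "material": prob.material.astype(str),
        }
    )


def iso_crossings(field: OxygenField, levels: np.ndarray | None = None) -> pd.DataFrame:
    """Axial positions where the profile crosses given iso-tension levels.

    Defaults to nine evenly spaced levels spanning 0-634 mmHg (the iso-surface
    scale used to visualize the chamber field).
    """
    if levels is None:
        levels = np.linspace(0.0, 634.0, 9)
    z = field.problem.z_centers
    p = field.tension
    rows = []
    for lev in np.asarray(levels, dtype=float):
        d = p - lev
        sign_change = np.flatnonzero(d[:-1] * d[1:] < 0)
        for i in sign_change:
            frac = d[i] / (d[i] - d[i + 1])
            rows.append((lev, z[i] + frac * (z[i + 1] - z[i])))
        for i in np.flatnonzero(d == 0):
            rows.append((lev, z[i]))
    return pd.DataFrame(rows, columns=["level_mmHg", "z_cm"])


# ---------------------------------------------------------------------------
# optional 2D plane-symmetric mode
# ---------------------------------------------------------------------------


@dataclass
class Field2D:
    """Solved 2D field: x along the flow, z through the stack."""

    x_centers: np.ndarray
    problem: Problem1D  # the axial template (grid, materials, dk, q)
    tension: np.ndarray  # shape (nx, nz)
    velocity: np.ndarray  # u(z) per column cell, cm/min

    def column(self, x: float) -> OxygenField:
        """Axial profile at streamwise position ``x`` as an OxygenField."""
        ix = int(np.argmin(np.abs(self.x_centers - x)))
        return OxygenField(
            problem=self.problem,
            tension=self.tension[ix],
            q_eff=self.problem.q * _clamp_factor(self.tension[ix], self.problem.p_crit),
        )


def solve_steady_2d(
    stack: StackGeometry,
    designs: list[MEADesign],
    params: PhysicalParams | None = None,
    *,
    inlet_tension: float | None = None,
    length_cm: float = 1.0,
    nx: int = 60,
    grid_refine: float = 0.5,
    fluid_diffusivity_cm2_min: float = 1.8e-3,
    velocity_model: str = "plug",
    p_crit: float = 2.0,
) -> Field2D:
    """Plane-symmetric steady solve with resolved streamwise flow.

    The fluid carries oxygen in with the perfusate (upwind advection along x),
    diffusion acts in both directions, the outer z boundaries are walls.
    ``fluid_diffusivity_cm2_min`` is the molecular O2 diffusivity of the
    medium, used to split dk_fluid into diffusivity times solubility for the
    advective flux.
    """
    params = params or PhysicalParams()
    prob = build_stack(
        stack,
        designs,
        params,
        inlet_tension=inlet_tension,
        fluid_model="resolved",
        grid_refine=grid_refine,
        p_crit=p_crit,
    )
    nz = prob.n_cells
    dx = length_cm / nx
    x_centers = (np.arange(nx) + 0.5) * dx

    # per-cell streamwise velocity from the per-layer channel profile
    u = np.zeros(nz)
    for name, mat, z0, z1 in prob.layer_bounds:
        if mat != "fluid":
            continue
        sel = (prob.z_centers >= z0) & (prob.z_centers <= z1)
        y = prob.z_centers[sel] - z0
        u[sel] = velocity_profile(
            params.flow_rate, z1 - z0, 1.0, model=velocity_model, y=y
        )
    k_f = params.dk_fluid_effective / fluid_diffusivity_cm2_min  # solubility
    fluid = prob.material == "fluid"

    g_z, g_top, g_bot = _face_conductances(prob)
    N = nx * nz

    def idx(ix: int, iz: int) -> int:
        return ix * nz + iz

    rows, cols, vals = [], [], []
    b = np.zeros(N)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    def assemble(ramp2d: np.ndarray):
        rows.clear()
        cols.clear()
        vals.clear()
        b[:] = 0.0
        for ix in range(nx):
            for iz in range(nz):
                r = idx(ix, iz)
                if ramp2d[ix, iz]:
                    add(r, r, prob.q[iz] * prob.h[iz] * dx / p_crit)
                else:
                    b[r] -= prob.q[iz] * prob.h[iz] * dx
                # z-diffusion
                if iz > 0:
                    g = g_z[iz - 1] * dx
                    add(r, r, g)
                    add(r, idx(ix, iz - 1), -g)
                if iz < nz - 1:
                    g = g_z[iz] * dx
                    add(r, r, g)
                    add(r, idx(ix, iz + 1), -g)
                # x-diffusion
                gx = prob.dk[iz] / dx * prob.h[iz]
                if ix > 0:
                    add(r, r, gx)
                    add(r, idx(ix - 1, iz), -gx)
                if ix < nx - 1:
                    add(r, r, gx)
                    add(r, idx(ix + 1, iz), -gx)
                # advection (fluid only), first-order upwind, u >= 0
                if fluid[iz] and u[iz] > 0:
                    a = u[iz] * k_f * prob.h[iz]
                    add(r, r, a)  # outflow through the right face
                    if ix > 0:
                        add(r, idx(ix - 1, iz), -a)  # inflow from the left
                    else:
                        b[r] += a * prob.p_bulk  # inlet
                        gx_in = prob.dk[iz] / dx * prob.h[iz] * 2.0
                        add(r, r, gx_in)
                        b[r] += gx_in * prob.p_bulk
        A = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
        return A

    ramp2d = np.zeros((nx, nz), dtype=bool)
    A = assemble(ramp2d)
    p = spla.spsolve(A, b).reshape(nx, nz)
    consuming = prob.q > 0
    if np.any(consuming) and p[:, consuming].min() < p_crit:
        for _ in range(60):
            ramp_new = consuming[None, :] & (p < p_crit)
            A = assemble(ramp_new)
            p_new = spla.spsolve(A, b).reshape(nx, nz)
            delta = np.abs(p_new - p).max() / max(np.abs(p_new).max(), 1.0)
            changed = np.any(ramp_new != ramp2d)
            ramp2d, p = ramp_new, p_new
            if delta < 1e-8 and not changed:
                break
    return Field2D(x_centers=x_centers, problem=prob, tension=p, velocity=u)
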