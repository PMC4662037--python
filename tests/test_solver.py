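"""Tests for the finite-volume transport solver over the layered chamber."""

import numpy as np
import pytest

from mtmkit.core import SlabProblem, slab_min, slab_profile
from mtmkit.mea import default_mea_design, uniform_mea_design
from mtmkit.params import CheckpointRequirements, GeometryParams, PhysicalParams
from mtmkit.solver import (
    ConfigurationError,
    Layer,
    StackGeometry,
    axial_profile,
    build_slab_problem,
    build_stack,
    conservation_error,
    extract_checkpoints,
    iso_crossings,
    paper_stack,
    single_mea_stack,
    solve_steady,
    solve_steady_2d,
    velocity_profile,
)

DK = 2.84e-6
Q_NR = 3.5


@pytest.fixture
def slab():
    return SlabProblem(0.017, 100.0, 100.0, Q_NR, DK)


class TestBuildStack:
    def test_paper_stack_layer_order_and_masks(self, design, phys):
        stack = paper_stack()
        assert [lay.material for lay in stack.layers] == [
            "fluid", "mea", "retina", "retina", "mea", "fluid",
        ]
        prob = build_stack(stack, [design, design], phys)
        # each material mask spans exactly its layer thicknesses
        for mat, expect in (("fluid", 0.5), ("mea", 0.004), ("retina", 0.017)):
            got = prob.h[prob.material == mat].sum()
            assert got == pytest.approx(expect, rel=1e-12)
        # MEA layers homogenize to oar * dk_fluid; consumption only in retina
        assert np.allclose(prob.dk[prob.material == "mea"], 0.189 * phys.dk)
        assert np.all(prob.q[prob.material == "retina"] == Q_NR)
        assert np.all(prob.q[prob.material != "retina"] == 0.0)
        # velocity is confined to the fluid: 100 ml/h over 0.25 cm^2
        assert np.allclose(prob.velocity[prob.material == "fluid"], 100 / 60 / 0.25)
        assert np.all(prob.velocity[prob.material != "fluid"] == 0.0)

    def test_all_fluid_stack_uniform(self, phys):
        stack = StackGeometry(layers=(Layer("bath", 0.5, "fluid"),))
        prob = build_stack(stack, [], phys)
        assert np.allclose(prob.dk, phys.dk_fluid_effective)
        assert np.all(prob.q == 0.0)
        field = solve_steady(prob)
        assert np.allclose(field.tension, prob.p_bulk)

    def test_mismatched_design_count_rejected(self, design, phys):
        with pytest.raises(ConfigurationError):
            build_stack(paper_stack(), [design], phys)

    def test_two_retina_blocks_rejected(self):
        with pytest.raises(ConfigurationError):
            StackGeometry(
                layers=(
                    Layer("r1", 0.01, "retina"),
                    Layer("f", 0.1, "fluid"),
                    Layer("r2", 0.01, "retina"),
                )
            )

    def test_near_zero_oar_decouples_sides(self, phys):
        # a practically solid MEA isolates the retina from the far chamber
        design = uniform_mea_design(1e-12)
        prob = build_stack(single_mea_stack(), [design], phys)
        field = solve_steady(prob)
        # tissue collapses to the hypoxic floor despite a fully oxygenated bath
        assert field.tension[prob.material == "retina"].max() < 1.0


class TestVelocityProfile:
    def test_plug_mean(self):
        u = velocity_profile(100.0, 0.25, 1.0, "plug")
        assert np.allclose(u, 100 / 60 / 0.25)

    def test_poiseuille_peak_and_mean(self):
        h = 0.25
        y = np.linspace(0, h, 2001)
        u = velocity_profile(100.0, h, 1.0, "poiseuille", y=y)
        u_mean = 100 / 60 / (h * 1.0)
        assert u.max() == pytest.approx(1.5 * u_mean, rel=1e-4)
        assert np.trapezoid(u, y) / h == pytest.approx(u_mean, rel=1e-4)

    def test_zero_flow(self):
        assert np.all(velocity_profile(0.0, 0.25, 1.0) == 0.0)


class TestSolveSteadyAgainstSlabOracle:
    def test_matches_closed_form_at_200_nodes(self, slab):
        field = solve_steady(build_slab_problem(slab, 200))
        exact = slab_profile(slab, field.z_centers)
        rel = np.max(np.abs(field.tension - exact) / np.abs(exact))
        assert rel < 0.005

    def test_second_order_grid_convergence(self, slab):
        errs = []
        for n in (100, 200, 400):
            field = solve_steady(build_slab_problem(slab, n))
            exact = slab_profile(slab, field.z_centers)
            errs.append(np.max(np.abs(field.tension - exact)))
        assert 3.0 < errs[0] / errs[1] < 5.0
        assert 3.0 < errs[1] / errs[2] < 5.0

    def test_conservation_exact(self, slab):
        field = solve_steady(build_slab_problem(slab, 300))
        assert conservation_error(field) < 1e-10

    def test_clamp_keeps_tension_nonnegative(self):
        # starvation scenario: long slab, weak boundaries
        hungry = SlabProblem(0.1, 5.0, 5.0, Q_NR, DK)
        field = solve_steady(build_slab_problem(hungry, 400))
        assert field.tension.min() >= 0.0
        assert conservation_error(field) < 1e-8
        # shut-off region consumes less than the nominal rate
        assert field.q_eff.min() < Q_NR


@pytest.fixture(scope="module")
def solved():
    phys = PhysicalParams()
    design = default_mea_design()
    prob = build_stack(paper_stack(), [design, design], phys)
    return prob, solve_steady(prob)


class TestDefaultScenario:
    def test_checkpoints_pass_requirements(self, solved):
        _, field = solved
        report = extract_checkpoints(field, CheckpointRequirements())
        assert report.all_pass
        assert report.p_smea > report.p_sr > report.p_ir > 0

    def test_retina_center_drop_matches_parabola(self, solved):
        # interior drop is the slab closed form regardless of the fluid model
        _, field = solved
        report = extract_checkpoints(field)
        expected_drop = Q_NR * 0.017**2 / (8 * DK)
        assert report.p_sr - report.p_ir == pytest.approx(expected_drop, rel=0.01)

    def test_profile_flat_in_bulk_steep_near_mea(self, solved):
        prob, field = solved
        prof = axial_profile(field)
        fluid = prof[prof.material == "fluid"]
        # bulk (>0.3 mm from the MEA face at z = 0.25 cm) sits at the inlet tension
        bulk = fluid[fluid.z_cm < 0.25 - 0.03]
        assert np.allclose(bulk.tension_mmHg, prob.p_bulk, rtol=1e-9)
        # the film right above the MEA carries a substantial drop
        film = fluid[(fluid.z_cm > 0.25 - 0.03) & (fluid.z_cm < 0.25)]
        assert film.tension_mmHg.min() < 0.6 * prob.p_bulk

    def test_conservation(self, solved):
        _, field = solved
        assert conservation_error(field) < 1e-10

    def test_symmetric_stack_gives_symmetric_profile(self, solved):
        prob, field = solved
        mid = prob.z_faces[-1] / 2
        flipped = np.interp(2 * mid - prob.z_centers[::-1], prob.z_centers, field.tension)
        assert np.allclose(field.tension[::-1], flipped, rtol=1e-6)

    def test_iso_crossings_bracket_the_film(self, solved):
        _, field = solved
        crossings = iso_crossings(field)
        # every crossing lies within 0.3 mm of an MEA face or inside the stack core
        assert (crossings.level_mmHg <= 634).all()
        assert len(crossings) > 0


class TestCheckpointExtraction:
    def test_uniform_field_all_pass(self, phys, design):
        stack = paper_stack()
        prob = build_stack(stack, [design, design], PhysicalParams(q_nr=1e-12))
        field = solve_steady(prob)
        report = extract_checkpoints(field, CheckpointRequirements())
        assert np.allclose(
            [report.p_smea, report.p_sr, report.p_ir], prob.p_bulk, rtol=1e-6
        )
        assert report.all_pass

    def test_slab_midplane_equals_slab_min(self, slab):
        field = solve_steady(build_slab_problem(slab, 400))
        # retina mid-plane checkpoint equals the closed-form interior minimum
        z_min, p_min = slab_min(slab)
        mid_idx = np.argmin(np.abs(field.z_centers - z_min))
        assert field.tension[mid_idx] == pytest.approx(p_min, rel=1e-3)

    def test_report_table_shape(self, phys, design):
        prob = build_stack(paper_stack(), [design, design], phys)
        report = extract_checkpoints(solve_steady(prob))
        frame = report.to_frame()
        assert list(frame.columns) == [
            "checkpoint", "required_mmHg", "simulated_mmHg", "pass",
        ]
        assert len(frame) == 3


class TestComparativeStatics:
    def test_oar_monotonicity(self, phys):
        p_irs = []
        for oar in (0.05, 0.1, 0.2, 0.3):
            design = uniform_mea_design(oar)
            prob = build_stack(paper_stack(), [design, design], phys)
            report = extract_checkpoints(solve_steady(prob))
            p_irs.append(report.p_ir)
        assert all(b >= a for a, b in zip(p_irs, p_irs[1:]))

    def test_dual_supply_beats_single(self, phys, design):
        dual = extract_checkpoints(
            solve_steady(build_stack(paper_stack(), [design, design], phys))
        )
        single = extract_checkpoints(
            solve_steady(build_stack(single_mea_stack(), [design], phys))
        )
        assert dual.p_ir >= single.p_ir


class Test2DMode:
    def test_plane_symmetric_solution_sane(self, phys, design):
        field = solve_steady_2d(
            paper_stack(), [design, design], phys, nx=24, grid_refine=0.3
        )
        assert field.tension.min() >= 0.0
        assert field.tension.max() <= field.problem.p_bulk * (1 + 1e-9)
        # mid-chamber column: boundary layer forms over the MEA
        report = extract_checkpoints(field.column(0.5))
        assert report.p_smea < field.problem.p_bulk
        assert report.p_sr - report.p_ir == pytest.approx(
            Q_NR * 0.017**2 / (8 * DK), rel=0.05
        )

    def test_downstream_depletion(self, phys, design):
        field = solve_steady_2d(
            paper_stack(), [design, design], phys, nx=24, grid_refine=0.3
        )
        up = extract_checkpoints(field.column(0.1)).p_ir
        down = extract_checkpoints(field.column(0.9)).p_ir
        # tissue tension can only stay equal or fall downstream
        assert down <= up + 1e-6
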