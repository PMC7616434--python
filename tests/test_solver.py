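"""Field solver verification: analytic fixtures, oracles and invariants."""

import numpy as np
import pytest

from electrotick import build_parallel_plate_scene, build_rig_scene
from electrotick.scenes import Conductor, FieldScene, rig_probe_point
from electrotick.shapes import InvalidGeometryError, Sphere
from electrotick.solver import (
    GridSpec,
    OutOfDomainError,
    ProximityError,
    ResolutionWarning,
    grid_convergence_report,
    rig_solution,
    solve_axisymmetric,
    solve_cartesian_3d_nested,
    sphere_plane_axis_field,
)

# Frozen output of the image-charge series (independent of the FD solver):
# sphere radius 7.5 mm, gap 3 mm, +750 V, evaluated 0.5 mm above the plane.
ORACLE_RIG_FIELD = -221648.04516940497


class TestImageChargeOracle:
    def test_frozen_regression_value(self):
        e = sphere_plane_axis_field(0.0075, 0.003, 750.0, 0.0005)
        assert e == pytest.approx(ORACLE_RIG_FIELD, rel=1e-10)

    def test_polarity_negates_exactly(self):
        e_pos = sphere_plane_axis_field(0.0075, 0.003, 750.0, 0.0005)
        e_neg = sphere_plane_axis_field(0.0075, 0.003, -750.0, 0.0005)
        assert e_neg == -e_pos

    def test_large_sphere_reaches_parallel_plate_limit(self):
        e = sphere_plane_axis_field(1.0, 0.003, 750.0, 0.0015)
        assert abs(e) == pytest.approx(750.0 / 0.003, rel=0.01)

    def test_z_outside_gap_rejected(self):
        with pytest.raises(ValueError):
            sphere_plane_axis_field(0.0075, 0.003, 750.0, 0.004)


class TestParallelPlate:
    def test_uniform_field_exact(self, parallel_plate):
        sol = parallel_plate
        z = sol.axes[1]
        interior = sol.E_magnitude[:, (z > 0.0002) & (z < 0.0028)]
        assert np.all(np.abs(interior / 250_000.0 - 1) < 1e-3)

    def test_zero_voltage_gives_zero_field(self):
        scene = build_parallel_plate_scene(0.003, 0.0)
        sol = solve_axisymmetric(scene, GridSpec(h=1e-4))
        assert np.abs(sol.V).max() == pytest.approx(0.0, abs=1e-12)

    def test_one_mm_gap_290_volts(self):
        scene = build_parallel_plate_scene(0.001, 290.0)
        sol = solve_axisymmetric(scene, GridSpec(h=2.5e-5))
        e = sol.probe([(0.01, 0.0005)])[0].E_magnitude
        assert e == pytest.approx(290_000.0, rel=1e-6)

    def test_probe_at_node_returns_node_value(self, parallel_plate):
        sol = parallel_plate
        i, j = 100, 15
        p = sol.probe([(sol.axes[0][i], sol.axes[1][j])])[0]
        assert p.E_magnitude == pytest.approx(sol.E_magnitude[i, j], rel=1e-12)
        assert p.V == pytest.approx(sol.V[i, j], rel=1e-12)

    def test_probe_errors(self, parallel_plate):
        with pytest.raises(OutOfDomainError):
            parallel_plate.probe([(0.2, 0.0015)])
        with pytest.raises(ProximityError):
            parallel_plate.probe([(0.01, 0.00295)])  # half a cell from the plate


class TestRigSolve:
    def test_matches_image_charge_oracle_within_2pct(self, rig_fine):
        e_fd = rig_fine.probe([rig_probe_point(0.0005)])[0].E_magnitude
        assert e_fd == pytest.approx(abs(ORACLE_RIG_FIELD), rel=0.02)

    def test_oracle_agreement_along_gap_axis(self, rig_fine):
        for z_mm in (0.5, 1.0, 1.5, 2.0):
            e_fd = rig_fine.probe([rig_probe_point(z_mm * 1e-3)])[0].E_magnitude
            e_or = abs(sphere_plane_axis_field(0.0075, 0.003, 750.0, z_mm * 1e-3))
            assert e_fd == pytest.approx(e_or, rel=0.02)

    def test_maximum_principle(self, rig_fine):
        rig_fine.check_maximum_principle()
        assert rig_fine.V.min() >= -1e-9
        assert rig_fine.V.max() <= 750.0 + 1e-9

    def test_conductor_adjacent_nodes_at_conductor_potential(self, rig_fine):
        assert np.all(np.abs(rig_fine.V[rig_fine.conductor_mask]) <= 750.0)
        electrode = rig_fine.scene.conductors[1]
        R, Z = np.meshgrid(*rig_fine.axes, indexing="ij")
        on_sphere = electrode.shape.contains(R, 0.0, Z)
        assert np.allclose(rig_fine.V[on_sphere], 750.0)

    def test_linearity_in_boundary_data(self, rig_pair):
        pos, _ = rig_pair
        half = rig_solution(gap=0.003, voltage=375.0, h_fine=1e-4)
        assert np.allclose(2 * half.V, pos.V, rtol=1e-10, atol=1e-8)
        assert np.allclose(2 * half.E_magnitude, pos.E_magnitude,
                           rtol=1e-9, atol=1e-6)

    def test_polarity_symmetry_of_field_magnitude(self, rig_pair):
        pos, neg = rig_pair
        assert np.allclose(pos.V, -neg.V, rtol=1e-12, atol=1e-9)
        assert np.allclose(pos.E_magnitude, neg.E_magnitude,
                           rtol=1e-12, atol=1e-9)

    def test_isolated_sphere_follows_coulomb_law(self):
        scene = FieldScene(
            domain_lo=(0, 0, 0),
            domain_hi=(0.3, 0, 0.6),
            conductors=[
                Conductor(Sphere(center=(0, 0, 0.3), radius=0.0075), 750.0, "ball")
            ],
            symmetry="axisymmetric",
        )
        fine = GridSpec(h=2.5e-4, refinement_box=((0.0, 0.25), (0.05, 0.35)))
        sol = solve_axisymmetric(scene, GridSpec(h=2e-3), fine=fine)
        r = 0.0075 + 0.0005
        e = sol.probe([(0.0, 0.3 - r)])[0].E_magnitude
        assert e == pytest.approx(750.0 * 0.0075 / r**2, rel=0.05)

    def test_under_resolved_gap_warns(self):
        scene = build_rig_scene(0.003, 750.0)
        with pytest.warns(ResolutionWarning):
            solve_axisymmetric(scene, GridSpec(h=1e-3))

    def test_wrong_symmetry_rejected(self, mini_scene):
        with pytest.raises(InvalidGeometryError):
            solve_axisymmetric(mini_scene, GridSpec(h=1e-3))


class TestNested3D:
    def test_all_grounded_scene_zero_field(self, mini_scene, mini_grids):
        coarse, fine = mini_grids
        sol = solve_cartesian_3d_nested(mini_scene.scaled(0.0), coarse, fine)
        assert np.abs(sol.V).max() == 0.0
        assert sol.E_magnitude.max() == 0.0

    def test_voltage_scaling_doubles_field(self, mini_scene, mini_grids):
        coarse, fine = mini_grids
        full = solve_cartesian_3d_nested(mini_scene, coarse, fine)
        half = solve_cartesian_3d_nested(mini_scene.scaled(0.5), coarse, fine)
        probes = [(0.05, 0.05, 0.04), (0.06, 0.05, 0.035), (0.04, 0.06, 0.07)]
        for pt in probes:
            e1 = full.probe([pt])[0].E_magnitude
            e2 = half.probe([pt])[0].E_magnitude
            assert e1 == pytest.approx(2 * e2, rel=1e-6)
        full.check_maximum_principle()

    def test_polarity_symmetry_3d(self, mini_scene, mini_grids):
        coarse, fine = mini_grids
        pos = solve_cartesian_3d_nested(mini_scene, coarse, fine)
        neg = solve_cartesian_3d_nested(mini_scene.scaled(-1.0), coarse, fine)
        assert np.allclose(pos.E_magnitude, neg.E_magnitude, rtol=1e-6, atol=1e-7)

    def test_missing_refinement_box_rejected(self, mini_scene):
        with pytest.raises(ValueError):
            solve_cartesian_3d_nested(
                mini_scene, GridSpec(h=2.5e-3), GridSpec(h=5e-4)
            )

    def test_refinement_box_outside_domain_rejected(self, mini_scene):
        fine = GridSpec(h=5e-4, refinement_box=((0.03, 0.03, 0.03), (0.2, 0.07, 0.07)))
        with pytest.raises(InvalidGeometryError):
            solve_cartesian_3d_nested(mini_scene, GridSpec(h=2.5e-3), fine)


class TestGridConvergence:
    def test_parallel_plate_exact_at_all_spacings(self):
        scene = build_parallel_plate_scene(0.003, 750.0)
        rep = grid_convergence_report(
            scene, (0.01, 0.0015), [1.5e-4, 1e-4, 5e-5]
        )
        assert np.allclose(rep["E_magnitude"], 250_000.0, rtol=1e-9)

    def test_rig_probe_converges_at_first_order_or_better(self):
        scene = build_rig_scene(0.003, 750.0)

        def solve_fn(h):
            return rig_solution(gap=0.003, voltage=750.0, h_fine=h)

        with pytest.warns(ResolutionWarning):  # the coarsest rung is marginal
            rep = grid_convergence_report(
                scene, rig_probe_point(0.0005), [2e-4, 1e-4, 5e-5],
                solve_fn=solve_fn,
            )
        changes = rep["change"].to_numpy()
        assert changes[2] < changes[1]  # successive refinement shrinks change
        assert rep.attrs["order"] >= 1.0
        # default-ladder stability: < 1% shift between the two finest grids
        assert changes[2] / rep["E_magnitude"].iloc[-1] < 0.01

    def test_requires_three_decreasing_spacings(self):
        scene = build_parallel_plate_scene(0.003, 750.0)
        with pytest.raises(ValueError):
            grid_convergence_report(scene, (0.01, 0.0015), [1e-4])
        with pytest.raises(ValueError):
            grid_convergence_report(scene, (0.01, 0.0015), [1e-4, 2e-4, 3e-4])


class TestExport:
    def test_csv_export_roundtrip_columns(self, parallel_plate, tmp_path):
        path = tmp_path / "field.csv"
        parallel_plate.export_csv(str(path), stride=4)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["r_m", "z_m", "V", "Er", "Ez", "Emag"]
        assert (df["Emag"] >= 0).all()
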