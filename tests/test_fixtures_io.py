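"""Analytic-field agent sandbox and text-based I/O round-trips."""

import math

import numpy as np
import pandas as pd
import pytest

from foldax import io as fio
from foldax.agents import AxonBundle
from foldax.config import SimulationConfig
from foldax.fields import agent_sandbox, make_field


@pytest.fixture()
def sandbox_config():
    return SimulationConfig(noise_std=0.0)


def bundle(theta=math.pi / 2, tip=(0.0, 0.0), seed=0):
    return AxonBundle(
        id=0,
        tip=np.array(tip, dtype=float),
        theta=theta,
        rng=np.random.default_rng(seed),
    )


class TestFieldConstruction:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_field("vortex", magnitude=1.0)

    def test_missing_parameters_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            make_field("rotated_uniaxial", angle=0.3)

    def test_uniform_returns_tensor(self):
        T = np.diag([10.0, 0.0])
        f = make_field("uniform", T=T)
        assert np.allclose(f((3.0, 4.0)), T)

    def test_rotated_uniaxial_principal_direction(self):
        f = make_field("rotated_uniaxial", angle=0.6458, magnitude=10.0)
        n = f.principal_direction((0.0, 0.0))
        T = f((0.0, 0.0))
        # n is the eigenvector of T with eigenvalue = magnitude
        assert np.allclose(T @ n, 10.0 * n, atol=1e-12)

    def test_spatially_varying_rotates_with_x(self):
        f = make_field(
            "spatially_varying", angle0=0.0, dangle_dx=0.05, magnitude=10.0
        )
        n0 = f.principal_direction((0.0, 0.0))
        n5 = f.principal_direction((5.0, 0.0))
        assert np.allclose(n0, [1.0, 0.0])
        assert math.acos(np.clip(n0 @ n5, -1, 1)) == pytest.approx(0.25)

    def test_degenerate_is_isotropic(self):
        f = make_field("degenerate", magnitude=10.0)
        assert np.allclose(f((1.0, 1.0)), 10.0 * np.eye(2))
        with pytest.raises(ValueError):
            f.principal_direction((0.0, 0.0))


class TestSandboxDynamics:
    def test_zero_field_grows_straight(self, sandbox_config):
        b = bundle(theta=math.pi / 2)
        f = make_field("uniform", T=np.zeros((2, 2)))
        out = agent_sandbox(f, sandbox_config, [b], n_steps=50)
        traj = out["trajectories"][0]
        # zero stress is degenerate: no reorientation, no noise -> straight up
        assert np.allclose(traj[:, 0], 0.0, atol=1e-14)
        speed = sandbox_config.G_axn * sandbox_config.agent_dt
        assert traj[-1, 1] == pytest.approx(50 * speed)
        assert np.allclose(np.array(out["angles"][0]), math.pi / 2)

    def test_degenerate_field_keeps_heading(self, sandbox_config):
        b = bundle(theta=1.0)
        f = make_field("degenerate", magnitude=10.0)
        out = agent_sandbox(f, sandbox_config, [b], n_steps=20)
        assert np.allclose(np.array(out["angles"][0]), 1.0)

    def test_elongation_linear_in_stress(self, sandbox_config):
        # heading aligned with a uniaxial field: dL = (a*sigma + G_axn) dt
        s = 10.0
        f = make_field("rotated_uniaxial", angle=math.pi / 2, magnitude=s)
        b = bundle(theta=math.pi / 2)
        n = 40
        out = agent_sandbox(f, sandbox_config, [b], n_steps=n)
        expect = n * (sandbox_config.a * s + sandbox_config.G_axn) * sandbox_config.agent_dt
        assert out["bundles"][0].length == pytest.approx(expect, rel=1e-12)

    def test_reorientation_converges_to_field_direction(self, sandbox_config):
        ang = 0.6458
        f = make_field("rotated_uniaxial", angle=ang, magnitude=10.0)
        b = bundle(theta=math.pi / 2)
        out = agent_sandbox(f, sandbox_config, [b], n_steps=3000)
        assert out["angles"][0][-1] == pytest.approx(ang, abs=1e-3)
        # gap decreases monotonically without noise
        gaps = np.abs(np.array(out["angles"][0]) - ang)
        assert (np.diff(gaps) <= 1e-15).all()

    def test_disabled_reorientation_ignores_field(self, sandbox_config):
        cfg = sandbox_config.replace(reorientation_enabled=False)
        f = make_field("rotated_uniaxial", angle=0.3, magnitude=10.0)
        b = bundle(theta=math.pi / 2)
        out = agent_sandbox(f, cfg, [b], n_steps=100)
        assert np.allclose(np.array(out["angles"][0]), math.pi / 2)


class TestVTKRoundtrip:
    def _grid(self, rng):
        nodes = rng.standard_normal((9, 2)) * 3.0
        quads = np.array([[0, 1, 4, 3], [1, 2, 5, 4], [3, 4, 7, 6], [4, 5, 8, 7]])
        cell_data = {
            "region": np.array([0, 1, 2, 1], dtype=np.int64),
            "mu": rng.standard_normal(4) * 100,
        }
        point_data = {"displacement": rng.standard_normal((9, 2))}
        return nodes, quads, cell_data, point_data

    def test_bit_exact_roundtrip(self, tmp_path, rng):
        nodes, quads, cd, pd_ = self._grid(rng)
        p = tmp_path / "grid.vtk"
        fio.write_vtk(p, nodes, quads, cell_data=cd, point_data=pd_)
        out = fio.read_vtk(p)
        assert np.array_equal(out["nodes"], nodes)  # 17 sig digits: lossless
        assert np.array_equal(out["quads"], quads)
        assert np.array_equal(out["cell_data"]["region"], cd["region"])
        assert np.array_equal(out["cell_data"]["mu"], cd["mu"])
        assert np.array_equal(out["point_data"]["displacement"], pd_["displacement"])

    def test_truncated_file_names_section(self, tmp_path, rng):
        nodes, quads, cd, pd_ = self._grid(rng)
        p = tmp_path / "grid.vtk"
        fio.write_vtk(p, nodes, quads, cell_data=cd)
        text = p.read_text()
        p.write_text(text[: len(text) // 2])
        with pytest.raises(fio.VTKParseError):
            fio.read_vtk(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "bad.vtk"
        p.write_text("not a vtk file\n")
        with pytest.raises(fio.VTKParseError, match="header"):
            fio.read_vtk(p)

    def test_non_quad_cell_rejected(self, tmp_path, rng):
        nodes, quads, cd, _ = self._grid(rng)
        p = tmp_path / "grid.vtk"
        fio.write_vtk(p, nodes, quads)
        p.write_text(p.read_text().replace("\n4 0 1 4 3\n", "\n3 0 1 4\n", 1))
        with pytest.raises(fio.VTKParseError):
            fio.read_vtk(p)


class TestTabularIO:
    def test_trajectories_roundtrip(self, tmp_path, rng):
        df = pd.DataFrame(
            {
                "agent": [0, 0, 1],
                "step": [0, 1, 0],
                "x": rng.standard_normal(3),
                "y": rng.standard_normal(3),
                "theta": rng.standard_normal(3),
                "sigma": [1.5, math.nan, -2.0],
                "status": ["growing", "settled", "growing"],
            }
        )
        p = tmp_path / "traj.csv"
        fio.write_trajectories_csv(p, df)
        out = fio.read_trajectories_csv(p)
        assert out["x"].tolist() == pytest.approx(df["x"].tolist())
        assert out["status"].tolist() == df["status"].tolist()

    def test_trajectories_missing_column_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="missing columns"):
            fio.write_trajectories_csv(tmp_path / "t.csv", pd.DataFrame({"x": [1]}))

    def test_report_json_roundtrip(self, tmp_path):
        p = tmp_path / "report.json"
        payload = {"GI": 1.25, "flags": [], "nested": {"a": [1, 2]}}
        fio.write_report_json(p, payload)
        assert fio.read_report_json(p) == payload

    def test_malformed_json_rejected(self, tmp_path):
        p = tmp_path / "report.json"
        p.write_text("{broken")
        with pytest.raises(ValueError, match="malformed"):
            fio.read_report_json(p)

    def test_polyline_roundtrip(self, tmp_path, rng):
        polys = {"pial": rng.standard_normal((7, 2))}
        p = tmp_path / "surf.json"
        fio.write_polyline_json(p, polys)
        out = fio.read_polyline_json(p)
        assert np.allclose(out["pial"], polys["pial"])


class TestCouplingEquivalence:
    def test_fe_probe_matches_analytic_field(self):
        """A homogeneously stressed FE state reproduces the analytic field.

        Impose a uniform deformation gradient on a solver via nodal
        displacements (zero growth), evaluate forces to fill the stress
        store, and compare probe_stress against the material law directly:
        the FE probe and an equivalent analytic field must agree to 1e-10.
        """
        from foldax.kinematics import cauchy_stress
        from foldax.solver import make_solver

        cfg = SimulationConfig(w=6.0, h=4.5, t_c=1.5, elem_size=0.75)
        solver = make_solver(cfg)
        A = np.array([[1.02, 0.0], [0.0, 1.01]])
        solver.state.u[:] = solver.mesh.nodes @ (A - np.eye(2)).T
        solver.internal_forces()

        F3 = np.eye(3)
        F3[:2, :2] = A
        for pt in [(1.0, 1.0), (3.1, 2.2), (5.0, 4.0)]:
            p_def = A @ np.array(pt)
            T_fe, ps, e = solver.probe_stress(p_def)
            T_exact = cauchy_stress(F3, solver.mu[e], solver.kbulk[e])
            assert np.allclose(T_fe, T_exact, atol=1e-10 * solver.mu[e])
            field = make_field("uniform", T=T_exact[:2, :2])
            assert np.allclose(T_fe[:2, :2], field(p_def), atol=1e-10 * solver.mu[e])
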