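"""Data-curve CSV I/O, the project container, synthetic datasets."""

import json

import numpy as np
import pytest

from conftest import FIT_WINDOW
from mmlsim import estimation, project
from mmlsim.estimation import NoiseSpec
from mmlsim.project import (DataCurve, Project, ProjectError,
                            generate_synthetic_dataset, load_project,
                            read_data_csv, save_project, write_data_csv)


class TestDataCsv:
    def test_weight_column_attaches_to_curve(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("# unit: t=sec, Cout=mM\n"
                        "t,Cout,weight_Cout\n0,0.1,1\n1,0.2,2\n2,0.3,0.5\n")
        curves = read_data_csv(path)
        assert len(curves) == 1
        c = curves[0]
        assert c.name == "Cout" and c.unit == "mM" and c.domain_unit == "sec"
        assert np.array_equal(c.weights, [1.0, 2.0, 0.5])

    def test_round_trip_exact_at_double_precision(self, tmp_path, box2_plan,
                                                  cin):
        from mmlsim.pde import solve_model_pde
        sol = solve_model_pde(box2_plan, inputs={"Cin": cin})
        curve = DataCurve("Cout", sol.t, sol["Cout"], "sec", "mM")
        path = tmp_path / "cout.csv"
        write_data_csv([curve], path)
        back = read_data_csv(path)[0]
        assert np.array_equal(back.domain, curve.domain)
        assert np.array_equal(back.samples, curve.samples)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("# unit: t=sec\nt,Cout\n")
        with pytest.raises(ProjectError, match="no data rows"):
            read_data_csv(path)

    def test_non_monotone_domain_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,y\n0,1\n2,2\n1,3\n")
        with pytest.raises(ProjectError, match="monotone"):
            read_data_csv(path)

    def test_curve_invariants(self):
        with pytest.raises(ProjectError):
            DataCurve("y", [0.0, 1.0], [1.0])
        with pytest.raises(ProjectError):
            DataCurve("y", [0.0, 0.0], [1.0, 2.0])


class TestProjectContainer:
    def make_project(self):
        proj = Project(notes="worked example")
        proj.models["mm2irrev"] = project.fixture_source("mm2irrev")
        proj.parameter_sets["printed"] = {
            "Vhmax": {"value": 1.84, "unit": "uM/s"},
            "Kmh": {"value": 3.67, "unit": "uM"},
        }
        t = np.linspace(0.0, 10.0, 6)
        proj.data_sets["demo"] = [DataCurve("U", t, t * 0.1, "sec", "uM")]
        proj.configs["run1"] = {"kind": "run", "model": "mm2irrev",
                                "summary_vars": ["U"]}
        return proj

    def test_round_trip(self, tmp_path):
        proj = self.make_project()
        path = tmp_path / "p.json"
        save_project(proj, path)
        back = load_project(path)
        assert back.notes == proj.notes
        assert back.models == proj.models
        assert back.parameter_sets == proj.parameter_sets
        assert back.configs == proj.configs
        a, b = proj.data_sets["demo"][0], back.data_sets["demo"][0]
        assert np.array_equal(a.domain, b.domain)
        assert np.array_equal(a.samples, b.samples)

    def test_hand_edit_is_visible_after_load(self, tmp_path):
        path = tmp_path / "p.json"
        save_project(self.make_project(), path)
        doc = json.loads(path.read_text())
        doc["parameter_sets"]["printed"]["Vhmax"]["value"] = 2.5
        path.write_text(json.dumps(doc))
        back = load_project(path)
        assert back.parameter_sets["printed"]["Vhmax"]["value"] == 2.5

    def test_missing_model_reference_is_integrity_error(self, tmp_path):
        proj = self.make_project()
        proj.configs["broken"] = {"kind": "run", "model": "nonexistent"}
        path = tmp_path / "p.json"
        save_project(proj, path)
        with pytest.raises(ProjectError, match="nonexistent"):
            load_project(path)

    def test_unknown_fields_preserved_on_round_trip(self, tmp_path):
        path = tmp_path / "p.json"
        save_project(self.make_project(), path)
        doc = json.loads(path.read_text())
        doc["future_extension"] = {"answer": 42}
        path.write_text(json.dumps(doc))
        back = load_project(path)
        assert back.extra["future_extension"] == {"answer": 42}
        path2 = tmp_path / "p2.json"
        save_project(back, path2)
        assert json.loads(path2.read_text())["future_extension"] == \
            {"answer": 42}

    def test_version_mismatch_reports_declared_version(self, tmp_path):
        path = tmp_path / "p.json"
        save_project(self.make_project(), path)
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ProjectError, match="99"):
            load_project(path)


class TestSyntheticData:
    def test_zero_noise_lies_on_the_trajectory(self, box1_plan,
                                               box1_trajectory):
        ts = np.linspace(0.0, 5000.0, 50)
        curve, truth = generate_synthetic_dataset(box1_plan, "U", ts)
        assert np.allclose(curve.samples,
                           np.interp(ts, box1_trajectory.grid,
                                     box1_trajectory["U"]),
                           rtol=0, atol=1e-12)
        assert truth["Vhmax"] == 1.84
        assert curve.unit == "uM" and curve.domain_unit == "sec"

    def test_proportional_noise_magnitude(self, box1_plan):
        ts = np.linspace(5.0, 295.0, 10_000)
        curve, _ = generate_synthetic_dataset(
            box1_plan, "U", ts, noise=NoiseSpec("proportional_gaussian",
                                                0.05),
            seed=12, params=dict(FIT_WINDOW))
        clean, _ = generate_synthetic_dataset(
            box1_plan, "U", ts, params=dict(FIT_WINDOW))
        ok = clean.samples > 1e-6
        ratio = curve.samples[ok] / clean.samples[ok] - 1.0
        assert ratio.std() == pytest.approx(0.05, abs=0.002)

    def test_same_seed_gives_identical_file_bytes(self, box1_plan, tmp_path):
        ts = np.linspace(0.0, 300.0, 30)
        noise = NoiseSpec("proportional_gaussian", 0.05)
        for name in ("a.csv", "b.csv"):
            curve, _ = generate_synthetic_dataset(
                box1_plan, "U", ts, noise=noise, seed=7,
                params=dict(FIT_WINDOW))
            write_data_csv([curve], tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == \
            (tmp_path / "b.csv").read_bytes()

    def test_sample_outside_domain_rejected(self, box1_plan):
        with pytest.raises(ProjectError, match="outside"):
            generate_synthetic_dataset(box1_plan, "U", [0.0, 5001.0])


class TestReproducibility:
    def test_project_rerun_reproduces_stored_fit(self, box1_plan, tmp_path):
        """A packed model + data + fit configuration re-executes to the
        stored result summary."""
        from mmlsim.cli import rerun_project
        ts = np.linspace(10.0, 290.0, 40)
        curve, truth = generate_synthetic_dataset(
            box1_plan, "U", ts, noise=NoiseSpec("proportional_gaussian",
                                                0.02),
            seed=21, params=dict(FIT_WINDOW))
        proj = Project(notes="recovery study")
        proj.models["mm2irrev"] = project.fixture_source("mm2irrev")
        proj.data_sets["noisy"] = [curve]
        proj.configs["fit_U"] = {
            "kind": "fit", "model": "mm2irrev", "data_set": "noisy",
            "map": {"U": "U"}, "free": ["Vhmax", "Kmh"],
            "start": {"Vhmax": 1.0, "Kmh": 1.0},
            "bounds": {"Vhmax": [0.01, 50.0], "Kmh": [0.01, 50.0]},
            "method": "sensop", "set": dict(FIT_WINDOW),
        }
        results = rerun_project(proj)
        proj.results = results
        path = tmp_path / "study.json"
        save_project(proj, path)

        again = rerun_project(load_project(path))
        stored = proj.results["fit_U"]["params"]
        for k, v in again["fit_U"]["params"].items():
            assert v == pytest.approx(stored[k], rel=1e-6)
        # and the recovered values sit near the generating truth
        assert again["fit_U"]["params"]["Vhmax"] == pytest.approx(
            truth["Vhmax"], rel=0.05)
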