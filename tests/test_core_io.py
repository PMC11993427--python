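"""Domain types, unit conventions and file round-trips."""

import numpy as np
import pytest

from cardioquant.core import (
    BloodConstants,
    ComponentResult,
    LVGeometry,
    MBFResult,
    OrificeDisk,
    Pathline,
    VelocityField4D,
)
from cardioquant.io import (
    read_component_result,
    read_field,
    read_geometry,
    read_mbf_result,
    read_pathlines_csv,
    read_pathlines_npz,
    write_field,
    write_geometry,
    write_pathlines_csv,
    write_pathlines_npz,
    write_results,
)
from cardioquant.phantoms import make_duct_phantom, PhantomParams
from cardioquant.tracing import trace_cycle

import json


def _toy_field(n_frames=30, hr=61.0):
    cycle = 60000.0 / hr
    rng = np.random.default_rng(0)
    vel = rng.normal(scale=0.1, size=(n_frames, 4, 5, 6, 3))
    times = np.arange(n_frames) * cycle / n_frames
    return VelocityField4D(
        velocities=vel, spacing=3.0, frame_times=times, cycle_length=cycle,
        venc=1.0, origin_mm=np.array([1.0, -2.0, 0.5]), periodic=True,
    )


class TestVelocityField:
    def test_round_trip_is_bit_exact(self, tmp_path):
        field = _toy_field()
        write_field(field, tmp_path / "f.nii.gz")
        back = read_field(tmp_path / "f.nii.gz")
        assert np.array_equal(back.velocities, field.velocities)
        assert np.array_equal(back.frame_times, field.frame_times)
        assert back.cycle_length == field.cycle_length
        assert back.venc == field.venc
        assert back.periodic == field.periodic
        assert np.array_equal(back.origin_mm, field.origin_mm)

    def test_61_bpm_cycle_gives_30_frames_within_cycle(self, tmp_path):
        # 60000 / 61 ~= 983.6 ms cycle
        field = _toy_field(n_frames=30, hr=61.0)
        write_field(field, tmp_path / "f.nii.gz")
        back = read_field(tmp_path / "f.nii.gz")
        assert back.n_frames == 30
        assert back.cycle_length == pytest.approx(983.6065573770492)
        assert np.all(back.frame_times <= back.cycle_length)
        assert back.spacing == 3.0

    def test_single_frame_field_is_rejected(self):
        with pytest.raises(ValueError, match="at least 2 frames"):
            VelocityField4D(
                velocities=np.zeros((1, 3, 3, 3, 3)), spacing=3.0,
                frame_times=np.array([0.0]), cycle_length=1000.0, venc=1.0,
            )

    def test_missing_timing_metadata_names_the_field(self, tmp_path):
        field = _toy_field()
        write_field(field, tmp_path / "f.nii.gz")
        sidecar = tmp_path / "f.json"
        meta = json.loads(sidecar.read_text())
        del meta["frame_times_ms"]
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="frame_times_ms"):
            read_field(tmp_path / "f.nii.gz")

    def test_non_monotone_frame_times_rejected(self, tmp_path):
        field = _toy_field()
        write_field(field, tmp_path / "f.nii.gz")
        sidecar = tmp_path / "f.json"
        meta = json.loads(sidecar.read_text())
        meta["frame_times_ms"] = meta["frame_times_ms"][::-1]
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="strictly increasing"):
            read_field(tmp_path / "f.nii.gz")

    def test_cm_per_s_files_are_converted(self, tmp_path):
        field = _toy_field()
        write_field(field, tmp_path / "f.nii.gz")
        sidecar = tmp_path / "f.json"
        meta = json.loads(sidecar.read_text())
        meta["velocity_units"] = "cm/s"
        sidecar.write_text(json.dumps(meta))
        back = read_field(tmp_path / "f.nii.gz")
        assert np.allclose(back.velocities, field.velocities / 100.0)


class TestGeometryAndPathlines:
    def test_geometry_round_trip(self, tmp_path):
        _field, geom = make_duct_phantom(0.05)
        write_geometry(geom, tmp_path / "g.nii.gz")
        back = read_geometry(tmp_path / "g.nii.gz")
        assert np.array_equal(back.ed_mask, geom.ed_mask)
        assert np.array_equal(back.es_mask_next, geom.es_mask_next)
        assert back.es_frame_prev == geom.es_frame_prev
        names = [o.name for o in back.orifices]
        assert "mitral_orifice" in names and "aortic_orifice" in names
        point, normal = back.mitral_plane
        assert np.linalg.norm(normal) == pytest.approx(1.0)

    def test_pathline_round_trips(self, tmp_path):
        params = PhantomParams(n_frames=10)
        field, geom = make_duct_phantom(0.05, extent_mm=12.0, params=params)
        pathlines = trace_cycle(field, geom)
        for writer, reader, name in (
            (write_pathlines_csv, read_pathlines_csv, "p.csv"),
            (write_pathlines_npz, read_pathlines_npz, "p.npz"),
        ):
            writer(pathlines, tmp_path / name)
            back = reader(tmp_path / name)
            assert np.allclose(back.positions, pathlines.positions)
            assert np.allclose(back.velocities, pathlines.velocities)
            assert np.allclose(back.volumes_mm3, pathlines.volumes_mm3)
            assert list(back.qc_status) == list(pathlines.qc_status)

    def test_empty_mask_is_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LVGeometry(
                ed_mask=np.zeros((4, 4, 4), bool),
                es_mask_prev=np.ones((4, 4, 4), bool),
                es_mask_next=np.ones((4, 4, 4), bool),
                orifices=[
                    OrificeDisk("mitral_orifice", (0, 0, 0), (0, 0, 1), 1.0),
                    OrificeDisk("aortic_orifice", (1, 0, 0), (0, 0, 1), 1.0),
                ],
                spacing=1.0,
            )


class TestResultsIO:
    def _component_result(self):
        return ComponentResult(
            volumes={"direct": 40.0, "retained_inflow": 30.0,
                     "delayed_ejection": 30.0, "residual": 79.0},
            ke_timeseries={},
            ke_per_ml_at_ed={"direct": 1.5, "residual": 0.2},
            direct_flow_split={"early": 25.0, "late": 15.0},
            edv=179.0, inflow=70.0, ejected=70.0,
        )

    def test_component_result_csv_schema_and_round_trip(self, tmp_path):
        res = self._component_result()
        write_results(res, tmp_path / "c.csv")
        header = (tmp_path / "c.csv").read_text().splitlines()[0]
        assert header == "component,volume_ml,ke_ed_uJ_per_ml"
        back = read_component_result(tmp_path / "c.csv")
        assert back.volumes == res.volumes
        assert back.edv == res.edv
        assert back.direct_flow_split == res.direct_flow_split

    def test_mbf_result_json_schema_and_round_trip(self, tmp_path):
        res = MBFResult(
            global_mbf=1.2,
            regional_mbf=np.linspace(1.0, 1.5, 6),
            septal_mbf=np.array([1.1, 1.2, 1.3]),
            per_pair_mbf=np.full(6, 1.2),
            pn=0.2, tn=0.05,
        )
        write_results(res, tmp_path / "m.json")
        payload = json.loads((tmp_path / "m.json").read_text())
        assert set(payload) >= {"global_mbf", "regional_mbf", "septal_mbf", "pn", "tn"}
        assert len(payload["regional_mbf"]) == 6
        assert len(payload["septal_mbf"]) == 3
        back = read_mbf_result(tmp_path / "m.json")
        assert back.global_mbf == res.global_mbf
        assert np.allclose(back.regional_mbf, res.regional_mbf)
        assert back.pn == res.pn


class TestTypeInvariants:
    @pytest.mark.parametrize("field", ["rho", "t1_blood", "partition_coefficient"])
    def test_blood_constants_must_be_positive(self, field):
        with pytest.raises(ValueError):
            BloodConstants(**{field: 0.0})

    def test_orifice_normal_must_be_unit(self):
        with pytest.raises(ValueError, match="unit"):
            OrificeDisk("mitral_orifice", (0, 0, 0), (0, 0, 2.0), 5.0)

    def test_component_only_on_valid_pathlines(self):
        with pytest.raises(ValueError, match="QC-valid"):
            Pathline(
                positions=np.zeros((3, 3)), velocities=np.zeros((3, 3)),
                times_ms=np.arange(3.0), volume_mm3=27.0,
                qc_status="exited_wall", component="direct",
            )

    def test_component_result_partition_is_enforced(self):
        res = ComponentResult(
            volumes={"direct": 10.0, "retained_inflow": 0.0,
                     "delayed_ejection": 0.0, "residual": 0.0},
            ke_timeseries={}, ke_per_ml_at_ed={},
            direct_flow_split={}, edv=50.0, inflow=10.0, ejected=10.0,
        )
        with pytest.raises(ValueError, match="partition"):
            res.validate(voxel_volume_ml=0.027)
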