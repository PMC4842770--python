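"""File-format readers/writers: round trips, hand-editing, validation."""

import numpy as np
import pytest

from cortimap import (Camera, CorrTable, ElectrodeSet, FormatError,
                      ParamTable, ParseError, ShapeError, ValidationError,
                      import_coordinates, place, preset_camera, read_camera,
                      read_electrodes, read_model, read_table, write_camera,
                      write_electrodes, write_model, write_table)
from cortimap.mesh_model import import_mesh

TETRA_V = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
TETRA_F = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


class TestModelFile:
    def test_tetrahedron_roundtrip(self, tmp_path):
        mesh = import_mesh(TETRA_V, TETRA_F)
        write_model(tmp_path / "t.mof", mesh)
        back = read_model(tmp_path / "t.mof")
        assert np.array_equal(back.faces, mesh.faces)
        assert np.abs(back.vertices - mesh.vertices).max() < 1e-6

    def test_icosphere_vertex_count_preserved(self, tmp_path, brain3):
        # icosahedron subdivision count: 10 * 4^3 + 2 = 642
        assert brain3.n_vertices == 642
        write_model(tmp_path / "b.mof", brain3)
        assert read_model(tmp_path / "b.mof").n_vertices == 642

    def test_dangling_face_index_rejected(self, tmp_path):
        mesh = import_mesh(TETRA_V, TETRA_F)
        write_model(tmp_path / "t.mof", mesh)
        raw = bytearray((tmp_path / "t.mof").read_bytes())
        # face block starts at 16 + 4*12; point one index at V (= 4)
        off = 16 + 4 * 12
        raw[off:off + 4] = (4).to_bytes(4, "little")
        (tmp_path / "bad.mof").write_bytes(bytes(raw))
        with pytest.raises(ValidationError, match="face"):
            read_model(tmp_path / "bad.mof")

    def test_bad_magic_names_offset(self, tmp_path):
        (tmp_path / "x.mof").write_bytes(b"NOTMAGIC" + b"\0" * 16)
        with pytest.raises(FormatError, match="byte offset 0"):
            read_model(tmp_path / "x.mof")


class TestElectrodeFile:
    def _set(self):
        es = ElectrodeSet()
        for p in ([0, 0, 80], [10, 0, 80], [20, 0, 80]):
            es = place(es, p)
        return es

    def test_roundtrip_identical(self, tmp_path):
        es = self._set()
        write_electrodes(tmp_path / "m.epf", es)
        back = read_electrodes(tmp_path / "m.epf")
        assert len(back) == 3
        assert back.labels == es.labels
        assert np.abs(back.positions - es.positions).max() <= 1e-6

    def test_hand_edited_coordinate_is_truth(self, tmp_path):
        es = self._set()
        path = tmp_path / "m.epf"
        write_electrodes(path, es)
        lines = path.read_text().splitlines()
        parts = lines[2].split("\t")  # electrode 2
        parts[2] = str(float(parts[2]) + 5.0)
        lines[2] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        back = read_electrodes(path)
        assert back[2].position[0] == pytest.approx(
            es[2].position[0] + 5.0, abs=1e-9)

    def test_empty_file_empty_set(self, tmp_path):
        (tmp_path / "e.epf").write_text("")
        assert len(read_electrodes(tmp_path / "e.epf")) == 0

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        (tmp_path / "b.epf").write_text("1\tA\t1.0\toops\t3.0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_electrodes(tmp_path / "b.epf")

    def test_duplicate_index_rejected(self, tmp_path):
        (tmp_path / "d.epf").write_text(
            "1\tA\t0\t0\t0\n1\tB\t1\t1\t1\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_electrodes(tmp_path / "d.epf")


class TestCameraFile:
    def test_roundtrip_identical(self, tmp_path):
        cam = Camera(position=[10, -20, 400], focal_point=[1, 2, 3],
                     view_up=[0, 1, 1], view_angle=25.0, rotation=12.5)
        write_camera(tmp_path / "v.cpf", cam)
        back = read_camera(tmp_path / "v.cpf")
        for attr in ("position", "focal_point", "view_up"):
            assert np.abs(getattr(back, attr)
                          - getattr(cam, attr)).max() <= 1e-6
        assert back.view_angle == pytest.approx(cam.view_angle, abs=1e-6)
        assert back.rotation == pytest.approx(cam.rotation, abs=1e-6)
        assert back.distance == pytest.approx(cam.distance, abs=1e-6)

    def test_missing_key_named(self, tmp_path):
        cam = preset_camera("left")
        write_camera(tmp_path / "v.cpf", cam)
        text = "\n".join(l for l in (tmp_path / "v.cpf").read_text()
                         .splitlines() if not l.startswith("view_angle"))
        (tmp_path / "m.cpf").write_text(text + "\n")
        with pytest.raises(ParseError, match="view_angle"):
            read_camera(tmp_path / "m.cpf")

    def test_inconsistent_distance_rejected(self, tmp_path):
        cam = preset_camera("left")
        write_camera(tmp_path / "v.cpf", cam)
        text = (tmp_path / "v.cpf").read_text().replace(
            "distance\t400", "distance\t390")
        (tmp_path / "b.cpf").write_text(text)
        with pytest.raises(ValidationError, match="distance"):
            read_camera(tmp_path / "b.cpf")

    @pytest.mark.parametrize("stored,expected", [(360.0, 0.0),
                                                 (450.0, 90.0),
                                                 (-90.0, 270.0)])
    def test_rotation_normalized_modulo_360(self, tmp_path, stored,
                                            expected):
        cam = preset_camera("left")
        write_camera(tmp_path / "v.cpf", cam)
        text = (tmp_path / "v.cpf").read_text().replace(
            "rotation\t0", f"rotation\t{stored:g}")
        (tmp_path / "r.cpf").write_text(text)
        assert read_camera(tmp_path / "r.cpf").rotation == pytest.approx(
            expected)


class TestTables:
    def test_params_shape(self, tmp_path):
        write_table(tmp_path / "p.txt", np.arange(8.0).reshape(2, 4))
        t = read_table(tmp_path / "p.txt", kind="params")
        assert (t.m, t.n) == (2, 4)

    def test_nonsquare_matrix_rejected(self, tmp_path):
        write_table(tmp_path / "p.txt", np.arange(8.0).reshape(2, 4))
        with pytest.raises(ShapeError):
            read_table(tmp_path / "p.txt", kind="matrix")

    def test_plv_matrix_roundtrip(self, tmp_path, rng):
        c = rng.random((64, 64))
        c = 0.5 * (c + c.T)
        write_table(tmp_path / "c.txt", CorrTable(values=c))
        back = read_table(tmp_path / "c.txt", kind="matrix")
        assert np.abs(back.values - c).max() <= 1e-9

    def test_ragged_rows_name_row(self, tmp_path):
        (tmp_path / "r.txt").write_text("1\t2\t3\n1\t2\n")
        with pytest.raises(ParseError, match="line 2"):
            read_table(tmp_path / "r.txt")

    def test_symmetrization_is_idempotent(self, rng):
        c = rng.random((5, 5))  # asymmetric on purpose
        once = CorrTable(values=c).values
        twice = CorrTable(values=once).values
        assert np.array_equal(once, twice)


class TestAsciiByteStability:
    """write(read(f)) reproduces f byte for byte for every ASCII format."""

    def test_all_ascii_formats(self, tmp_path, rng, montage):
        write_electrodes(tmp_path / "m.epf", montage)
        write_camera(tmp_path / "v.cpf", preset_camera("anterior"))
        write_table(tmp_path / "p.txt", rng.normal(size=(3, 7)))
        c = rng.random((5, 5))
        write_table(tmp_path / "c.txt", CorrTable(values=0.5 * (c + c.T)))
        readers = {"m.epf": (read_electrodes, write_electrodes),
                   "v.cpf": (read_camera, write_camera),
                   "p.txt": (lambda p: read_table(p, "params"), write_table),
                   "c.txt": (lambda p: read_table(p, "matrix"), write_table)}
        for name, (reader, writer) in readers.items():
            obj = reader(tmp_path / name)
            writer(tmp_path / ("re_" + name), obj)
            assert (tmp_path / name).read_bytes() == \
                (tmp_path / ("re_" + name)).read_bytes(), name


class TestImportCoordinates:
    def test_identity_keeps_positions(self, rng):
        xyz = rng.normal(size=(5, 3))
        es = import_coordinates(xyz, transform=np.eye(4))
        assert np.abs(es.positions - xyz).max() <= 1e-12
        assert es.labels == ["1", "2", "3", "4", "5"]

    def test_translation(self, rng):
        xyz = rng.normal(size=(4, 3))
        tr = np.eye(4)
        tr[0, 3] = 10.0
        es = import_coordinates(xyz, transform=tr)
        assert np.allclose(es.positions, xyz + [10, 0, 0])

    def test_rotation_90deg_about_z(self):
        tr = np.eye(4)
        tr[:2, :2] = [[0, -1], [1, 0]]
        es = import_coordinates([[1.0, 0, 0]], transform=tr)
        assert np.abs(es.positions[0] - [0, 1, 0]).max() <= 1e-9

    def test_singular_transform_rejected(self):
        with pytest.raises(ValidationError, match="singular"):
            import_coordinates([[1.0, 2, 3]], transform=np.zeros((4, 4)))
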