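"""model_io: formats, round trips, selections, hinge group auto-build."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hingedyn.hinge_model import embed_series
from hingedyn.model_io import (
    CVSeries,
    FileFormatError,
    Hill,
    PDBParseError,
    SelectionError,
    StructureError,
    Topology,
    Trajectory,
    read_colvar,
    read_hills,
    read_pdb,
    read_xyzt,
    resolve_selection,
    write_colvar,
    write_hills,
    write_pdb,
    write_xyzt,
)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
                   width=64)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _write_simple_pdb(path, models):
    """models: list of lists of (x, y, z) in Angstrom for 3 fixed atoms."""
    lines = []
    for m, coords in enumerate(models, start=1):
        if len(models) > 1:
            lines.append(f"MODEL     {m}")
        for i, (x, y, z) in enumerate(coords, start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        if len(models) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def test_pdb_angstrom_to_nm_conversion(tmp_path):
    p = tmp_path / "one.pdb"
    _write_simple_pdb(p, [[(0, 0, 0), (10, 0, 0), (0, 10, 0)]])
    traj = read_pdb(str(p))
    assert traj.n_frames == 1
    np.testing.assert_allclose(
        traj.coords[0], [[0, 0, 0], [1, 0, 0], [0, 1, 0]], atol=1e-12
    )


def test_pdb_multimodel_default_times(tmp_path):
    p = tmp_path / "two.pdb"
    coords = [(0, 0, 0), (1, 2, 3), (4, 5, 6)]
    _write_simple_pdb(p, [coords, coords])
    traj = read_pdb(str(p))
    assert traj.n_frames == 2
    np.testing.assert_array_equal(traj.times, [0.0, 1.0])


def test_pdb_malformed_coordinate_names_line(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text(
        "ATOM      1  CA  GLY A   1         x   0.000   0.000"
        "  1.00  0.00           C\n"
    )
    with pytest.raises(PDBParseError, match=":1:"):
        read_pdb(str(p))


def test_pdb_inconsistent_model_sizes(tmp_path):
    p = tmp_path / "ragged.pdb"
    text = ["MODEL     1"]
    for i in range(3):
        text.append(
            f"ATOM  {i+1:5d}  CA  GLY A{i+1:4d}    "
            f"{0.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
        )
    text += ["ENDMDL", "MODEL     2",
             text[1], "ENDMDL", "END"]
    p.write_text("\n".join(text) + "\n")
    with pytest.raises(StructureError, match="inconsistent atom count"):
        read_pdb(str(p))


def test_hinge_pdb_auto_groups(tmp_path):
    """A dimeric hinge PDB gets the standard groups; 4 cluster sulfurs."""
    series = CVSeries(names=["theta", "ww"], units=["deg", "nm"],
                      times=[0.0], values=[[95.0, 1.4]])
    traj = embed_series(series)
    p = tmp_path / "hinge.pdb"
    write_pdb(traj, str(p))
    back = read_pdb(str(p))
    # independent scan: count SG atoms of first/last residue in both chains
    expected = sum(
        1 for a in back.topology.atoms
        if a.name == "SG" and a.res_id in (1, 12)
    )
    assert expected == 4
    assert len(back.topology.groups["sulfur_cluster"]) == 4
    assert len(back.topology.groups["trpA"]) == 1
    assert len(back.topology.groups["c5c8_B"]) == 2


def test_pdb_round_trip_quantized(tmp_path, hinge_traj):
    """Write -> read reproduces coordinates at PDB precision (1e-4 nm)."""
    p = tmp_path / "rt.pdb"
    write_pdb(hinge_traj, str(p))
    back = read_pdb(str(p))
    assert back.n_frames == hinge_traj.n_frames
    np.testing.assert_allclose(back.coords, hinge_traj.coords, atol=5.1e-5)
    # a second round trip is exact: values are already on the grid
    p2 = tmp_path / "rt2.pdb"
    write_pdb(back, str(p2))
    again = read_pdb(str(p2))
    np.testing.assert_array_equal(again.coords, back.coords)


def test_xyzt_round_trip(tmp_path, hinge_traj):
    p = tmp_path / "traj.xyzt"
    write_xyzt(hinge_traj, str(p))
    back = read_xyzt(str(p), hinge_traj.topology)
    # %.9g keeps 9 significant digits: half-ulp relative error 5e-9
    np.testing.assert_allclose(back.coords, hinge_traj.coords, rtol=5e-9,
                               atol=1e-12)
    np.testing.assert_allclose(back.times, hinge_traj.times, rtol=5e-9)


# ---------------------------------------------------------------------------
# COLVAR
# ---------------------------------------------------------------------------

def test_colvar_basic_parse(tmp_path):
    p = tmp_path / "COLVAR"
    p.write_text("#! FIELDS time d\n0.0 1.5\n1.0 2.0\n")
    series = read_colvar(str(p))
    assert series.names == ["d"]
    assert series.n_rows == 2
    np.testing.assert_array_equal(series.values[:, 0], [1.5, 2.0])


def test_colvar_header_only_is_empty_series(tmp_path):
    p = tmp_path / "COLVAR"
    p.write_text("#! FIELDS time d\n")
    series = read_colvar(str(p))
    assert series.n_rows == 0


def test_colvar_missing_header(tmp_path):
    p = tmp_path / "COLVAR"
    p.write_text("0.0 1.5\n")
    with pytest.raises(FileFormatError, match="FIELDS"):
        read_colvar(str(p))


def test_colvar_ragged_row_names_line(tmp_path):
    p = tmp_path / "COLVAR"
    p.write_text("#! FIELDS time d\n0.0 1.5\n1.0 2.0 99\n")
    with pytest.raises(FileFormatError, match=":3:"):
        read_colvar(str(p))


@settings(max_examples=100, deadline=None)
@given(
    data=st.lists(st.tuples(finite, finite), min_size=0, max_size=20),
)
def test_colvar_round_trip_property(tmp_path_factory, data):
    """write -> read is value-identical at the written (9 sig-fig) precision."""
    tmp = tmp_path_factory.mktemp("colvar")
    times = np.arange(len(data), dtype=float)
    values = np.array(data, dtype=float).reshape(len(data), 2)
    series = CVSeries(names=["a", "b"], units=["nm", "deg"],
                      times=times, values=values)
    path = str(tmp / "COLVAR")
    write_colvar(series, path)
    back = read_colvar(path)
    assert back.names == series.names
    assert back.units == series.units
    # %.9g keeps >= 9 significant digits: round trip through text is exact
    # for values that were themselves printed with %.9g
    expected = np.array([[float(f"{v:.9g}") for v in row] for row in values]
                        ).reshape(len(data), 2)
    np.testing.assert_array_equal(back.values, expected)


# ---------------------------------------------------------------------------
# HILLS
# ---------------------------------------------------------------------------

def test_hills_single_row_parse(tmp_path):
    p = tmp_path / "HILLS"
    p.write_text("#! FIELDS time d sigma_d height biasf\n1.0 2.3 0.05 0.2 10\n")
    hills = read_hills(str(p))
    assert len(hills) == 1
    h = hills[0]
    assert h.time == 1.0 and h.centers == (2.3,) and h.widths == (0.05,)
    assert h.height == 0.2 and h.bias_factor == 10


def test_hills_empty_gives_zero_bias(tmp_path):
    from hingedyn.metadynamics import BiasState, MetadParams

    p = tmp_path / "HILLS"
    p.write_text("#! FIELDS time d sigma_d height biasf\n")
    hills = read_hills(str(p))
    assert hills == []
    state = BiasState(params=MetadParams(), cv_names=["d"], cv_units=["nm"],
                      hills=hills)
    assert state.value([1.23]) == 0.0


def test_hills_invalid_row_reports_position(tmp_path):
    p = tmp_path / "HILLS"
    p.write_text("#! FIELDS time d sigma_d height biasf\n"
                 "1.0 2.3 0.05 0.2 10\n"
                 "2.0 2.3 -0.05 0.2 10\n")
    with pytest.raises(FileFormatError, match="row 2"):
        read_hills(str(p))


def test_hills_bulk_round_trip_and_height_sum(tmp_path, rng):
    n = 1000
    hills = [
        Hill(time=float(i + 1),
             centers=(float(rng.uniform(0, 3)),),
             widths=(0.05,),
             height=float(rng.uniform(0, 0.2)),
             bias_factor=10.0)
        for i in range(n)
    ]
    p = tmp_path / "HILLS"
    write_hills(hills, str(p), ["ww"])
    back = read_hills(str(p))
    assert len(back) == n
    # independent oracle: plain text column sum
    text_sum = sum(
        float(line.split()[3])
        for line in p.read_text().splitlines()
        if not line.startswith("#")
    )
    assert np.isclose(sum(h.height for h in back), text_sum, rtol=1e-12)
    for a, b in zip(hills, back):
        assert b.centers[0] == float(f"{a.centers[0]:.9g}")
        assert b.height == float(f"{a.height:.9g}")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def test_selection_single_atom(hinge_top):
    idx = resolve_selection(hinge_top, "chain A and resid 7 and name CA")
    assert len(idx) == 1
    atom = hinge_top.atoms[idx[0]]
    assert (atom.chain_id, atom.res_id, atom.name) == ("A", 7, "CA")


def test_selection_resname_glycine(hinge_top):
    idx = resolve_selection(hinge_top, "resname GLY")
    assert {hinge_top.atoms[i].res_id for i in idx} == {7}
    assert {hinge_top.atoms[i].chain_id for i in idx} == {"A", "B"}


def test_selection_or_and_parentheses(hinge_top):
    idx = resolve_selection(
        hinge_top, "(chain A or chain B) and resid 3 and name CB"
    )
    assert len(idx) == 2


def test_selection_empty_is_error(hinge_top):
    with pytest.raises(SelectionError, match="matches no atoms"):
        resolve_selection(hinge_top, "name ZZ")


def test_selection_syntax_error_reports_position(hinge_top):
    with pytest.raises(SelectionError, match="position"):
        resolve_selection(hinge_top, "chain A and")
    with pytest.raises(SelectionError):
        resolve_selection(hinge_top, "frobnicate X")


def test_selection_order_preserving_and_deterministic(hinge_top):
    a = resolve_selection(hinge_top, "name CA")
    b = resolve_selection(hinge_top, "name CA")
    assert a == b == sorted(a)


# ---------------------------------------------------------------------------
# invariants of the domain types
# ---------------------------------------------------------------------------

def test_trajectory_rejects_time_disorder(hinge_top, hinge_frame):
    with pytest.raises(StructureError, match="strictly increasing"):
        Trajectory(topology=hinge_top,
                   coords=np.stack([hinge_frame, hinge_frame]),
                   times=np.array([1.0, 1.0]))


def test_topology_group_validation(toy_topology):
    with pytest.raises(StructureError, match="duplicate"):
        Topology(atoms=toy_topology.atoms, groups={"g": [0, 0]})
    with pytest.raises(StructureError, match="out-of-range"):
        Topology(atoms=toy_topology.atoms, groups={"g": [99]})


def test_hill_validation():
    with pytest.raises(ValueError):
        Hill(time=0.0, centers=(1.0,), widths=(0.0,), height=0.1,
             bias_factor=10.0)
    with pytest.raises(ValueError):
        Hill(time=0.0, centers=(1.0,), widths=(0.1,), height=-0.1,
             bias_factor=10.0)
    with pytest.raises(ValueError):
        Hill(time=0.0, centers=(1.0,), widths=(0.1,), height=0.1,
             bias_factor=1.0)


def test_group_autobuild_is_pure_function_of_topology(tmp_path):
    series = CVSeries(names=["theta", "ww"], units=["deg", "nm"],
                      times=[0.0], values=[[80.0, 1.2]])
    traj = embed_series(series)
    p = tmp_path / "hinge.pdb"
    write_pdb(traj, str(p))
    g1 = read_pdb(str(p)).topology.groups
    g2 = read_pdb(str(p)).topology.groups
    assert g1 == g2
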