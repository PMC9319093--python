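"""Activation-state geometry: PDB I/O, lock/cage/TM3–TM6, superposition."""

import math

import numpy as np
import pytest

from gpcrstars import geometry
from gpcrstars.numbering import AnchorSet, ResidueID, SegmentSpan, build_numbering
from gpcrstars.structure import PDBFormatError, Structure, read_pdb, write_pdb

RNG = np.random.default_rng(2024)


# ----- helpers ------------------------------------------------------------


def _pdb_line(serial, name, resname, resseq, x, y, z, altloc=" ", occ=1.0, chain="A"):
    element = name.strip()[0]
    return (
        f"ATOM  {serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2}"
    )


def make_lock_pair(arg_atoms, ser_atoms):
    """Structure with a minimal Arg(3.50)/Ser(6.33) pair at seqnums 119/230."""
    anchors = AnchorSet((SegmentSpan(3, 110, 125, 119), SegmentSpan(6, 225, 247, 247)))
    nmap = build_numbering(anchors)
    s = Structure(numbering=nmap)
    for name, coord in arg_atoms.items():
        element = "H" if name.startswith("H") else name[0]
        s.add_atom(ResidueID("A", 119), "ARG", name, coord, element)
    for name, coord in ser_atoms.items():
        s.add_atom(ResidueID("A", 230), "SER", name, coord, name[0])
    return s, nmap


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def horn_quaternion_rmsd(P, Q):
    """Independent superposition oracle: Horn's closed-form quaternion method."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx = P.T @ Q
    N = np.array(
        [
            [Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2], Sxx[1, 2] - Sxx[2, 1], Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] - Sxx[1, 0]],
            [Sxx[1, 2] - Sxx[2, 1], Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2], Sxx[0, 1] + Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2]],
            [Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] + Sxx[1, 0], -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2], Sxx[1, 2] + Sxx[2, 1]],
            [Sxx[0, 1] - Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2], Sxx[1, 2] + Sxx[2, 1], -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]],
        ]
    )
    _, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, -1]  # eigenvector of the largest eigenvalue
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return math.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))


# ----- PDB I/O ------------------------------------------------------------


def test_read_two_residue_pdb(tmp_path):
    lines = [
        _pdb_line(1, "N", "ALA", 1, 0.0, 0.0, 0.0),
        _pdb_line(2, "CA", "ALA", 1, 1.5, 0.0, 0.0),
        _pdb_line(3, "CA", "GLY", 2, 4.5, 0.0, 0.0),
        "END",
    ]
    p = tmp_path / "two.pdb"
    p.write_text("\n".join(lines) + "\n")
    s = read_pdb(p)
    assert len(s) == 2
    np.testing.assert_allclose(s.coord(ResidueID("A", 1), "CA"), [1.5, 0, 0])


def test_multi_model_read(tmp_path):
    body = []
    for m in range(1, 4):
        body.append(f"MODEL     {m:>4}")
        body.append(_pdb_line(1, "CA", "ALA", 1, float(m), 0.0, 0.0))
        body.append("ENDMDL")
    p = tmp_path / "traj.pdb"
    p.write_text("\n".join(body) + "\n")
    frames = read_pdb(p)
    assert isinstance(frames, list) and len(frames) == 3
    assert frames[0].same_topology(frames[2])
    assert frames[2].coord(ResidueID("A", 1), "CA")[0] == pytest.approx(3.0)


def test_altloc_highest_occupancy_kept(tmp_path):
    lines = [
        _pdb_line(1, "CA", "SER", 1, 0.0, 0.0, 0.0, altloc="A", occ=0.4),
        _pdb_line(2, "CA", "SER", 1, 9.0, 0.0, 0.0, altloc="B", occ=0.6),
        "END",
    ]
    p = tmp_path / "alt.pdb"
    p.write_text("\n".join(lines) + "\n")
    s = read_pdb(p)
    assert s.coord(ResidueID("A", 1), "CA")[0] == pytest.approx(9.0)


def test_malformed_atom_line_reports_line_number(tmp_path):
    lines = [
        _pdb_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0),
        "ATOM      2  CA  ALA A   2      bad_x   0.000   0.000  1.00  0.00           C",
    ]
    p = tmp_path / "bad.pdb"
    p.write_text("\n".join(lines) + "\n")
    with pytest.raises(PDBFormatError, match="line 2"):
        read_pdb(p)


def test_empty_pdb_rejected(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("REMARK nothing here\n")
    with pytest.raises(PDBFormatError, match="no ATOM"):
        read_pdb(p)


def test_coordinates_match_reference_parser(tmp_path, default_bundle):
    """Round-tripped coordinates agree with Biopython's independent parser."""
    from Bio.PDB import PDBParser

    structure, _ = default_bundle
    p = tmp_path / "bundle.pdb"
    write_pdb(p, structure)
    ours = read_pdb(p)
    ref = PDBParser(QUIET=True).get_structure("b", str(p))
    ref_atoms = {
        (res.id[1], atom.get_name()): atom.coord
        for res in ref[0]["A"]
        for atom in res
    }
    count = 0
    for rid, _res, atom in ours.iter_atoms():
        np.testing.assert_allclose(atom.coord, ref_atoms[(rid.seqnum, atom.name)], atol=1e-3)
        count += 1
    assert count == len(ref_atoms)


# ----- ionic lock ---------------------------------------------------------


def test_lock_constructed_distance():
    s, nmap = make_lock_pair(
        {"CA": (6, 0, 0), "NE": (3.0, 0, 0), "HE": (2.0, 0, 0)},
        {"CA": (-2.4, 0, 0), "OG": (0, 0, 0)},
    )
    lock = geometry.ionic_lock(s, nmap, ser="6.33")
    assert lock.h_distance == pytest.approx(2.0)
    assert lock.no_distance == pytest.approx(3.0)
    assert lock.nho_angle == pytest.approx(180.0)  # collinear N–H–O


def test_lock_without_hydrogens_degrades_to_heavy_atoms():
    s, nmap = make_lock_pair(
        {"CA": (6, 0, 0), "NE": (3.2, 0, 0), "NH1": (4.0, 1.0, 0)},
        {"CA": (-2.4, 0, 0), "OG": (0, 0, 0)},
    )
    lock = geometry.ionic_lock(s, nmap, ser="6.33")
    assert not lock.has_hydrogens
    assert lock.h_distance is None
    assert lock.distance == pytest.approx(3.2)


def test_lock_missing_og_raises():
    s, nmap = make_lock_pair(
        {"CA": (6, 0, 0), "NE": (3, 0, 0)}, {"CA": (-2.4, 0, 0)}
    )
    with pytest.raises(KeyError, match="OG"):
        geometry.ionic_lock(s, nmap, ser="6.33")


def test_lock_minimum_over_random_poses():
    """h_distance equals the exhaustive min over all H×O pairs."""
    h_names = ["HE", "HH11", "HH12", "HH21", "HH22"]
    parents = {"HE": "NE", "HH11": "NH1", "HH12": "NH1", "HH21": "NH2", "HH22": "NH2"}
    for _ in range(25):
        arg = {"CA": RNG.uniform(-1, 1, 3) + [8, 0, 0]}
        for n in ("NE", "NH1", "NH2"):
            arg[n] = RNG.uniform(2, 6, 3)
        for h in h_names:
            arg[h] = arg[parents[h]] + RNG.normal(0, 0.7, 3)
        ser = {"CA": np.array([-2.4, 0, 0]), "OG": RNG.uniform(-1, 1, 3)}
        s, nmap = make_lock_pair(arg, ser)
        lock = geometry.ionic_lock(s, nmap, ser="6.33")
        brute = min(np.linalg.norm(arg[h] - ser["OG"]) for h in h_names)
        assert lock.h_distance == pytest.approx(brute, abs=1e-12)
        for h in h_names:  # min property
            assert lock.h_distance <= np.linalg.norm(arg[h] - ser["OG"]) + 1e-12


# ----- aspartate cage -----------------------------------------------------


def _cage_structure(arg_atoms, asp_atoms):
    anchors = AnchorSet((SegmentSpan(3, 110, 125, 119),))
    nmap = build_numbering(anchors)
    s = Structure(numbering=nmap)
    for name, coord in arg_atoms.items():
        s.add_atom(ResidueID("A", 119), "ARG", name, coord, name[0])
    for name, coord in asp_atoms.items():
        s.add_atom(ResidueID("A", 118), "ASP", name, coord, name[0])
    return s, nmap


def test_cage_constructed_minimum():
    s, nmap = _cage_structure(
        {"NH1": (0, 0, 0), "NE": (0, 0, -3), "NH2": (2, 2, 0)},
        {"OD1": (0, 0, 2.8), "OD2": (0, 0, 5)},
    )
    d, bridge = geometry.aspartate_cage(s, nmap)
    assert d == pytest.approx(2.8)
    assert bridge  # within the 4.0 Å salt-bridge convention


def test_cage_label_swap_symmetric():
    atoms_a = {"OD1": (0, 0, 2.8), "OD2": (0, 0, 5)}
    atoms_b = {"OD2": (0, 0, 2.8), "OD1": (0, 0, 5)}
    arg = {"NH1": (0, 0, 0), "NE": (0, 1, -3)}
    d1, _ = geometry.aspartate_cage(*_cage_structure(arg, atoms_a))
    d2, _ = geometry.aspartate_cage(*_cage_structure(arg, atoms_b))
    assert d1 == d2


def test_cage_beyond_threshold_not_bridge():
    s, nmap = _cage_structure({"NH1": (0, 0, 0)}, {"OD1": (0, 0, 4.5)})
    d, bridge = geometry.aspartate_cage(s, nmap)
    assert d == pytest.approx(4.5) and not bridge


def test_cage_missing_heteroatoms_raise():
    s, nmap = _cage_structure({"CA": (0, 0, 0)}, {"OD1": (0, 0, 2)})
    with pytest.raises(KeyError, match="nitrogen"):
        geometry.aspartate_cage(s, nmap)


# ----- TM3–TM6 distance ---------------------------------------------------


def _stub_helices(d):
    """Two parallel 5-residue Cα stubs separated by exactly d in x."""
    anchors = AnchorSet((SegmentSpan(3, 118, 124, 119), SegmentSpan(6, 227, 247, 247)))
    nmap = build_numbering(anchors)
    s = Structure(numbering=nmap)
    for i, seq in enumerate(range(120, 125)):  # 3.51..3.55 going down
        s.add_atom(ResidueID("A", seq), "ALA", "CA", (0.0, 0.0, -1.5 * i), "C")
    for i, seq in enumerate(range(227, 232)):  # 6.30..6.34 going up
        s.add_atom(ResidueID("A", seq), "ALA", "CA", (d, 0.0, -1.5 * (4 - i)), "C")
    return s, nmap


@pytest.mark.parametrize("mode", ["paired", "index", "all-pairs"])
def test_constant_separation_any_mode(mode):
    s, nmap = _stub_helices(11.0)
    if mode == "paired":
        expected = 11.0  # ends aligned: every pair is exactly d apart
        assert geometry.tm3_tm6_distance(s, nmap, mode=mode) == pytest.approx(expected)
    else:
        assert geometry.tm3_tm6_distance(s, nmap, mode=mode) >= 11.0


def test_all_pairs_matches_exhaustive_mean():
    s, nmap = _stub_helices(9.0)
    p3 = np.array([s.coord(nmap.lookup(f"3.5{i}"), "CA") for i in range(1, 6)])
    p6 = np.array([s.coord(nmap.lookup(f"6.3{i}"), "CA") for i in range(0, 5)])
    brute = np.mean([np.linalg.norm(a - b) for a in p3 for b in p6])
    assert geometry.tm3_tm6_distance(s, nmap, mode="all-pairs") == pytest.approx(brute)


def test_all_pairs_bounded_by_extremes():
    s, nmap = _stub_helices(9.0)
    p3 = np.array([s.coord(nmap.lookup(f"3.5{i}"), "CA") for i in range(1, 6)])
    p6 = np.array([s.coord(nmap.lookup(f"6.3{i}"), "CA") for i in range(0, 5)])
    dists = [np.linalg.norm(a - b) for a in p3 for b in p6]
    ap = geometry.tm3_tm6_distance(s, nmap, mode="all-pairs")
    assert min(dists) <= ap <= max(dists)


def test_missing_ca_names_generic_number():
    s, nmap = _stub_helices(9.0)
    del s.residues[ResidueID("A", 229)].atoms["CA"]  # 6.32
    with pytest.raises(KeyError, match="6.32"):
        geometry.tm3_tm6_distance(s, nmap)


# ----- state classification ----------------------------------------------


@pytest.mark.parametrize(
    "distance,label",
    [
        (10.0, "inactive"),
        (11.0, "inactive"),
        (12.0, "inactive"),
        (13.0, "intermediate-ambiguous"),
        (14.0, "active"),
        (15.28, "active"),
        (15.97, "active"),
    ],
)
def test_state_labels(distance, label):
    assert geometry.classify_state(distance) == label


def test_state_monotone():
    order = {"inactive": 0, "intermediate-ambiguous": 1, "active": 2}
    grid = np.linspace(5, 20, 200)
    labels = [order[geometry.classify_state(d)] for d in grid]
    assert all(b >= a for a, b in zip(labels, labels[1:]))


# ----- superposition ------------------------------------------------------


def test_self_superposition_zero(default_bundle):
    structure, _ = default_bundle
    _, _, value = geometry.superpose(structure, structure)
    assert value == pytest.approx(0.0, abs=1e-10)


def test_rigid_motion_removed(default_bundle):
    structure, _ = default_bundle
    R = random_rotation(RNG)
    t = RNG.uniform(-20, 20, 3)
    moved = structure.transformed(R, t)
    Rfit, tfit, value = geometry.superpose(moved, structure)
    assert value == pytest.approx(0.0, abs=1e-8)
    assert np.linalg.det(Rfit) == pytest.approx(1.0)


def test_random_point_sets_match_quaternion_oracle():
    for _ in range(20):
        n = int(RNG.integers(4, 60))
        P = RNG.normal(scale=5.0, size=(n, 3))
        Q = RNG.normal(scale=5.0, size=(n, 3))
        _, _, value = geometry.kabsch(P, Q)
        assert value == pytest.approx(horn_quaternion_rmsd(P, Q), abs=1e-8)


def test_kabsch_input_validation():
    with pytest.raises(ValueError, match="at least 3"):
        geometry.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(ValueError, match="degenerate"):
        geometry.kabsch(line, line)


def test_metrics_invariant_under_rigid_motion(default_bundle):
    structure, nmap = default_bundle
    R = random_rotation(RNG)
    t = RNG.uniform(-30, 30, 3)
    moved = structure.transformed(R, t)
    assert geometry.tm3_tm6_distance(moved, nmap) == pytest.approx(
        geometry.tm3_tm6_distance(structure, nmap), abs=1e-9
    )
    assert geometry.ionic_lock(moved, nmap).h_distance == pytest.approx(
        geometry.ionic_lock(structure, nmap).h_distance, abs=1e-9
    )
    assert geometry.aspartate_cage(moved, nmap)[0] == pytest.approx(
        geometry.aspartate_cage(structure, nmap)[0], abs=1e-9
    )
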