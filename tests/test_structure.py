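"""Structure parsing, surface areas and relative exposure."""

import math

import numpy as np
import pytest

from fviiirin import (GeneratorSpec, StructureError, compute_surface_area,
                      generate_structure, load_reference_areas, load_structure,
                      relative_exposure)
from fviiirin.structure import (AtomRecord, ResidueKey, Structure, atom_radius,
                                classify_chain_part)
from oracles import shrake_rupley_oracle


def _tiny_pdb(tmp_path, extra_lines=()):
    spec = GeneratorSpec(seed=3, n_residues=5)
    _, text = generate_structure(spec)
    lines = text.strip().splitlines()
    body, end = lines[:-1], lines[-1]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(body + list(extra_lines) + [end]) + "\n")
    return path


class TestLoadStructure:
    def test_fixture_round_trip(self, tmp_path):
        path = _tiny_pdb(tmp_path)
        s = load_structure(path)
        assert len(s) == 5
        for key, atoms in s.residues.items():
            assert any(a.name == "CA" for a in atoms)

    def test_hetero_and_water_records_dropped(self, tmp_path):
        extra = [
            "HETATM 9991  O   HOH A 900      10.000  10.000  10.000  1.00  0.00           O",
            "HETATM 9992  C1  NAG A 901      12.000  12.000  12.000  1.00  0.00           C",
        ]
        s = load_structure(_tiny_pdb(tmp_path, extra))
        assert len(s) == 5
        assert all(k.residue_type != "HOH" for k in s.residues)

    def test_residue_count_matches_independent_parser(self, helix_pdb_file):
        from Bio.PDB import PDBParser

        s = load_structure(helix_pdb_file)
        model = next(PDBParser(QUIET=True).get_structure(
            "x", str(helix_pdb_file)).get_models())
        n_ref = sum(1 for chain in model for res in chain
                    if not res.id[0].strip())
        assert len(s) == n_ref

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.40  0.00           C",
            "ATOM      3  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C",
            "ATOM      4  C   ALA A   1       2.009   1.421   0.000  1.00  0.00           C",
            "ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O",
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        s = load_structure(path)
        (key,) = s.residues
        ca = next(a for a in s.residues[key] if a.name == "CA")
        assert ca.coords[0] == pytest.approx(9.0)

    def test_empty_selection_raises(self, helix_pdb_file):
        with pytest.raises(StructureError, match="no protein residues"):
            load_structure(helix_pdb_file, chains=["Z"])

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a pdb file\n")
        with pytest.raises(StructureError):
            load_structure(bad)


class TestChainPartClassification:
    @pytest.mark.parametrize("name,element,expected", [
        ("N", "N", "main_chain"), ("CA", "C", "main_chain"),
        ("C", "C", "main_chain"), ("O", "O", "main_chain"),
        ("OXT", "O", "main_chain"), ("CB", "C", "side_chain"),
        ("OG", "O", "side_chain"), ("H", "H", "main_chain"),
        ("HA", "H", "main_chain"), ("HB2", "H", "side_chain"),
    ])
    def test_backbone_atoms_and_their_hydrogens(self, name, element, expected):
        assert classify_chain_part(name, element) == expected


def _single_residue_structure(restype="GLY"):
    spec = GeneratorSpec(seed=5, n_residues=3)
    s, _ = generate_structure(spec, residue_types=[restype] * 3)
    key = list(s.residues)[1]
    return Structure("single", {key: s.residues[key]})


class TestSurfaceArea:
    def test_free_residue_matches_shrake_rupley_oracle(self):
        s = _single_residue_structure("GLY")
        areas = compute_surface_area(s)
        atoms = s.heavy_atoms()
        coords = np.array([a.coords for a in atoms])
        radii = np.array([atom_radius(a.element) for a in atoms])
        expected = shrake_rupley_oracle(coords, radii).sum()
        assert sum(areas.values()) == pytest.approx(expected, rel=0.01)

    def test_residue_enclosed_by_shell_is_buried(self):
        # two concentric dense cages: every point of the residue's probe-
        # expanded surface sits within an occluding dummy-atom sphere
        s = _single_residue_structure("ALA")
        key = list(s.residues)[0]
        atoms = list(s.residues[key])
        center = np.array([a.coords for a in atoms]).mean(axis=0)

        def cage(radius, n, cage_key):
            out = []
            for i in range(n):
                golden = math.pi * (3 - math.sqrt(5))
                z = 1 - 2 * (i + 0.5) / n
                r = math.sqrt(max(0.0, 1 - z * z))
                p = center + radius * np.array(
                    [r * math.cos(golden * i), r * math.sin(golden * i), z])
                out.append(AtomRecord(
                    name="CA" if i == 0 else "X", element="C",
                    residue_key=cage_key, coords=tuple(p),
                    chain_part="main_chain" if i == 0 else "side_chain"))
            return out

        k1 = ResidueKey("S", 98, "", "GLY")
        k2 = ResidueKey("S", 99, "", "GLY")
        buried = Structure("buried", {key: atoms, k1: cage(5.5, 600, k1),
                                      k2: cage(7.5, 900, k2)})
        areas = compute_surface_area(buried)
        assert areas[key] < 1.0

    def test_identical_far_apart_residues_have_equal_areas(self):
        spec = GeneratorSpec(seed=5, n_residues=3)
        s, _ = generate_structure(spec, residue_types=["ALA"] * 3)
        key = list(s.residues)[1]
        atoms = s.residues[key]
        far_key = ResidueKey("B", 50, "", "ALA")
        far = [AtomRecord(a.name, a.element, far_key,
                          (a.coords[0] + 100, a.coords[1], a.coords[2]),
                          a.chain_part) for a in atoms]
        pair = Structure("pair", {key: list(atoms), far_key: far})
        areas = compute_surface_area(pair)
        assert areas[key] == pytest.approx(areas[far_key], rel=1e-9)

    def test_rigid_motion_changes_no_area_beyond_one_percent(self, helix30):
        s = helix30["structure"]
        base = compute_surface_area(s, sphere_points=1920)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]])
        moved = {}
        for key, atoms in s.residues.items():
            moved[key] = [AtomRecord(
                a.name, a.element, key,
                tuple(rot @ np.array(a.coords) + np.array([5.0, -3.0, 2.0])),
                a.chain_part) for a in atoms]
        rotated = Structure("rot", moved)
        after = compute_surface_area(rotated, sphere_points=1920)
        for key in base:
            assert after[key] == pytest.approx(base[key], rel=0.01, abs=0.5)

    def test_per_residue_areas_sum_to_structure_total(self, helix30):
        s = helix30["structure"]
        areas = compute_surface_area(s)
        atoms = s.heavy_atoms()
        coords = np.array([a.coords for a in atoms])
        radii = np.array([atom_radius(a.element) for a in atoms])
        total = shrake_rupley_oracle(coords, radii).sum()
        assert sum(areas.values()) == pytest.approx(total, rel=0.005)

    def test_probe_radius_must_be_positive(self, helix30):
        with pytest.raises(ValueError):
            compute_surface_area(helix30["structure"], probe_radius=0.0)


class TestRelativeExposure:
    def test_zero_area_gives_zero_ratio(self):
        key = ResidueKey("A", 1, "", "ALA")
        ref = load_reference_areas()
        assert relative_exposure({key: 0.0}, ref)[key] == 0.0

    def test_area_equal_to_reference_gives_ratio_one(self):
        key = ResidueKey("A", 1, "", "TRP")
        ref = load_reference_areas()
        out = relative_exposure({key: ref["TRP"]}, ref)
        assert out[key] == pytest.approx(1.0)

    def test_gly_x_gly_middle_residue_near_unity(self):
        spec = GeneratorSpec(seed=2, n_residues=3, fold="extended")
        s, _ = generate_structure(spec, residue_types=["GLY", "ALA", "GLY"])
        areas = compute_surface_area(s)
        rel = relative_exposure(areas, load_reference_areas())
        middle = list(s.residues)[1]
        assert 0.8 <= rel[middle] <= 1.2

    def test_scale_equivariance_in_numerator(self):
        keys = [ResidueKey("A", i, "", "LEU") for i in range(1, 4)]
        ref = load_reference_areas()
        areas = {k: 40.0 + 10 * i for i, k in enumerate(keys)}
        doubled = {k: 2 * v for k, v in areas.items()}
        r1 = relative_exposure(areas, ref)
        r2 = relative_exposure(doubled, ref)
        for k in keys:
            assert r2[k] == pytest.approx(2 * r1[k])

    def test_missing_reference_entry_names_the_type(self):
        key = ResidueKey("A", 1, "", "TRP")
        with pytest.raises(KeyError, match="TRP"):
            relative_exposure({key: 10.0}, {"ALA": 129.0})


def test_reference_table_has_twenty_positive_entries():
    ref = load_reference_areas()
    assert len(ref) == 20
    assert all(v > 0 for v in ref.values())
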