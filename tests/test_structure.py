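import numpy as np
import pytest

from kturn.core import Conformation
from kturn.structure import (
    Atom,
    ResidueMap,
    StructureError,
    StructureModel,
    check_wobble,
    classify_N3_N1,
    detect_sheared_GA,
    interhelical_angle,
    make_imino_ga_pair,
    make_sheared_ga_pair,
    make_synthetic_duplex_helix,
    make_synthetic_kturn_core,
    make_wobble_gu_pair,
    measure_distance,
    read_structure,
    _random_rotation,
)

# minimal two-residue coordinate file, PDB layout
MINI_PDB = """\
ATOM      1  P     G A   1       0.000   0.000   0.000  1.00  0.00           P
ATOM      2  C1'   G A   1       4.000   1.000   0.000  1.00  0.00           C
ATOM      3  N1    G A   1       5.500   2.000   1.000  1.00  0.00           N
ATOM      4  P     A A   2       3.000   4.000   0.000  1.00  0.00           P
ATOM      5  O2*   A A   2       6.000   5.000   2.000  1.00  0.00           O
END
"""

MINI_CIF = """\
data_mini
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.auth_asym_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.pdbx_PDB_model_num
ATOM 1 P P . G A 1 A 1 0.000 0.000 0.000 1.00 0.00 1
ATOM 2 C "C1'" . G A 1 A 1 4.000 1.000 0.000 1.00 0.00 1
ATOM 3 N N1 . G A 1 A 1 5.500 2.000 1.000 1.00 0.00 1
ATOM 4 P P . A A 2 A 2 3.000 4.000 0.000 1.00 0.00 1
ATOM 5 O "O2'" . A A 2 A 2 6.000 5.000 2.000 1.00 0.00 1
"""

ALTLOC_PDB = """\
ATOM      1  N1 A  G A   1     0.000   0.000   0.000  0.30  0.00           N
ATOM      2  N1 B  G A   1     1.000   0.000   0.000  0.70  0.00           N
END
"""


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINI_PDB)
        model = read_structure(path)
        assert len(model.residues()) == 2
        assert model.residue_name("A", 1) == "G"
        # star-prime normalization
        assert model.has_atom("A", 2, "O2'")

    def test_pdb_and_mmcif_agree(self, tmp_path):
        pdb = tmp_path / "m.pdb"
        cif = tmp_path / "m.cif"
        pdb.write_text(MINI_PDB)
        cif.write_text(MINI_CIF)
        m1 = read_structure(pdb)
        m2 = read_structure(cif)
        assert sorted(model_atoms(m1)) == sorted(model_atoms(m2))

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        with pytest.warns(UserWarning, match="occupancy"):
            model = read_structure(path)
        assert model.atom("A", 1, "N1").pos[0] == pytest.approx(1.0)

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(MINI_PDB)
        with pytest.raises(StructureError, match="format"):
            read_structure(path, fmt="xyz")


def model_atoms(model):
    return [
        (a.chain, a.resnum, a.name, round(a.pos[0], 3), round(a.pos[1], 3), round(a.pos[2], 3))
        for a in model.atoms
    ]


class TestMeasureDistance:
    def _model(self):
        return StructureModel(
            [
                Atom("P", "P", "G", "A", 1, (0.0, 0.0, 0.0)),
                Atom("O2'", "O", "G", "A", 1, (3.0, 4.0, 0.0)),
            ]
        )

    def test_identical_selectors_zero(self):
        m = self._model()
        assert measure_distance(m, (("A", 1), "P"), (("A", 1), "P")) == 0.0

    def test_pythagorean(self):
        m = self._model()
        assert measure_distance(m, (("A", 1), "P"), (("A", 1), "O2'")) == pytest.approx(5.0)

    def test_missing_atom_names_selector(self):
        m = self._model()
        with pytest.raises(StructureError, match="N7"):
            measure_distance(m, (("A", 1), "P"), (("A", 1), "N7"))

    def test_string_and_label_selectors(self):
        m = self._model()
        rmap = ResidueMap({"-1n": ("A", 1)})
        d1 = measure_distance(m, ("A/1", "P"), ("-1n", "O2'"), rmap)
        assert d1 == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, seed):
        m = self._model()
        rng = np.random.default_rng(seed)
        R = _random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = m.transformed(R, t)
        d0 = measure_distance(m, (("A", 1), "P"), (("A", 1), "O2'"))
        d1 = measure_distance(moved, (("A", 1), "P"), (("A", 1), "O2'"))
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestShearedGA:
    def test_idealized_sheared_pair_detected(self):
        m = make_sheared_ga_pair(h_bond=2.9)
        res = detect_sheared_GA(m, ("A", 2), ("A", 1))
        assert res["sheared"]
        assert res["d_GN2_AN7"] == pytest.approx(2.9)
        assert res["d_AN6_GN3"] == pytest.approx(2.9)

    def test_imino_geometry_rejected(self):
        res = detect_sheared_GA(make_imino_ga_pair(), ("A", 2), ("A", 1))
        assert not res["sheared"]
        assert res["d_GN2_AN7"] > 4.5

    def test_wrong_residue_type_rejected(self):
        m = make_sheared_ga_pair()
        with pytest.raises(StructureError, match="expected"):
            detect_sheared_GA(m, ("A", 1), ("A", 2))  # swapped: A fed as G


class TestWobble:
    def test_idealized_wobble_detected(self):
        res = check_wobble(make_wobble_gu_pair(), ("A", 1), ("A", 2))
        assert res["wobble"]
        assert res["d_GO6_UN3"] == pytest.approx(2.8)

    def test_wc_like_geometry_rejected(self):
        res = check_wobble(make_wobble_gu_pair(wobble=False), ("A", 1), ("A", 2))
        assert not res["wobble"]


class TestClassifyN3N1:
    @pytest.mark.parametrize("label", ["N3", "N1"])
    def test_forced_geometry_classified(self, label):
        model, rmap = make_synthetic_kturn_core(label, seed=123)
        report = classify_N3_N1(model, rmap)
        assert report.conformation is Conformation(label)
        # both tandem sheared pairs verified
        assert report.sheared["2b:2n"]["sheared"]
        assert report.sheared["1b:1n"]["sheared"]

    def test_n1_core_shows_lengthened_n6_n3(self):
        """The N1 conformation stretches A2b N6 - G2n N3 to ~5.3 A."""
        model, rmap = make_synthetic_kturn_core("N1", seed=9, jitter=0.0)
        report = classify_N3_N1(model, rmap)
        assert report.conformation is Conformation.N1
        assert report.distances["A2bN6-G2nN3"] == pytest.approx(5.3, abs=0.1)

    def test_explicit_acceptor_distances_decide(self):
        """O2' at 2.8 A from N3 and 4.8 A from N1 must classify N3."""
        model, rmap = make_synthetic_kturn_core("N3", seed=5, jitter=0.0)
        report = classify_N3_N1(model, rmap)
        d3 = report.distances["-1nO2'-A2bN3"]
        d1 = report.distances["-1nO2'-A2bN1"]
        assert d3 < 3.5 < d1
        assert report.conformation is Conformation.N3

    @pytest.mark.parametrize("seed", range(25))
    def test_label_recovery_on_random_geometries(self, seed):
        label = "N3" if seed % 2 == 0 else "N1"
        model, rmap = make_synthetic_kturn_core(label, seed=seed)
        assert classify_N3_N1(model, rmap).conformation is Conformation(label)

    def test_verdict_invariant_under_rigid_motion(self):
        model, rmap = make_synthetic_kturn_core("N1", seed=77)
        rng = np.random.default_rng(4)
        moved = model.transformed(_random_rotation(rng), rng.uniform(-100, 100, 3))
        assert classify_N3_N1(moved, rmap).conformation is Conformation.N1

    def test_missing_labels_give_unknown_with_reason(self):
        model, rmap = make_synthetic_kturn_core("N3", seed=1)
        partial = ResidueMap({k: v for k, v in rmap.entries.items() if k != "-1n"})
        report = classify_N3_N1(model, partial)
        assert report.conformation is Conformation.UNKNOWN
        assert any("-1n" in n for n in report.notes)

    def test_missing_atom_gives_unknown_not_exception(self):
        model, rmap = make_synthetic_kturn_core("N3", seed=2)
        stripped = StructureModel([a for a in model.atoms if a.name != "O2'" or a.chain != "N"])
        report = classify_N3_N1(stripped, rmap)
        assert report.conformation is Conformation.UNKNOWN
        assert report.notes


class TestInterhelicalAngle:
    def test_continuous_helix_split_nearly_collinear(self):
        model, pairs = make_synthetic_duplex_helix(12)
        angle = interhelical_angle(model, pairs[:6], pairs[6:])
        assert angle <= 15.0

    def test_perpendicular_helices(self):
        m1, p1 = make_synthetic_duplex_helix(8)
        m2, p2 = make_synthetic_duplex_helix(
            8, axis=[1, 0, 0], origin=[40, 0, 0], chain_ids=("C", "D"), resnum_start=50
        )
        merged = StructureModel(m1.atoms + m2.atoms)
        assert interhelical_angle(merged, p1, p2) == pytest.approx(90.0, abs=2.0)

    def test_helix_with_itself_zero(self):
        model, pairs = make_synthetic_duplex_helix(8)
        assert interhelical_angle(model, pairs, pairs) == pytest.approx(0.0, abs=1e-6)

    def test_too_few_pairs_rejected(self):
        model, pairs = make_synthetic_duplex_helix(8)
        with pytest.raises(StructureError, match=">= 3"):
            interhelical_angle(model, pairs[:2], pairs[2:])


def test_residue_map_tsv_round_trip(tmp_path):
    rmap = ResidueMap({"-1n": ("A", 14), "2b": ("B", 12), "L1": ("B", 11)})
    path = tmp_path / "map.tsv"
    rmap.to_tsv(path)
    assert ResidueMap.from_tsv(path).entries == rmap.entries
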