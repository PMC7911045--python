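"""Structure I/O, molecular weight, candidate filter and SASA."""

import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight as bio_mw
from hypothesis import given, settings, strategies as st

from scaffoldsmith.constants import MAX_ASA
from scaffoldsmith.errors import EmptyModelError, InputError, ParseError
from scaffoldsmith.fixtures import synthetic_structure
from scaffoldsmith.structure_model import (
    Atom, FilterCriteria, Residue, StructureModel, candidate_filter,
    compute_sasa, golden_spiral_points, molecular_weight, read_structure,
    relative_sasa, write_annotated_structure,
)
from conftest import point_model, single_atom_model


class TestReadStructure:
    def test_two_residue_fixture(self, gly_ala_pdb):
        model = read_structure(gly_ala_pdb)
        assert list(model.chains) == ["A"]
        assert model.sequence("A") == "GA"
        assert model.resolution == pytest.approx(1.8)

    def test_altloc_resolved_to_highest_occupancy(self, altloc_pdb):
        model = read_structure(altloc_pdb)
        cb = model.residues()[0].atom("CB")
        assert cb.coord[0] == pytest.approx(2.0)
        assert cb.occupancy == pytest.approx(0.60)

    def test_heterogens_inventoried_not_dropped(self, tmp_path):
        text = (tmp_path / "het.pdb")
        from conftest import GLY_ALA_PDB
        lines = GLY_ALA_PDB.splitlines()
        lines.insert(-2, "HETATM   10  O   HOH A 101      8.000   8.000"
                         "   8.000  1.00  0.00           O")
        text.write_text("\n".join(lines) + "\n")
        model = read_structure(text)
        assert model.sequence("A") == "GA"
        assert any("HOH" in h for h in model.heterogens)

    def test_unparseable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ParseError):
            read_structure(bad, format="mmcif")

    def test_no_polymer_residues_raises(self, tmp_path):
        p = tmp_path / "waters.pdb"
        p.write_text("HETATM    1  O   HOH A   1       0.000   0.000   0.000"
                     "  1.00  0.00           O\nEND\n")
        with pytest.raises(EmptyModelError):
            read_structure(p)

    def test_mmcif_roundtrip_matches_pdb(self, gly_ala_pdb, tmp_path):
        import gemmi
        st_ = gemmi.read_structure(str(gly_ala_pdb))
        st_.setup_entities()
        cif = tmp_path / "conv.cif"
        doc = st_.make_mmcif_document()
        doc.write_file(str(cif))
        assert read_structure(cif, format="mmcif").sequence("A") == "GA"


class TestMolecularWeight:
    def test_single_glycine(self):
        assert molecular_weight("G") == pytest.approx(0.0750672, abs=1e-6)

    def test_deca_alanine(self):
        assert molecular_weight("A" * 10) == pytest.approx(0.7288, abs=1e-4)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            molecular_weight("")

    def test_unknown_letter_rejected(self):
        with pytest.raises(InputError):
            molecular_weight("AB")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_agrees_with_biopython_average_weight(self, seq):
        ours = molecular_weight(seq) * 1000.0
        theirs = bio_mw(seq, seq_type="protein", monoisotopic=False)
        assert ours == pytest.approx(theirs, rel=1e-4)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=15),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=15))
    @settings(derandomize=True, max_examples=50)
    def test_additive_up_to_one_water(self, s1, s2):
        lhs = molecular_weight(s1 + s2)
        rhs = molecular_weight(s1) + molecular_weight(s2) - 18.0153 / 1000.0
        assert lhs == pytest.approx(rhs, abs=1e-9)


def _model_with(sequence, resolution=2.0, n_chains=1):
    chains = {}
    for c in range(n_chains):
        cid = chr(ord("A") + c)
        chains[cid] = [Residue(cid, i + 1, "", aa, [Atom("CA", "C", np.zeros(3))])
                       for i, aa in enumerate(sequence)]
    return StructureModel("T", chains, resolution=resolution)


class TestCandidateFilter:
    def test_good_candidate_passes(self):
        v = candidate_filter(_model_with("L" * 140, resolution=2.0))
        assert v.passed and v.reasons == []
        assert 10 <= v.metrics["molecular_weight_kda"] <= 25

    def test_overweight_fails_on_molecular_weight(self):
        v = candidate_filter(_model_with("L" * 270, resolution=2.0))
        assert not v.passed and "molecular_weight" in v.reasons

    def test_resolution_bound_is_strict(self):
        assert "resolution" in candidate_filter(_model_with("L" * 140, 3.5)).reasons
        assert "resolution" in candidate_filter(_model_with("L" * 140, 3.0)).reasons
        assert "resolution" not in candidate_filter(_model_with("L" * 140, 2.99)).reasons

    def test_missing_resolution_gets_distinct_label(self):
        v = candidate_filter(_model_with("L" * 140, resolution=None))
        assert "resolution_unknown" in v.reasons
        assert "resolution" not in v.reasons

    def test_multimer_fails_monomer_rule(self):
        v = candidate_filter(_model_with("L" * 70, resolution=2.0, n_chains=2))
        assert "monomer" in v.reasons

    def test_cysteine_count_rule(self):
        seq = "L" * 130 + "C" * 3
        v = candidate_filter(_model_with(seq, 2.0))
        assert "cysteine_count" in v.reasons
        assert v.metrics["cysteine_count"] == 3
        ok = candidate_filter(_model_with(seq, 2.0), FilterCriteria(max_cysteines=3))
        assert "cysteine_count" not in ok.reasons

    def test_filter_is_pure(self):
        m = _model_with("L" * 140)
        assert candidate_filter(m) == candidate_filter(m)


class TestSasa:
    def test_isolated_carbon_matches_closed_form(self):
        area = compute_sasa(single_atom_model()).atom_areas[0]
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert abs(area - expected) / expected < 0.01

    def test_distant_atoms_do_not_occlude(self):
        model = point_model([[0, 0, 0], [100, 0, 0]])
        areas = compute_sasa(model).atom_areas
        expected = 4 * np.pi * 3.1 ** 2
        assert np.allclose(areas, expected, rtol=0.01)

    def test_caged_atom_has_near_zero_sasa(self):
        # 12 neighbours at 2.0 A (icosahedron vertices) bury the central atom
        phi = (1 + np.sqrt(5)) / 2
        verts = []
        for a in (-1, 1):
            for b in (-phi, phi):
                verts += [[0, a, b], [a, b, 0], [b, 0, a]]
        verts = 2.0 * np.array(verts) / np.linalg.norm(verts[0])
        model = point_model([[0, 0, 0]] + verts.tolist())
        areas = compute_sasa(model).atom_areas
        assert areas[0] < 1.0

    def test_adding_atoms_never_increases_sasa(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            coords = rng.uniform(-4, 4, size=(6, 3))
            before = compute_sasa(point_model(coords[:5])).atom_areas
            after = compute_sasa(point_model(coords)).atom_areas[:5]
            assert np.all(after <= before + 1e-9)

    def test_convergence_with_point_count(self):
        expected = 4 * np.pi * 3.1 ** 2
        errors = [abs(compute_sasa(single_atom_model(), n_points=n).atom_areas[0]
                      - expected)
                  for n in (24, 96, 960)]
        assert errors[2] <= errors[0]
        assert errors[2] / expected < 0.01

    def test_deterministic_across_runs(self):
        model = synthetic_structure(20, 5)
        a = compute_sasa(model).atom_areas
        b = compute_sasa(model).atom_areas
        assert np.array_equal(a, b)

    def test_point_lattice_on_unit_sphere(self):
        pts = golden_spiral_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            compute_sasa(single_atom_model(), n_points=10)


class TestRelativeSasa:
    def test_zero_sasa_not_surface(self):
        model = single_atom_model()
        out = relative_sasa(model, {("A", 1, ""): 0.0})
        assert out[("A", 1, "")].rsasa == 0.0
        assert not out[("A", 1, "")].surface

    def test_table_maximum_gives_unity(self):
        model = single_atom_model(aa="G")
        out = relative_sasa(model, {("A", 1, ""): MAX_ASA["G"]})
        assert out[("A", 1, "")].rsasa == pytest.approx(1.0)
        assert out[("A", 1, "")].surface

    def test_half_maximum_alanine(self):
        model = single_atom_model(aa="A")
        out = relative_sasa(model, {("A", 1, ""): MAX_ASA["A"] / 2})
        assert out[("A", 1, "")].rsasa == pytest.approx(0.5)

    def test_unknown_residue_type_warns_and_uses_mean(self):
        model = single_atom_model(aa="X")
        with pytest.warns(UserWarning, match="max-ASA"):
            out = relative_sasa(model, {("A", 1, ""): 100.0})
        mean_max = sum(MAX_ASA.values()) / len(MAX_ASA)
        assert out[("A", 1, "")].rsasa == pytest.approx(100.0 / mean_max)


class TestAnnotatedWriter:
    def test_scores_land_in_bfactor(self, gly_ala_pdb, tmp_path):
        model = read_structure(gly_ala_pdb)
        out = tmp_path / "scored.pdb"
        write_annotated_structure(model, {("A", 1, ""): 55.0}, out)
        bfactors = {line[22:26].strip(): float(line[60:66])
                    for line in out.read_text().splitlines()
                    if line.startswith("ATOM")}
        assert bfactors["1"] == 55.0
        assert bfactors["2"] == 0.0

    def test_roundtrip_preserves_coordinates(self, gly_ala_pdb, tmp_path):
        model = read_structure(gly_ala_pdb)
        out = tmp_path / "rt.pdb"
        write_annotated_structure(model, {}, out)
        back = read_structure(out)
        for r1, r2 in zip(model.residues(), back.residues()):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.allclose(a1.coord, a2.coord, atol=1e-3)
        assert back.resolution == pytest.approx(1.8)

    def test_out_of_range_score_clipped_with_warning(self, gly_ala_pdb, tmp_path):
        model = read_structure(gly_ala_pdb)
        out = tmp_path / "clip.pdb"
        with pytest.warns(UserWarning, match="clipped"):
            write_annotated_structure(model, {("A", 1, ""): 1234.5}, out)
        b = max(float(line[60:66]) for line in out.read_text().splitlines()
                if line.startswith("ATOM"))
        assert b == 999.99
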