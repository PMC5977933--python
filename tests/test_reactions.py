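"""Reaction library: round trips, classification, deconstruction, forward."""

import json

import pytest
from rdkit import Chem

from poisedfrag.chem import canonical_smiles
from poisedfrag.records import FragmentRecord
from poisedfrag.reactions import (
    HETEROCYCLE,
    LINKING,
    ReactionDefinitionError,
    builtin_reaction_library,
    classify_poised,
    deconstruct,
    export_reaction_library,
    forward_products,
    forward_synthesize,
    get_reaction,
    load_reaction_library,
    round_trip_ok,
)

from conftest import ROUND_TRIP_SUBSTRATES


def test_builtin_roster_composition(library):
    assert len(library) == 21
    assert sum(d.category == LINKING for d in library) == 8
    assert sum(d.category == HETEROCYCLE for d in library) == 13
    names = [d.name for d in library]
    assert len(set(names)) == 21
    for d in library:
        minimum = 2 if d.category == LINKING else 1
        assert len(d.synthon_classes) >= minimum


@pytest.mark.parametrize(
    "reaction_name,smiles",
    [(name, smi) for name, subs in ROUND_TRIP_SUBSTRATES.items() for smi in subs],
)
def test_forward_retro_round_trip(library, reaction_name, smiles):
    """forward(retro(x)) regenerates x for every curated substrate."""
    assert round_trip_ok(smiles, reaction_name, library)


class TestClassify:
    def test_compound_2_is_amide_poised(self, library):
        anns = classify_poised("CC(=O)NCc1c(Cl)cccc1Cl", library)
        amide = [a for a in anns if a.reaction_name == "amide"]
        assert len(amide) == 1
        assert set(amide[0].synthons) == {
            canonical_smiles("CC(=O)Cl"),
            canonical_smiles("NCc1c(Cl)cccc1Cl"),
        }

    def test_benzene_not_poised(self, library):
        assert classify_poised("c1ccccc1", library) == []

    def test_unparsable_smiles_names_fragment(self, library):
        rec = FragmentRecord.from_smiles("f1", "CC(=O)NC")
        object.__setattr__(rec, "smiles", "not-a-smiles")
        with pytest.raises(ValueError, match="f1"):
            classify_poised(rec, library)

    def test_deterministic_and_ordered(self, library):
        smi = "COc1cccc(OC)c1CNC(C)=O"  # amide + two methyl ethers
        first = classify_poised(smi, library)
        second = classify_poised(smi, library)
        assert first == second
        names = [a.reaction_name for a in first]
        assert names == sorted(names)
        assert "amide" in names and names.count("ether") == 2

    def test_annotation_atoms_are_valid_indices(self, library):
        smi = "CC(=O)NCc1c(Cl)cccc1Cl"
        n = Chem.MolFromSmiles(smi).GetNumAtoms()
        for ann in classify_poised(smi, library):
            assert all(0 <= i < n for i in ann.matched_atoms)
            for s in ann.synthons:
                assert Chem.MolFromSmiles(s) is not None

    def test_all_22_reference_compounds_are_poised(self, library, reference_compounds):
        for cid, rec in reference_compounds.items():
            anns = classify_poised(
                FragmentRecord.from_smiles(cid, rec.smiles), library
            )
            assert anns, f"compound {cid} should be poised"


class TestSymmetry:
    """Symmetry-unique match counts vs a brute-force bond enumeration."""

    @staticmethod
    def _brute_force_amide_bonds(smiles):
        """Count acyclic C(=O)-N bonds by direct atom loops (independent of
        the SMARTS engine)."""
        mol = Chem.MolFromSmiles(smiles)
        count = 0
        for bond in mol.GetBonds():
            if bond.IsInRing():
                continue
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            for c, n in ((a, b), (b, a)):
                if c.GetSymbol() != "C" or n.GetSymbol() != "N":
                    continue
                has_carbonyl = any(
                    nb.GetSymbol() == "O"
                    and mol.GetBondBetweenAtoms(c.GetIdx(), nb.GetIdx()).GetBondTypeAsDouble() == 2
                    for nb in c.GetNeighbors()
                )
                has_c_subst = any(
                    nb.GetSymbol() == "C" and nb.GetIdx() != n.GetIdx()
                    for nb in c.GetNeighbors()
                )
                n_acyls = sum(
                    any(
                        nb2.GetSymbol() == "O"
                        and mol.GetBondBetweenAtoms(nb.GetIdx(), nb2.GetIdx()).GetBondTypeAsDouble() == 2
                        for nb2 in nb.GetNeighbors()
                    ) or any(
                        nb2.GetSymbol() == "O" and nb.GetSymbol() == "S"
                        for nb2 in nb.GetNeighbors()
                    )
                    for nb in n.GetNeighbors()
                    if nb.GetIdx() != c.GetIdx() and nb.GetSymbol() in ("C", "S")
                )
                if has_carbonyl and has_c_subst and n_acyls == 0:
                    count += 1
        return count

    @pytest.mark.parametrize(
        "smiles",
        [
            "NC(=O)CC(N)=O",  # two equivalent amide bonds
            "CC(=O)NCCNC(C)=O",  # two equivalent amides, longer linker
            "CC(=O)NC",  # one
            "CC(=O)N(C)C(C)=O",  # imide: zero poised amides
            "O=C1CCCN1C",  # lactam: ring amide not poised
        ],
    )
    def test_amide_count_matches_brute_force(self, library, smiles):
        anns = [
            a for a in classify_poised(smiles, library) if a.reaction_name == "amide"
        ]
        assert len(anns) == self._brute_force_amide_bonds(smiles)


class TestDeconstruct:
    def test_compound_2_amide(self, library):
        assert deconstruct("CC(=O)NCc1c(Cl)cccc1Cl", "amide", library) == [
            ["CC(=O)Cl", "NCc1c(Cl)cccc1Cl"]
        ]

    def test_compound_1_thiourea(self, library):
        sets = deconstruct("Cc1ccccc1NC(N)=S", "thiourea", library)
        assert len(sets) == 1
        assert set(sets[0]) == {canonical_smiles("Cc1ccccc1N"), "N"}

    def test_non_matching_fragment_gives_empty(self, library):
        assert deconstruct("C", "amide", library) == []

    def test_unknown_reaction_raises(self, library):
        with pytest.raises(KeyError):
            deconstruct("CC(=O)NC", "aldol", library)

    def test_leaving_group_conventions(self, library):
        acyl, _ = deconstruct("CC(=O)Nc1ccccc1", "amide", library)[0]
        assert acyl == "CC(=O)Cl"
        sulfonyl, _ = deconstruct("CS(=O)(=O)Nc1ccccc1", "sulfonamide", library)[0]
        assert sulfonyl == canonical_smiles("CS(=O)(=O)Cl")
        boronic, bromide = deconstruct("c1ccc(-c2ccncc2)cc1", "suzuki", library)[0]
        assert "B(O)O" in boronic or "OB(O)" in boronic
        assert "Br" in bromide


class TestForward:
    def test_thiourea_gives_compound_1(self, library):
        product = forward_synthesize("thiourea", ["Cc1ccccc1N", "N"], library)
        assert product == canonical_smiles("Cc1ccccc1NC(N)=S")

    def test_aminooxazole_gives_compound_4(self, library):
        product = forward_synthesize(
            "aminooxazole_carbonitrile", ["CC(C)CC(=O)Cl"], library
        )
        assert product == canonical_smiles("Nc1oc(CC(C)C)nc1C#N")

    def test_role_mismatch_gives_none(self, library):
        assert forward_synthesize("amide", ["c1ccccc1", "c1ccccc1"], library) is None

    def test_wrong_synthon_count_raises(self, library):
        with pytest.raises(ValueError, match="synthons"):
            forward_synthesize("amide", ["CC(=O)Cl"], library)

    def test_pure_function(self, library):
        args = ("amide", ["CC(=O)Cl", "NCc1ccccc1"], library)
        assert forward_synthesize(*args) == forward_synthesize(*args)

    def test_closure_forward_then_classify(self, library):
        """Products of a forward synthesis classify as poised for it."""
        cases = [
            ("amide", ["CC(=O)Cl", "NCc1ccccc1"]),
            ("sulfonamide", ["CS(=O)(=O)Cl", "NC1CCCC1"]),
            ("ether", ["Oc1ccccc1", "BrCC"]),
            ("pyrazole", ["CC(=O)CC(C)=O", "NN"]),
            ("tetrazole", ["CC#N"]),
        ]
        for name, synthons in cases:
            product = forward_synthesize(name, synthons, library)
            assert product is not None
            assert name in {a.reaction_name for a in classify_poised(product, library)}


class TestLoadExport:
    def test_default_is_builtin(self, library):
        assert [d.name for d in load_reaction_library()] == [d.name for d in library]

    def test_single_reaction_file(self, tmp_path, library):
        path = tmp_path / "amide_only.json"
        export_reaction_library([get_reaction(library, "amide")], path)
        loaded = load_reaction_library(path)
        assert len(loaded) == 1 and loaded[0].name == "amide"

    def test_export_load_round_trip(self, tmp_path, library):
        path = tmp_path / "roster.json"
        export_reaction_library(library, path)
        assert load_reaction_library(path) == library

    def test_malformed_smarts_names_reaction(self, tmp_path, library):
        record = get_reaction(library, "amide").to_dict()
        record["retro_transform"] = "[C:1](((>>[C:1]"
        path = tmp_path / "bad.json"
        path.write_text(json.dumps([record]))
        with pytest.raises(ReactionDefinitionError, match="amide"):
            load_reaction_library(path)

    def test_duplicate_names_rejected(self, tmp_path, library):
        record = get_reaction(library, "amide").to_dict()
        path = tmp_path / "dup.json"
        path.write_text(json.dumps([record, record]))
        with pytest.raises(ReactionDefinitionError, match="duplicate"):
            load_reaction_library(path)
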