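"""Token dictionaries, sequence encoding and molecular-graph construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem

from dtafuse.featurization import (
    ATOM_FEATURE_DIM,
    DEFAULT_ATOM_SCHEMA,
    PROTEIN_ALPHABET,
    SMILES_ALPHABET,
    TokenDictionary,
    build_dictionary,
    decode_sequence,
    default_protein_dictionary,
    default_smiles_dictionary,
    encode_sequence,
    featurize_atom,
    parse_protein_input,
    smiles_to_graph,
)

# Partial dictionaries printed in the source description of the encoding
# scheme; kept as fixtures only (the full 64/22-entry orderings are not
# recoverable).
PRINTED_PROTEIN_DICT = TokenDictionary(
    {"A": 1, "N": 14, "C": 2, "Q": 15, "I": 8, "V": 22, "W": 21}, "protein")
PRINTED_SMILES_DICT = TokenDictionary(
    {"C": 22, "N": 34, "O": 33, "(": 4, ")": 3}, "smiles")

FIXTURE_SMILES = [
    "C", "CC", "CCO", "c1ccccc1", "CC(=O)O", "CC(=O)Oc1ccccc1C(=O)O",
    "CN1C=NC2=C1C(=O)N(C(=O)N2C)C", "C1CCCCC1", "c1ccncc1", "CC(C)CC(N)C(=O)O",
    "N[C@@H](C)C(=O)O", "OC(=O)c1ccccc1", "CCN(CC)CC", "CSCC", "FC(F)(F)c1ccccc1",
    "O=C(N)c1ccccc1", "Clc1ccccc1", "BrCCBr", "IC", "C#N", "C=C", "OCC(O)CO",
    "NCCN", "CC(C)(C)O", "C1=CC=CN=C1", "[O-]C(=O)C", "[NH4+]", "CC(N)=O",
    "c1ccc2ccccc2c1", "CC1=CC(=O)C=CC1=O", "S=C=S", "CCOC(=O)C", "NC(=O)N",
    "COc1ccccc1", "CCCCCCCC", "CC(O)CO", "CNC(=O)N", "OC1CCCCC1", "Cn1cnc2ccccc21",
    "OS(=O)(=O)O", "CP(=O)(O)O", "CC#CC", "N#Cc1ccccc1", "CC(C)=CC", "C1CC1",
    "C1CCC1", "CC(Cl)CC", "CO", "CN", "CCCN",
]


class TestDictionaries:
    def test_shipped_defaults_have_documented_sizes(self):
        assert default_smiles_dictionary().size == 64
        assert default_protein_dictionary().size == 22

    def test_codes_are_insertion_ordered_from_one(self):
        d = build_dictionary(["X", "Y", "Z"], "protein")
        assert d.mapping == {"X": 1, "Y": 2, "Z": 3}

    def test_single_character_alphabet(self):
        assert build_dictionary(["A"], "protein").mapping == {"A": 1}

    def test_duplicate_character_is_named_in_error(self):
        with pytest.raises(ValueError, match="'B'"):
            build_dictionary(["A", "B", "B"], "smiles")

    def test_alphabets_have_no_duplicates(self):
        assert len(set(SMILES_ALPHABET)) == 64
        assert len(set(PROTEIN_ALPHABET)) == 22

    def test_tsv_roundtrip(self, tmp_path):
        d = default_protein_dictionary()
        path = tmp_path / "protein.tsv"
        d.save_tsv(path)
        loaded = TokenDictionary.load_tsv(path)
        assert loaded.mapping == d.mapping and loaded.modality == "protein"


class TestEncodeSequence:
    def test_printed_protein_example(self):
        # "NWCVQIA" under the printed partial dictionary
        enc = encode_sequence("NWCVQIA", PRINTED_PROTEIN_DICT, max_len=10)
        np.testing.assert_array_equal(enc.codes, [14, 21, 2, 22, 15, 8, 1, 0, 0, 0])
        assert enc.original_length == 7

    def test_printed_smiles_example_characterwise(self):
        # character-wise application of the printed SMILES dictionary to
        # "CC(O)CO" (the concatenated rendering in the source contains a typo)
        enc = encode_sequence("CC(O)CO", PRINTED_SMILES_DICT, max_len=8)
        np.testing.assert_array_equal(enc.codes, [22, 22, 4, 33, 3, 22, 33, 0])

    def test_empty_string_is_all_padding(self):
        enc = encode_sequence("", default_protein_dictionary(), max_len=5)
        np.testing.assert_array_equal(enc.codes, np.zeros(5))
        assert enc.original_length == 0

    def test_truncation_caps_original_length(self):
        enc = encode_sequence("ACDEFG", default_protein_dictionary(), max_len=3)
        assert enc.original_length == 3
        assert len(enc.codes) == 3

    def test_unknown_character_raises_by_default(self):
        with pytest.raises(KeyError, match="'J'"):
            encode_sequence("AJ", default_protein_dictionary(), max_len=4)

    def test_unknown_character_maps_to_zero_when_permissive(self):
        enc = encode_sequence("AJ", default_protein_dictionary(), max_len=4,
                              unknown_policy="zero")
        assert enc.codes[1] == 0

    @given(st.text(alphabet=list(PROTEIN_ALPHABET), min_size=0, max_size=30))
    def test_decode_inverts_encode_for_untruncated_strings(self, text):
        d = default_protein_dictionary()
        assert decode_sequence(encode_sequence(text, d, max_len=30), d) == text

    def test_encoding_is_deterministic(self):
        d = default_smiles_dictionary()
        a = encode_sequence("CCO", d, 10).codes
        b = encode_sequence("CCO", d, 10).codes
        np.testing.assert_array_equal(a, b)


class TestProteinInput:
    def test_fasta_header_is_discarded(self):
        assert parse_protein_input(">sp|X|Y test\nACDE\nFGHI\n") == "ACDEFGHI"

    def test_raw_string_passes_through(self):
        assert parse_protein_input("ACDE") == "ACDE"


class TestGraphs:
    def test_methane_single_node_no_edges(self):
        g = smiles_to_graph("C")
        assert g.num_nodes == 1 and g.num_edges == 0

    def test_ethanol_path_graph(self):
        g = smiles_to_graph("CCO")
        assert g.num_nodes == 3
        assert sorted(tuple(sorted(e)) for e in g.edges) == [(0, 1), (1, 2)]

    def test_benzene_ring_and_aromatic_flags(self):
        g = smiles_to_graph("c1ccccc1")
        assert g.num_nodes == 6 and g.num_edges == 6
        arom_col = sum(b.width for b in DEFAULT_ATOM_SCHEMA.blocks[:6])  # aromaticity block
        assert np.all(g.node_features[:, arom_col] == 1.0)

    def test_unparseable_smiles_rejected_with_string(self):
        with pytest.raises(ValueError, match="not-a-smiles"):
            smiles_to_graph("not-a-smiles")
        with pytest.raises(ValueError, match="empty"):
            smiles_to_graph("")

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    def test_counts_match_toolkit_oracle(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        g = smiles_to_graph(smiles)
        assert g.num_nodes == mol.GetNumAtoms()
        assert g.num_edges == mol.GetNumBonds()
        assert g.node_features.shape == (mol.GetNumAtoms(), ATOM_FEATURE_DIM)

    def test_alias_smiles_yield_isomorphic_graphs(self):
        g1, g2 = smiles_to_graph("OCC"), smiles_to_graph("CCO")
        deg = lambda g: sorted(np.bincount(np.asarray(g.edge_index()[0]),
                                           minlength=g.num_nodes))
        assert deg(g1) == deg(g2)
        f1 = sorted(map(tuple, g1.node_features.tolist()))
        f2 = sorted(map(tuple, g2.node_features.tolist()))
        assert f1 == f2

    def test_edge_index_is_symmetric(self):
        ei = smiles_to_graph("CCO").edge_index()
        pairs = set(map(tuple, ei.T))
        assert all((j, i) in pairs for i, j in pairs)


class TestAtomDescriptors:
    def test_schema_width_is_package_constant(self):
        assert DEFAULT_ATOM_SCHEMA.width == ATOM_FEATURE_DIM
        assert len(DEFAULT_ATOM_SCHEMA.blocks) == 10

    def test_methane_carbon_descriptor_values(self):
        mol = Chem.MolFromSmiles("C")
        vec = featurize_atom(mol.GetAtomWithIdx(0))
        names = {}
        offset = 0
        for block in DEFAULT_ATOM_SCHEMA.blocks:
            names[block.name] = (offset, block.width)
            offset += block.width
        start, _ = names["num_adjacent_atoms"]
        assert vec[start] == 0.0  # no heavy neighbours
        start, _ = names["num_bonded_hydrogens"]
        assert vec[start] == 4.0
        start, _ = names["atomic_number"]
        assert vec[start] == 6.0

    def test_charged_oxygen_formal_charge(self):
        mol = Chem.MolFromSmiles("[O-]")
        vec = featurize_atom(mol.GetAtomWithIdx(0))
        offset = sum(b.width for b in DEFAULT_ATOM_SCHEMA.blocks[:5])
        assert vec[offset] == -1.0

    def test_unknown_symbol_routes_to_other_slot(self):
        mol = Chem.MolFromSmiles("[Xe]")
        vec = featurize_atom(mol.GetAtomWithIdx(0))
        symbol_width = DEFAULT_ATOM_SCHEMA.blocks[0].width
        assert vec[symbol_width - 1] == 1.0  # the reserved "other" slot
        assert vec[:symbol_width - 1].sum() == 0.0

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "[O-]C(=O)C"])
    def test_every_vector_has_schema_width(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        for atom in mol.GetAtoms():
            assert featurize_atom(atom).shape == (ATOM_FEATURE_DIM,)
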