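"""Tokenisation of SMILES / protein strings and molecular-graph construction.

Drug SMILES and protein sequences are mapped character-wise to integer
labels (code 0 is reserved for padding) and separately, for drugs, parsed
into heavy-atom graphs whose nodes carry a fixed 10-block descriptor
vector computed with RDKit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

# Shipped default alphabets.  Codes are assigned in insertion order, 1-based;
# 0 is the padding code.  The SMILES alphabet covers the character set of
# canonicalised SMILES (64 characters); the protein alphabet is the 20
# standard amino acids plus X (unknown) and U (selenocysteine).
SMILES_ALPHABET = tuple(
    "#%()+-./=@[\\]" + "0123456789" + "ABCDEFGHIKLMNOPRSTUVWXYZ" + "abcdefghilnoprstu"
)
PROTEIN_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY" + "XU")


@dataclass(frozen=True)
class TokenDictionary:
    """Single-character token -> positive integer code mapping."""

    mapping: dict
    modality: str  # "smiles" | "protein"

    def __post_init__(self):
        codes = list(self.mapping.values())
        if len(set(codes)) != len(codes):
            raise ValueError("token codes must be unique")
        if any(c < 1 for c in codes):
            raise ValueError("codes must be >= 1 (0 is reserved for padding)")

    @property
    def size(self) -> int:
        return len(self.mapping)

    def inverse(self) -> dict:
        return {code: tok for tok, code in self.mapping.items()}

    def save_tsv(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# modality={self.modality}\n")
            for tok, code in self.mapping.items():
                fh.write(f"{tok}\t{code}\n")

    @classmethod
    def load_tsv(cls, path) -> "TokenDictionary":
        mapping: dict = {}
        modality = "smiles"
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("# modality="):
                    modality = line.split("=", 1)[1]
                    continue
                tok, code = line.split("\t")
                mapping[tok] = int(code)
        return cls(mapping=mapping, modality=modality)


def build_dictionary(alphabet, modality: str) -> TokenDictionary:
    """Assign codes 1..len(alphabet) in alphabet order."""
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    seen = set()
    for ch in alphabet:
        if ch in seen:
            raise ValueError(f"duplicate character in alphabet: {ch!r}")
        seen.add(ch)
    return TokenDictionary(
        mapping={ch: i + 1 for i, ch in enumerate(alphabet)}, modality=modality
    )


def default_smiles_dictionary() -> TokenDictionary:
    return build_dictionary(SMILES_ALPHABET, "smiles")


def default_protein_dictionary() -> TokenDictionary:
    return build_dictionary(PROTEIN_ALPHABET, "protein")


@dataclass
class EncodedSequence:
    """Fixed-length padded integer label vector for one string."""

    codes: np.ndarray
    original_length: int
    modality: str

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)


def encode_sequence(text: str, dictionary: TokenDictionary, max_len: int,
                    unknown_policy: str = "raise") -> EncodedSequence:
    """Character-wise lookup, truncated to ``max_len``, right-padded with 0."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if unknown_policy not in ("raise", "zero"):
        raise ValueError("unknown_policy must be 'raise' or 'zero'")
    codes = np.zeros(max_len, dtype=np.int64)
    clipped = text[:max_len]
    for i, ch in enumerate(clipped):
        code = dictionary.mapping.get(ch)
        if code is None:
            if unknown_policy == "raise":
                raise KeyError(
                    f"character {ch!r} at position {i} not in {dictionary.modality} dictionary"
                )
            logger.warning("unknown character %r mapped to padding code 0", ch)
            code = 0
        codes[i] = code
    return EncodedSequence(codes=codes, original_length=len(clipped),
                           modality=dictionary.modality)


def decode_sequence(seq: EncodedSequence, dictionary: TokenDictionary) -> str:
    inv = dictionary.inverse()
    return "".join(inv[int(c)] for c in seq.codes[: seq.original_length])


def parse_protein_input(text: str) -> str:
    """Accept a raw sequence or a single-record FASTA block (header dropped)."""
    text = text.strip()
    if text.startswith(">"):
        lines = text.splitlines()[1:]
        return "".join(line.strip() for line in lines)
    return "".join(text.split())


# ---------------------------------------------------------------------------
# Atom descriptors and molecular graphs
# ---------------------------------------------------------------------------

# 44 explicit element symbols; anything else routes to a reserved "other" slot.
ATOM_SYMBOLS = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Bi",
)
HYBRIDIZATIONS = ("SP", "SP2", "SP3", "SP3D", "SP3D2")
CHIRAL_TAGS = ("CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW")


@dataclass(frozen=True)
class DescriptorBlock:
    name: str
    kind: str  # "onehot" | "scalar"
    width: int
    vocab: tuple = ()


@dataclass(frozen=True)
class AtomDescriptorSchema:
    """Ordered list of the 10 atom-descriptor blocks."""

    blocks: tuple = field(default_factory=tuple)

    @property
    def width(self) -> int:
        return sum(b.width for b in self.blocks)


def _onehot(value, vocab) -> list:
    # trailing slot is the reserved "other" bucket
    vec = [0.0] * (len(vocab) + 1)
    try:
        vec[vocab.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


DEFAULT_ATOM_SCHEMA = AtomDescriptorSchema(blocks=(
    DescriptorBlock("atom_symbol", "onehot", len(ATOM_SYMBOLS) + 1, ATOM_SYMBOLS),
    DescriptorBlock("atomic_number", "scalar", 1),
    DescriptorBlock("hybridization", "onehot", len(HYBRIDIZATIONS) + 1, HYBRIDIZATIONS),
    DescriptorBlock("num_adjacent_atoms", "scalar", 1),
    DescriptorBlock("chirality", "onehot", len(CHIRAL_TAGS) + 1, CHIRAL_TAGS),
    DescriptorBlock("formal_charge", "scalar", 1),
    DescriptorBlock("aromaticity", "scalar", 1),
    DescriptorBlock("num_bonded_hydrogens", "scalar", 1),
    DescriptorBlock("explicit_valence", "scalar", 1),
    DescriptorBlock("implicit_valence", "scalar", 1),
))

#: Package-wide node feature dimension (sum of the 10 descriptor block widths).
ATOM_FEATURE_DIM = DEFAULT_ATOM_SCHEMA.width


def featurize_atom(atom: Chem.Atom, schema: AtomDescriptorSchema = DEFAULT_ATOM_SCHEMA) -> np.ndarray:
    values = {
        "atom_symbol": atom.GetSymbol(),
        "atomic_number": float(atom.GetAtomicNum()),
        "hybridization": str(atom.GetHybridization()),
        "num_adjacent_atoms": float(atom.GetDegree()),
        "chirality": str(atom.GetChiralTag()),
        "formal_charge": float(atom.GetFormalCharge()),
        "aromaticity": float(atom.GetIsAromatic()),
        "num_bonded_hydrogens": float(atom.GetTotalNumHs()),
        "explicit_valence": float(atom.GetExplicitValence()),
        "implicit_valence": float(atom.GetImplicitValence()),
    }
    parts: list = []
    for block in schema.blocks:
        if block.kind == "onehot":
            parts.extend(_onehot(values[block.name], list(block.vocab)))
        else:
            parts.append(values[block.name])
    vec = np.asarray(parts, dtype=np.float64)
    assert vec.shape[0] == schema.width
    return vec


@dataclass
class MolecularGraph:
    """Heavy-atom graph: node descriptor matrix plus undirected bond list."""

    node_features: np.ndarray  # (|V|, ATOM_FEATURE_DIM)
    edges: list  # one (i, j) pair per bond
    smiles: str  # canonical SMILES of origin

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def edge_index(self) -> np.ndarray:
        """Symmetric (2, 2E) directed expansion of the bond list."""
        if not self.edges:
            return np.zeros((2, 0), dtype=np.int64)
        src, dst = zip(*self.edges)
        return np.asarray([list(src) + list(dst), list(dst) + list(src)], dtype=np.int64)


def smiles_to_graph(smiles: str, schema: AtomDescriptorSchema = DEFAULT_ATOM_SCHEMA) -> MolecularGraph:
    """Parse a SMILES into a heavy-atom molecular graph with atom descriptors."""
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    features = np.stack([featurize_atom(atom, schema) for atom in mol.GetAtoms()])
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    for i, j in edges:
        if not (0 <= i < mol.GetNumAtoms() and 0 <= j < mol.GetNumAtoms()):
            raise ValueError("bond endpoint outside atom range")  # defensive
    return MolecularGraph(node_features=features, edges=edges,
                          smiles=Chem.MolToSmiles(mol))
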