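"""Drug representations computed from standardized SMILES.

Six schemes are supported, matching the encoder families of the model
builder: 1024-bit Morgan (ECFP4-equivalent) and layered fingerprints for
dense subnetworks, tokenized one-hot SMILES for TextCNN, molecular graphs
for GCN/GAT, precomputed 512-d transformer embeddings loaded from a
table, and one-hot entity identifiers for the diagnostic baseline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Fingerprint",
    "TokenizedSmiles",
    "MoleculeGraph",
    "EmbeddingTable",
    "morgan_fingerprint",
    "layered_fingerprint",
    "bit_atom_environments",
    "SmilesVocab",
    "tokenize_smiles",
    "tokenize_and_encode",
    "smiles_to_graph",
    "load_embedding_table",
    "one_hot_identity",
    "ATOM_PALETTE",
]

N_BITS = 1024
MORGAN_RADIUS = 2
EMBEDDING_DIM = 512


_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=N_BITS
)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class Fingerprint:
    """Binary substructure fingerprint folded to 1024 bits."""

    bits: np.ndarray
    scheme: str  # "morgan_r2" | "layered"

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (N_BITS,):
            raise ValueError(f"fingerprint must have exactly {N_BITS} bits")
        if not np.isin(bits, [0, 1]).all():
            raise ValueError("fingerprint entries must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def on_bits(self) -> list[int]:
        return np.flatnonzero(self.bits).tolist()


def morgan_fingerprint(smiles: str) -> Fingerprint:
    """1024-bit Morgan fingerprint, radius 2 (ECFP4-equivalent).

    A function of the molecule, not the SMILES string: any rewriting of
    the same structure yields an identical bit vector.
    """
    mol = _mol_from_smiles(smiles)
    bv = _MORGAN_GEN.GetFingerprint(mol)
    bits = np.zeros(N_BITS, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits, scheme="morgan_r2")


def layered_fingerprint(smiles: str) -> Fingerprint:
    """1024-bit layered (path-based, layered atom/bond abstraction) fingerprint."""
    mol = _mol_from_smiles(smiles)
    bv = Chem.LayeredFingerprint(mol, fpSize=N_BITS)
    bits = np.zeros(N_BITS, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits, scheme="layered")


def bit_atom_environments(smiles: str, bit: int) -> list[tuple[int, int]]:
    """All (center atom index, radius) environments hashing to ``bit``.

    Returns an empty list when the bit is off for this molecule. Multiple
    environments mapping to one bit indicate either repeated substructures
    or hash collisions after folding.
    """
    if not 0 <= bit < N_BITS:
        raise ValueError(f"bit index {bit} outside 0..{N_BITS - 1}")
    mol = _mol_from_smiles(smiles)
    extra = rdFingerprintGenerator.AdditionalOutput()
    extra.AllocateBitInfoMap()
    _MORGAN_GEN.GetFingerprint(mol, additionalOutput=extra)
    info = extra.GetBitInfoMap()
    return [tuple(env) for env in info.get(bit, ())]


# --- SMILES tokenization --------------------------------------------------

# Multi-character lexemes are single tokens: bracket atoms, two-letter
# elements, %NN ring-closure escapes. Everything else is one character.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|.)"
)

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into chemically meaningful tokens.

    Concatenating the returned tokens reproduces the input exactly.
    """
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:  # pragma: no cover - regex covers any char
        raise ValueError(f"tokenization failed to cover input: {smiles!r}")
    return tokens


@dataclass(frozen=True)
class SmilesVocab:
    """Ordered token vocabulary fitted on training drugs.

    Index 0 is the pad symbol, index 1 the unknown symbol; chemical tokens
    follow in first-seen order.
    """

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens[:2] != (PAD_TOKEN, UNK_TOKEN):
            raise ValueError("vocab must start with the pad and unknown symbols")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocab tokens must be unique")

    @classmethod
    def fit(cls, training_smiles: list[str]) -> "SmilesVocab":
        seen: dict[str, None] = {}
        for smi in training_smiles:
            for tok in tokenize_smiles(smi):
                seen.setdefault(tok, None)
        return cls(tokens=(PAD_TOKEN, UNK_TOKEN, *seen))

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            return 1  # unknown

    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens)})

    @classmethod
    def from_json(cls, text: str) -> "SmilesVocab":
        return cls(tokens=tuple(json.loads(text)["tokens"]))

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class TokenizedSmiles:
    """One-hot encoded token sequence, padded to ``max_len`` rows.

    Each row carries at most one 1; rows beyond the sequence length are
    all-zero pad rows.
    """

    tokens: tuple[str, ...]
    one_hot: np.ndarray
    vocab: SmilesVocab


def tokenize_and_encode(smiles: str, vocab: SmilesVocab, max_len: int) -> TokenizedSmiles:
    """Tokenize a SMILES string and one-hot encode it against ``vocab``.

    Sequences longer than ``max_len`` are an error rather than silently
    truncated: truncation would alter the chemistry the encoder sees.
    Tokens absent from the vocabulary map to the unknown symbol.
    """
    tokens = tokenize_smiles(smiles)
    if len(tokens) > max_len:
        raise ValueError(
            f"SMILES {smiles!r} tokenizes to {len(tokens)} tokens, "
            f"exceeding max_len={max_len}"
        )
    one_hot = np.zeros((max_len, len(vocab)), dtype=np.float32)
    for row, tok in enumerate(tokens):
        one_hot[row, vocab.index(tok)] = 1.0
    return TokenizedSmiles(tokens=tuple(tokens), one_hot=one_hot, vocab=vocab)


# --- molecular graphs -----------------------------------------------------

ATOM_PALETTE = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
_MAX_DEGREE = 5


@dataclass(frozen=True)
class MoleculeGraph:
    """Heavy-atom graph with node features and a binary adjacency matrix.

    The adjacency is symmetric with a zero diagonal; self-loops are the
    model layer's responsibility, not the data's.
    """

    node_features: np.ndarray
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(adj).any():
            raise ValueError("adjacency diagonal must be zero (no self-loops)")

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.node_features.shape[1]


def atom_feature_dim() -> int:
    # element one-hot (+other), degree one-hot (+more), formal charge, aromatic
    return (len(ATOM_PALETTE) + 1) + (_MAX_DEGREE + 1) + 1 + 1


def smiles_to_graph(smiles: str) -> MoleculeGraph:
    """Build the heavy-atom molecular graph for a SMILES string.

    Default node features: element one-hot over a fixed palette plus an
    "other" slot, degree one-hot, formal charge, aromaticity flag.
    """
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    feats = np.zeros((n, atom_feature_dim()), dtype=np.float32)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        elem = ATOM_PALETTE.index(sym) if sym in ATOM_PALETTE else len(ATOM_PALETTE)
        feats[i, elem] = 1.0
        deg = min(atom.GetDegree(), _MAX_DEGREE)
        feats[i, len(ATOM_PALETTE) + 1 + deg] = 1.0
        feats[i, -2] = float(atom.GetFormalCharge())
        feats[i, -1] = float(atom.GetIsAromatic())
    adj = np.zeros((n, n), dtype=np.float32)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[a, b] = adj[b, a] = 1.0
    return MoleculeGraph(node_features=feats, adjacency=adj)


# --- precomputed embeddings and identity baselines ------------------------


@dataclass(frozen=True)
class EmbeddingTable:
    """drug_id -> 512-dimensional precomputed embedding."""

    vectors: dict[str, np.ndarray]

    def __getitem__(self, drug_id: str) -> np.ndarray:
        try:
            return self.vectors[drug_id]
        except KeyError:
            raise KeyError(
                f"drug id {drug_id!r} missing from embedding table "
                f"({len(self.vectors)} entries)"
            ) from None

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def load_embedding_table(path, dim: int = EMBEDDING_DIM) -> EmbeddingTable:
    """Load a TSV/CSV of ``drug_id`` plus ``dim`` float columns.

    Ragged rows are an error naming the offending drug id.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, header=None, index_col=0)
    vectors: dict[str, np.ndarray] = {}
    for drug_id, row in frame.iterrows():
        vec = row.to_numpy(dtype=float)
        vec = vec[~np.isnan(vec)] if np.isnan(vec).any() else vec
        if vec.shape != (dim,):
            raise ValueError(
                f"embedding row for {drug_id!r} has {vec.shape[0]} values, expected {dim}"
            )
        vectors[str(drug_id)] = vec
    return EmbeddingTable(vectors=vectors)


def one_hot_identity(entity_id: str, vocab: list[str]) -> np.ndarray:
    """Unit basis vector for an entity id over an ordered vocabulary.

    Unseen ids are an error: the identity baseline cannot represent
    entities outside its vocabulary, which is exactly its diagnostic
    purpose.
    """
    try:
        pos = list(vocab).index(entity_id)
    except ValueError:
        raise KeyError(f"id {entity_id!r} not in the {len(vocab)}-entry vocabulary") from None
    vec = np.zeros(len(vocab), dtype=np.float32)
    vec[pos] = 1.0
    return vec
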