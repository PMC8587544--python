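"""Circular bit fingerprints, molecular graph encodings, and Tanimoto similarity.

Bit indices produced by the folded hash are implementation-specific; callers
should only rely on similarity values and graph invariances, never on the
identity of particular bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "BitFingerprint",
    "GraphEncoding",
    "ecfp4",
    "tanimoto",
    "max_tanimoto_novelty",
    "encode_graph",
    "mol_from_smiles",
    "write_fingerprint_tsv",
    "read_fingerprint_tsv",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
]

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
_MAX_DEGREE = 5
_MAX_H = 4

# one-hot element (+other) + one-hot degree 0..5 + one-hot H count 0..4 + aromatic flag
ATOM_FEATURE_DIM = (len(_ELEMENTS) + 1) + (_MAX_DEGREE + 1) + (_MAX_H + 1) + 1
# one-hot order (single/double/triple/aromatic) + conjugated + in-ring
BOND_FEATURE_DIM = 4 + 2


class FingerprintError(ValueError):
    """Raised for unparseable structures or incompatible fingerprints."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`FingerprintError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary feature vector with set semantics on the on-bits."""

    length: int
    on_bits: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("fingerprint length must be positive")
        bits = frozenset(int(b) for b in self.on_bits)
        if bits and (min(bits) < 0 or max(bits) >= self.length):
            raise ValueError("on-bit index out of range")
        object.__setattr__(self, "on_bits", bits)

    def popcount(self) -> int:
        return len(self.on_bits)

    def to_dense(self) -> np.ndarray:
        """Dense 0/1 vector of shape (length,)."""
        v = np.zeros(self.length, dtype=np.float64)
        if self.on_bits:
            v[sorted(self.on_bits)] = 1.0
        return v

    def to_hex(self) -> str:
        n = int(0)
        for b in self.on_bits:
            n |= 1 << b
        width = (self.length + 3) // 4
        return format(n, f"0{width}x")

    @classmethod
    def from_hex(cls, hex_string: str, length: int) -> "BitFingerprint":
        n = int(hex_string, 16)
        bits = {i for i in range(length) if (n >> i) & 1}
        return cls(length=length, on_bits=frozenset(bits))


def ecfp4(molecule: Chem.Mol | str, length: int = 2048) -> BitFingerprint:
    """Extended-connectivity fingerprint of diameter 4 (radius 2), folded to
    ``length`` bits.

    Deterministic and invariant to input atom numbering: identical molecular
    graphs always give identical fingerprints.
    """
    if isinstance(molecule, str):
        molecule = mol_from_smiles(molecule)
    if molecule is None:
        raise FingerprintError("molecule is None")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=length)
    bv = gen.GetFingerprint(molecule)
    return BitFingerprint(length=length, on_bits=frozenset(bv.GetOnBits()))


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b|; 0/0 is defined as 0."""
    if a.length != b.length:
        raise ValueError(f"fingerprint length mismatch: {a.length} != {b.length}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 0.0
    return len(a.on_bits & b.on_bits) / union


def max_tanimoto_novelty(
    query: BitFingerprint, references: list[BitFingerprint]
) -> float:
    """Maximum Tanimoto of ``query`` against a reference set (lower = more novel)."""
    if not references:
        raise ValueError("reference fingerprint list must be nonempty")
    return max(tanimoto(query, ref) for ref in references)


@dataclass(frozen=True)
class GraphEncoding:
    """Molecular graph as per-atom / per-bond feature vectors plus adjacency.

    ``neighbors[i]`` lists (neighbor atom index, bond index) pairs; adjacency is
    symmetric by construction. Feature rows have uniform width.
    """

    atom_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    bond_features: np.ndarray  # (n_bonds, BOND_FEATURE_DIM)
    neighbors: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_features.shape[0]

    def adjacency(self) -> np.ndarray:
        """Dense symmetric adjacency matrix (n_atoms, n_atoms)."""
        a = np.zeros((self.n_atoms, self.n_atoms), dtype=np.float64)
        for i, nbrs in enumerate(self.neighbors):
            for j, _ in nbrs:
                a[i, j] = 1.0
        return a

    def bond_sums(self) -> np.ndarray:
        """Per-atom sum of incident bond feature vectors (n_atoms, BOND_FEATURE_DIM)."""
        out = np.zeros((self.n_atoms, BOND_FEATURE_DIM), dtype=np.float64)
        for i, nbrs in enumerate(self.neighbors):
            for _, b in nbrs:
                out[i] += self.bond_features[b]
        return out


def _atom_vector(atom: Chem.Atom) -> np.ndarray:
    v = np.zeros(ATOM_FEATURE_DIM, dtype=np.float64)
    sym = atom.GetSymbol()
    idx = _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)
    v[idx] = 1.0
    off = len(_ELEMENTS) + 1
    v[off + min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
    off += _MAX_DEGREE + 1
    v[off + min(atom.GetTotalNumHs(), _MAX_H)] = 1.0
    off += _MAX_H + 1
    v[off] = 1.0 if atom.GetIsAromatic() else 0.0
    return v


def _bond_vector(bond: Chem.Bond) -> np.ndarray:
    v = np.zeros(BOND_FEATURE_DIM, dtype=np.float64)
    order = {
        Chem.BondType.SINGLE: 0,
        Chem.BondType.DOUBLE: 1,
        Chem.BondType.TRIPLE: 2,
        Chem.BondType.AROMATIC: 3,
    }.get(bond.GetBondType(), 0)
    v[order] = 1.0
    v[4] = 1.0 if bond.GetIsConjugated() else 0.0
    v[5] = 1.0 if bond.IsInRing() else 0.0
    return v


def encode_graph(molecule: Chem.Mol | str) -> GraphEncoding:
    """Encode a molecule's heavy-atom graph for the neural-fingerprint network."""
    if isinstance(molecule, str):
        molecule = mol_from_smiles(molecule)
    if molecule is None:
        raise FingerprintError("molecule is None")
    n = molecule.GetNumAtoms()
    atom_feats = np.zeros((n, ATOM_FEATURE_DIM), dtype=np.float64)
    for atom in molecule.GetAtoms():
        atom_feats[atom.GetIdx()] = _atom_vector(atom)
    nb = molecule.GetNumBonds()
    bond_feats = np.zeros((nb, BOND_FEATURE_DIM), dtype=np.float64)
    neighbors: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for bond in molecule.GetBonds():
        b = bond.GetIdx()
        bond_feats[b] = _bond_vector(bond)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        neighbors[i].append((j, b))
        neighbors[j].append((i, b))
    return GraphEncoding(
        atom_features=atom_feats,
        bond_features=bond_feats,
        neighbors=tuple(tuple(sorted(nbrs)) for nbrs in neighbors),
    )


def write_fingerprint_tsv(path, entries: list[tuple[str, BitFingerprint]]) -> None:
    """Cache fingerprints as TSV rows of (id, length, hex)."""
    with open(path, "w") as fh:
        fh.write("id\tlength\thex\n")
        for ident, fp in entries:
            fh.write(f"{ident}\t{fp.length}\t{fp.to_hex()}\n")


def read_fingerprint_tsv(path) -> list[tuple[str, BitFingerprint]]:
    """Read a fingerprint cache written by :func:`write_fingerprint_tsv`."""
    out: list[tuple[str, BitFingerprint]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError("not a fingerprint cache file")
        for line in fh:
            ident, length, hexs = line.rstrip("\n").split("\t")
            out.append((ident, BitFingerprint.from_hex(hexs, int(length))))
    return out
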