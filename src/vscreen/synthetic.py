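"""Synthetic fixture generators.

Every pipeline stage can be exercised without external downloads: labeled
fingerprint datasets with a known generating rule, motif-labeled molecule
libraries, rigid 3D molecules realizing a known feature geometry, ranked
screens with prescribed active placement, and a combined library for funnel
integration tests. All generators are pure functions of their arguments and
seed. Fixtures encode statistical structure, not chemical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol

from .chem_data import MoleculeRecord, record_from_mol
from .fingerprints import BitFingerprint
from .ranking_metrics import RankedScreen, ScreenEntry

__all__ = [
    "FixtureSpec",
    "FingerprintDataset",
    "make_fingerprint_dataset",
    "make_motif_library",
    "make_pharmacophore_set",
    "make_funnel_library",
    "make_ranked_screen",
    "DEFAULT_MOTIF",
    "core_feature_geometry",
]

DEFAULT_MOTIF = "S(N)(=O)=O"  # sulfonamide group; scaffold pool is S-free


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a fixture (used by the CLI)."""

    kind: str  # fingerprint_dataset | motif_library | pharmacophore_set | ranked_screen
    n: int = 100
    noise_rate: float = 0.0
    seed: int = 0
    informative_bits: int = 10
    fingerprint_length: int = 512
    motif: str = DEFAULT_MOTIF
    active_fraction: float = 0.5
    active_ranks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# 1. labeled fingerprint dataset


@dataclass
class FingerprintDataset:
    pairs: list[tuple[BitFingerprint, int]]
    informative_bits: tuple[int, ...]
    length: int

    def rule(self, fp: BitFingerprint) -> int:
        """The noise-free generating rule (majority of informative bits on)."""
        on = sum(1 for b in self.informative_bits if b in fp.on_bits)
        return int(on >= math.ceil(len(self.informative_bits) / 2))


def make_fingerprint_dataset(
    n: int,
    length: int = 512,
    informative: int = 10,
    noise_rate: float = 0.0,
    background_p: float = 0.05,
    seed: int = 0,
) -> FingerprintDataset:
    """Random bit vectors labeled by a majority-threshold rule over a fixed
    set of informative bits, with labels flipped at ``noise_rate``."""
    if informative >= length:
        raise ValueError("informative bit count must be below fingerprint length")
    rng = np.random.default_rng(seed)
    info = tuple(sorted(rng.choice(length, size=informative, replace=False).tolist()))
    threshold = math.ceil(informative / 2)
    # counts right at the decision boundary are redrawn so the two classes
    # keep a margin and the rule is learnable from desk-scale samples
    margin_band = {threshold - 1, threshold}
    pairs: list[tuple[BitFingerprint, int]] = []
    for _ in range(n):
        bits = set(np.flatnonzero(rng.random(length) < background_p).tolist())
        info_on = {b for b in info if rng.random() < 0.5}
        while len(info_on) in margin_band:
            info_on = {b for b in info if rng.random() < 0.5}
        bits -= set(info)
        bits |= info_on
        label = int(len(info_on) > threshold)
        if noise_rate > 0 and rng.random() < noise_rate:
            label = 1 - label
        pairs.append((BitFingerprint(length=length, on_bits=frozenset(bits)), label))
    return FingerprintDataset(pairs=pairs, informative_bits=info, length=length)


# ---------------------------------------------------------------------------
# 2. motif-labeled molecule library

_SCAFFOLDS = (
    "c1ccccc1",
    "C1CCCCC1",
    "c1ccncc1",
    "C1CCNCC1",
    "C1CCOCC1",
    "c1ccc2ccccc2c1",
)
_SUBSTITUENTS = ("C", "CC", "CCC", "O", "N", "OC", "C(C)C", "F", "Cl", "CO")


def _random_attach(base: Chem.Mol, frag: Chem.Mol, rng: np.random.Generator,
                   frag_site: int = 0) -> Chem.Mol | None:
    """Bond a random H-bearing atom of ``base`` to ``frag_site`` of ``frag``."""
    sites = [
        a.GetIdx()
        for a in base.GetAtoms()
        if a.GetTotalNumHs() > 0
    ]
    if not sites:
        return None
    base_site = int(rng.choice(sites))
    combo = RWMol(Chem.CombineMols(base, frag))
    combo.AddBond(base_site, base.GetNumAtoms() + frag_site, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def make_motif_library(
    n: int,
    active_fraction: float = 0.5,
    motif: str = DEFAULT_MOTIF,
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Molecules built from a small S-free scaffold grammar; actives carry the
    planted motif fragment grafted on, inactives never contain it."""
    motif_mol = Chem.MolFromSmiles(motif)
    if motif_mol is None:
        raise ValueError(f"invalid motif fragment {motif!r}")
    rng = np.random.default_rng(seed)
    n_active = int(round(n * active_fraction))
    records: list[MoleculeRecord] = []
    for i in range(n):
        is_active = i < n_active
        mol = None
        while mol is None:
            base = Chem.MolFromSmiles(str(rng.choice(_SCAFFOLDS)))
            for _ in range(int(rng.integers(1, 4))):
                sub = Chem.MolFromSmiles(str(rng.choice(_SUBSTITUENTS)))
                attached = _random_attach(base, sub, rng)
                if attached is not None:
                    base = attached
            if is_active:
                base = _random_attach(base, motif_mol, rng)
                if base is None:
                    continue
            if base.HasSubstructMatch(motif_mol) != is_active:
                mol = None
                continue
            mol = base
        records.append(
            record_from_mol(
                mol,
                ident=f"{'act' if is_active else 'dec'}{i:04d}",
                label="active" if is_active else "inactive",
            )
        )
    return records


# ---------------------------------------------------------------------------
# 3. rigid 3D molecules realizing a planted feature geometry

# planted core: aromatic ring (R at origin), a CH2 hydrophobe and a carbonyl
# acceptor on one arm, an ether acceptor and a methyl hydrophobe on the other
_RING_RADIUS = 1.39


def _core_atoms() -> tuple[list[tuple[str, tuple[float, float, float]]], list]:
    atoms: list[tuple[str, tuple[float, float, float]]] = []
    for i in range(6):  # ring C0..C5
        ang = math.radians(60 * i)
        atoms.append(("C", (_RING_RADIUS * math.cos(ang),
                            _RING_RADIUS * math.sin(ang), 0.0)))
    atoms += [
        ("C", (2.9, 0.0, 0.0)),    # 6: CH2 hydrophobe
        ("C", (4.3, 0.0, 0.0)),    # 7: carbonyl carbon
        ("O", (5.5, 0.0, 0.0)),    # 8: carbonyl O -> acceptor
        ("O", (-2.8, 0.0, 0.0)),   # 9: ether O -> acceptor
        ("C", (-3.6, 1.1, 0.0)),   # 10: methyl hydrophobe
    ]
    bonds = [
        (0, 1, "ar"), (1, 2, "ar"), (2, 3, "ar"),
        (3, 4, "ar"), (4, 5, "ar"), (5, 0, "ar"),
        (0, 6, "s"), (6, 7, "s"), (7, 8, "d"),
        (3, 9, "s"), (9, 10, "s"),
    ]
    return atoms, bonds


def core_feature_geometry() -> dict[str, np.ndarray]:
    """The planted feature centers: two acceptors, two hydrophobes, one ring."""
    return {
        "A1": np.array([5.5, 0.0, 0.0]),
        "A2": np.array([-2.8, 0.0, 0.0]),
        "H1": np.array([2.9, 0.0, 0.0]),
        "H2": np.array([-3.6, 1.1, 0.0]),
        "R": np.array([0.0, 0.0, 0.0]),
    }


_BOND_TYPES = {
    "s": Chem.BondType.SINGLE,
    "d": Chem.BondType.DOUBLE,
    "ar": Chem.BondType.AROMATIC,
}


def _build_3d(atoms, bonds, aromatic_idx=frozenset(range(6))) -> Chem.Mol:
    rw = RWMol()
    for sym, _ in atoms:
        atom = Chem.Atom(sym)
        rw.AddAtom(atom)
    for i, j, kind in bonds:
        rw.AddBond(i, j, _BOND_TYPES[kind])
    for i in aromatic_idx:
        rw.GetAtomWithIdx(i).SetIsAromatic(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (_, xyz) in enumerate(atoms):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    mol.AddConformer(conf, assignId=True)
    return mol


_DECORATIONS = (  # (ring atom, element, direction multiplier)
    None,
    (1, "C"),
    (2, "C"),
    (4, "Cl"),
    (5, "F"),
    (1, "Cl"),
    (2, "F"),
)


def _decorated_core(decoration, extra=None):
    atoms, bonds = _core_atoms()
    if decoration is not None:
        ring_atom, elem = decoration
        ang = math.radians(60 * ring_atom)
        pos = (2.9 * math.cos(ang), 2.9 * math.sin(ang), 0.0)
        atoms.append((elem, pos))
        bonds.append((ring_atom, len(atoms) - 1, "s"))
    if extra is not None:
        atoms, bonds = extra(atoms, bonds)
    return atoms, bonds


def make_pharmacophore_set(
    n_actives: int = 5,
    n_decoys: int = 10,
    seed: int = 0,
    min_displacement: float = 6.0,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Rigid molecules realizing the planted A/A/H/H/R core geometry.

    Actives share the core with exact coordinates (plus varying ring
    decorations); decoys share the molecular graph but have their acceptor arm
    displaced so that at least one planted pairwise distance is violated by
    more than 3 Angstroms.
    """
    if n_actives < 2:
        raise ValueError("need at least 2 actives")
    rng = np.random.default_rng(seed)
    actives: list[MoleculeRecord] = []
    for i in range(n_actives):
        decoration = _DECORATIONS[i % len(_DECORATIONS)]
        atoms, bonds = _decorated_core(decoration)
        mol = _build_3d(atoms, bonds)
        actives.append(record_from_mol(mol, f"plant{i:03d}", label="active"))

    decoys: list[MoleculeRecord] = []
    target = core_feature_geometry()
    tolerance = 2.0
    for i in range(n_decoys):
        atoms, bonds = _core_atoms()
        while True:
            shift_a = rng.normal(size=3)
            shift_a = shift_a / np.linalg.norm(shift_a) * (
                min_displacement + rng.random() * 3.0
            )
            new_o8 = np.array(atoms[8][1]) + shift_a
            shift_h = rng.normal(size=3)
            shift_h = shift_h / np.linalg.norm(shift_h) * (3.0 + rng.random() * 2.0)
            new_c10 = np.array(atoms[10][1]) + shift_h
            feats = {
                "A1": new_o8,
                "A2": np.array(atoms[9][1]),
                "H1": np.array(atoms[6][1]),
                "H2": new_c10,
                "R": np.zeros(3),
            }
            if _geometry_clearly_violated(feats, target, tolerance):
                break
        atoms[8] = ("O", tuple(new_o8.tolist()))
        # drag the carbonyl carbon halfway so the graph stays identical
        atoms[7] = ("C", tuple(((np.array(atoms[6][1]) + new_o8) / 2.0).tolist()))
        atoms[10] = ("C", tuple(new_c10.tolist()))
        mol = _build_3d(atoms, bonds)
        decoys.append(record_from_mol(mol, f"decoy{i:03d}", label="inactive"))
    return actives, decoys


def _geometry_clearly_violated(
    feats: dict[str, np.ndarray], target: dict[str, np.ndarray], tolerance: float
) -> bool:
    """True when every kind-respecting correspondence of ``feats`` onto
    ``target`` has some pairwise distance off by more than 2 * tolerance
    (which makes a rigid match within per-feature tolerance impossible)."""

    def dists(points: dict[str, np.ndarray], order: list[str]) -> np.ndarray:
        pts = np.stack([points[k] for k in order])
        diff = pts[:, None, :] - pts[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    base_order = ["A1", "A2", "H1", "H2", "R"]
    target_d = dists(target, base_order)
    for a_swap in (False, True):
        for h_swap in (False, True):
            order = list(base_order)
            if a_swap:
                order[0], order[1] = order[1], order[0]
            if h_swap:
                order[2], order[3] = order[3], order[2]
            query_d = dists(feats, order)
            if np.max(np.abs(query_d - target_d)) <= 2.0 * tolerance + 0.5:
                return False
    return True


# ---------------------------------------------------------------------------
# 4. combined funnel library (motif + pharmacophore plants)


def _motif_arm(atoms, bonds):
    """Graft a sulfonamide (the classifier motif) onto ring atom 1."""
    ang = math.radians(60)
    s_pos = (2.9 * math.cos(ang), 2.9 * math.sin(ang), 0.3)
    atoms = list(atoms)
    bonds = list(bonds)
    s_idx = len(atoms)
    atoms.append(("S", s_pos))
    atoms.append(("O", (s_pos[0] + 1.0, s_pos[1], 1.3)))
    atoms.append(("O", (s_pos[0] - 1.0, s_pos[1], 1.3)))
    atoms.append(("N", (s_pos[0] + 0.7, s_pos[1] + 1.3, -0.5)))
    bonds.append((1, s_idx, "s"))
    bonds.append((s_idx, s_idx + 1, "d"))
    bonds.append((s_idx, s_idx + 2, "d"))
    bonds.append((s_idx, s_idx + 3, "s"))
    return atoms, bonds


def make_funnel_library(
    n: int = 500,
    n_active: int = 20,
    motif: str = DEFAULT_MOTIF,
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Screening library for funnel integration tests.

    The ``n_active`` planted actives carry both the classifier motif (a
    sulfonamide) and the rigid planted pharmacophore core; the remaining
    molecules come from the motif-free scaffold grammar and get random 3D
    coordinates, so neither filter should retain them.
    """
    if n_active > n:
        raise ValueError("n_active cannot exceed n")
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    for i in range(n_active):
        decoration = _DECORATIONS[i % len(_DECORATIONS)]
        if decoration is not None and decoration[0] == 1:
            decoration = (2, decoration[1])  # ring atom 1 is taken by the motif arm
        atoms, bonds = _decorated_core(decoration, extra=_motif_arm)
        mol = _build_3d(atoms, bonds)
        rec = record_from_mol(mol, f"fact{i:04d}", label="active")
        records.append(rec)

    fillers = make_motif_library(
        n - n_active, active_fraction=0.0, motif=motif, seed=seed + 1
    )
    for j, rec in enumerate(fillers):
        mol = Chem.MolFromSmiles(rec.smiles)
        coords = rng.normal(scale=3.0, size=(mol.GetNumAtoms(), 3))
        records.append(
            MoleculeRecord(
                id=f"fdec{j:04d}",
                smiles=rec.smiles,
                conformers=[coords],
                label="inactive",
            )
        )
    return records


# ---------------------------------------------------------------------------
# 5. ranked screens with prescribed active placement


def make_ranked_screen(
    N: int, A: int, active_ranks, seed: int = 0
) -> RankedScreen:
    """A screen of N compounds with actives exactly at the given 1-based ranks
    and strictly decreasing scores."""
    ranks = sorted(int(r) for r in active_ranks)
    if len(ranks) != len(set(ranks)):
        raise ValueError("active ranks must be distinct")
    if len(ranks) != A:
        raise ValueError("|active_ranks| must equal A")
    if ranks and (ranks[0] < 1 or ranks[-1] > N):
        raise ValueError("active ranks must lie in [1, N]")
    rank_set = set(ranks)
    entries = [
        ScreenEntry(f"cmpd{r:05d}", (N - r + 1) / N, r in rank_set)
        for r in range(1, N + 1)
    ]
    return RankedScreen(entries=tuple(entries))
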