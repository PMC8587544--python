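"""Typed 3D feature perception, common-feature hypothesis generation, and
k-of-n pharmacophore screening.

The approach is an open re-specification of a common-feature pharmacophore
workflow: perceive features from a documented SMARTS dictionary, hash size-n
feature combinations of each active by kind multiset plus binned pairwise
distances, emit a hypothesis for every arrangement shared by enough actives
(feature centers are mean positions after least-squares superposition), and
screen by enumerating kind-compatible correspondences followed by rigid Kabsch
alignment. No numerical agreement with any proprietary implementation is
claimed.

Feature chemistry (heavy atoms only):

====  =====================================================================
kind  definition
====  =====================================================================
A     acceptor: O (not positively charged) or N with an available lone pair
      (nitrile/imine N, pyridine-type aromatic N, non-amide amine N)
D     donor: N-H or O-H
H     hydrophobe: connected component of aliphatic carbons (no double/triple
      bond to a heteroatom) plus attached halogens, centroid-placed
R     aromatic ring: centroid, ring normal as direction
P/N   formally charged atoms (positive / negative)
====  =====================================================================
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_data import InputError, MoleculeRecord, record_to_mol
from .ranking_metrics import RankedScreen, ScreenEntry

__all__ = [
    "PharmacophoreFeature",
    "PharmacophoreHypothesis",
    "MatchResult",
    "perceive_features",
    "generate_hypotheses",
    "match_hypothesis",
    "screen_with_hypothesis",
    "ensure_conformers",
    "hypothesis_to_json",
    "hypothesis_from_json",
    "kabsch",
]

FEATURE_KINDS = ("A", "D", "H", "R", "P", "N")

_ACCEPTOR_SMARTS = (
    "[OX1;!$([OX1]~[N+])]",
    "[OX2;!+]",
    "[nX2;!+]",
    "[NX1]",
    "[NX2;!+;!$([NX2]=O)]",
    "[NX3;!+;!$([NX3][C,S]=[O,S,N]);!$([NX3]a)]",
)
_DONOR_SMARTS = ("[#7;!H0]", "[#8;!H0]")
_POSITIVE_SMARTS = ("[+;!$([+]~[-])]",)
_NEGATIVE_SMARTS = ("[-;!$([-]~[+])]",)
_HALOGENS = {9, 17, 35, 53}


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: tuple[float, float, float]
    direction: tuple[float, float, float] | None = None
    tolerance: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=np.float64)
            norm = float(np.linalg.norm(d))
            if norm == 0:
                raise ValueError("direction must be nonzero")
            object.__setattr__(self, "direction", tuple((d / norm).tolist()))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=np.float64)


@dataclass(frozen=True)
class PharmacophoreHypothesis:
    features: tuple[PharmacophoreFeature, ...]
    min_required_matches: int
    actives_matched: int = 0
    hypothesis_score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.features)
        if not 1 <= self.min_required_matches <= n:
            raise ValueError("min_required_matches must be in [1, n_features]")
        dm = self.distance_matrix()
        for i, j, l in itertools.permutations(range(n), 3):
            if dm[i, j] > dm[i, l] + dm[l, j] + 1e-9:
                raise ValueError("feature distances violate the triangle inequality")

    def distance_matrix(self) -> np.ndarray:
        pts = np.stack([f.xyz for f in self.features])
        diff = pts[:, None, :] - pts[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    @property
    def n_features(self) -> int:
        return len(self.features)

    def kinds(self) -> str:
        return "".join(sorted(f.kind for f in self.features))


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    correspondence: tuple[tuple[int, int], ...]  # (hypothesis idx, query feature idx)
    rmsd: float
    fit_score: float


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of points P onto Q.

    Returns (rotation, translation, rmsd) such that ``P @ R.T + t`` best
    matches Q in the least-squares sense (proper rotation only).
    """
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    aligned = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - Q) ** 2, axis=1))))
    return R, t, rmsd


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def perceive_features(
    mol: Chem.Mol, conf_id: int = 0, tolerance: float = 2.0
) -> list[PharmacophoreFeature]:
    """Perceive typed features on one conformer of a molecule."""
    if mol.GetNumConformers() == 0:
        raise InputError("molecule has no 3D conformer")
    conf = mol.GetConformer(conf_id)
    coords = np.array(conf.GetPositions(), dtype=np.float64)
    features: list[PharmacophoreFeature] = []

    def match_atoms(smarts_list) -> set[int]:
        out: set[int] = set()
        for smarts in smarts_list:
            patt = Chem.MolFromSmarts(smarts)
            for m in mol.GetSubstructMatches(patt):
                out.add(m[0])
        return out

    for idx in sorted(match_atoms(_ACCEPTOR_SMARTS)):
        features.append(
            PharmacophoreFeature("A", tuple(coords[idx]), tolerance=tolerance)
        )
    for idx in sorted(match_atoms(_DONOR_SMARTS)):
        features.append(
            PharmacophoreFeature("D", tuple(coords[idx]), tolerance=tolerance)
        )
    for idx in sorted(match_atoms(_POSITIVE_SMARTS)):
        features.append(
            PharmacophoreFeature("P", tuple(coords[idx]), tolerance=tolerance)
        )
    for idx in sorted(match_atoms(_NEGATIVE_SMARTS)):
        features.append(
            PharmacophoreFeature("N", tuple(coords[idx]), tolerance=tolerance)
        )

    # hydrophobes: connected components of eligible atoms
    eligible: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in _HALOGENS:
            eligible.add(atom.GetIdx())
        elif atom.GetAtomicNum() == 6 and not atom.GetIsAromatic():
            polar_multiple = any(
                b.GetBondTypeAsDouble() > 1.0
                and b.GetOtherAtom(atom).GetAtomicNum() not in (6,)
                for b in atom.GetBonds()
            )
            if not polar_multiple:
                eligible.add(atom.GetIdx())
    visited: set[int] = set()
    for start in sorted(eligible):
        if start in visited:
            continue
        comp = [start]
        visited.add(start)
        queue = [start]
        while queue:
            cur = queue.pop()
            for nbr in mol.GetAtomWithIdx(cur).GetNeighbors():
                j = nbr.GetIdx()
                if j in eligible and j not in visited:
                    visited.add(j)
                    comp.append(j)
                    queue.append(j)
        centroid = coords[sorted(comp)].mean(axis=0)
        features.append(
            PharmacophoreFeature("H", tuple(centroid), tolerance=tolerance)
        )

    # aromatic rings: centroid + normal
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            pts = coords[list(ring)]
            features.append(
                PharmacophoreFeature(
                    "R",
                    tuple(pts.mean(axis=0)),
                    direction=tuple(_ring_normal(pts)),
                    tolerance=tolerance,
                )
            )
    return features


# ---------------------------------------------------------------------------
# Hypothesis generation


def _combo_key(feats: tuple[PharmacophoreFeature, ...], bin_width: float) -> tuple:
    """Order-invariant hash key: sorted kind multiset plus the sorted multiset
    of (kind pair, binned distance) edges."""
    kinds = tuple(sorted(f.kind for f in feats))
    edges = []
    for a, b in itertools.combinations(feats, 2):
        d = float(np.linalg.norm(a.xyz - b.xyz))
        pair = tuple(sorted((a.kind, b.kind)))
        edges.append((pair, int(round(d / bin_width))))
    return kinds, tuple(sorted(edges))


def _best_correspondence(
    combo: tuple[PharmacophoreFeature, ...],
    ref: tuple[PharmacophoreFeature, ...],
) -> tuple[np.ndarray, float]:
    """Best kind-respecting assignment of ``combo`` onto ``ref``; returns the
    aligned combo points (in ref order) and the alignment RMSD."""
    by_kind: dict[str, list[int]] = {}
    for i, f in enumerate(combo):
        by_kind.setdefault(f.kind, []).append(i)
    ref_kind_slots: dict[str, list[int]] = {}
    for j, f in enumerate(ref):
        ref_kind_slots.setdefault(f.kind, []).append(j)

    best_rmsd = math.inf
    best_points: np.ndarray | None = None
    kind_names = sorted(ref_kind_slots)
    perms_per_kind = [
        list(itertools.permutations(by_kind.get(k, []), len(ref_kind_slots[k])))
        for k in kind_names
    ]
    for combo_perm in itertools.product(*perms_per_kind):
        mapping: dict[int, int] = {}
        for k_idx, k in enumerate(kind_names):
            for slot, ci in zip(ref_kind_slots[k], combo_perm[k_idx]):
                mapping[slot] = ci
        P = np.stack([combo[mapping[j]].xyz for j in range(len(ref))])
        Q = np.stack([f.xyz for f in ref])
        _, _, rmsd = kabsch(P, Q)
        if rmsd < best_rmsd:
            best_rmsd = rmsd
            R, t, _ = kabsch(P, Q)
            best_points = P @ R.T + t
    if best_points is None:
        raise ValueError("no kind-compatible correspondence")
    return best_points, best_rmsd


@dataclass(frozen=True)
class HypothesisConfig:
    sizes: tuple[int, ...] = (4, 5)
    bin_width: float = 1.0
    tolerance: float = 2.0
    rmsd_cap: float = 2.0
    weight_coverage: float = 0.7
    weight_geometry: float = 0.3
    max_combos_per_active: int = 5000


def generate_hypotheses(
    actives: list[MoleculeRecord],
    min_actives_matched: int = 2,
    k: int | None = None,
    config: HypothesisConfig = HypothesisConfig(),
) -> list[PharmacophoreHypothesis]:
    """Enumerate common feature arrangements across active conformers.

    Size-n feature combinations of each active (first conformer) are hashed by
    kind multiset and binned pairwise distances; each arrangement present in at
    least ``min_actives_matched`` actives becomes a hypothesis whose feature
    centers are the mean aligned positions of the contributing actives.
    Returns hypotheses sorted by score (coverage- and geometry-weighted),
    best first. An empty list means no common arrangement — not an error.
    """
    if len(actives) < 2:
        raise InputError("need at least 2 actives to generate hypotheses")
    perceived: list[list[PharmacophoreFeature]] = []
    for rec in actives:
        mol = record_to_mol(rec)
        perceived.append(perceive_features(mol, tolerance=config.tolerance))

    buckets: dict[tuple, dict[int, tuple[PharmacophoreFeature, ...]]] = {}
    for ai, feats in enumerate(perceived):
        for size in config.sizes:
            if len(feats) < size:
                continue
            for count, combo in enumerate(itertools.combinations(feats, size)):
                if count >= config.max_combos_per_active:
                    break
                key = _combo_key(combo, config.bin_width)
                bucket = buckets.setdefault(key, {})
                bucket.setdefault(ai, combo)  # first combo per active

    hypotheses: list[PharmacophoreHypothesis] = []
    for key in sorted(buckets, key=repr):
        bucket = buckets[key]
        if len(bucket) < min_actives_matched:
            continue
        active_ids = sorted(bucket)
        ref = bucket[active_ids[0]]
        n = len(ref)
        aligned_sets = [np.stack([f.xyz for f in ref])]
        rmsds = [0.0]
        ok = True
        for ai in active_ids[1:]:
            try:
                pts, rmsd = _best_correspondence(bucket[ai], ref)
            except ValueError:
                ok = False
                break
            aligned_sets.append(pts)
            rmsds.append(rmsd)
        if not ok:
            continue
        centers = np.mean(np.stack(aligned_sets), axis=0)
        mean_rmsd = float(np.mean(rmsds))
        feats = tuple(
            replace(ref[j], center=tuple(centers[j]), direction=None)
            for j in range(n)
        )
        score = config.weight_coverage * (len(bucket) / len(actives)) + (
            config.weight_geometry * max(0.0, 1.0 - mean_rmsd / config.rmsd_cap)
        )
        hypotheses.append(
            PharmacophoreHypothesis(
                features=feats,
                min_required_matches=min(k or n, n),
                actives_matched=len(bucket),
                hypothesis_score=score,
            )
        )
    hypotheses.sort(key=lambda h: (-h.hypothesis_score, h.kinds()))
    named = []
    counter: dict[str, int] = {}
    for h in hypotheses:
        kinds = h.kinds()
        counter[kinds] = counter.get(kinds, 0) + 1
        named.append(replace(h, name=f"{kinds}_{counter[kinds]}"))
    return named


# ---------------------------------------------------------------------------
# Matching and screening


def _assignments(hyp_feats, query_feats, cap: int):
    """Yield kind-compatible injective assignments hypothesis -> query."""
    q_by_kind: dict[str, list[int]] = {}
    for qi, f in enumerate(query_feats):
        q_by_kind.setdefault(f.kind, []).append(qi)
    count = 0

    def recurse(pos: int, used: set[int], current: list[int]):
        nonlocal count
        if count >= cap:
            return
        if pos == len(hyp_feats):
            count += 1
            yield tuple(current)
            return
        for qi in q_by_kind.get(hyp_feats[pos].kind, []):
            if qi in used:
                continue
            used.add(qi)
            current.append(qi)
            yield from recurse(pos + 1, used, current)
            current.pop()
            used.discard(qi)

    yield from recurse(0, set(), [])


def _check_directions(hyp_feats, query_feats, assignment, R, cone_deg: float) -> bool:
    cos_min = math.cos(math.radians(cone_deg))
    for hj, qi in enumerate(assignment):
        hd = hyp_feats[hj].direction
        qd = query_feats[qi].direction
        if hd is None or qd is None:
            continue
        rotated = np.asarray(qd) @ R.T
        if abs(float(np.dot(rotated, np.asarray(hd)))) < cos_min:
            return False
    return True


def match_hypothesis(
    mol_or_record: Chem.Mol | MoleculeRecord,
    hypothesis: PharmacophoreHypothesis,
    k: int | None = None,
    cone_deg: float = 45.0,
    max_assignments: int = 20000,
) -> MatchResult:
    """Best k-of-n match over all conformers.

    For each conformer, every subset of at least ``k`` hypothesis features is
    tried against kind-compatible query feature assignments; after rigid
    superposition, each matched query feature must land inside the hypothesis
    feature's tolerance sphere. Larger matches are preferred; ties are broken
    by lower RMSD. Fit score = matched_count - RMSD / mean tolerance.
    """
    if isinstance(mol_or_record, MoleculeRecord):
        mol = record_to_mol(mol_or_record)
    else:
        mol = mol_or_record
    if mol.GetNumConformers() == 0:
        raise InputError("molecule has no conformers to match")
    n = hypothesis.n_features
    k = hypothesis.min_required_matches if k is None else k
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, n_features]")

    best: tuple[int, float, tuple[tuple[int, int], ...]] | None = None
    for conf in mol.GetConformers():
        query = perceive_features(mol, conf_id=conf.GetId())
        if not query:
            continue
        for m in range(n, k - 1, -1):
            for subset in itertools.combinations(range(n), m):
                hyp_feats = [hypothesis.features[j] for j in subset]
                Q = np.stack([f.xyz for f in hyp_feats])
                for assignment in _assignments(hyp_feats, query, max_assignments):
                    P = np.stack([query[qi].xyz for qi in assignment])
                    R, t, rmsd = kabsch(P, Q)
                    aligned = P @ R.T + t
                    dists = np.linalg.norm(aligned - Q, axis=1)
                    tols = np.array([f.tolerance for f in hyp_feats])
                    if np.any(dists > tols):
                        continue
                    if not _check_directions(hyp_feats, query, assignment, R, cone_deg):
                        continue
                    if best is None or (m, -rmsd) > (best[0], -best[1]):
                        corr = tuple(zip(subset, assignment))
                        best = (m, rmsd, corr)
            if best is not None and best[0] >= m:
                break  # nothing below this level can beat the current best
        # keep scanning other conformers: a later conformer may match more
    if best is None:
        return MatchResult(matched=False, correspondence=(), rmsd=math.nan,
                           fit_score=-math.inf)
    m, rmsd, corr = best
    mean_tol = float(np.mean([f.tolerance for f in hypothesis.features]))
    return MatchResult(
        matched=True,
        correspondence=corr,
        rmsd=rmsd,
        fit_score=m - rmsd / mean_tol,
    )


def ensure_conformers(
    record: MoleculeRecord, n_confs: int = 10, seed: int = 0
) -> MoleculeRecord:
    """Return a record that has conformers, generating them with ETKDG when
    absent. Conformer generation is an upstream hook, not part of the method
    core."""
    if record.conformers:
        return record
    from .chem_data import record_from_mol

    mol = Chem.AddHs(record_to_mol(record, with_conformers=False))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    mol = Chem.RemoveHs(mol)
    if mol.GetNumConformers() == 0:
        raise InputError(f"conformer generation failed for {record.id}")
    out = record_from_mol(mol, record.id, pKi=record.pKi, label=record.label)
    return out


def screen_with_hypothesis(
    library: list[MoleculeRecord],
    hypothesis: PharmacophoreHypothesis,
    k: int | None = None,
    active_ids: set[str] | None = None,
    generate_missing_conformers: bool = False,
    conformer_seed: int = 0,
) -> tuple[RankedScreen, list[str]]:
    """Screen a conformer library against a hypothesis.

    Returns the full ranked screen (non-matching molecules kept at the bottom
    with a -inf score so enrichment metrics see the whole library) and the
    pass-list of matching compound ids.
    """
    results: list[tuple[str, float, bool]] = []
    for rec in library:
        if not rec.conformers:
            if generate_missing_conformers:
                rec = ensure_conformers(rec, seed=conformer_seed)
            else:
                raise InputError(f"record {rec.id} has no conformers")
        res = match_hypothesis(rec, hypothesis, k=k)
        is_active = (
            rec.id in active_ids if active_ids is not None else rec.label == "active"
        )
        results.append((rec.id, res.fit_score, is_active))
    matched = sorted(
        (r for r in results if r[1] != -math.inf), key=lambda r: (-r[1], r[0])
    )
    unmatched = sorted((r for r in results if r[1] == -math.inf), key=lambda r: r[0])
    entries = [ScreenEntry(i, s, a) for i, s, a in matched + unmatched]
    screen = RankedScreen(entries=tuple(entries))
    return screen, [r[0] for r in matched]


# ---------------------------------------------------------------------------
# Serialization


def hypothesis_to_json(hypothesis: PharmacophoreHypothesis) -> str:
    payload = {
        "name": hypothesis.name,
        "min_required_matches": hypothesis.min_required_matches,
        "actives_matched": hypothesis.actives_matched,
        "hypothesis_score": hypothesis.hypothesis_score,
        "features": [
            {
                "kind": f.kind,
                "center": list(f.center),
                "direction": list(f.direction) if f.direction else None,
                "tolerance": f.tolerance,
            }
            for f in hypothesis.features
        ],
    }
    return json.dumps(payload, indent=2)


def hypothesis_from_json(text: str) -> PharmacophoreHypothesis:
    payload = json.loads(text)
    feats = tuple(
        PharmacophoreFeature(
            kind=f["kind"],
            center=tuple(f["center"]),
            direction=tuple(f["direction"]) if f.get("direction") else None,
            tolerance=f["tolerance"],
        )
        for f in payload["features"]
    )
    return PharmacophoreHypothesis(
        features=feats,
        min_required_matches=payload["min_required_matches"],
        actives_matched=payload.get("actives_matched", 0),
        hypothesis_score=payload.get("hypothesis_score", 0.0),
        name=payload.get("name", ""),
    )
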