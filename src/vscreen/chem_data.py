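"""Molecule/activity I/O, label curation, dataset splitting, clustering of
actives to representatives, and property-matched decoy selection."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from statistics import median

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .fingerprints import BitFingerprint, ecfp4, tanimoto

__all__ = [
    "MoleculeRecord",
    "CurationConfig",
    "DecoySpec",
    "ParseResult",
    "parse_activity_table",
    "assign_labels",
    "split_dataset",
    "cluster_representatives",
    "select_decoys",
    "record_to_mol",
    "read_smiles_file",
    "write_curated_csv",
    "read_curated_csv",
    "write_rejection_tsv",
    "write_sdf",
    "read_sdf",
]

LABELS = ("active", "inactive", "excluded", "unknown")


class ConfigurationError(ValueError):
    """Bad configuration (missing columns, invalid thresholds, ...)."""


class InputError(ValueError):
    """Unusable input data (zero parseable rows, missing conformers, ...)."""


@dataclass
class MoleculeRecord:
    """A compound: structure, optional conformers, optional activity.

    ``conformers`` holds (n_heavy_atoms, 3) coordinate arrays in Angstroms.
    ``label`` is ``unknown`` exactly when ``pKi`` is absent.
    """

    id: str
    smiles: str
    conformers: list[np.ndarray] = field(default_factory=list)
    pKi: float | None = None
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        if self.pKi is not None and self.pKi < 0:
            raise ValueError("pKi must be nonnegative")


def record_to_mol(record: MoleculeRecord, with_conformers: bool = True) -> Chem.Mol:
    """Build an RDKit molecule from a record, attaching stored heavy-atom
    conformers when present."""
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise InputError(f"record {record.id}: unparseable SMILES {record.smiles!r}")
    if with_conformers:
        for coords in record.conformers:
            coords = np.asarray(coords, dtype=np.float64)
            if coords.shape != (mol.GetNumAtoms(), 3):
                raise InputError(
                    f"record {record.id}: conformer shape {coords.shape} does not "
                    f"match {mol.GetNumAtoms()} heavy atoms"
                )
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, (x, y, z) in enumerate(coords):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol.AddConformer(conf, assignId=True)
    return mol


@dataclass(frozen=True)
class CurationConfig:
    active_threshold: float = 8.0
    inactive_threshold: float = 6.0
    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.active_threshold <= self.inactive_threshold:
            raise ConfigurationError("active_threshold must exceed inactive_threshold")
        if any(r <= 0 for r in self.split_ratios):
            raise ConfigurationError("split ratios must be positive")
        if not math.isclose(sum(self.split_ratios), 1.0, abs_tol=1e-9):
            raise ConfigurationError("split ratios must sum to 1")


@dataclass(frozen=True)
class DecoySpec:
    """Property windows and similarity cap for decoy selection."""

    n_per_active: int = 30
    mw_window: float = 25.0
    logp_window: float = 1.0
    hbd_window: int = 1
    hba_window: int = 1
    rotb_window: int = 1
    max_tc_to_actives: float = 0.75

    def __post_init__(self) -> None:
        for w in (self.mw_window, self.logp_window, self.hbd_window,
                  self.hba_window, self.rotb_window):
            if w < 0:
                raise ConfigurationError("property windows must be nonnegative")
        if not 0.0 <= self.max_tc_to_actives <= 1.0:
            raise ConfigurationError("max_tc_to_actives must be in [0, 1]")


@dataclass
class ParseResult:
    """Outcome of activity-table parsing: accepted records plus an explicit
    rejection/duplication report (nothing is silently dropped)."""

    records: list[MoleculeRecord]
    rejected: list[tuple[str, str]]  # (row id or index, reason)
    duplicates: list[tuple[str, int]]  # (id, number of rows merged)


def parse_activity_table(path, fmt: str = "csv") -> ParseResult:
    """Read an activity table with columns id, smiles, pKi.

    Rows whose SMILES fails to parse are excluded and listed in the rejection
    report. Duplicated ids are merged to a single record carrying the median
    pKi, with the merge logged in ``duplicates``.
    """
    if fmt not in ("csv", "tsv"):
        raise ConfigurationError(f"unknown format {fmt!r}")
    df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("id", "smiles", "pki") if c not in cols]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")

    rejected: list[tuple[str, str]] = []
    rows: list[tuple[str, str, float | None]] = []
    for idx, row in df.iterrows():
        ident = str(row[cols["id"]])
        smi = row[cols["smiles"]]
        if not isinstance(smi, str) or Chem.MolFromSmiles(smi) is None:
            rejected.append((ident, f"unparseable SMILES: {smi!r}"))
            continue
        raw = row[cols["pki"]]
        pki = None if pd.isna(raw) else float(raw)
        rows.append((ident, Chem.CanonSmiles(smi), pki))

    if not rows:
        raise InputError("no parseable rows in activity table")

    by_id: dict[str, list[tuple[str, float | None]]] = {}
    order: list[str] = []
    for ident, smi, pki in rows:
        if ident not in by_id:
            order.append(ident)
        by_id.setdefault(ident, []).append((smi, pki))

    records: list[MoleculeRecord] = []
    duplicates: list[tuple[str, int]] = []
    for ident in order:
        group = by_id[ident]
        smi = group[0][0]
        pkis = [p for _, p in group if p is not None]
        pki = median(pkis) if pkis else None
        if len(group) > 1:
            duplicates.append((ident, len(group)))
        records.append(MoleculeRecord(id=ident, smiles=smi, pKi=pki))
    return ParseResult(records=records, rejected=rejected, duplicates=duplicates)


def assign_labels(
    records: list[MoleculeRecord], config: CurationConfig = CurationConfig()
) -> list[MoleculeRecord]:
    """Label records by strict pKi thresholds.

    pKi strictly above the active threshold -> active; strictly below the
    inactive threshold -> inactive; anything in between (inclusive of both
    boundaries) -> excluded. Records without pKi stay ``unknown``.
    """
    out = []
    for rec in records:
        if rec.pKi is None:
            label = "unknown"
        elif rec.pKi > config.active_threshold:
            label = "active"
        elif rec.pKi < config.inactive_threshold:
            label = "inactive"
        else:
            label = "excluded"
        out.append(replace(rec, label=label))
    return out


def largest_remainder_sizes(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Apportion ``n`` items to parts proportional to ``ratios`` using
    largest-remainder rounding (ties to the earlier part)."""
    quotas = [n * r for r in ratios]
    sizes = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(sizes)
    frac_order = sorted(
        range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i)
    )
    for i in frac_order[:remainder]:
        sizes[i] += 1
    return sizes


def split_dataset(
    records: list[MoleculeRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[MoleculeRecord], list[MoleculeRecord], list[MoleculeRecord]]:
    """Stratified train/test/validation partition.

    Total split sizes follow largest-remainder apportionment of the configured
    ratios; within that, strata (labels) are apportioned by largest remainder
    and then repaired so the totals match exactly. Reproducible for fixed seed.
    """
    if len(records) < 3:
        raise InputError("need at least 3 records to split")
    ratios = config.split_ratios
    n_splits = len(ratios)
    global_sizes = largest_remainder_sizes(len(records), ratios)

    strata: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault(rec.label, []).append(i)
    stratum_names = sorted(strata)

    alloc: dict[str, list[int]] = {}
    for name in stratum_names:
        members = strata[name]
        if len(members) < n_splits:
            warnings.warn(
                f"stratum {name!r} has {len(members)} record(s), fewer than "
                f"{n_splits} splits: degenerate assignment",
                stacklevel=2,
            )
        alloc[name] = largest_remainder_sizes(len(members), ratios)

    # repair: move single records between splits until per-split totals match
    # the global apportionment, preferring moves that least distort quotas
    totals = [sum(alloc[name][j] for name in stratum_names) for j in range(n_splits)]
    while totals != global_sizes:
        over = next(j for j in range(n_splits) if totals[j] > global_sizes[j])
        under = next(j for j in range(n_splits) if totals[j] < global_sizes[j])

        def distortion(name: str) -> float:
            quota = len(strata[name]) * ratios[over]
            return quota - alloc[name][over]  # lower = more over-allocated

        candidates = [n for n in stratum_names if alloc[n][over] > 0]
        chosen = min(candidates, key=lambda n: (distortion(n), n))
        alloc[chosen][over] -= 1
        alloc[chosen][under] += 1
        totals[over] -= 1
        totals[under] += 1

    rng = np.random.default_rng(config.seed)
    splits: list[list[MoleculeRecord]] = [[] for _ in range(n_splits)]
    for name in stratum_names:
        members = list(strata[name])
        rng.shuffle(members)
        start = 0
        for j in range(n_splits):
            for i in members[start : start + alloc[name][j]]:
                splits[j].append(records[i])
            start += alloc[name][j]
    return tuple(splits)  # type: ignore[return-value]


def cluster_representatives(
    fingerprints: list[BitFingerprint], n_clusters: int
) -> list[int]:
    """Pick one representative per cluster of an average-linkage hierarchical
    clustering on (1 - Tanimoto) distances.

    The representative of each cluster is its medoid: the member with the
    highest mean Tanimoto to the rest of its cluster. Returns sorted indices.
    """
    n = len(fingerprints)
    if n_clusters <= 0:
        raise ValueError("n_clusters must be positive")
    if n_clusters > n:
        raise ValueError("n_clusters exceeds number of molecules")
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = tanimoto(fingerprints[i], fingerprints[j])
            sim[i, j] = sim[j, i] = s
    if n_clusters == n:
        return list(range(n))
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=n_clusters, criterion="maxclust")
    # tied (e.g. zero) distances can make maxclust under-split; peel singletons
    # off the largest clusters until the requested count is reached
    while len(set(assignment)) < n_clusters:
        sizes = {c: int(np.sum(assignment == c)) for c in set(assignment)}
        biggest = max(sizes, key=lambda c: (sizes[c], -c))
        member = int(np.flatnonzero(assignment == biggest)[-1])
        assignment[member] = max(assignment) + 1

    reps: list[int] = []
    for c in sorted(set(assignment)):
        members = np.flatnonzero(assignment == c)
        if len(members) == 1:
            reps.append(int(members[0]))
            continue
        mean_sim = sim[np.ix_(members, members)].mean(axis=1)
        reps.append(int(members[int(np.argmax(mean_sim))]))
    return sorted(reps)


def _properties(mol: Chem.Mol) -> tuple[float, float, int, int, int]:
    return (
        Descriptors.MolWt(mol),
        Crippen.MolLogP(mol),
        Lipinski.NumHDonors(mol),
        Lipinski.NumHAcceptors(mol),
        Lipinski.NumRotatableBonds(mol),
    )


def select_decoys(
    actives: list[MoleculeRecord],
    candidate_pool: list[MoleculeRecord],
    spec: DecoySpec = DecoySpec(),
) -> list[MoleculeRecord]:
    """Select property-matched, structurally dissimilar decoys.

    A candidate qualifies if it sits within every property window of at least
    one active and its maximum ECFP4 Tanimoto to the actives does not exceed
    ``spec.max_tc_to_actives``. Each active sponsors at most ``n_per_active``
    decoys. The result is independent of pool ordering (candidates are
    processed in id order) and free of duplicate structures.
    """
    if not candidate_pool:
        warnings.warn("empty decoy candidate pool", stacklevel=2)
        return []
    active_mols = [record_to_mol(a, with_conformers=False) for a in actives]
    active_props = [_properties(m) for m in active_mols]
    active_fps = [ecfp4(m) for m in active_mols]

    counts = [0] * len(actives)
    seen: set[str] = set()
    selected: list[MoleculeRecord] = []
    for cand in sorted(candidate_pool, key=lambda r: r.id):
        try:
            mol = record_to_mol(cand, with_conformers=False)
        except InputError:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        props = _properties(mol)
        fitting = []
        for ai, ap in enumerate(active_props):
            if (
                abs(props[0] - ap[0]) <= spec.mw_window
                and abs(props[1] - ap[1]) <= spec.logp_window
                and abs(props[2] - ap[2]) <= spec.hbd_window
                and abs(props[3] - ap[3]) <= spec.hba_window
                and abs(props[4] - ap[4]) <= spec.rotb_window
            ):
                fitting.append(ai)
        if not fitting:
            continue
        fp = ecfp4(mol)
        if max(tanimoto(fp, afp) for afp in active_fps) > spec.max_tc_to_actives:
            continue
        open_slots = [ai for ai in fitting if counts[ai] < spec.n_per_active]
        if not open_slots:
            continue
        sponsor = min(open_slots, key=lambda ai: (counts[ai], ai))
        counts[sponsor] += 1
        seen.add(canon)
        selected.append(cand)
    return selected


def record_from_mol(
    mol: Chem.Mol,
    ident: str,
    pKi: float | None = None,
    label: str = "unknown",
) -> MoleculeRecord:
    """Create a record from an RDKit molecule, remapping any conformer
    coordinates to the atom order of the canonical SMILES so that
    :func:`record_to_mol` reattaches them consistently."""
    mol = Chem.RemoveHs(mol)
    smiles = Chem.MolToSmiles(mol)
    conformers: list[np.ndarray] = []
    if mol.GetNumConformers():
        import re

        order_str = mol.GetProp("_smilesAtomOutputOrder")
        order = [int(tok) for tok in re.findall(r"\d+", order_str)]
        for conf in mol.GetConformers():
            coords = np.array(conf.GetPositions(), dtype=np.float64)
            conformers.append(coords[order])
    return MoleculeRecord(
        id=ident, smiles=smiles, conformers=conformers, pKi=pKi, label=label
    )


# ---------------------------------------------------------------------------
# I/O helpers


def read_smiles_file(path) -> list[MoleculeRecord]:
    """Read a .smi file: one 'SMILES<whitespace>ID' record per line."""
    records: list[MoleculeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            records.append(MoleculeRecord(id=ident, smiles=smi))
    return records


def write_curated_csv(path, records: list[MoleculeRecord],
                      splits: dict[str, str] | None = None) -> None:
    """Write curated records as CSV (id, canonical_smiles, pKi, label, split)."""
    rows = []
    for rec in records:
        rows.append({
            "id": rec.id,
            "canonical_smiles": Chem.CanonSmiles(rec.smiles),
            "pKi": rec.pKi if rec.pKi is not None else "",
            "label": rec.label,
            "split": (splits or {}).get(rec.id, ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curated_csv(path) -> tuple[list[MoleculeRecord], dict[str, str]]:
    df = pd.read_csv(path)
    records = []
    splits: dict[str, str] = {}
    for _, row in df.iterrows():
        pki = None if pd.isna(row["pKi"]) else float(row["pKi"])
        records.append(
            MoleculeRecord(
                id=str(row["id"]),
                smiles=row["canonical_smiles"],
                pKi=pki,
                label=row["label"],
            )
        )
        if "split" in df.columns and not pd.isna(row["split"]):
            splits[str(row["id"])] = str(row["split"])
    return records, splits


def write_rejection_tsv(path, rejected: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for ident, reason in rejected:
            fh.write(f"{ident}\t{reason}\n")


def write_sdf(path, records: list[MoleculeRecord]) -> None:
    """Write records (first conformer if any) as an SDF V2000 file."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for rec in records:
        mol = record_to_mol(rec)
        mol.SetProp("_Name", rec.id)
        if rec.pKi is not None:
            mol.SetProp("pKi", repr(rec.pKi))
        mol.SetProp("label", rec.label)
        writer.write(mol, confId=0 if rec.conformers else -1)
    writer.close()


def read_sdf(path) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=True):
        if mol is None:
            continue
        pki = float(mol.GetProp("pKi")) if mol.HasProp("pKi") else None
        label = mol.GetProp("label") if mol.HasProp("label") else "unknown"
        ident = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append(record_from_mol(mol, ident, pKi=pki, label=label))
    return records
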