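"""Screening-funnel orchestration: classifier consensus, pharmacophore filter,
cascade percentage filtering over externally produced docking scores, and the
final annotated shortlist with novelty scores.

Docking is consumed, never computed: the adapter ingests plain (id, score)
TSV tables — one per cascade stage — where lower scores mean better binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .chem_data import ConfigurationError, InputError, MoleculeRecord, record_to_mol
from .deep_models import TrainedClassifier, predict
from .fingerprints import BitFingerprint, ecfp4, encode_graph, max_tanimoto_novelty
from .pharmacophore import PharmacophoreHypothesis, match_hypothesis

__all__ = [
    "FunnelConfig",
    "FunnelReport",
    "consensus_filter",
    "cascade_percent_filter",
    "attach_docking_scores",
    "run_funnel",
]


@dataclass(frozen=True)
class FunnelConfig:
    classifier_a: TrainedClassifier
    classifier_b: TrainedClassifier
    hypothesis: PharmacophoreHypothesis
    k: int | None = None
    consensus_rule: str = "intersection"  # intersection | union
    threshold: float = 0.5
    docking_tables: tuple = ()  # paths or DataFrames, one per cascade stage
    cascade_fractions: tuple[float, ...] = (0.25, 0.25, 0.25)
    final_stage_cap: int | None = None
    shortlist_size: int = 10
    novelty_references: tuple[BitFingerprint, ...] = ()

    def __post_init__(self) -> None:
        if self.consensus_rule not in ("intersection", "union"):
            raise ConfigurationError(f"unknown consensus rule {self.consensus_rule!r}")
        if any(not 0.0 < f <= 1.0 for f in self.cascade_fractions):
            raise ConfigurationError("cascade fractions must be in (0, 1]")
        if self.shortlist_size < 1:
            raise ConfigurationError("shortlist size must be >= 1")


@dataclass
class FunnelReport:
    stages: list[tuple[str, int, int]]  # (stage name, n in, n out)
    eliminated: dict[str, str]  # compound id -> stage that removed it
    shortlist: list[dict] = field(default_factory=list)

    def stage_counts(self) -> list[int]:
        return [n_out for _, _, n_out in self.stages]


def _probabilities(
    classifier: TrainedClassifier, library: list[MoleculeRecord]
) -> dict[str, float]:
    mols = [record_to_mol(rec, with_conformers=False) for rec in library]
    if classifier.architecture == "ecfp_dense":
        items = [ecfp4(m, length=classifier.mlp.sizes[0]) for m in mols]
    else:
        items = [encode_graph(m) for m in mols]
    probs = predict(classifier, items)
    return {rec.id: float(p) for rec, p in zip(library, probs)}


def consensus_filter(
    library: list[MoleculeRecord],
    classifier_a: TrainedClassifier,
    classifier_b: TrainedClassifier,
    threshold: float = 0.5,
    rule: str = "intersection",
) -> tuple[list[MoleculeRecord], dict[str, tuple[float, float]]]:
    """Keep compounds predicted active by both classifiers (or either, with
    rule='union'). Returns the surviving subset in input order plus the
    per-compound probability pair."""
    pa = _probabilities(classifier_a, library)
    pb = _probabilities(classifier_b, library)
    probs = {rec.id: (pa[rec.id], pb[rec.id]) for rec in library}
    if rule == "intersection":
        keep = [r for r in library if pa[r.id] >= threshold and pb[r.id] >= threshold]
    elif rule == "union":
        keep = [r for r in library if pa[r.id] >= threshold or pb[r.id] >= threshold]
    else:
        raise ConfigurationError(f"unknown consensus rule {rule!r}")
    return keep, probs


def cascade_percent_filter(
    scored_list: list[tuple[str, float]], fraction: float
) -> list[tuple[str, float]]:
    """Top floor(fraction * n) entries by score (higher = better), minimum 1.
    Ties are broken stably by id."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not scored_list:
        return []
    n_keep = max(1, math.floor(fraction * len(scored_list)))
    ranked = sorted(scored_list, key=lambda item: (-item[1], item[0]))
    return ranked[:n_keep]


def attach_docking_scores(
    compounds: list[MoleculeRecord] | list[str],
    score_table,
) -> tuple[list[tuple[str, float]], list[str]]:
    """Join external docking scores onto a compound list.

    The table holds (id, score) rows with lower = better binding; scores are
    negated on ingestion so that downstream "top" always means best. Duplicate
    ids keep their best (lowest) raw score. Returns (scored, unmatched ids).
    """
    ids = [c.id if isinstance(c, MoleculeRecord) else c for c in compounds]
    if isinstance(score_table, pd.DataFrame):
        df = score_table.copy()
    else:
        df = pd.read_csv(score_table, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "score" not in cols:
        raise ConfigurationError("score table needs 'id' and 'score' columns")
    df = df.rename(columns={cols["id"]: "id", cols["score"]: "score"})
    df["id"] = df["id"].astype(str)
    best = df.groupby("id")["score"].min()
    scored = [(i, -float(best[i])) for i in ids if i in best.index]
    unmatched = [i for i in ids if i not in best.index]
    if not scored:
        raise InputError("no compound ids matched the docking score table")
    return scored, unmatched


def run_funnel(library: list[MoleculeRecord], config: FunnelConfig) -> FunnelReport:
    """Execute the full screen: consensus -> pharmacophore k-of-n ->
    optional docking cascade -> shortlist with novelty annotation.

    Any stage that empties the candidate set finalizes the report early with
    an empty shortlist (this is a result, not an error).
    """
    if not library:
        raise InputError("library is empty")
    report = FunnelReport(stages=[], eliminated={})

    survivors, probs = consensus_filter(
        library,
        config.classifier_a,
        config.classifier_b,
        threshold=config.threshold,
        rule=config.consensus_rule,
    )
    surviving_ids = {r.id for r in survivors}
    for rec in library:
        if rec.id not in surviving_ids:
            report.eliminated[rec.id] = "consensus"
    report.stages.append(("consensus", len(library), len(survivors)))
    if not survivors:
        return report

    fits: dict[str, float] = {}
    kept: list[MoleculeRecord] = []
    for rec in survivors:
        res = match_hypothesis(rec, config.hypothesis, k=config.k)
        if res.matched:
            fits[rec.id] = res.fit_score
            kept.append(rec)
        else:
            report.eliminated[rec.id] = "pharmacophore"
    report.stages.append(("pharmacophore", len(survivors), len(kept)))
    if not kept:
        return report

    current: list[tuple[str, float]] = sorted(
        ((rec.id, fits[rec.id]) for rec in kept), key=lambda x: (-x[1], x[0])
    )
    docking_scores: dict[str, float] = {}
    n_stages = len(config.docking_tables)
    for si, table in enumerate(config.docking_tables):
        stage_name = f"docking{si + 1}"
        scored, unmatched = attach_docking_scores([i for i, _ in current], table)
        for ident in unmatched:
            report.eliminated[ident] = stage_name
        fraction = (
            config.cascade_fractions[si]
            if si < len(config.cascade_fractions)
            else config.cascade_fractions[-1]
        )
        filtered = cascade_percent_filter(scored, fraction)
        if si == n_stages - 1 and config.final_stage_cap is not None:
            filtered = filtered[: config.final_stage_cap]
        kept_ids = {i for i, _ in filtered}
        for ident, _ in scored:
            if ident not in kept_ids:
                report.eliminated[ident] = stage_name
        docking_scores.update(dict(filtered))
        report.stages.append((stage_name, len(current), len(filtered)))
        current = filtered
        if not current:
            return report

    shortlist_ids = [i for i, _ in current[: config.shortlist_size]]
    for ident, _ in current[config.shortlist_size :]:
        report.eliminated[ident] = "shortlist_cut"
    report.stages.append(("shortlist", len(current), len(shortlist_ids)))

    by_id = {rec.id: rec for rec in library}
    for ident in shortlist_ids:
        rec = by_id[ident]
        row = {
            "id": ident,
            "prob_a": probs[ident][0],
            "prob_b": probs[ident][1],
            "pharmacophore_fit": fits[ident],
        }
        if ident in docking_scores:
            row["docking_score"] = -docking_scores[ident]  # back to raw convention
        if config.novelty_references:
            fp = ecfp4(record_to_mol(rec, with_conformers=False))
            row["max_tc_novelty"] = max_tanimoto_novelty(
                fp, list(config.novelty_references)
            )
        report.shortlist.append(row)
    return report
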