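"""Early-recognition metrics for ranked screening outputs.

Implements the enrichment factor at a fixed top fraction, BEDROC(alpha) in the
exact min/max-normalized closed form, the ROC area via the rank statistic with
average-rank tie handling, and the area under the accumulation curve (AUAC).

Conventions
-----------
* Ranks are 1-based; rank 1 is the best-scored compound.
* Ties on score are broken stably by input order when a screen is built from
  unsorted entries.
* Metrics that are undefined for a screen (e.g. no actives) return ``nan``
  rather than a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ScreenEntry",
    "RankedScreen",
    "EnrichmentReport",
    "ef_at",
    "bedroc",
    "roc_area",
    "auac",
    "enrichment_report",
    "read_screen_tsv",
    "write_screen_tsv",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class ScreenEntry:
    id: str
    score: float
    is_active: bool


@dataclass(frozen=True)
class RankedScreen:
    """Ordered screening output; entries are sorted by non-increasing score."""

    entries: tuple[ScreenEntry, ...]

    def __post_init__(self) -> None:
        scores = [e.score for e in self.entries]
        for a, b in zip(scores, scores[1:]):
            if b > a:
                raise ValueError("entries must be sorted by non-increasing score")

    @classmethod
    def from_entries(
        cls, entries: list[ScreenEntry] | list[tuple[str, float, bool]]
    ) -> "RankedScreen":
        """Build a screen from possibly-unsorted entries (stable sort on score)."""
        norm = [
            e if isinstance(e, ScreenEntry) else ScreenEntry(e[0], float(e[1]), bool(e[2]))
            for e in entries
        ]
        norm.sort(key=lambda e: -e.score)  # stable: ties keep input order
        return cls(entries=tuple(norm))

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def A(self) -> int:
        return sum(1 for e in self.entries if e.is_active)

    def active_ranks(self) -> list[int]:
        """1-based ranks of the active entries."""
        return [i + 1 for i, e in enumerate(self.entries) if e.is_active]

    def scores(self) -> np.ndarray:
        return np.array([e.score for e in self.entries], dtype=np.float64)

    def labels(self) -> np.ndarray:
        return np.array([e.is_active for e in self.entries], dtype=bool)


@dataclass(frozen=True)
class EnrichmentReport:
    ef: float
    ef_fraction: float
    bedroc: float
    bedroc_alpha: float
    roc: float
    auac: float
    total_actives: int
    ranked_actives: int


def ef_at(screen: RankedScreen, fraction: float = 0.01) -> float:
    """Enrichment factor in the top ``fraction`` of the list.

    The top bin holds ``ceil(fraction * N)`` compounds (always nonempty), and
    EF = (a / n_top) / (A / N) with ``a`` the actives inside the bin.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    N, A = screen.N, screen.A
    if N == 0 or A == 0:
        return math.nan
    n_top = math.ceil(fraction * N)
    a = sum(1 for e in screen.entries[:n_top] if e.is_active)
    return (a / n_top) / (A / N)


def bedroc(screen: RankedScreen, alpha: float = 160.9) -> float:
    """Boltzmann-enhanced discrimination of ROC with exact normalization.

    RIE = mean over actives of exp(-alpha * r_i / N), normalized by the value a
    uniform active distribution would give; BEDROC maps RIE onto [0, 1] with the
    exact min/max closed form. Larger alpha weights earlier ranks more heavily.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    N, A = screen.N, screen.A
    if N == 0 or A == 0:
        return math.nan
    ra = A / N
    ranks = np.array(screen.active_ranks(), dtype=np.float64)
    s = float(np.sum(np.exp(-alpha * ranks / N)))
    rand_sum = ra * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)
    rie = s / rand_sum
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    const = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return rie * factor + const


def roc_area(screen: RankedScreen) -> float:
    """ROC area via the Mann-Whitney rank statistic (average ranks on ties)."""
    N, A = screen.N, screen.A
    if A == 0 or A == N:
        return math.nan
    scores = screen.scores()
    labels = screen.labels()
    # rankdata ranks ascending; higher score should mean higher rank
    r = rankdata(scores, method="average")
    rank_sum = float(r[labels].sum())
    return (rank_sum - A * (A + 1) / 2.0) / (A * (N - A))


def auac(screen: RankedScreen) -> float:
    """Area under the accumulation curve: 1 - mean(r_i / N) over active ranks."""
    N, A = screen.N, screen.A
    if N == 0 or A == 0:
        return math.nan
    ranks = screen.active_ranks()
    return 1.0 - sum(r / N for r in ranks) / A


def enrichment_report(
    screen: RankedScreen,
    fraction: float = 0.01,
    alpha: float = 160.9,
    ranked_actives: int | None = None,
) -> EnrichmentReport:
    """All four metrics on one screen. ``ranked_actives`` is the number of
    actives the upstream filter actually matched (defaults to all actives)."""
    return EnrichmentReport(
        ef=ef_at(screen, fraction),
        ef_fraction=fraction,
        bedroc=bedroc(screen, alpha),
        bedroc_alpha=alpha,
        roc=roc_area(screen),
        auac=auac(screen),
        total_actives=screen.A,
        ranked_actives=screen.A if ranked_actives is None else ranked_actives,
    )


def read_screen_tsv(path) -> RankedScreen:
    """Read a ranked screen from TSV columns (id, score, is_active)."""
    entries: list[ScreenEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "score", "is_active"]:
            raise ValueError("expected TSV header: id\tscore\tis_active")
        for line in fh:
            ident, score, flag = line.rstrip("\n").split("\t")[:3]
            entries.append(ScreenEntry(ident, float(score), flag not in ("0", "", "false")))
    return RankedScreen.from_entries(entries)


def write_screen_tsv(path, screen: RankedScreen) -> None:
    with open(path, "w") as fh:
        fh.write("id\tscore\tis_active\n")
        for e in screen.entries:
            fh.write(f"{e.id}\t{e.score:.6g}\t{int(e.is_active)}\n")


def write_enrichment_tsv(path, rows: list[tuple[str, float, EnrichmentReport]]) -> None:
    """Write (hypothesis id, hypothesis score, report) rows as a TSV table."""
    cols = [
        "hypothesis", "score", "EF", "BEDROC", "ROC", "AUAC",
        "total_actives", "ranked_actives",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for name, score, rep in rows:
            fh.write(
                f"{name}\t{score:.4f}\t{rep.ef:.2f}\t{rep.bedroc:.2f}\t"
                f"{rep.roc:.2f}\t{rep.auac:.2f}\t{rep.total_actives}\t{rep.ranked_actives}\n"
            )
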