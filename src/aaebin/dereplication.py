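"""Quality-score-driven de-replication of competing bin sets.

Several binnings of the same contig catalogue (e.g. the z-space and
y-space bins, optionally plus an external binner's output) contain the
same genome many times over. De-replication reduces them to a single
duplicate-free set in three steps:

1. score every bin (``score = completeness - 5 * contamination``) and drop
   bins that are not near-complete (completeness > 0.9 and contamination
   < 0.05, strict);
2. repeatedly find near-identical bin pairs — at least 75% of the smaller
   bin's nucleotide content present in the larger — and remove the
   lower-scoring member;
3. for each contig still present in two or more bins, recompute each
   owner's score without the contig and assign the contig to the owner
   whose score would drop the most, removing it from all others.

The output never contains a duplicated contig. Because overlap is defined
on shared contig identity within one catalogue, no sequence alignment is
involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol

import pandas as pd

from .clustering import BinSet

logger = logging.getLogger(__name__)

SCORE_CONTAMINATION_WEIGHT = 5.0
NC_MIN_COMPLETENESS = 0.9
NC_MAX_CONTAMINATION = 0.05
NEAR_IDENTICAL_OVERLAP = 0.75


class QualityScorer(Protocol):
    """Assigns (completeness, contamination) to a bin's current contents.

    Implementations must be deterministic for fixed input. The report-file
    adapter looks scores up by bin name (and therefore cannot see content
    changes); the ground-truth scorer recomputes from contig membership.
    """

    def score_bin(self, name: str, contigs: frozenset[str]) -> tuple[float, float]:
        ...


@dataclass(frozen=True)
class QualityReport:
    """Static per-bin completeness/contamination, e.g. parsed from an
    external quality tool's TSV report."""

    entries: dict[str, tuple[float, float]]

    def score_bin(self, name: str, contigs: frozenset[str]) -> tuple[float, float]:
        if name not in self.entries:
            raise KeyError(f"quality report has no entry for bin {name!r}")
        return self.entries[name]


@dataclass(frozen=True)
class ScoredBin:
    name: str
    contigs: frozenset[str]
    total_bp: int
    completeness: float
    contamination: float

    @property
    def score(self) -> float:
        return self.completeness - SCORE_CONTAMINATION_WEIGHT * self.contamination


def score_bins(
    bins: BinSet,
    scorer: QualityScorer,
    contig_lengths: dict[str, int],
) -> list[ScoredBin]:
    """Score every bin; sorted by name for determinism."""
    out = []
    for name in sorted(bins.bins):
        contigs = frozenset(bins.bins[name])
        completeness, contamination = scorer.score_bin(name, contigs)
        out.append(
            ScoredBin(
                name=name,
                contigs=contigs,
                total_bp=sum(contig_lengths[c] for c in contigs),
                completeness=completeness,
                contamination=contamination,
            )
        )
    return out


def filter_nc(
    scored: list[ScoredBin],
    min_completeness: float = NC_MIN_COMPLETENESS,
    max_contamination: float = NC_MAX_CONTAMINATION,
) -> list[ScoredBin]:
    """Keep only near-complete bins; both inequalities are strict."""
    return [
        b for b in scored
        if b.completeness > min_completeness and b.contamination < max_contamination
    ]


def find_near_identical_pairs(
    bins: list[ScoredBin],
    contig_lengths: dict[str, int],
    overlap_threshold: float = NEAR_IDENTICAL_OVERLAP,
) -> list[tuple[ScoredBin, ScoredBin, float]]:
    """All bin pairs where >= ``overlap_threshold`` of the smaller bin's bp
    is present in the larger bin ('smaller' by total bp, ties by name)."""
    pairs = []
    ordered = sorted(bins, key=lambda b: b.name)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            shared = a.contigs & b.contigs
            if not shared:
                continue
            shared_bp = sum(contig_lengths[c] for c in shared)
            smaller_bp = min(a.total_bp, b.total_bp)
            if smaller_bp == 0:
                continue
            overlap = shared_bp / smaller_bp
            if overlap >= overlap_threshold:
                pairs.append((a, b, overlap))
    return pairs


def _loser(a: ScoredBin, b: ScoredBin) -> ScoredBin:
    """The pair member to remove: lower score; ties to smaller total bp,
    then to the lexicographically larger name."""
    if a.score != b.score:
        return a if a.score < b.score else b
    if a.total_bp != b.total_bp:
        return a if a.total_bp < b.total_bp else b
    return a if a.name > b.name else b


@dataclass
class DereplicationLog:
    removed_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    reassignments: list[tuple[str, str, dict[str, float]]] = field(default_factory=list)


def dereplicate(
    bin_sets: list[BinSet],
    scorer: QualityScorer,
    contig_lengths: dict[str, int],
    min_completeness: float = NC_MIN_COMPLETENESS,
    max_contamination: float = NC_MAX_CONTAMINATION,
    overlap_threshold: float = NEAR_IDENTICAL_OVERLAP,
    keep_sub_nc: bool = False,
    log: DereplicationLog | None = None,
) -> BinSet:
    """Merge bin sets into one duplicate-free, NC-filtered set.

    Near-identical pairs are processed by descending overlap, then by the
    lexicographic pair of names; removing a bin voids its pending pairs.
    Contigs are reassigned in lexicographic order, recomputing scores
    against current bin contents.
    """
    merged: dict[str, frozenset[str]] = {}
    for bin_set in bin_sets:
        for name, contigs in bin_set.bins.items():
            if name in merged:
                raise ValueError(f"duplicate bin name across input sets: {name!r}")
            merged[name] = frozenset(contigs)
    bins = score_bins(BinSet(bins={k: set(v) for k, v in merged.items()}),
                      scorer, contig_lengths)
    if not keep_sub_nc:
        bins = filter_nc(bins, min_completeness, max_contamination)
    alive: dict[str, ScoredBin] = {b.name: b for b in bins}

    # step 2: remove the lower-scoring member of each near-identical pair
    while True:
        pairs = find_near_identical_pairs(
            list(alive.values()), contig_lengths, overlap_threshold
        )
        if not pairs:
            break
        pairs.sort(key=lambda p: (-p[2], p[0].name, p[1].name))
        for a, b, overlap in pairs:
            if a.name not in alive or b.name not in alive:
                continue
            loser = _loser(alive[a.name], alive[b.name])
            del alive[loser.name]
            if log is not None:
                winner = a.name if loser.name == b.name else b.name
                log.removed_pairs.append((loser.name, winner, overlap))

    # step 3: largest-score-drop contig reassignment
    def rescore(b: ScoredBin, contigs: frozenset[str]) -> ScoredBin:
        comp, cont = scorer.score_bin(b.name, contigs)
        return replace(
            b,
            contigs=contigs,
            total_bp=sum(contig_lengths[c] for c in contigs),
            completeness=comp,
            contamination=cont,
        )

    owners_of: dict[str, list[str]] = {}
    for b in alive.values():
        for contig in b.contigs:
            owners_of.setdefault(contig, []).append(b.name)
    for contig in sorted(c for c, owners in owners_of.items() if len(owners) > 1):
        owners = sorted(n for n in owners_of[contig] if n in alive
                        and contig in alive[n].contigs)
        if len(owners) < 2:
            continue
        drops: dict[str, float] = {}
        for name in owners:
            b = alive[name]
            without = rescore(b, b.contigs - {contig})
            drops[name] = b.score - without.score
        winner = min(
            owners, key=lambda n: (-drops[n], -alive[n].score, n)
        )
        if log is not None:
            log.reassignments.append((contig, winner, drops))
        for name in owners:
            if name == winner:
                continue
            b = alive[name]
            remaining = b.contigs - {contig}
            if remaining:
                alive[name] = rescore(b, remaining)
            else:
                del alive[name]

    result = BinSet(bins={name: set(b.contigs) for name, b in alive.items()})
    _assert_no_duplicates(result)
    logger.info(
        "de-replication: %d input bins -> %d bins, %d pair removals",
        len(merged), len(result.bins),
        len(log.removed_pairs) if log is not None else -1,
    )
    return result


def _assert_no_duplicates(bin_set: BinSet) -> None:
    seen: set[str] = set()
    for name, contigs in bin_set.bins.items():
        dup = seen & contigs
        if dup:
            raise AssertionError(
                f"duplicated contigs after de-replication: {sorted(dup)[:5]}"
            )
        seen |= contigs


def parse_quality_report(tsv_path: str | Path) -> QualityReport:
    """Parse an external bin-quality TSV (columns Name, Completeness,
    Contamination). Percent-scale values (detected by completeness > 1.5
    anywhere) are divided by 100; fraction-scale values pass through."""
    df = pd.read_csv(tsv_path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("name", "completeness", "contamination"):
        if needed not in cols:
            raise ValueError(f"quality report {tsv_path} missing column {needed!r}")
    comp = df[cols["completeness"]].astype(float)
    cont = df[cols["contamination"]].astype(float)
    if comp.max() > 1.5:
        comp = comp / 100.0
        cont = cont / 100.0
    entries = {
        str(name): (float(c), float(x))
        for name, c, x in zip(df[cols["name"]], comp, cont)
    }
    if len(entries) != len(df):
        raise ValueError(f"duplicate bin names in quality report {tsv_path}")
    return QualityReport(entries=entries)
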