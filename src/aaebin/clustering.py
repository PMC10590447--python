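"""Clustering of latent codes and multi-split binning.

The continuous z space is clustered with an iterative medoid algorithm on
cosine distance: repeatedly seed on the longest unclustered contig, wander
to a local medoid among close neighbours, set a cluster radius at the
first density valley of the medoid's distance histogram (with a fallback
radius when no valley exists), and emit everything within the radius as
one cluster. The categorical y space needs no clustering — identical
labels form a cluster. Catalogue-level clusters are then split by contig
sample-of-origin into sample-pure bins (multi-split binning).

Distances are ``(1 - cos) / 2`` on per-dimension-centred, length-normalised
latent rows, so they lie in [0, 1]; the radius heuristics below are on
that scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import sample_of_contig

logger = logging.getLogger(__name__)


@dataclass
class ClusterParams:
    """Knobs of the medoid-wander clusterer (cosine-distance scale)."""

    neighbour_radius: float = 0.05  # window for medoid wandering
    hist_max: float = 0.3
    hist_bin_width: float = 0.005
    valley_ratio: float = 0.6  # valley bin must fall below this x peak
    fallback_radius: float = 0.09
    max_medoid_steps: int = 25


@dataclass
class ClusterAssignment:
    """A partition of contig ids into named clusters; origin is 'z' or 'y'."""

    clusters: dict[str, set[str]]
    origin: str

    def n_contigs(self) -> int:
        return sum(len(v) for v in self.clusters.values())

    def validate_partition(self, contig_ids: list[str]) -> None:
        seen: set[str] = set()
        for name, members in self.clusters.items():
            if not members:
                raise ValueError(f"empty cluster {name!r}")
            overlap = seen & members
            if overlap:
                raise ValueError(f"contigs in multiple clusters: {sorted(overlap)[:5]}")
            seen |= members
        if seen != set(contig_ids):
            raise ValueError("clusters do not cover exactly the input contigs")


@dataclass
class BinSet:
    """Sample-pure bins: name -> contig ids."""

    bins: dict[str, set[str]] = field(default_factory=dict)

    def n_contigs(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def all_contigs(self) -> set[str]:
        out: set[str] = set()
        for members in self.bins.values():
            out |= members
        return out


def _normalise_rows(Z: np.ndarray) -> np.ndarray:
    """Centre each latent dimension, then length-normalise each row.

    Rows that coincide with the centroid (zero after centring) fall back
    to their uncentred direction so that identical inputs keep zero
    pairwise distance instead of becoming degenerate."""
    centred = Z - Z.mean(axis=0)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    degenerate = norms[:, 0] == 0
    if degenerate.any():
        centred[degenerate] = Z[degenerate]
        norms = np.linalg.norm(centred, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return centred / norms


def _cosine_distances(u: np.ndarray, M: np.ndarray) -> np.ndarray:
    return np.clip((1.0 - M @ u) / 2.0, 0.0, None)


def _find_valley_radius(dist: np.ndarray, params: ClusterParams) -> float:
    """Radius at the first density valley of the distance histogram.

    Walking the histogram left to right while tracking the running peak, a
    valley is the first bin that drops below ``valley_ratio`` times the
    peak and does not exceed its right neighbour. Falls back to
    ``fallback_radius`` when no valley is found.
    """
    n_bins = int(round(params.hist_max / params.hist_bin_width))
    hist, edges = np.histogram(dist, bins=n_bins, range=(0.0, params.hist_max))
    peak = hist[0]
    for i in range(1, n_bins - 1):
        peak = max(peak, hist[i - 1])
        if peak > 0 and hist[i] < params.valley_ratio * peak and hist[i] <= hist[i + 1]:
            return float(edges[i + 1])
    return params.fallback_radius


def cluster_z(
    Z: np.ndarray,
    contig_ids: list[str],
    lengths: list[int] | None = None,
    params: ClusterParams | None = None,
) -> ClusterAssignment:
    """Iterative medoid clustering of the continuous latent space.

    Deterministic: seeds are taken in order of descending contig length
    (ties broken by contig id), and all remaining ties break
    lexicographically on contig id.
    """
    params = params or ClusterParams()
    n = len(contig_ids)
    if Z.shape[0] != n:
        raise ValueError("Z row count does not match contig_ids")
    if n == 0:
        return ClusterAssignment(clusters={}, origin="z")
    if not np.isfinite(Z).all():
        raise ValueError("non-finite values in latent matrix")
    lengths = lengths if lengths is not None else [0] * n
    U = _normalise_rows(np.asarray(Z, dtype=float))
    seed_order = sorted(range(n), key=lambda i: (-lengths[i], contig_ids[i]))
    unclustered = np.ones(n, dtype=bool)
    clusters: dict[str, set[str]] = {}
    cluster_no = 0
    # A wandering medoid may leave its seed outside the emitted cluster, so
    # seeds are re-drawn until everything is clustered; each cluster always
    # contains its medoid, which guarantees termination.
    while unclustered.any():
        seed = next(i for i in seed_order if unclustered[i])
        medoid = seed
        for _ in range(params.max_medoid_steps):
            d = _cosine_distances(U[medoid], U)
            close = np.flatnonzero(unclustered & (d <= params.neighbour_radius))
            if close.size <= 1:
                break
            sub = np.clip((1.0 - U[close] @ U[close].T) / 2.0, 0.0, None)
            sums = sub.sum(axis=1)
            best_pos = min(
                range(close.size), key=lambda j: (sums[j], contig_ids[close[j]])
            )
            best = int(close[best_pos])
            if best == medoid:
                break
            cur_pos = int(np.flatnonzero(close == medoid)[0]) if medoid in close else None
            if cur_pos is not None and sums[best_pos] >= sums[cur_pos]:
                break
            medoid = best
        d = _cosine_distances(U[medoid], U)
        radius = _find_valley_radius(d[unclustered], params)
        members = np.flatnonzero(unclustered & (d <= radius))
        if members.size == 0:
            members = np.array([medoid])
        cluster_no += 1
        clusters[str(cluster_no)] = {contig_ids[i] for i in members}
        unclustered[members] = False
    assignment = ClusterAssignment(clusters=clusters, origin="z")
    assignment.validate_partition(contig_ids)
    logger.info("z clustering: %d clusters from %d contigs", len(clusters), n)
    return assignment


def clusters_from_y(Y: np.ndarray, contig_ids: list[str]) -> ClusterAssignment:
    """Read clusters directly off the categorical latent labels."""
    if len(Y) != len(contig_ids):
        raise ValueError("Y length does not match contig_ids")
    clusters: dict[str, set[str]] = {}
    for label, cid in zip(Y, contig_ids):
        clusters.setdefault(str(int(label)), set()).add(cid)
    assignment = ClusterAssignment(clusters=clusters, origin="y")
    assignment.validate_partition(contig_ids)
    return assignment


def multi_split(assignment: ClusterAssignment, separator: str = "C") -> BinSet:
    """Split each catalogue-level cluster by sample of origin.

    Bin names are ``<origin><cluster-id><separator><sample>`` and are
    deterministic for a given assignment.
    """
    bins: dict[str, set[str]] = {}
    for cid, members in assignment.clusters.items():
        by_sample: dict[str, set[str]] = {}
        for contig in members:
            by_sample.setdefault(sample_of_contig(contig, separator), set()).add(contig)
        for sample, group in by_sample.items():
            name = f"{assignment.origin}{cid}{separator}{sample}"
            if name in bins:
                raise ValueError(f"duplicate bin name {name!r}")
            bins[name] = group
    return BinSet(bins=bins)


def write_clusters(
    obj: ClusterAssignment | BinSet, path: str | Path
) -> None:
    """Two-column TSV (cluster/bin name, contig id), sorted, deterministic."""
    mapping = obj.clusters if isinstance(obj, ClusterAssignment) else obj.bins
    rows = []
    for name, members in mapping.items():
        if "\t" in name or "\n" in name:
            raise ValueError(f"cluster name {name!r} contains tab/newline")
        for contig in members:
            if "\t" in contig or "\n" in contig:
                raise ValueError(f"contig id {contig!r} contains tab/newline")
            rows.append((name, contig))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("clustername\tcontigname\n")
        for name, contig in rows:
            fh.write(f"{name}\t{contig}\n")


def read_clusters(path: str | Path) -> BinSet:
    """Read a cluster/bin TSV written by :func:`write_clusters`."""
    bins: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("clustername"):
            raise ValueError(f"unexpected cluster file header in {path}: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            bins.setdefault(parts[0], set()).add(parts[1])
    return BinSet(bins=bins)
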