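"""Contig feature extraction: tetranucleotide composition and co-abundance.

Each contig is represented by the concatenation of

* its tetranucleotide frequencies (TNF), projected into a 103-dimensional
  orthonormal subspace that is invariant under reverse complementation and
  free of the linear redundancies of raw 4-mer counts, then z-scaled per
  dimension across the catalogue, and
* its depth of coverage across samples, normalised per contig to sum to one
  (the co-abundance profile).

The resulting ``103 + n_samples`` vector is the model input.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
from Bio import SeqIO

logger = logging.getLogger(__name__)

TNF_DIM = 103
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# byte -> base code lookup (A=0 C=1 G=2 T=3, -1 for anything else incl. N)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class ContigRecord:
    """A single contig: id carries the sample prefix, sequence is ACGTN."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProjectionKernel:
    """256 x 103 orthonormal basis of the admissible TNF deviation subspace.

    Columns span the null space of: the all-ones row (frequencies sum to a
    constant), one row per reverse-complement tetramer pair (single-strand
    counts carry no strand information), and one row per trinucleotide
    (the 4-mers starting with a 3-mer and those ending with it both sum to
    that 3-mer's frequency in a long sequence).
    """

    matrix: np.ndarray  # (256, 103)

    def project(self, frequencies: np.ndarray) -> np.ndarray:
        """Project raw 256-dim frequency rows into the 103-dim subspace."""
        return np.asarray(frequencies) @ self.matrix


@dataclass
class CompositionMatrix:
    """Per-contig TNF: raw frequencies, projection, and z-scaled features."""

    values: np.ndarray  # (n, 103) z-scaled
    projected: np.ndarray  # (n, 103) pre-z-scaling
    raw_frequencies: np.ndarray  # (n, 256), rows sum to 1


@dataclass
class AbundanceMatrix:
    """Per-contig per-sample depths, raw and row-normalised."""

    raw: np.ndarray  # (n, S) >= 0
    normalized: np.ndarray  # (n, S), rows sum to 1
    sample_names: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.raw.shape[1]


@dataclass
class FeatureDataset:
    """Assembled model input: X = [TNF || co-abundance] per contig."""

    X: np.ndarray  # (n, 103 + S)
    contig_ids: list[str]
    lengths: list[int]
    sample_of: list[int]
    sample_names: list[str]

    @property
    def n_contigs(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1] - TNF_DIM


def all_tetramers() -> list[str]:
    return ["".join(p) for p in itertools.product(_BASES, repeat=4)]


def reverse_complement(kmer: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(kmer))


def tetramer_index(kmer: str) -> int:
    i = 0
    for c in kmer:
        i = i * 4 + _BASES.index(c)
    return i


def read_contigs(fasta_path: str | Path, min_length: int = 2000) -> list[ContigRecord]:
    """Read a contig catalogue from FASTA, dropping contigs below ``min_length``.

    Ids are the first whitespace-delimited token of each header and must be
    unique. Sequences may contain upper/lower case A, C, G, T and N.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(f"FASTA file not found: {fasta_path}")
    records: list[ContigRecord] = []
    seen: set[str] = set()
    n_total = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_total += 1
        if rec.id in seen:
            raise ValueError(f"duplicate contig header in {fasta_path}: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(
                f"contig {rec.id!r} contains non-ACGTN symbols: {bad}"
            )
        if len(seq) >= min_length:
            records.append(ContigRecord(id=rec.id, sequence=seq))
    if n_total == 0:
        raise ValueError(f"no FASTA records parsed from {fasta_path}")
    if not records:
        raise ValueError(
            f"all {n_total} contigs shorter than min_length={min_length} bp"
        )
    logger.info(
        "read %d contigs from %s (%d dropped below %d bp)",
        len(records), fasta_path, n_total - len(records), min_length,
    )
    return records


def compute_projection_kernel() -> ProjectionKernel:
    """Build the deterministic 256 x 103 TNF projection kernel.

    The constraint matrix stacks the all-ones row, a difference row per
    reverse-complement tetramer pair, and a prefix-minus-suffix row per
    trinucleotide; its null space (rank 153, hence 103 free dimensions) is
    orthonormalised by SVD, and each basis vector's sign is fixed so that
    its first non-negligible entry is positive.
    """
    kmers = all_tetramers()
    rows = [np.ones(256)]
    for k in kmers:
        r = reverse_complement(k)
        if k < r:
            v = np.zeros(256)
            v[tetramer_index(k)] = 1.0
            v[tetramer_index(r)] = -1.0
            rows.append(v)
    for t in itertools.product(_BASES, repeat=3):
        tri = "".join(t)
        v = np.zeros(256)
        for x in _BASES:
            v[tetramer_index(tri + x)] += 1.0
            v[tetramer_index(x + tri)] -= 1.0
        rows.append(v)
    basis = scipy.linalg.null_space(np.array(rows))
    if basis.shape != (256, TNF_DIM):  # pragma: no cover - construction guard
        raise RuntimeError(f"unexpected kernel shape {basis.shape}")
    for j in range(basis.shape[1]):
        col = basis[:, j]
        lead = col[np.abs(col) > 1e-10]
        if lead.size and lead[0] < 0:
            basis[:, j] = -col
    return ProjectionKernel(matrix=basis)


def _tetramer_counts(sequence: str) -> np.ndarray:
    """Count overlapping 4-mers on the given strand, skipping windows with
    any non-ACGT symbol."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < 4:
        return np.zeros(256, dtype=np.int64)
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    kidx = c0 * 64 + c1 * 16 + c2 * 4 + c3
    return np.bincount(kidx[valid], minlength=256)


def compute_tnf(
    contigs: list[ContigRecord], kernel: ProjectionKernel
) -> CompositionMatrix:
    """Projected, z-scaled tetranucleotide frequencies for a catalogue.

    Contigs with no valid tetramer window (all-N or shorter than 4 bp) get
    the uniform frequency vector, which projects to the zero vector.
    Z-scaling columns of zero variance are left at zero after centring.
    """
    if not contigs:
        raise ValueError("compute_tnf requires at least one contig")
    freqs = np.empty((len(contigs), 256))
    for i, contig in enumerate(contigs):
        counts = _tetramer_counts(contig.sequence)
        total = counts.sum()
        if total == 0:
            freqs[i] = 1.0 / 256.0
        else:
            freqs[i] = counts / total
    projected = kernel.project(freqs)
    mean = projected.mean(axis=0)
    std = projected.std(axis=0)
    centred = projected - mean
    values = np.where(std > 0, centred / np.where(std > 0, std, 1.0), centred)
    return CompositionMatrix(values=values, projected=projected, raw_frequencies=freqs)


_JGI_META_COLUMNS = ("contigName", "contigLen", "totalAvgDepth")


def read_depths(tsv_path: str | Path, contig_ids: list[str]) -> AbundanceMatrix:
    """Parse a depth matrix in the jgi_summarize_bam_contig_depths dialect.

    Expects columns contigName, contigLen, totalAvgDepth followed by one
    depth column per sample, optionally interleaved with variance columns
    (header suffix ``-var``), which are ignored. Rows are re-ordered to
    ``contig_ids``; contigs absent from the file are an error.
    """
    tsv_path = Path(tsv_path)
    # round_trip parsing: depths reproduce their written doubles exactly,
    # so file-based and in-memory pipelines give identical results
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    for col in _JGI_META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"depth file {tsv_path} missing column {col!r}")
    sample_cols = [
        c for c in df.columns
        if c not in _JGI_META_COLUMNS and not c.endswith("-var")
    ]
    if not sample_cols:
        raise ValueError(f"depth file {tsv_path} has no sample depth columns")
    df = df.set_index("contigName")
    missing = [cid for cid in contig_ids if cid not in df.index]
    if missing:
        raise ValueError(
            f"{len(missing)} contigs absent from depth file {tsv_path}: "
            + ", ".join(missing[:5])
        )
    raw = df.loc[contig_ids, sample_cols].to_numpy(dtype=float)
    if (raw < 0).any():
        raise ValueError(f"negative depth values in {tsv_path}")
    normalized = normalize_abundances(raw).normalized
    return AbundanceMatrix(raw=raw, normalized=normalized, sample_names=sample_cols)


def normalize_abundances(raw: np.ndarray) -> AbundanceMatrix:
    """Normalise each contig's depth row to sum to one across samples.

    Mimics the probability that a random read mapping to the contig came
    from each sample. All-zero rows become the uniform vector 1/S.
    """
    # C-contiguous layout fixes the summation order, so results do not
    # depend on whether the matrix arrived from a file or from memory
    raw = np.ascontiguousarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("abundance matrix must be 2-dimensional")
    if (raw < 0).any():
        raise ValueError("abundances must be nonnegative")
    sums = raw.sum(axis=1, keepdims=True)
    n_samples = raw.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(sums > 0, raw / np.where(sums > 0, sums, 1.0),
                              1.0 / n_samples)
    return AbundanceMatrix(raw=raw, normalized=normalized)


def sample_of_contig(contig_id: str, separator: str) -> str:
    """Sample prefix of a contig id: the part before the first separator."""
    prefix, sep, _rest = contig_id.partition(separator)
    if not sep:
        raise ValueError(
            f"contig id {contig_id!r} lacks sample separator {separator!r}; "
            "multi-split binning is impossible"
        )
    if not prefix:
        raise ValueError(
            f"contig id {contig_id!r} has an empty sample prefix before "
            f"separator {separator!r}"
        )
    return prefix


def assemble_dataset(
    tnf: CompositionMatrix,
    ab: AbundanceMatrix,
    contigs: list[ContigRecord],
    separator: str = "C",
) -> FeatureDataset:
    """Concatenate TNF and co-abundance into the model input matrix."""
    n = len(contigs)
    if tnf.values.shape[0] != n or ab.normalized.shape[0] != n:
        raise ValueError("TNF, abundance and contig list row counts differ")
    prefixes = [sample_of_contig(c.id, separator) for c in contigs]
    sample_names = sorted(set(prefixes))
    index = {s: i for i, s in enumerate(sample_names)}
    return FeatureDataset(
        X=np.hstack([tnf.values, ab.normalized]),
        contig_ids=[c.id for c in contigs],
        lengths=[c.length for c in contigs],
        sample_of=[index[p] for p in prefixes],
        sample_names=sample_names,
    )


def load_dataset(
    fasta_path: str | Path,
    depths_path: str | Path,
    min_length: int = 2000,
    separator: str = "C",
) -> FeatureDataset:
    """Read FASTA + depth TSV and assemble the feature dataset in one call."""
    contigs = read_contigs(fasta_path, min_length=min_length)
    kernel = compute_projection_kernel()
    tnf = compute_tnf(contigs, kernel)
    ab = read_depths(depths_path, [c.id for c in contigs])
    return assemble_dataset(tnf, ab, contigs, separator=separator)
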