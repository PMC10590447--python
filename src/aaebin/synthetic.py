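"""Desk-scale synthetic multi-sample metagenomes with exact ground truth.

The generator emulates the statistical structure the binner exploits:

* genomes drawn from genome-specific order-3 Markov chains (Dirichlet-
  sampled transition rows), giving each genome a distinct tetranucleotide
  signature;
* each genome fragmented into contigs that tile the genome without
  overlap; every genome has a home sample and its contigs carry that
  sample's prefix (``S<sample>C<k>``), so the catalogue spans samples the
  way a single co-assembled multi-sample catalogue does;
* per-sample genome abundances drawn i.i.d. log-normal, contig depths
  equal to the genome abundance times multiplicative gamma noise with
  mean 1 — preserving the within-genome co-abundance correlation without
  read-level simulation.

Outputs cross-parse with the feature module (FASTA catalogue, depth TSV in
the jgi dialect) and the benchmark module (truth and taxonomy TSVs), and a
ground-truth quality scorer stands in for an external marker-gene tool:
completeness and contamination are computed bin-versus-assembled-truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ContigRecord

_BASES = "ACGT"


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic metagenome."""

    n_genomes: int = 10
    genome_length: int = 50_000
    n_samples: int = 8
    n_contigs_per_genome: int = 10
    contig_min_length: int = 3_000
    contig_max_length: int = 7_000
    abundance_mu: float = 0.0  # log-normal location of per-sample abundance
    abundance_sigma: float = 1.0  # log-normal scale: order-of-magnitude spread
    depth_dispersion: float = 0.05  # relative sd of multiplicative depth noise
    markov_order: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genomes", "genome_length", "n_samples", "n_contigs_per_genome",
            "contig_min_length", "contig_max_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.markov_order not in (0, 1, 2, 3):
            raise ValueError("markov_order must be in {0, 1, 2, 3}")
        if self.depth_dispersion < 0 or self.abundance_sigma < 0:
            raise ValueError("dispersion parameters must be nonnegative")
        if self.contig_min_length > self.contig_max_length:
            raise ValueError("contig_min_length exceeds contig_max_length")


@dataclass
class SyntheticMetagenome:
    spec: SyntheticSpec
    genomes: list[str]
    contigs: list[ContigRecord]
    truth: pd.DataFrame  # columns contig, genome, covered_bp
    taxonomy: pd.DataFrame  # columns genome, species, genus
    depths: pd.DataFrame  # jgi-dialect depth table
    abundances: np.ndarray = field(default=None)  # (n_genomes, n_samples)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.contigs}

    @property
    def genome_of(self) -> dict[str, str]:
        return dict(zip(self.truth["contig"], self.truth["genome"]))


def generate_genomes(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    """One sequence per genome from its own Markov transition table."""
    order = spec.markov_order
    n_states = 4**order
    genomes = []
    for _ in range(spec.n_genomes):
        # Dirichlet(1) rows: distinct, moderately skewed transition tables
        table = rng.dirichlet(np.ones(4), size=n_states)
        cum = np.cumsum(table, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(spec.genome_length)
        seq = np.empty(spec.genome_length, dtype=np.int64)
        state = 0
        for i in range(spec.genome_length):
            row = cum[state]
            b = int(np.searchsorted(row, u[i], side="right"))
            b = min(b, 3)
            seq[i] = b
            if order > 0:
                state = (state * 4 + b) % n_states
        genomes.append("".join(_BASES[b] for b in seq))
    return genomes


def _fragment_lengths(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[int]:
    """Contig lengths tiling one genome completely (no overlap, no gaps)."""
    n = spec.n_contigs_per_genome
    raw = rng.uniform(spec.contig_min_length, spec.contig_max_length, size=n)
    scaled = np.floor(raw * spec.genome_length / raw.sum()).astype(int)
    scaled[-1] = spec.genome_length - int(scaled[:-1].sum())
    if (scaled <= 0).any():
        raise ValueError(
            "contig length bounds incompatible with genome_length / "
            "n_contigs_per_genome"
        )
    return [int(v) for v in scaled]


def fragment_genomes(
    genomes: list[str], spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[ContigRecord], pd.DataFrame, pd.DataFrame]:
    """Cut genomes into contigs and emit truth + taxonomy tables.

    Genome g's home sample is ``g mod n_samples``; all its contigs carry
    that sample's prefix. Covered bp equals contig length by construction.
    Taxonomy: each genome its own species; genera assigned in pairs.
    """
    contigs: list[ContigRecord] = []
    truth_rows = []
    tax_rows = []
    counter = 0
    for g, genome_seq in enumerate(genomes):
        genome_id = f"G{g:03d}"
        sample = g % spec.n_samples
        tax_rows.append(
            {
                "genome": genome_id,
                "species": f"species{g:03d}",
                "genus": f"genus{g // 2:03d}",
            }
        )
        pos = 0
        for length in _fragment_lengths(spec, rng):
            counter += 1
            cid = f"S{sample}C{counter}"
            contigs.append(ContigRecord(id=cid, sequence=genome_seq[pos: pos + length]))
            truth_rows.append(
                {"contig": cid, "genome": genome_id, "covered_bp": length}
            )
            pos += length
    return (
        contigs,
        pd.DataFrame(truth_rows, columns=["contig", "genome", "covered_bp"]),
        pd.DataFrame(tax_rows, columns=["genome", "species", "genus"]),
    )


def simulate_depths(
    truth: pd.DataFrame,
    contig_lengths: dict[str, int],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-contig per-sample depths in the jgi dialect.

    Genome g's abundance in sample s is log-normal(mu_a, sigma_a) i.i.d.;
    each contig's depth is its genome's abundance times gamma noise with
    mean 1 and relative standard deviation ``depth_dispersion``.
    """
    genome_ids = sorted(truth["genome"].unique())
    abundances = rng.lognormal(
        spec.abundance_mu, spec.abundance_sigma,
        size=(len(genome_ids), spec.n_samples),
    )
    genome_index = {g: i for i, g in enumerate(genome_ids)}
    n_contigs = len(truth)
    depth = np.empty((n_contigs, spec.n_samples))
    for i, genome in enumerate(truth["genome"]):
        profile = abundances[genome_index[genome]]
        if spec.depth_dispersion > 0:
            shape = 1.0 / spec.depth_dispersion**2
            noise = rng.gamma(shape, 1.0 / shape, size=spec.n_samples)
        else:
            noise = np.ones(spec.n_samples)
        depth[i] = profile * noise
    table = pd.DataFrame({"contigName": truth["contig"]})
    table["contigLen"] = [contig_lengths[c] for c in truth["contig"]]
    table["totalAvgDepth"] = depth.mean(axis=1)
    for s in range(spec.n_samples):
        table[f"S{s}.bam"] = depth[:, s]
    return table, abundances


def generate_metagenome(spec: SyntheticSpec) -> SyntheticMetagenome:
    """Run the whole generator under one seed; bitwise reproducible."""
    rng = np.random.default_rng(spec.seed)
    genomes = generate_genomes(spec, rng)
    contigs, truth, taxonomy = fragment_genomes(genomes, spec, rng)
    lengths = {c.id: c.length for c in contigs}
    depths, abundances = simulate_depths(truth, lengths, spec, rng)
    return SyntheticMetagenome(
        spec=spec, genomes=genomes, contigs=contigs, truth=truth,
        taxonomy=taxonomy, depths=depths, abundances=abundances,
    )


class GroundTruthScorer:
    """Bin quality from the synthetic truth (stand-in for an external
    marker-gene quality tool).

    Completeness is the dominant genome's bp in the bin over that genome's
    total assembled bp; contamination is the non-dominant bp over the same
    denominator. Dominance ties break lexicographically on genome id.
    """

    def __init__(self, truth: pd.DataFrame):
        self.genome_of = dict(zip(truth["contig"], truth["genome"]))
        self.covered_bp = dict(
            zip(truth["contig"], truth["covered_bp"].astype(int))
        )
        self.assembled_bp: dict[str, int] = {}
        for contig, genome in self.genome_of.items():
            self.assembled_bp[genome] = (
                self.assembled_bp.get(genome, 0) + self.covered_bp[contig]
            )

    def score_bin(self, name: str, contigs: frozenset[str]) -> tuple[float, float]:
        if not contigs:
            raise ValueError(f"cannot score empty bin {name!r}")
        by_genome: dict[str, int] = {}
        for contig in contigs:
            genome = self.genome_of.get(contig)
            if genome is None:
                raise KeyError(f"contig {contig!r} absent from ground truth")
            by_genome[genome] = by_genome.get(genome, 0) + self.covered_bp[contig]
        dominant = min(by_genome, key=lambda g: (-by_genome[g], g))
        denom = self.assembled_bp[dominant]
        completeness = min(1.0, by_genome[dominant] / denom)
        contamination = (sum(by_genome.values()) - by_genome[dominant]) / denom
        return completeness, contamination


def ground_truth_scorer(truth: pd.DataFrame) -> GroundTruthScorer:
    return GroundTruthScorer(truth)


def write_fasta(contigs: list[ContigRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, contig.length, width):
                fh.write(contig.sequence[i: i + width] + "\n")


def write_metagenome(meta: SyntheticMetagenome, outdir: str | Path) -> dict[str, Path]:
    """Materialise the four standard files (+ spec echo) into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "catalogue.fna",
        "depths": outdir / "depths.tsv",
        "truth": outdir / "truth.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "spec": outdir / "spec.yaml",
    }
    write_fasta(meta.contigs, paths["fasta"])
    # full-precision floats so a file round-trip reproduces in-memory runs
    meta.depths.to_csv(paths["depths"], sep="\t", index=False)
    meta.truth.to_csv(paths["truth"], sep="\t", index=False)
    meta.taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    import yaml

    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(vars(meta.spec), fh, sort_keys=True)
    return paths
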