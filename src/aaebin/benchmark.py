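"""Ground-truth benchmarking of bins against reference genomes.

For a bin B and genome G, precision is the fraction of the bin's covered
base pairs that belong to G, and recall is the fraction of G's total base
pairs covered by the bin:

    precision(B, G) = bp of G covered by B / bp of any genome covered by B
    recall(B, G)    = bp of G covered by B / total bp of G

At a higher clade L (species, genus) recall is the maximum and precision
the sum over L's genomes. A genome or clade counts as recovered when any
bin covering at least one of its base pairs reaches both thresholds
(typically recall 0.9 / precision 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clustering import BinSet

STRAIN, SPECIES, GENUS = "strain", "species", "genus"
LEVELS = (STRAIN, SPECIES, GENUS)

# alternative threshold preset used during model selection
SELECTION_THRESHOLDS = (0.9, 0.9, True)  # (recall, precision, strict)
DEFAULT_RECALL_THRESHOLD = 0.9
DEFAULT_PRECISION_THRESHOLD = 0.95


@dataclass
class GenomeReference:
    """Truth: contig -> (genome, covered bp), genome sizes, taxonomy.

    Genome sizes default to the summed covered bp over the catalogue (the
    assembled genome size); pass ``genome_sizes`` to override, e.g. with
    the true genome lengths.
    """

    contig_genome: dict[str, str]
    contig_covered_bp: dict[str, int]
    genome_sizes: dict[str, int] = field(default_factory=dict)
    species_of: dict[str, str] = field(default_factory=dict)
    genus_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genome_sizes:
            sizes: dict[str, int] = {}
            for contig, genome in self.contig_genome.items():
                sizes[genome] = sizes.get(genome, 0) + self.contig_covered_bp[contig]
            self.genome_sizes = sizes
        for genome, size in self.genome_sizes.items():
            if size <= 0:
                raise ValueError(f"genome {genome} has non-positive total bp")

    @property
    def genomes(self) -> list[str]:
        return sorted(self.genome_sizes)

    def clade_of(self, genome: str, level: str) -> str:
        if level == STRAIN:
            return genome
        if level == SPECIES:
            return self.species_of.get(genome, genome)
        if level == GENUS:
            return self.genus_of.get(genome, genome)
        raise ValueError(f"unknown taxonomic level {level!r}")

    def clades(self, level: str) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for genome in self.genomes:
            out.setdefault(self.clade_of(genome, level), []).append(genome)
        return out

    @classmethod
    def from_files(
        cls,
        truth_tsv: str | Path,
        taxonomy_tsv: str | Path | None = None,
        genome_sizes: dict[str, int] | None = None,
    ) -> "GenomeReference":
        truth = pd.read_csv(truth_tsv, sep="\t")
        for col in ("contig", "genome", "covered_bp"):
            if col not in truth.columns:
                raise ValueError(f"truth file {truth_tsv} missing column {col!r}")
        species_of: dict[str, str] = {}
        genus_of: dict[str, str] = {}
        if taxonomy_tsv is not None:
            tax = pd.read_csv(taxonomy_tsv, sep="\t")
            for col in ("genome", "species", "genus"):
                if col not in tax.columns:
                    raise ValueError(
                        f"taxonomy file {taxonomy_tsv} missing column {col!r}"
                    )
            species_of = dict(zip(tax["genome"], tax["species"]))
            genus_of = dict(zip(tax["genome"], tax["genus"]))
        return cls(
            contig_genome=dict(zip(truth["contig"], truth["genome"])),
            contig_covered_bp=dict(
                zip(truth["contig"], truth["covered_bp"].astype(int))
            ),
            genome_sizes=genome_sizes or {},
            species_of=species_of,
            genus_of=genus_of,
        )


def genome_bp_in_bin(bin_contigs: set[str], ref: GenomeReference) -> dict[str, int]:
    """Covered bp per genome among a bin's contigs (truthless contigs ignored)."""
    out: dict[str, int] = {}
    for contig in bin_contigs:
        genome = ref.contig_genome.get(contig)
        if genome is not None:
            out[genome] = out.get(genome, 0) + ref.contig_covered_bp[contig]
    return out


def precision_recall(
    bin_contigs: set[str], ref: GenomeReference
) -> dict[str, tuple[float, float]]:
    """Per-genome (precision, recall) of a bin; genomes not covered by the
    bin are omitted (their recall is 0)."""
    by_genome = genome_bp_in_bin(bin_contigs, ref)
    total_covered = sum(by_genome.values())
    out = {}
    for genome, bp in by_genome.items():
        precision = bp / total_covered if total_covered else 0.0
        recall = bp / ref.genome_sizes[genome]
        out[genome] = (precision, recall)
    return out


def clade_metrics(
    genome_metrics: dict[str, tuple[float, float]],
    ref: GenomeReference,
    level: str,
) -> dict[str, tuple[float, float]]:
    """(precision, recall) per clade: precision sums, recall maxes over the
    clade's genomes present in the bin."""
    out: dict[str, tuple[float, float]] = {}
    for genome, (precision, recall) in genome_metrics.items():
        clade = ref.clade_of(genome, level)
        if clade in out:
            p, r = out[clade]
            out[clade] = (p + precision, max(r, recall))
        else:
            out[clade] = (precision, recall)
    return out


def count_recovered(
    bins: BinSet,
    ref: GenomeReference,
    recall_threshold: float = DEFAULT_RECALL_THRESHOLD,
    precision_threshold: float = DEFAULT_PRECISION_THRESHOLD,
    level: str = STRAIN,
    strict: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Number of clades recovered by any single bin at the thresholds.

    A clade is recovered if some bin covering >= 1 bp of it has clade
    recall and precision at or above the thresholds (strictly above with
    ``strict=True``, the model-selection convention). Returns the count
    and a per-clade best-bin table.
    """
    best: dict[str, tuple[float, float, str]] = {}
    recovered: set[str] = set()
    for name in sorted(bins.bins):
        metrics = clade_metrics(
            precision_recall(bins.bins[name], ref), ref, level
        )
        for clade, (precision, recall) in metrics.items():
            key = (recall, precision)
            if clade not in best or key > best[clade][:2]:
                best[clade] = (recall, precision, name)
            if strict:
                ok = recall > recall_threshold and precision > precision_threshold
            else:
                ok = recall >= recall_threshold and precision >= precision_threshold
            if ok:
                recovered.add(clade)
    rows = [
        {
            "clade": clade,
            "level": level,
            "best_bin": name,
            "recall": recall,
            "precision": precision,
            "recovered": clade in recovered,
        }
        for clade, (recall, precision, name) in sorted(best.items())
    ]
    for clade in ref.clades(level):
        if clade not in best:
            rows.append(
                {
                    "clade": clade, "level": level, "best_bin": "",
                    "recall": 0.0, "precision": 0.0, "recovered": False,
                }
            )
    table = pd.DataFrame(
        rows, columns=["clade", "level", "best_bin", "recall", "precision", "recovered"]
    ).sort_values("clade").reset_index(drop=True)
    return len(recovered), table
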