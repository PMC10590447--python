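"""High-level pipeline: features -> train -> cluster -> split -> de-replicate.

This module glues the per-stage modules into the runs the command-line
interface exposes, and provides the scaled-down synthetic end-to-end run
used for validation: a 10-genome, 8-sample catalogue binned with a reduced
model (64 hidden units, 16-dim z, 32-dim y, 200 epochs, batches of 32).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .aae import AAE, AAEConfig, LatentCodes
from .benchmark import GenomeReference, count_recovered
from .clustering import (
    BinSet,
    ClusterAssignment,
    ClusterParams,
    cluster_z,
    clusters_from_y,
    multi_split,
)
from .dereplication import DereplicationLog, QualityScorer, dereplicate
from .features import (
    FeatureDataset,
    assemble_dataset,
    compute_projection_kernel,
    compute_tnf,
    normalize_abundances,
)
from .synthetic import (
    GroundTruthScorer,
    SyntheticMetagenome,
    SyntheticSpec,
    generate_metagenome,
)

logger = logging.getLogger(__name__)

# the reduced model used for desk-scale synthetic runs
REDUCED_MODEL = dict(
    n_hidden=64, n_hidden_layers=2, n_z=16, n_y=32, epochs=200, batch_size=32
)


@dataclass
class BinningResult:
    model: AAE
    latents: LatentCodes
    z_assignment: ClusterAssignment
    y_assignment: ClusterAssignment
    z_bins: BinSet
    y_bins: BinSet
    dereplicated: BinSet | None
    derep_log: DereplicationLog | None


def run_binning(
    dataset: FeatureDataset,
    config: AAEConfig,
    separator: str = "C",
    cluster_params: ClusterParams | None = None,
    scorer: QualityScorer | None = None,
    extra_bin_sets: list[BinSet] | None = None,
    skip_dereplication: bool = False,
) -> BinningResult:
    """Train the AAE and produce z/y bin sets, optionally de-replicated.

    De-replication (of z + y + any ``extra_bin_sets``, e.g. another
    binner's output) requires a quality scorer; without one, or with
    ``skip_dereplication``, the two bin sets are returned separately.
    """
    model = AAE(dataset.n_samples, config)
    model.train(dataset)
    latents = model.extract_latents(dataset)
    z_assignment = cluster_z(
        latents.Z, dataset.contig_ids, dataset.lengths, cluster_params
    )
    y_assignment = clusters_from_y(latents.Y, dataset.contig_ids)
    z_bins = multi_split(z_assignment, separator)
    y_bins = multi_split(y_assignment, separator)
    dereplicated = None
    derep_log = None
    if scorer is not None and not skip_dereplication:
        derep_log = DereplicationLog()
        lengths = dict(zip(dataset.contig_ids, dataset.lengths))
        dereplicated = dereplicate(
            [z_bins, y_bins] + (extra_bin_sets or []),
            scorer,
            lengths,
            log=derep_log,
        )
    return BinningResult(
        model=model,
        latents=latents,
        z_assignment=z_assignment,
        y_assignment=y_assignment,
        z_bins=z_bins,
        y_bins=y_bins,
        dereplicated=dereplicated,
        derep_log=derep_log,
    )


def dataset_from_metagenome(meta: SyntheticMetagenome) -> FeatureDataset:
    """Build the feature dataset from an in-memory synthetic metagenome."""
    kernel = compute_projection_kernel()
    tnf = compute_tnf(meta.contigs, kernel)
    sample_cols = [c for c in meta.depths.columns
                   if c not in ("contigName", "contigLen", "totalAvgDepth")]
    order = {cid: i for i, cid in enumerate(meta.depths["contigName"])}
    raw = meta.depths[sample_cols].to_numpy(dtype=float)
    raw = raw[[order[c.id] for c in meta.contigs]]
    ab = normalize_abundances(raw)
    return assemble_dataset(tnf, ab, meta.contigs, separator="C")


def reference_from_metagenome(meta: SyntheticMetagenome) -> GenomeReference:
    return GenomeReference(
        contig_genome=dict(zip(meta.truth["contig"], meta.truth["genome"])),
        contig_covered_bp=dict(
            zip(meta.truth["contig"], meta.truth["covered_bp"].astype(int))
        ),
        species_of=dict(zip(meta.taxonomy["genome"], meta.taxonomy["species"])),
        genus_of=dict(zip(meta.taxonomy["genome"], meta.taxonomy["genus"])),
    )


@dataclass
class SyntheticRunSummary:
    seed: int
    n_genomes: int
    n_recovered: int
    n_final_bins: int
    ari_z: float
    ari_y: float
    result: BinningResult
    meta: SyntheticMetagenome


def _adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index between two labelings (pair-counting form)."""
    from collections import Counter

    n = len(labels_a)
    if n != len(labels_b):
        raise ValueError("label lists differ in length")
    contingency = Counter(zip(labels_a, labels_b))
    a_counts = Counter(labels_a)
    b_counts = Counter(labels_b)

    def comb2(x: int) -> float:
        return x * (x - 1) / 2.0

    sum_ij = sum(comb2(v) for v in contingency.values())
    sum_a = sum(comb2(v) for v in a_counts.values())
    sum_b = sum(comb2(v) for v in b_counts.values())
    expected = sum_a * sum_b / comb2(n) if n > 1 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def _cluster_labels(assignment: ClusterAssignment, contig_ids: list[str]) -> list[str]:
    label_of = {}
    for name, members in assignment.clusters.items():
        for contig in members:
            label_of[contig] = name
    return [label_of[c] for c in contig_ids]


def run_synthetic_benchmark(
    seed: int,
    spec: SyntheticSpec | None = None,
    model_overrides: dict | None = None,
    recall_threshold: float = 0.9,
    precision_threshold: float = 0.95,
) -> SyntheticRunSummary:
    """End-to-end scaled-down run: generate, bin, de-replicate, evaluate.

    The same seed drives the generator and the model, so the whole run is
    reproducible from one integer.
    """
    spec = replace(spec or SyntheticSpec(), seed=seed)
    meta = generate_metagenome(spec)
    dataset = dataset_from_metagenome(meta)
    config = AAEConfig(**{**REDUCED_MODEL, **(model_overrides or {}), "seed": seed})
    scorer = GroundTruthScorer(meta.truth)
    result = run_binning(dataset, config, scorer=scorer)
    ref = reference_from_metagenome(meta)
    n_recovered, _table = count_recovered(
        result.dereplicated, ref,
        recall_threshold=recall_threshold,
        precision_threshold=precision_threshold,
    )
    genome_of = meta.genome_of
    true_labels = [genome_of[c] for c in dataset.contig_ids]
    ari_z = _adjusted_rand_index(
        true_labels, _cluster_labels(result.z_assignment, dataset.contig_ids)
    )
    ari_y = _adjusted_rand_index(
        true_labels, [str(v) for v in result.latents.Y]
    )
    logger.info(
        "synthetic run seed=%d: %d/%d genomes recovered, ARI z=%.3f y=%.3f",
        seed, n_recovered, spec.n_genomes, ari_z, ari_y,
    )
    return SyntheticRunSummary(
        seed=seed,
        n_genomes=spec.n_genomes,
        n_recovered=n_recovered,
        n_final_bins=len(result.dereplicated.bins),
        ari_z=ari_z,
        ari_y=ari_y,
        result=result,
        meta=meta,
    )
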