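# Methods

## Input representation

**TNF projection.** Tetramers are counted on the given strand with
overlapping windows; any window containing a non-ACGT symbol is skipped.
Counts are normalised to frequencies (a contig with no valid window gets
the uniform vector, which projects to zero — "no information"). The
256-dim frequency vector is projected by a fixed 256×103 orthonormal
kernel: the null-space basis of the constraint matrix stacking (i) the
all-ones row (frequencies sum to a constant), (ii) one difference row per
reverse-complement tetramer pair (single-strand counts carry no strand
information), and (iii) one prefix-minus-suffix row per trinucleotide
(in a long sequence, 4-mers starting with a 3-mer and 4-mers ending with
it both sum to that 3-mer's frequency, up to edge effects). The
constraint matrix has rank 153, leaving the familiar 103 free dimensions.
The basis is orthonormalised by SVD with a fixed sign convention (first
non-negligible entry of each column positive), so the kernel is
deterministic. Because the kernel is reverse-complement invariant,
counting on one strand or canonicalising during counting are equivalent;
we count one strand. Projected features are z-scaled per dimension across
the catalogue; zero-variance dimensions are left at zero after centring.

**Co-abundance.** Depths are read from a
`jgi_summarize_bam_contig_depths`-style TSV (variance columns detected by
the `-var` header suffix and ignored; `totalAvgDepth` ignored). The 1/n
multi-mapping read split is the upstream depth tool's job; the TSV is the
interface. Each contig's depth row is normalised to sum to 1 (all-zero
rows become uniform 1/S), mimicking the probability that a random read
mapping to the contig came from each sample. Depth parsing uses
round-trip float precision and a fixed summation order, so file-based and
in-memory runs are bit-identical.

## Model

Encoder: two dense layers (547 units at full scale) with leaky-ReLU and
batch normalisation, feeding three heads — μ and σ (283 each; σ is the
exponential of a linear output clamped to [1e-6, 50]) and 700 y-logits.
Decoder mirrors the encoder from `[z ‖ y]`; the abundance head is a
softmax (the input block is a distribution), the TNF head linear. The two
discriminators share the hidden shape but use no batch normalisation and
end in a single node; a softmax over a single output is degenerate
(identically 1), so the node is a sigmoid — the only form under which the
binary cross-entropies are well-defined.

**Losses.** All CE/BCE terms clamp probabilities at 1e-9, so saturated
outputs give large but finite losses. The reconstruction loss is
`w_coab·CE + w_TNF·MSE` with CE the per-row cross-entropy of the
abundance distributions and MSE the element-mean squared TNF error.
Defaults `w_coab = 0.85/ln S` (0.85 when S = 1) keep the CE term
scale-stable in the number of samples; `w_TNF = 0.15` reproduces the
established VAMB-style balance between the two blocks given that our MSE
is an element mean rather than a per-row sum. Two published forms of the
regularisation term exist; the default is the numerically stable
non-saturating form `(1−slr)·BCE(D_z(z),1) + slr·BCE(D_y(y),1)`, with the
negated-discriminator-loss form available via
`AAEConfig(minimax_regularization=True)`. The temperature τ = 0.1596 (the
tuned final value) is used both for the encoder's Gumbel-softmax
relaxation and for sampling the categorical prior.

**Training.** Each minibatch performs three Adam updates in fixed order:
encoder/decoder on `L = (1−sl)·L_rec + sl·L_reg` (gradients flow through
the discriminators, whose parameter gradients are then discarded), D_z on
LDz, D_y on LDy. Per-batch alternation and μ (not a posterior sample) as
the clustering input are deliberate design choices of this
implementation; both favour stability and determinism. Defaults: batch 256, 300 epochs,
learning rate 1e-3 for all three optimisers, all CLI-exposed. Runs are
seeded end to end and single-threaded NumPy, so identical config + seed
gives identical loss histories, latents, clusters and bins. A non-finite
loss aborts training naming the offending term. Latent extraction always
runs in evaluation mode (batchnorm running statistics, no sampling):
`Z = μ(X)`, `Y = argmax y_probs(X)`.

## Clustering

z is clustered by iterative medoid search on cosine distance
`d = (1 − cos)/2 ∈ [0, 1]` over per-dimension-centred, length-normalised
latent rows (rows equal to the centroid fall back to their uncentred
direction so identical inputs stay at distance zero). Seeds are drawn in
descending contig-length order (ties by id); the seed wanders to a local
medoid among neighbours within 0.05 (up to 25 steps, moving only on
strict improvement); the cluster radius is the first density valley of
the medoid's distance histogram (bin width 0.005 over [0, 0.3]; a valley
bin falls below 60 % of the running peak and does not exceed its right
neighbour), falling back to 0.09 when no valley exists. All parameters
are configurable; they are this package's own deterministic
instantiation of the medoid-wander-and-valley clustering family used by
reference-free binners. A wandering medoid can leave its seed outside the emitted
cluster; seeds are therefore re-drawn until every contig is clustered,
and termination is guaranteed because every cluster contains its medoid.
y needs no clustering: equal labels form a cluster. Multi-split then
partitions each cluster by the contig id's sample prefix (the part before
the first separator, default `C`), naming bins
`<origin><cluster><separator><sample>`.

## De-replication

Bins are scored `completeness − 5·contamination`; the near-complete (NC)
filter is strict on both sides (completeness > 0.9, contamination
< 0.05). Near-identical pairs (shared bp ≥ 75 % of the smaller bin's bp)
are processed by descending overlap then lexicographic names, removing
the lower-scoring member (ties: smaller total bp loses, then the
lexicographically larger name); bins are not re-scored between pair
removals, since removal deletes whole bins and leaves the others
unchanged. Remaining shared contigs are reassigned in lexicographic
order: each owner is re-scored with and without the contig against its
*current* contents, the largest score drop wins (ties: higher current
score, then lexicographic name), and the contig is removed from the rest
(bins emptied in the process are dropped). The output is asserted
duplicate-free on every run. Scorers are pluggable: the report-file
adapter parses an external quality TSV (percent scales auto-detected by
completeness > 1.5 and divided by 100) but, being a name-keyed lookup,
returns unchanged scores for modified bins — its reassignment score drops
are 0 and ties decide; the ground-truth scorer recomputes exactly.
Overlap is exact shared-contig identity within one catalogue; no sequence
alignment is attempted, which is precisely why this narrower problem is
solvable without an ANI-based tool.

## Benchmarking

Per bin and genome, precision is the genome's covered bp over all covered
bp in the bin, recall is the genome's covered bp over the genome's total
bp; per clade, precision sums and recall maxes over the clade's genomes.
Genome totals default to the summed covered bp over the catalogue (the
assembled size) because the truth table carries only per-contig coverage;
an explicit size map can override this. A clade counts as recovered when
a single bin covering at least 1 bp of it meets both thresholds
(inclusive ≥ at the default 0.9/0.95; a strict-inequality preset matches
the model-selection convention of > 0.9/> 0.9). Clade precision can
exceed 1 only if contig placements overlap within a genome; the synthetic
generator never produces such overlaps.

## Synthetic data

The generator emulates a single multi-sample co-assembled catalogue.
Defaults — 10 genomes × 50 kb, 8 samples, 10 contigs per genome
(3–7 kb, tiling each genome completely), log-normal(0, 1) per-sample
genome abundances, gamma depth noise with relative sd 0.05, order-3
Markov composition with Dirichlet(1) transition rows — are the conditions
used throughout the tests and the acceptance script. Each genome has a
home sample (round-robin) and all its contigs carry that sample's prefix,
as when each genome is assembled from the sample that dominates its
coverage; genomes, not individual contigs, are therefore distributed
across samples, which keeps whole genomes recoverable after multi-split.
Abundance is multiplicative per contig and sample (no read-level
simulation, no sequencing error, no strain mixtures, no inter-genome
homology); taxonomy assigns each genome its own species and genera in
pairs. Consequently, passing tests demonstrate that the machinery
recovers genomes when composition and co-abundance signals are present
and clean — they do not bound performance on real assemblies, where
fragmented repeats, uneven coverage and shared sequence blur both
signals.

## Scaled-down validation

The end-to-end checks run the default generator with a reduced model
(64 hidden units, z = 16, y = 32, 200 epochs, batches of 32 — chosen so
several optimiser steps occur per epoch on a 100-contig catalogue) for
three seeds, requiring ≥ 7/10 genomes recovered at recall ≥ 0.9 /
precision ≥ 0.95 for at least one seed; a run takes a few seconds on one
CPU. Training adversarial models is seed-sensitive at this scale — the
mean across seeds is typically 6–9 genomes — which is why the check takes
the best of three seeds. `scripts/acceptance.py` reports both the best and the
mean, alongside the analytic checks (kernel algebra to 1e-8/1e-10, the
Gumbel-softmax mean max-component > 0.99 at τ = 0.01 over 1000 draws, and
the exact `L = (1−sl)·L_rec + sl·L_reg` decomposition at every step).

## Known limitations

* The AAE is NumPy on one CPU; full-scale catalogues (hundreds of
  thousands of contigs, 283/700-dim latents) train far slower than a GPU
  implementation would.
* The report-file quality scorer cannot re-score modified bins (above);
  with it, contig reassignment degenerates to the tie rules.
* Medoid clustering is O(n·m) in distance computations per cluster and is
  tuned for latent geometries resembling the synthetic conditions; the
  valley heuristic can fragment diffuse clusters (the y space and
  de-replication partly compensate).
* Single-copy-gene re-clustering, alignment-based de-replication and
  marker-gene quality estimation are out of scope; external tools'
  outputs are consumed through files instead.
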