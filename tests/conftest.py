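import pytest

from aaebin.features import compute_projection_kernel
from aaebin.pipeline import dataset_from_metagenome, run_synthetic_benchmark
from aaebin.synthetic import SyntheticSpec, generate_metagenome

E2E_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def kernel():
    return compute_projection_kernel()


@pytest.fixture(scope="session")
def tiny_meta():
    """A small but well-separated synthetic metagenome for unit tests."""
    return generate_metagenome(
        SyntheticSpec(
            n_genomes=4,
            genome_length=12_000,
            n_samples=3,
            n_contigs_per_genome=6,
            contig_min_length=1_500,
            contig_max_length=2_500,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_meta):
    return dataset_from_metagenome(tiny_meta)


@pytest.fixture(scope="session")
def e2e_runs():
    """Scaled-down full-pipeline runs at the study conditions, one per seed.

    Computed once per session; several tests read off different facets
    (genome recovery, cluster agreement with truth).
    """
    return {seed: run_synthetic_benchmark(seed) for seed in E2E_SEEDS}
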