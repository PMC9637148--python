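import numpy as np
import pytest

from chromoformer import (
    FeatureConfig,
    GeneRecord,
    ModelConfig,
    SimConfig,
    derive_labels,
    featurize_dataset,
    simulate,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """Tiny synthetic dataset: 2 chromosomes x 20 genes, fixed seed."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_tracks(tiny_sim):
    return tiny_sim.coverage_tracks()


def _genes_of(sim):
    return [
        GeneRecord(t.gene_id, t.chrom, int(t.tss), t.strand)
        for t in sim.truth.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def tiny_genes(tiny_sim):
    return _genes_of(tiny_sim)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim, tiny_tracks, tiny_genes):
    """Tiny dataset featurized at the standard 100/500/2000 bp resolutions."""
    labels = derive_labels(tiny_sim.expression.set_index("gene_id"), "clf", "sim")
    return featurize_dataset(
        tiny_genes,
        tiny_tracks,
        tiny_sim.interactions[["gene_id", "chrom", "start", "end", "norm_freq"]],
        labels,
        FeatureConfig(),
        k_folds=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_dataset(tiny_sim, tiny_tracks, tiny_genes):
    """Same tiny genes at the coarse 1000/2000/4000 bp scale used for
    CPU-sized training tests."""
    labels = derive_labels(tiny_sim.expression.set_index("gene_id"), "clf", "sim")
    return featurize_dataset(
        tiny_genes,
        tiny_tracks,
        tiny_sim.interactions[["gene_id", "chrom", "start", "end", "norm_freq"]],
        labels,
        FeatureConfig(resolutions=(1000, 2000, 4000)),
        k_folds=2,
        seed=11,
    )


@pytest.fixture
def toy_model_config():
    return ModelConfig.scaled_down(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
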