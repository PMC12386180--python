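import pytest

from genmon.synthetic import (
    NO_ERROR,
    SurveyDesign,
    generate_reference_clusters,
    simulate_pedigree,
    simulate_survey,
)


@pytest.fixture(scope="session")
def divergent_world():
    """Four well-separated clusters plus the 19-locus panel."""
    clusters, loci = generate_reference_clusters(
        n_loci=18, alleles_per_locus=8, divergence=0.5, seed=11
    )
    return clusters, loci


@pytest.fixture(scope="session")
def small_pedigree(divergent_world):
    clusters, loci = divergent_world
    individuals = simulate_pedigree(
        clusters, loci, n_founders_per_cluster=6, n_generations=2, seed=21
    )
    return individuals, loci


@pytest.fixture(scope="session")
def clean_survey(small_pedigree):
    """Zero-error full-detection survey over the pedigree."""
    individuals, loci = small_pedigree
    design = SurveyDesign(
        "winter_1", detection_prob=1.0, replicates_per_sample=8
    )
    samples, truth = simulate_survey(
        individuals, design, NO_ERROR, loci, seed=31
    )
    return samples, truth, individuals, loci
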