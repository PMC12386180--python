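"""Generator contracts: determinism, divergence behaviour, Mendelian
inheritance, and the replicate error process."""

import numpy as np
import pytest

from genmon.synthetic import (
    NO_ERROR,
    ErrorModel,
    SurveyDesign,
    alleles_in_parents,
    apparent_homozygote_rate,
    default_panel,
    generate_reference_clusters,
    mean_fst,
    simulate_pedigree,
    simulate_survey,
)


def test_panel_shape_and_sex_locus():
    loci = default_panel()
    assert len(loci) == 19
    assert sum(l.is_sex_linked for l in loci) == 1
    for l in loci:
        assert len({a % l.repeat_unit for a in l.allele_sizes}) == 1


def test_cluster_frequencies_are_valid_and_deterministic():
    c1, _ = generate_reference_clusters(6, 4, 0.2, seed=5)
    c2, _ = generate_reference_clusters(6, 4, 0.2, seed=5)
    for a, b in zip(c1, c2):
        assert a.freqs == b.freqs
    for cluster in c1:
        for table in cluster.freqs.values():
            assert abs(sum(table.values()) - 1.0) < 1e-9


def test_zero_divergence_collapses_clusters():
    clusters, loci = generate_reference_clusters(6, 4, 0.0, seed=1)
    first = clusters[0].freqs
    for c in clusters[1:]:
        assert c.freqs == first
    assert mean_fst(clusters, loci) < 1e-12


def test_divergence_orders_fst_and_high_divergence_private_alleles():
    low, loci = generate_reference_clusters(12, 6, 0.05, seed=3)
    high, _ = generate_reference_clusters(12, 6, 0.8, seed=3)
    assert mean_fst(high, loci) > mean_fst(low, loci)
    # private alleles: scan the emitted high-divergence panel for an allele
    # effectively present in exactly one cluster
    found_private = False
    for locus in loci:
        if locus.is_sex_linked:
            continue
        for a in locus.allele_sizes:
            carriers = [
                c.name
                for c in high
                if c.freqs[locus.name].get(a, 0.0) > 0.05
            ]
            if len(carriers) == 1:
                found_private = True
    assert found_private


def test_invalid_divergence_rejected():
    with pytest.raises(ValueError):
        generate_reference_clusters(6, 4, 1.5, seed=0)


def test_pedigree_ancestry_propagates_as_parental_mean(divergent_world):
    clusters, loci = divergent_world
    individuals = simulate_pedigree(
        clusters, loci, n_founders_per_cluster=4, n_generations=2, seed=9
    )
    by_id = {i.id: i for i in individuals}
    offspring = [i for i in individuals if i.mother_id is not None]
    assert offspring
    for off in offspring:
        expected = (
            by_id[off.mother_id].ancestry_true
            + by_id[off.father_id].ancestry_true
        ) / 2.0
        np.testing.assert_allclose(off.ancestry_true, expected)
        assert abs(off.ancestry_true.sum() - 1.0) < 1e-12


def test_pedigree_mendelian_inheritance_exhaustive(divergent_world):
    """With mutation off, every offspring allele occurs in a parent and the
    Y allele follows the father->son path."""
    clusters, loci = divergent_world
    individuals = simulate_pedigree(
        clusters, loci, n_founders_per_cluster=6, n_generations=3,
        mutation_rate=0.0, seed=13,
    )
    by_id = {i.id: i for i in individuals}
    offspring = [i for i in individuals if i.mother_id is not None]
    assert len(offspring) > 20
    for off in offspring:
        assert alleles_in_parents(off, by_id, loci)
        if off.sex == "M":
            assert (
                off.genotype["Y05"] == by_id[off.father_id].genotype["Y05"]
            )
        else:
            assert "Y05" not in off.genotype


def test_pure_and_crossed_ancestry_vectors(divergent_world):
    clusters, loci = divergent_world
    inds = simulate_pedigree(
        clusters, loci, n_founders_per_cluster=4, n_generations=1, seed=17
    )
    by_id = {i.id: i for i in inds}
    for off in (i for i in inds if i.mother_id):
        m = by_id[off.mother_id]
        f = by_id[off.father_id]
        if (m.ancestry_true == f.ancestry_true).all():
            np.testing.assert_allclose(off.ancestry_true, m.ancestry_true)
        if m.ancestry_true[0] == 1.0 and f.ancestry_true[1] == 1.0:
            np.testing.assert_allclose(
                off.ancestry_true, [0.5, 0.5, 0.0, 0.0]
            )


def test_zero_error_replicates_reproduce_truth(clean_survey):
    samples, truth, individuals, loci = clean_survey
    by_id = {i.id: i for i in individuals}
    assert len(samples) == len(individuals)  # full detection
    for s in samples[:20]:
        ind = by_id[truth[s.sample_id]]
        for locus in loci:
            reps = s.calls[locus.name]
            if locus.name not in ind.genotype:
                assert all(r is None for r in reps)
                continue
            expected = tuple(sorted(ind.genotype[locus.name]))
            assert all(r == expected for r in reps)


def test_zero_detection_emits_no_samples(small_pedigree):
    individuals, loci = small_pedigree
    design = SurveyDesign("empty", detection_prob=0.0)
    samples, truth = simulate_survey(
        individuals, design, NO_ERROR, loci, seed=3
    )
    assert samples == [] and truth == {}


def test_dropout_rate_matches_closed_form(divergent_world):
    """Per-allele independent dropout: a heterozygote replicate reads as
    an apparent homozygote with probability 2p(1-p)."""
    _, loci = divergent_world
    locus = next(l for l in loci if not l.is_sex_linked)
    p = 0.5
    error = ErrorModel(p_fail=0.0, p_dropout=p, p_false=0.0)
    rng_seed = 101
    from genmon.synthetic import TrueIndividual

    het = TrueIndividual(
        id="X", sex="F",
        genotype={locus.name: (locus.allele_sizes[0], locus.allele_sizes[3])},
        ancestry_true=np.array([1.0, 0, 0, 0]),
    )
    design = SurveyDesign(
        "w", detection_prob=1.0, replicates_per_sample=8,
        samples_per_detected_individual=1250,
    )
    samples, _ = simulate_survey([het], design, error, [locus], seed=rng_seed)
    calls = [c for s in samples for c in s.calls[locus.name]]
    n = len(calls)
    assert n == 10_000
    apparent_hom = sum(
        1 for c in calls if c is not None and c[0] == c[1]
    )
    expected = apparent_homozygote_rate(p)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(apparent_hom / n - expected) < 3 * se


def test_survey_is_deterministic_given_seed(small_pedigree):
    individuals, loci = small_pedigree
    design = SurveyDesign("w", detection_prob=0.7, replicates_per_sample=4)
    error = ErrorModel()
    s1, t1 = simulate_survey(individuals, design, error, loci, seed=77)
    s2, t2 = simulate_survey(individuals, design, error, loci, seed=77)
    assert t1 == t2
    assert [s.calls for s in s1] == [s.calls for s in s2]


def test_founder_frequencies_converge_to_panel():
    """Allele frequencies of 500 simulated founders approach the
    generating panel within 0.05 everywhere."""
    clusters, loci = generate_reference_clusters(8, 6, 0.3, seed=41)
    inds = simulate_pedigree(
        clusters, loci, n_founders_per_cluster=500, n_generations=0, seed=42
    )
    target = clusters[0]
    members = [i for i in inds if i.id.startswith("F0_CB_")]
    assert len(members) == 500
    for locus in loci:
        if locus.is_sex_linked:
            continue
        counts = {}
        for ind in members:
            for a in ind.genotype[locus.name]:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        for a, f in target.freqs[locus.name].items():
            assert abs(counts.get(a, 0) / total - f) < 0.05
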