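"""PID statistics vs genotype-pair enumeration, the matcher rule table,
and registry counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genmon.consensus import ConsensusGenotype, LocusCall, era_rules
from genmon.matching import (
    AlleleFrequencyTable,
    IndividualRecord,
    cumulative_pid,
    frequencies_from_genotypes,
    match_genotype,
    pid_sibs_locus,
    pid_unrelated_locus,
    register_and_count,
)
from genmon.synthetic import default_panel
from oracles import pid_sibs_bruteforce, pid_unrelated_bruteforce


@given(
    st.lists(
        st.floats(min_value=0.05, max_value=10.0), min_size=2, max_size=6
    )
)
@settings(max_examples=60, deadline=None)
def test_pid_formulas_match_enumeration(weights):
    """Closed forms agree with brute-force genotype-pair enumeration at
    random Dirichlet-like frequencies to 1e-10."""
    p = np.array(weights) / np.sum(weights)
    assert abs(pid_unrelated_locus(list(p)) - pid_unrelated_bruteforce(p)) < 1e-10
    assert abs(pid_sibs_locus(list(p)) - pid_sibs_bruteforce(p)) < 1e-10
    # sibs always at least as likely to match as unrelated
    assert pid_sibs_locus(list(p)) >= pid_unrelated_locus(list(p))


def test_pid_known_values():
    assert pid_unrelated_locus([1.0]) == 1.0
    assert pid_sibs_locus([1.0]) == 1.0
    assert abs(pid_unrelated_locus([0.5, 0.5]) - 0.375) < 1e-12
    assert abs(pid_sibs_locus([0.5, 0.5]) - 0.59375) < 1e-12


def test_cumulative_pid_product_and_threshold_interplay():
    freqs = AlleleFrequencyTable(
        {f"L{i}": {100: 0.5, 102: 0.5} for i in range(8)},
        {f"L{i}": 100 for i in range(8)},
    )
    two = cumulative_pid(freqs, ["L0", "L1"], kind="unrelated")
    assert abs(two - 0.140625) < 1e-12
    eight = cumulative_pid(freqs, [f"L{i}" for i in range(8)], kind="sibs")
    assert abs(eight - 0.59375**8) < 1e-12
    # eight such loci are NOT enough to clear the 0.01 threshold
    assert eight > 0.01


def test_cumulative_pid_permutation_invariant_and_monotone():
    rng = np.random.default_rng(4)
    freqs = {}
    for i in range(6):
        p = rng.dirichlet(np.ones(4))
        freqs[f"L{i}"] = {100 + 2 * j: float(v) for j, v in enumerate(p)}
    table = AlleleFrequencyTable(freqs, {k: 50 for k in freqs})
    loci = list(freqs)
    a = cumulative_pid(table, loci, "sibs")
    b = cumulative_pid(table, loci[::-1], "sibs")
    assert abs(a - b) < 1e-15
    running = 1.0
    for i in range(1, len(loci) + 1):
        val = cumulative_pid(table, loci[:i], "sibs")
        assert val <= running + 1e-15
        running = val


def test_empty_locus_set_rejected():
    table = AlleleFrequencyTable({"L0": {1: 1.0}}, {"L0": 10})
    with pytest.raises(ValueError):
        cumulative_pid(table, [], "sibs")


def _consensus_from(genotype, sample_id="q"):
    calls = {
        name: LocusCall(
            "hom" if a == b else "het", (a,) if a == b else (a, b)
        )
        for name, (a, b) in genotype.items()
    }
    return ConsensusGenotype(sample_id, calls)


def _informative_freqs(loci_names, n_alleles=6):
    rng = np.random.default_rng(8)
    freqs = {}
    for name in loci_names:
        p = rng.dirichlet(np.ones(n_alleles))
        freqs[name] = {100 + 2 * j: float(v) for j, v in enumerate(p)}
    return AlleleFrequencyTable(freqs, {k: 60 for k in freqs})


def brute_force_match(query, registry, rules, freqs, loci):
    """Independent matcher: enumerate registry entries and literally apply
    the declaration rule, without the production code's candidate logic."""
    ru = {l.name: l.repeat_unit for l in loci}
    match_set = set(rules.match_loci)
    hits = []
    for ind_id, rec in registry.items():
        shared = [
            n
            for n in query
            if n in rec.genotype and n in match_set
        ]
        if len(shared) < rules.match_min_loci:
            continue
        pid = 1.0
        for n in shared:
            pid *= pid_sibs_locus(list(freqs.freqs[n].values()))
        if pid >= 0.01:
            continue
        mism = [
            n
            for n in shared
            if tuple(sorted(query[n])) != tuple(sorted(rec.genotype[n]))
        ]
        if len(mism) == 0:
            hits.append((ind_id, 0))
        elif len(mism) == 1:
            n = mism[0]
            q = sorted(query[n])
            r = sorted(rec.genotype[n])
            ok = False
            for qa, ra in ((0, 0), (0, 1), (1, 0), (1, 1)):
                other_q = q[1 - qa]
                other_r = r[1 - ra]
                if other_q == other_r and abs(q[qa] - r[ra]) == ru[n]:
                    ok = True
            if ok:
                hits.append((ind_id, 1))
    return hits


def test_exact_match_and_locus_floor_and_stepwise():
    loci = default_panel()
    rules = era_rules("A")
    names = list(rules.match_loci)
    freqs = _informative_freqs(names)
    geno = {n: (100 + 2 * (i % 3), 102 + 2 * (i % 3)) for i, n in enumerate(names)}
    registry = {
        "I001": IndividualRecord("I001", dict(geno), origin="released")
    }
    # identical at 9 loci, tiny PIDsibs -> match
    q9 = {n: geno[n] for n in names[:9]}
    res = match_genotype(_consensus_from(q9), registry, rules, freqs, loci)
    assert res.individual_id == "I001"
    assert res.cumulative_pid_sibs < 1e-3
    assert res.n_mismatch_loci == 0
    # only 3 shared loci: below the era-A floor, no declaration
    q3 = {n: geno[n] for n in names[:3]}
    res3 = match_genotype(_consensus_from(q3), registry, rules, freqs, loci)
    assert res3.individual_id is None
    assert res3.flag == "below-locus-floor"
    # one stepwise mismatch over 10 loci -> accepted and flagged
    q10 = {n: geno[n] for n in names[:10]}
    lname = names[0]
    repeat = next(l.repeat_unit for l in loci if l.name == lname)
    a, b = q10[lname]
    q10[lname] = (a, b + repeat)
    res10 = match_genotype(_consensus_from(q10), registry, rules, freqs, loci)
    assert res10.individual_id == "I001"
    assert res10.flag == "stepwise-accepted"
    assert res10.n_mismatch_loci == 1
    # agrees with the brute-force matcher
    hits = brute_force_match(q10, registry, rules, freqs, loci)
    assert hits == [("I001", 1)]


def test_two_dropout_mismatches_accepted_others_reviewed():
    loci = default_panel()
    rules = era_rules("A")
    names = list(rules.match_loci)
    freqs = _informative_freqs(names)
    geno = {n: (100, 104) for n in names}
    registry = {"I001": IndividualRecord("I001", dict(geno))}
    q = dict(geno)
    q[names[0]] = (100, 100)  # dropout of 104
    q[names[1]] = (104, 104)  # dropout of 100
    res = match_genotype(_consensus_from(q), registry, rules, freqs, loci)
    assert res.individual_id == "I001"
    assert res.flag == "dropout-accepted"
    # a non-dropout second mismatch defaults to no-match
    q2 = dict(geno)
    q2[names[0]] = (100, 100)
    q2[names[1]] = (102, 106)
    res2 = match_genotype(_consensus_from(q2), registry, rules, freqs, loci)
    assert res2.individual_id is None


def test_register_and_count_collapses_samples_to_individuals():
    loci = default_panel()
    rules = era_rules("A")
    names = list(rules.match_loci)
    rng = np.random.default_rng(3)
    genos = {}
    for i in range(3):
        genos[f"T{i}"] = {
            n: tuple(sorted(rng.choice([100, 102, 104, 106], 2)))
            for n in names
        }
    samples = []
    for i in range(10):
        owner = f"T{i % 3}"
        samples.append(_consensus_from(genos[owner], sample_id=f"s{i:02d}"))
    registry = {}
    count, breakdown, results = register_and_count(
        samples, registry, rules, loci, period_id="w1"
    )
    assert count == 3
    assert breakdown == {"wild_born": 3}
    assert len(registry) == 3


def test_zero_samples_count_zero():
    registry = {}
    count, breakdown, results = register_and_count(
        [], registry, era_rules("A"), default_panel(), "w1"
    )
    assert count == 0 and breakdown == {} and results == []


def test_frequencies_from_individuals_not_samples():
    genos = {
        "A": {"L1": (100, 102)},
        "B": {"L1": (100, 100)},
    }
    table = frequencies_from_genotypes(genos)
    assert table.n_copies["L1"] == 4
    assert abs(table.freqs["L1"][100] - 0.75) < 1e-12
    assert abs(table.freqs["L1"][102] - 0.25) < 1e-12
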