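"""Independent brute-force oracles shared by the test modules.

Each oracle recomputes a statistic by exhaustive enumeration or literal
rule application, independently of the library code paths it checks.
"""

import itertools
import math

import numpy as np


def pid_unrelated_bruteforce(p):
    """P(two unrelated HWE genotypes identical) by full enumeration."""
    k = len(p)
    total = 0.0
    for i in range(k):
        for j in range(i, k):
            gp = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            total += gp**2
    return total


def pid_sibs_bruteforce(p):
    """P(two full sibs share a genotype): enumerate both parents' HWE
    genotypes, then the Mendelian offspring distribution."""
    k = len(p)
    genos = [(i, j) for i in range(k) for j in range(i, k)]

    def gprob(g):
        i, j = g
        return p[i] ** 2 if i == j else 2 * p[i] * p[j]

    total = 0.0
    for gm in genos:
        for gf in genos:
            dist = {}
            for a in gm:
                for b in gf:
                    key = (min(a, b), max(a, b))
                    dist[key] = dist.get(key, 0.0) + 0.25
            share = sum(q**2 for q in dist.values())
            total += gprob(gm) * gprob(gf) * share
    return total


def oracle_consensus_call(replicates):
    """Brute-force consensus rule oracle: score every candidate genotype
    over the alleles seen, then apply the confirmation thresholds
    literally."""
    usable = [r for r in replicates if r is not None]
    if not usable:
        return "missing", ()
    alleles = sorted({a for r in usable for a in r})

    def seen_in(allele):
        return sum(1 for r in usable if allele in r)

    def hom_calls(allele):
        return sum(1 for r in usable if r == (allele, allele))

    confirmed = [a for a in alleles if seen_in(a) >= 2]
    het_candidates = [
        (a, b)
        for a, b in itertools.combinations(alleles, 2)
        if seen_in(a) >= 2 and seen_in(b) >= 2
    ]
    if len(confirmed) == 2 and len(het_candidates) == 1:
        return "het", het_candidates[0]
    if len(confirmed) == 1 and hom_calls(confirmed[0]) >= 3:
        return "hom", (confirmed[0],)
    return "unresolved", ()


def all_replicate_multisets(alleles, max_size):
    """Every replicate multiset of size 1..max_size over the genotype
    calls (all unordered pairs plus the failed call)."""
    calls = [None] + [
        tuple(sorted(p))
        for p in itertools.combinations_with_replacement(alleles, 2)
    ]
    for size in range(1, max_size + 1):
        yield from itertools.combinations_with_replacement(calls, size)


def grid_search_admixture(geno, panel, step=0.001):
    """Exhaustive 2-cluster likelihood oracle over q in [0, 1]."""
    qs = np.arange(0.0, 1.0 + step / 2, step)
    rows = []
    for locus in sorted(geno):
        for allele in geno[locus]:
            rows.append(
                (
                    panel.freqs[panel.cluster_names[0]][locus][allele],
                    panel.freqs[panel.cluster_names[1]][locus][allele],
                )
            )
    F = np.array(rows)
    best_q, best_ll = None, -np.inf
    for q in qs:
        mix = q * F[:, 0] + (1 - q) * F[:, 1]
        ll = np.log(mix).sum()
        if ll > best_ll:
            best_q, best_ll = q, ll
    return best_q


def exhaustive_rarefied_ar(counts, g):
    """Mean allele count over every subsample of g gene copies."""
    copies = [a for a, c in counts.items() for _ in range(c)]
    vals = [len(set(sub)) for sub in itertools.combinations(copies, g)]
    return sum(vals) / len(vals)


def fisher_two_sided_oracle(table):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(
        prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9)
    )
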