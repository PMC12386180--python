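"""Individual identification from consensus genotypes.

Two samples are declared the same rabbit when they agree at enough loci
that the probability of two full siblings sharing the multilocus genotype
(PIDsibs) falls below 0.01.  Matching tolerates one mismatching locus if it
is explainable as a single stepwise mutation, and two mismatches only when
both look like allelic dropout in the query; everything else founds a new
individual record.  The registry of distinct individuals is the currency of
all downstream analyses and of the per-period minimum counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consensus import ConsensusGenotype, EraRules
from .synthetic import NULL_PRONE_LOCUS, Locus

PID_SIBS_THRESHOLD = 0.01


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies with the number of gene copies behind
    each locus's estimate."""

    freqs: dict[str, dict[int, float]]
    n_copies: dict[str, int]

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{locus}: frequencies sum to {total}, not 1"
                )
            if self.n_copies.get(locus, 0) < 2:
                raise ValueError(f"{locus}: fewer than 2 gene copies")


def frequencies_from_genotypes(
    genotypes: dict[str, dict[str, tuple[int, int]]],
) -> AlleleFrequencyTable:
    """Allele frequencies over a set of distinct individuals' confirmed
    genotypes (never over samples, which would double-count animals)."""
    counts: dict[str, dict[int, int]] = {}
    for geno in genotypes.values():
        for locus, (a, b) in geno.items():
            table = counts.setdefault(locus, {})
            table[a] = table.get(a, 0) + 1
            table[b] = table.get(b, 0) + 1
    freqs = {}
    copies = {}
    for locus, table in counts.items():
        total = sum(table.values())
        if total < 2:
            continue
        freqs[locus] = {a: c / total for a, c in table.items()}
        copies[locus] = total
    return AlleleFrequencyTable(freqs, copies)


def pid_unrelated_locus(p: list[float]) -> float:
    """Per-locus probability two unrelated individuals share a genotype
    under HWE: 2(Σp_i²)² − Σp_i⁴."""
    if not p:
        raise ValueError("empty frequency vector")
    s2 = sum(x * x for x in p)
    s4 = sum(x**4 for x in p)
    return 2.0 * s2 * s2 - s4


def pid_sibs_locus(p: list[float]) -> float:
    """Per-locus probability two full siblings share a genotype:
    0.25 + 0.5Σp_i² + 0.5(Σp_i²)² − 0.25Σp_i⁴."""
    if not p:
        raise ValueError("empty frequency vector")
    s2 = sum(x * x for x in p)
    s4 = sum(x**4 for x in p)
    return 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4


def cumulative_pid(
    freqs: AlleleFrequencyTable,
    loci: list[str],
    kind: str = "sibs",
) -> float:
    """Product of per-locus PID values over the compared loci."""
    if not loci:
        raise ValueError("empty locus set")
    fn = pid_sibs_locus if kind == "sibs" else pid_unrelated_locus
    out = 1.0
    for name in loci:
        out *= fn(list(freqs.freqs[name].values()))
    return out


@dataclass
class MatchResult:
    sample_id: str
    individual_id: str | None
    n_compared_loci: int = 0
    n_mismatch_loci: int = 0
    mismatch_detail: list[tuple] = field(default_factory=list)
    cumulative_pid_sibs: float = 1.0
    flag: str = ""  # "", "stepwise-accepted", "dropout-accepted",
    #               # "review-2-mismatch", "review-tie", "below-locus-floor"


@dataclass
class IndividualRecord:
    individual_id: str
    genotype: dict[str, tuple[int, int]]
    sex: str = "unknown"
    origin: str = "wild_born"  # {"released", "wild_born", "translocated_wild"}
    first_detected_period: str = ""
    detected_periods: set[str] = field(default_factory=set)
    release_day: int | None = None
    release_weight: float | None = None
    ancestry: dict[str, float] | None = None


def _genotypes_equal(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return tuple(sorted(a)) == tuple(sorted(b))


def _stepwise_explainable(
    a: tuple[int, int], b: tuple[int, int], repeat_unit: int
) -> bool:
    """True if the two genotypes differ by exactly one allele that is one
    repeat unit away from its counterpart (a single stepwise mutation)."""
    a1, a2 = sorted(a)
    b1, b2 = sorted(b)
    for (x1, x2), (y1, y2) in (((a1, a2), (b1, b2)), ((a2, a1), (b2, b1))):
        if x1 == y1 and abs(x2 - y2) == repeat_unit:
            return True
        if x1 == y2 and abs(x2 - y1) == repeat_unit:
            return True
    return False


def _dropout_explainable(
    query: tuple[int, int], registry: tuple[int, int]
) -> bool:
    """True if the query is an apparent homozygote whose single allele is a
    subset of the registry heterozygote (classic allelic dropout)."""
    q = sorted(query)
    r = set(registry)
    return q[0] == q[1] and q[0] in r and len(r) == 2


def compare_genotypes(
    query: dict[str, tuple[int, int]],
    registry: dict[str, tuple[int, int]],
    repeat_units: dict[str, int],
) -> tuple[int, list[tuple]]:
    """Mismatch count and detail over the loci confirmed in both."""
    detail = []
    shared = sorted(set(query) & set(registry))
    n_mismatch = 0
    for name in shared:
        if _genotypes_equal(query[name], registry[name]):
            continue
        n_mismatch += 1
        detail.append(
            (
                name,
                tuple(sorted(query[name])),
                tuple(sorted(registry[name])),
                _stepwise_explainable(
                    query[name], registry[name], repeat_units[name]
                ),
                _dropout_explainable(query[name], registry[name]),
            )
        )
    return n_mismatch, detail


def match_genotype(
    query: ConsensusGenotype,
    registry: dict[str, IndividualRecord],
    rules: EraRules,
    freqs: AlleleFrequencyTable,
    loci: list[Locus],
    pid_threshold: float = PID_SIBS_THRESHOLD,
) -> MatchResult:
    """Match one gated sample against the individual registry.

    A match requires >= ``rules.match_min_loci`` shared confirmed loci,
    cumulative PIDsibs below the threshold, and either no mismatches, one
    stepwise-explainable mismatch, or two mismatches that are both
    dropout-explainable in the query.  Ties between registry entries go to
    the entry compared at more loci; a residual tie is flagged for review
    and not merged.
    """
    repeat_units = {l.name: l.repeat_unit for l in loci}
    match_set = set(rules.match_loci)
    q_loci = {
        n: g
        for n, g in query.confirmed_loci.items()
        if n in match_set
    }
    candidates: list[MatchResult] = []
    best_floor = 0
    for ind_id, record in sorted(registry.items()):
        r_loci = {
            n: g for n, g in record.genotype.items() if n in match_set
        }
        shared = sorted(set(q_loci) & set(r_loci))
        if not shared:
            continue
        best_floor = max(best_floor, len(shared))
        if len(shared) < rules.match_min_loci:
            continue
        known = [n for n in shared if n in freqs.freqs]
        pid = cumulative_pid(freqs, known, "sibs") if known else 1.0
        if pid >= pid_threshold:
            continue
        n_mm, detail = compare_genotypes(q_loci, r_loci, repeat_units)
        flag = ""
        if n_mm == 1:
            if not detail[0][3]:
                continue
            flag = "stepwise-accepted"
        elif n_mm == 2:
            if not all(d[4] for d in detail):
                continue  # emitted for review; defaults to no-match
            flag = "dropout-accepted"
        elif n_mm > 2:
            continue
        candidates.append(
            MatchResult(
                sample_id=query.sample_id,
                individual_id=ind_id,
                n_compared_loci=len(shared),
                n_mismatch_loci=n_mm,
                mismatch_detail=detail,
                cumulative_pid_sibs=pid,
                flag=flag,
            )
        )
    if not candidates:
        flag = "below-locus-floor" if (
            registry and 0 < best_floor < rules.match_min_loci
        ) else ""
        return MatchResult(query.sample_id, None, flag=flag)
    candidates.sort(
        key=lambda m: (m.n_mismatch_loci, -m.n_compared_loci, m.individual_id)
    )
    best = candidates[0]
    ties = [
        c
        for c in candidates[1:]
        if c.n_mismatch_loci == best.n_mismatch_loci
        and c.n_compared_loci == best.n_compared_loci
    ]
    if ties:
        return MatchResult(
            query.sample_id, None, flag="review-tie"
        )
    return best


def register_and_count(
    samples: list[ConsensusGenotype],
    registry: dict[str, IndividualRecord],
    rules: EraRules,
    loci: list[Locus],
    period_id: str,
    pid_threshold: float = PID_SIBS_THRESHOLD,
    frequency_source: AlleleFrequencyTable | None = None,
) -> tuple[int, dict[str, int], list[MatchResult]]:
    """Match all of a period's gated samples and maintain the registry.

    Each unmatched sample founds a new wild-born record.  Frequencies for
    PIDsibs come from the current registry of distinct individuals unless a
    global table is supplied.  Returns the minimum count of distinct
    individuals detected in the period, a per-origin breakdown, and the
    match results.
    """
    results: list[MatchResult] = []
    detected: set[str] = set()
    counter = sum(1 for i in registry if i.startswith("W"))
    for sample in sorted(samples, key=lambda s: s.sample_id):
        freqs = frequency_source
        if freqs is None:
            genos = {i: r.genotype for i, r in registry.items()}
            if genos:
                try:
                    freqs = frequencies_from_genotypes(genos)
                except ValueError:
                    freqs = AlleleFrequencyTable({}, {})
            else:
                freqs = AlleleFrequencyTable({}, {})
        res = match_genotype(
            sample, registry, rules, freqs, loci, pid_threshold
        )
        if res.individual_id is None and res.flag in ("", "review-2-mismatch"):
            counter += 1
            new_id = f"W{counter:05d}"
            registry[new_id] = IndividualRecord(
                individual_id=new_id,
                genotype=dict(sample.confirmed_loci),
                sex=sample.sex_call,
                origin="wild_born",
                first_detected_period=period_id,
                detected_periods={period_id},
            )
            res = MatchResult(
                sample.sample_id,
                new_id,
                n_compared_loci=len(sample.confirmed_loci),
            )
            detected.add(new_id)
        elif res.individual_id is not None:
            record = registry[res.individual_id]
            record.detected_periods.add(period_id)
            if not record.first_detected_period:
                record.first_detected_period = period_id
            if record.sex == "unknown" and sample.sex_call != "unknown":
                record.sex = sample.sex_call
            detected.add(res.individual_id)
        results.append(res)
    breakdown: dict[str, int] = {}
    for ind_id in detected:
        origin = registry[ind_id].origin
        breakdown[origin] = breakdown.get(origin, 0) + 1
    return len(detected), breakdown, results


def downstream_loci(loci: list[Locus]) -> list[Locus]:
    """Autosomal loci used by parentage/population genetics: the Y locus
    and the null-allele-prone locus are excluded."""
    return [
        l
        for l in loci
        if not l.is_sex_linked and l.name != NULL_PRONE_LOCUS
    ]
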