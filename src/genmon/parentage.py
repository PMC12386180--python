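"""Strict-exclusion parentage with a single stepwise-mutation allowance.

A candidate parent is excluded at a locus when it shares no allele with the
offspring there.  A dyad survives with zero exclusions, or with exactly one
that is explainable as a single stepwise mutation (one repeat unit).  A
parent pair is accepted only when, additionally, the trio is jointly
Mendelian-consistent at every shared locus — the offspring's two alleles
must partition across the pair — with at most one mutation excused across
the whole trio, which is stricter than excusing one per dyad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matching import IndividualRecord
from .synthetic import Locus


@dataclass
class ParentageAssignment:
    offspring_id: str
    mother_id: str | None = None
    father_id: str | None = None
    n_loci_compared: dict[str, int] = field(default_factory=dict)
    n_mismatch: dict[str, int] = field(default_factory=dict)
    accepted_mutation: bool = False
    mother_ambiguity: int = 0
    father_ambiguity: int = 0
    evaluable: bool = True


def dyad_compatible(
    offspring: dict[str, tuple[int, int]],
    candidate: dict[str, tuple[int, int]],
    loci: list[Locus],
    min_loci: int = 4,
) -> tuple[bool, int, bool, int]:
    """Exclusion test for one offspring/candidate dyad.

    Returns ``(compatible, n_mismatch, stepwise_ok, n_compared)``.  A locus
    mismatches when offspring and candidate share no allele; the dyad is
    compatible with zero mismatches, or exactly one whose nearest allele
    distance equals one repeat unit.  Dyads with fewer than ``min_loci``
    shared confirmed loci are not evaluable (``n_compared`` tells).
    """
    n_compared = 0
    mismatches: list[str] = []
    stepwise: dict[str, bool] = {}
    for locus in loci:
        name = locus.name
        if name not in offspring or name not in candidate:
            continue
        n_compared += 1
        off = set(offspring[name])
        cand = set(candidate[name])
        if off & cand:
            continue
        mismatches.append(name)
        gap = min(abs(a - b) for a in off for b in cand)
        stepwise[name] = gap == locus.repeat_unit
    if n_compared < min_loci:
        return False, len(mismatches), False, n_compared
    if not mismatches:
        return True, 0, False, n_compared
    if len(mismatches) == 1 and stepwise[mismatches[0]]:
        return True, 1, True, n_compared
    return False, len(mismatches), False, n_compared


def _partition_ok(
    off: tuple[int, int],
    mother: tuple[int, int],
    father: tuple[int, int],
    repeat_unit: int,
) -> tuple[bool, bool]:
    """Can the offspring alleles be drawn one from each parent?

    Returns ``(exact, one_step)``: exact Mendelian consistency, and
    consistency after shifting exactly one transmitted allele by one
    repeat unit.
    """
    a, b = off
    exact = False
    one_step = False
    for x, y in ((a, b), (b, a)):
        for m in set(mother):
            for f in set(father):
                if x == m and y == f:
                    exact = True
                elif x == m and abs(y - f) == repeat_unit:
                    one_step = True
                elif y == f and abs(x - m) == repeat_unit:
                    one_step = True
    return exact, one_step


def trio_consistent(
    offspring: dict[str, tuple[int, int]],
    mother: dict[str, tuple[int, int]],
    father: dict[str, tuple[int, int]],
    loci: list[Locus],
) -> tuple[bool, int]:
    """Joint Mendelian check of a trio over the loci shared by all three.

    Returns ``(consistent, n_mutations_used)``; at most one stepwise
    mutation is excused across the whole trio.
    """
    failures = 0
    steps = 0
    for locus in loci:
        name = locus.name
        if (
            name not in offspring
            or name not in mother
            or name not in father
        ):
            continue
        exact, one_step = _partition_ok(
            offspring[name], mother[name], father[name], locus.repeat_unit
        )
        if exact:
            continue
        if one_step:
            steps += 1
        else:
            failures += 1
    if failures > 0:
        return False, steps
    return steps <= 1, steps


def assign_parents(
    offspring: IndividualRecord,
    candidate_mothers: list[IndividualRecord],
    candidate_fathers: list[IndividualRecord],
    loci: list[Locus],
    min_loci: int = 4,
) -> ParentageAssignment:
    """Assign a parent pair (or single parent) by exclusion.

    A pair is accepted only when both dyads survive exclusion and the trio
    is jointly Mendelian-consistent; multiple surviving pairs leave the
    ambiguous role unknown with the ambiguity count reported.  A single
    parent is assigned when exactly one candidate of that sex survives.
    Results do not depend on candidate ordering (candidates are scanned in
    a sorted order and ambiguity is resolved by counting, not by
    first-found).
    """
    out = ParentageAssignment(offspring_id=offspring.individual_id)
    n_typed = sum(
        1 for l in loci if l.name in offspring.genotype
    )
    if n_typed < min_loci:
        out.evaluable = False
        return out

    def survivors(
        candidates: list[IndividualRecord],
    ) -> list[IndividualRecord]:
        keep = []
        for cand in sorted(candidates, key=lambda c: c.individual_id):
            if cand.individual_id == offspring.individual_id:
                continue
            ok, n_mm, _, n_cmp = dyad_compatible(
                offspring.genotype, cand.genotype, loci, min_loci
            )
            out.n_loci_compared[cand.individual_id] = n_cmp
            out.n_mismatch[cand.individual_id] = n_mm
            if ok:
                keep.append(cand)
        return keep

    mothers = survivors(candidate_mothers)
    fathers = survivors(candidate_fathers)
    pairs = []
    for m in mothers:
        for f in fathers:
            ok, steps = trio_consistent(
                offspring.genotype, m.genotype, f.genotype, loci
            )
            mut_m = out.n_mismatch[m.individual_id]
            mut_f = out.n_mismatch[f.individual_id]
            # one excused mutation across the whole trio, not one per dyad
            if ok and mut_m + mut_f <= 1:
                pairs.append((m, f, steps))
    pair_mothers = {m.individual_id for m, _, _ in pairs}
    pair_fathers = {f.individual_id for _, f, _ in pairs}
    if len(pairs) == 1:
        m, f, steps = pairs[0]
        out.mother_id = m.individual_id
        out.father_id = f.individual_id
        out.accepted_mutation = (
            steps > 0
            or out.n_mismatch[m.individual_id] > 0
            or out.n_mismatch[f.individual_id] > 0
        )
        return out
    if pairs:
        # several pairs survive: a role is only filled if unambiguous
        if len(pair_mothers) == 1:
            out.mother_id = next(iter(pair_mothers))
        if len(pair_fathers) == 1:
            out.father_id = next(iter(pair_fathers))
        out.mother_ambiguity = len(pair_mothers)
        out.father_ambiguity = len(pair_fathers)
        return out
    # no jointly consistent pair: fall back to single-parent assignment
    if len(mothers) == 1:
        out.mother_id = mothers[0].individual_id
        out.accepted_mutation = out.n_mismatch[out.mother_id] > 0
    out.mother_ambiguity = len(mothers)
    if len(fathers) == 1:
        out.father_id = fathers[0].individual_id
        out.accepted_mutation = (
            out.accepted_mutation or out.n_mismatch[out.father_id] > 0
        )
    out.father_ambiguity = len(fathers)
    return out


def contributing_breeders(
    assignments: list[ParentageAssignment],
) -> tuple[int, int, int, int]:
    """Distinct assigned mothers/fathers and unknown counts, the reporting
    format of the per-cohort breeder summaries."""
    mothers = {a.mother_id for a in assignments if a.mother_id}
    fathers = {a.father_id for a in assignments if a.father_id}
    unknown_m = sum(1 for a in assignments if a.mother_id is None)
    unknown_f = sum(1 for a in assignments if a.father_id is None)
    return len(mothers), len(fathers), unknown_m, unknown_f
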