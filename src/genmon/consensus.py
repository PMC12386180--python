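"""Consensus genotyping of replicate PCR amplifications.

Fecal-DNA extracts are amplified four to eight times per locus; a genotype
is only accepted once each allele has been seen often enough to rule out
allelic dropout and false alleles.  The confirmation rule is the standard
multi-tubes protocol: two independent observations of each allele confirm a
heterozygote, three apparent-homozygote calls confirm a homozygote.

Samples then pass era-specific multiplex gates before they are allowed
into identity matching: in the 2012–2017 protocol (era A) a sample had to
amplify at >= 5 of the seven first-multiplex autosomal loci; in the
2018–2020 protocol (era B) a minimum of eight confirmed loci across the
second and third multiplexes is required.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .synthetic import PANEL_LAYOUT, Locus, ReplicateSet

CONFIRM_HET = 2  # observations of each allele to confirm a heterozygote
CONFIRM_HOM = 3  # apparent-homozygote calls to confirm a homozygote


@dataclass(frozen=True)
class LocusCall:
    """Consensus status of one locus: ``het``/``hom``/``unresolved``/``missing``."""

    status: str
    alleles: tuple[int, ...] = ()

    @property
    def confirmed(self) -> bool:
        return self.status in ("het", "hom")

    def genotype(self) -> tuple[int, int] | None:
        if self.status == "het":
            return self.alleles
        if self.status == "hom":
            return (self.alleles[0], self.alleles[0])
        return None


@dataclass
class ConsensusGenotype:
    sample_id: str
    calls: dict[str, LocusCall]
    sex_call: str = "unknown"
    period_id: str = ""

    @property
    def confirmed_loci(self) -> dict[str, tuple[int, int]]:
        return {
            name: call.genotype()
            for name, call in self.calls.items()
            if call.confirmed
        }

    def n_confirmed_autosomal(
        self, autosomal: set[str] | None = None, y_locus: str = "Y05"
    ) -> int:
        names = [
            n
            for n, c in self.calls.items()
            if c.confirmed and n != y_locus
        ]
        if autosomal is not None:
            names = [n for n in names if n in autosomal]
        return len(names)


@dataclass(frozen=True)
class EraRules:
    """Quality gates and matching floor for one laboratory era."""

    era: str
    stage1_loci: tuple[str, ...]
    stage2_loci: tuple[str, ...]
    stage1_min: int
    match_min_loci: int
    y_locus: str = "Y05"

    @property
    def match_loci(self) -> tuple[str, ...]:
        return tuple(self.stage1_loci) + tuple(self.stage2_loci)


def era_rules(era: str) -> EraRules:
    """The two published protocols.

    Era A (2012–2017): multiplex 1 screens samples (>= 5 of its 7 autosomal
    loci), multiplex 2 completes the 12-locus identity set, and >= 4 shared
    loci may declare a match.  Era B (2018–2020): multiplexes 2 and 3 are
    run together and >= 8 confirmed loci are required.
    """
    mux = {
        m: tuple(n for n in block if n != "Y05")
        for m, block in PANEL_LAYOUT.items()
    }
    if era == "A":
        return EraRules("A", mux[1], mux[2], stage1_min=5, match_min_loci=4)
    if era == "B":
        return EraRules(
            "B", mux[2], mux[3], stage1_min=8, match_min_loci=8
        )
    raise ValueError(f"unknown era {era!r} (expected 'A' or 'B')")


def call_locus_consensus(
    replicate_calls: list[tuple[int, int] | None],
    ladder: tuple[int, ...] | None = None,
) -> LocusCall:
    """Apply the confirmation rule to one locus's replicate calls.

    An allele is confirmed once it appears in >= 2 replicates; a
    heterozygote needs exactly two confirmed alleles, a homozygote needs
    >= 3 apparent-homozygote calls of a single confirmed allele.  Three or
    more confirmed alleles are contradictory and stay unresolved (no
    three-allele calls).  Calls carrying alleles off the locus ladder are
    out-of-bin (the signature of non-target species) and count as failed.
    """
    if not replicate_calls:
        raise ValueError("need at least one replicate call")
    usable: list[tuple[int, int]] = []
    for call in replicate_calls:
        if call is None:
            continue
        if ladder is not None and any(a not in ladder for a in call):
            continue  # out-of-bin: treated as failed for consensus
        usable.append(call)
    if not usable:
        return LocusCall("missing")
    support: Counter[int] = Counter()
    hom_support: Counter[int] = Counter()
    for a, b in usable:
        support[a] += 1
        if b != a:
            support[b] += 1
        else:
            hom_support[a] += 1
    confirmed = sorted(a for a, n in support.items() if n >= CONFIRM_HET)
    if len(confirmed) == 2:
        return LocusCall("het", (confirmed[0], confirmed[1]))
    if len(confirmed) == 1:
        a = confirmed[0]
        if hom_support[a] >= CONFIRM_HOM:
            return LocusCall("hom", (a,))
    return LocusCall("unresolved")


def has_out_of_bin(
    replicate_calls: list[tuple[int, int] | None],
    ladder: tuple[int, ...],
) -> bool:
    return any(
        call is not None and any(a not in ladder for a in call)
        for call in replicate_calls
    )


def call_sex(
    calls: dict[str, LocusCall],
    y_replicates: list[tuple[int, int] | None],
    y_locus: str = "Y05",
) -> str:
    """Sex from the Y locus, guarded by autosomal amplification.

    Male iff the Y locus amplified in >= 2 replicates while autosomal loci
    confirmed (so failed DNA is not read as female); female iff autosomal
    loci confirmed and the Y locus never amplified; unknown otherwise.
    """
    n_autosomal = sum(
        1 for n, c in calls.items() if n != y_locus and c.confirmed
    )
    n_y = sum(1 for c in y_replicates if c is not None)
    if n_autosomal == 0:
        return "unknown"
    if n_y >= 2:
        return "M"
    if n_y == 0:
        return "F"
    return "unknown"


def consensus_genotype(
    repset: ReplicateSet,
    loci: list[Locus],
    rules: EraRules | None = None,
) -> ConsensusGenotype:
    """Consensus-call every locus of a sample and attach the sex call."""
    by_name = {l.name: l for l in loci}
    calls: dict[str, LocusCall] = {}
    y_reps: list[tuple[int, int] | None] = []
    for name, reps in repset.calls.items():
        locus = by_name.get(name)
        ladder = locus.allele_sizes if locus is not None else None
        if locus is not None and locus.is_sex_linked:
            y_reps = reps
            calls[name] = call_locus_consensus(reps, ladder)
            continue
        calls[name] = call_locus_consensus(reps, ladder)
    y_name = rules.y_locus if rules is not None else "Y05"
    sex = call_sex(
        {n: c for n, c in calls.items()}, y_reps, y_locus=y_name
    )
    return ConsensusGenotype(
        sample_id=repset.sample_id,
        calls=calls,
        sex_call=sex,
        period_id=repset.period_id,
    )


def gate_sample(consensus: ConsensusGenotype, rules: EraRules) -> bool:
    """Era quality gate.

    Era A passes a sample once >= ``stage1_min`` of the stage-1 autosomal
    loci are confirmed (the sex locus never counts).  Era B gates on the
    combined stage-1/stage-2 set with the ``match_min_loci`` floor.
    """
    if rules.era == "A":
        stage1 = set(rules.stage1_loci)
        n = sum(
            1
            for name, call in consensus.calls.items()
            if name in stage1 and call.confirmed
        )
        return n >= rules.stage1_min
    if rules.era == "B":
        combined = set(rules.match_loci)
        n = sum(
            1
            for name, call in consensus.calls.items()
            if name in combined and call.confirmed
        )
        return n >= rules.match_min_loci
    raise ValueError(f"unknown era {rules.era!r}")
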