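"""Ground-truthed synthetic populations for the monitoring pipeline.

The reintroduced Columbia Basin pygmy rabbit population is a mixture of four
source lineages (Columbia Basin plus three translocation sources).  Nothing
from the field program is deposited, so every downstream stage of the
pipeline is exercised against simulated data with the same statistical
structure: four source clusters with distinct microsatellite allele
frequencies, an admixed pedigree bred over multiple cohorts, a
release/detection program, and a per-replicate genotyping error process
(amplification failure, allelic dropout, false alleles).

All randomness flows from an explicit ``seed`` argument per call; there is
no module-level random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CLUSTER_NAMES = ("CB", "NV_OR_ID", "WY_NUT", "S_UT")

#: Locus panel of the monitoring program: 18 autosomal microsatellites and
#: one Y-linked locus, laid out over three PCR multiplexes.
PANEL_LAYOUT = {
    1: ["A12", "A124", "A140", "Sat7", "Sat8", "Sol08", "Sol44", "Y05"],
    2: ["A113", "A121", "A133", "A2", "D118", "Sat5"],
    3: ["A128", "A129", "D103", "D2", "7LID3"],
}

#: Locus dropped from everything downstream of identity matching because of
#: its high null-allele frequency.
NULL_PRONE_LOCUS = "A124"


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: an allele ladder in integer base pairs."""

    name: str
    repeat_unit: int
    allele_sizes: tuple[int, ...]
    is_sex_linked: bool = False
    multiplex_id: int = 1

    def __post_init__(self) -> None:
        if not self.allele_sizes:
            raise ValueError(f"locus {self.name}: empty allele ladder")
        if self.repeat_unit < 1:
            raise ValueError(f"locus {self.name}: repeat unit must be >= 1")
        r = {a % self.repeat_unit for a in self.allele_sizes}
        if len(r) != 1:
            raise ValueError(
                f"locus {self.name}: allele sizes not congruent modulo "
                f"repeat unit {self.repeat_unit}"
            )


@dataclass
class SourceCluster:
    """Per-locus allele frequencies of one source lineage."""

    name: str
    freqs: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            if any(p < 0 for p in table.values()):
                raise ValueError(f"{self.name}/{locus}: negative frequency")
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}/{locus}: frequencies sum to {total}, not 1"
                )


@dataclass
class TrueIndividual:
    """Ground-truth record for one simulated rabbit.

    ``genotype`` maps locus name to an ordered allele pair; at the Y locus
    males carry ``(a, a)`` and females have no entry.  ``ancestry_true`` is
    the expected (pedigree) ancestry: offspring get the mean of their
    parents' vectors.
    """

    id: str
    sex: str
    genotype: dict[str, tuple[int, int]]
    ancestry_true: np.ndarray
    mother_id: str | None = None
    father_id: str | None = None
    origin: str = "founder"
    release_day: int | None = None
    release_weight: float | None = None
    alive_by_period: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class ErrorModel:
    """Per-replicate genotyping error process.

    ``p_fail``   -- amplification failure of the whole locus in a replicate.
    ``p_dropout``-- independent per-allele dropout; a heterozygote with
                    exactly one dropped allele appears homozygous, both
                    dropped reads as a failed replicate.
    ``p_false``  -- a surviving allele is misread one repeat unit away
                    (stepwise false allele).

    The defaults are fixture choices for a moderately noisy fecal-DNA
    extract, not published rates.
    """

    p_fail: float = 0.2
    p_dropout: float = 0.15
    p_false: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p_fail", "p_dropout", "p_false"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


#: Zero-noise error model, used for exact-recovery checks.
NO_ERROR = ErrorModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SurveyDesign:
    """One monitoring survey period."""

    period_id: str
    detection_prob: float = 0.8
    replicates_per_sample: int = 4
    samples_per_detected_individual: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob outside [0, 1]")
        if not 4 <= self.replicates_per_sample <= 8:
            raise ValueError("replicates_per_sample must lie in [4, 8]")
        if self.samples_per_detected_individual < 1:
            raise ValueError("samples_per_detected_individual must be >= 1")


@dataclass
class ReplicateSet:
    """All replicate PCR calls for one fecal sample.

    ``calls`` maps locus name to a list of per-replicate results, each an
    ordered allele pair or ``None`` for a failed amplification.
    """

    sample_id: str
    period_id: str
    calls: dict[str, list[tuple[int, int] | None]]
    species_id: str = "pygmy"  # {"pygmy", "cottontail", "fail"}


def default_panel(
    n_autosomal: int = 18, alleles_per_locus: int = 8
) -> list[Locus]:
    """The 19-locus monitoring panel with a synthetic allele ladder."""
    names = [
        (n, m)
        for m, block in PANEL_LAYOUT.items()
        for n in block
        if n != "Y05"
    ][:n_autosomal]
    loci = []
    for i, (name, mux) in enumerate(names):
        repeat = 2 if i % 2 == 0 else 4
        base = 100 + 10 * i
        ladder = tuple(base + repeat * k for k in range(alleles_per_locus))
        loci.append(Locus(name, repeat, ladder, False, mux))
    loci.append(
        Locus("Y05", 2, tuple(90 + 2 * k for k in range(4)), True, 1)
    )
    return loci


def _dirichlet_panel(
    rng: np.random.Generator,
    loci: list[Locus],
    divergence: float,
) -> list[SourceCluster]:
    """F-model cluster frequencies: Dirichlet(base * (1-F)/F)."""
    clusters: dict[str, dict[str, dict[int, float]]] = {
        c: {} for c in CLUSTER_NAMES
    }
    for locus in loci:
        k = len(locus.allele_sizes)
        base = rng.dirichlet(np.ones(k))
        for cname in CLUSTER_NAMES:
            if divergence == 0.0:
                p = base
            else:
                conc = base * (1.0 - divergence) / divergence
                # Dirichlet with tiny concentrations can produce exact 0s;
                # clip and renormalise so the invariant sum==1 holds.
                p = rng.dirichlet(np.maximum(conc, 1e-6))
                p = np.maximum(p, 0.0)
                p = p / p.sum()
            clusters[cname][locus.name] = {
                a: float(q) for a, q in zip(locus.allele_sizes, p)
            }
    return [SourceCluster(c, clusters[c]) for c in CLUSTER_NAMES]


def generate_reference_clusters(
    n_loci: int = 18,
    alleles_per_locus: int = 8,
    divergence: float = 0.2,
    seed: int = 0,
) -> tuple[list[SourceCluster], list[Locus]]:
    """Draw four source clusters with Dirichlet-perturbed frequencies.

    ``divergence`` acts as the F parameter of an F-model: 0 gives four
    identical clusters, values near 1 give nearly-private allele sets and
    hence large pairwise FST.
    """
    if n_loci < 2:
        raise ValueError("n_loci must be >= 2")
    if alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    loci = default_panel(n_loci, alleles_per_locus)
    clusters = _dirichlet_panel(rng, loci, divergence)
    return clusters, loci


def mean_fst(clusters: list[SourceCluster], loci: list[Locus]) -> float:
    """Unweighted mean FST across autosomal loci (variance / p̄(1-p̄))."""
    vals = []
    for locus in loci:
        if locus.is_sex_linked:
            continue
        mat = np.array(
            [
                [c.freqs[locus.name].get(a, 0.0) for a in locus.allele_sizes]
                for c in clusters
            ]
        )
        pbar = mat.mean(axis=0)
        num = mat.var(axis=0).sum()
        den = (pbar * (1 - pbar)).sum()
        if den > 0:
            vals.append(num / den)
    return float(np.mean(vals))


def _draw_genotype(
    rng: np.random.Generator, cluster: SourceCluster, loci: list[Locus], sex: str
) -> dict[str, tuple[int, int]]:
    geno = {}
    for locus in loci:
        table = cluster.freqs[locus.name]
        alleles = np.array(list(table.keys()))
        probs = np.array(list(table.values()))
        probs = probs / probs.sum()
        if locus.is_sex_linked:
            if sex == "M":
                a = int(rng.choice(alleles, p=probs))
                geno[locus.name] = (a, a)
            continue
        pair = rng.choice(alleles, size=2, p=probs)
        geno[locus.name] = (int(pair[0]), int(pair[1]))
    return geno


def _mutate(rng: np.random.Generator, allele: int, locus: Locus, rate: float) -> int:
    if rate > 0 and rng.random() < rate:
        step = locus.repeat_unit if rng.random() < 0.5 else -locus.repeat_unit
        moved = allele + step
        lo, hi = min(locus.allele_sizes), max(locus.allele_sizes)
        if moved < lo or moved > hi:
            moved = allele - step
        return moved
    return allele


def simulate_pedigree(
    clusters: list[SourceCluster],
    loci: list[Locus],
    n_founders_per_cluster: int = 10,
    n_generations: int = 2,
    mean_litter: float = 2.0,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> list[TrueIndividual]:
    """Breed an admixed pedigree from cluster founders.

    Mendelian inheritance at autosomal loci (with optional stepwise
    mutation), father-to-son transmission at the Y locus, and expected
    (pedigree) ancestry propagated as the parental mean.  Each generation
    mates every female with a randomly chosen male of the parental pool.
    """
    if n_founders_per_cluster < 2:
        raise ValueError("need >= 2 founders per contributing cluster")
    if not 0.0 <= mutation_rate <= 0.01:
        raise ValueError("mutation_rate must lie in [0, 0.01]")
    rng = np.random.default_rng(seed)
    individuals: list[TrueIndividual] = []
    k = len(clusters)
    for ci, cluster in enumerate(clusters):
        for j in range(n_founders_per_cluster):
            sex = "M" if j % 2 == 0 else "F"
            anc = np.zeros(k)
            anc[ci] = 1.0
            individuals.append(
                TrueIndividual(
                    id=f"F0_{cluster.name}_{j:03d}",
                    sex=sex,
                    genotype=_draw_genotype(rng, cluster, loci, sex),
                    ancestry_true=anc,
                    origin="founder",
                )
            )
    pool = list(individuals)
    for gen in range(1, n_generations + 1):
        males = [i for i in pool if i.sex == "M"]
        females = [i for i in pool if i.sex == "F"]
        if not males or not females:
            raise RuntimeError(f"generation {gen}: a sex has no breeders")
        offspring = []
        counter = 0
        for mother in females:
            n_off = rng.poisson(mean_litter)
            for _ in range(n_off):
                father = males[int(rng.integers(len(males)))]
                sex = "M" if rng.random() < 0.5 else "F"
                geno = {}
                for locus in loci:
                    if locus.is_sex_linked:
                        if sex == "M":
                            a = father.genotype[locus.name][0]
                            geno[locus.name] = (a, a)
                        continue
                    ma = mother.genotype[locus.name][int(rng.integers(2))]
                    pa = father.genotype[locus.name][int(rng.integers(2))]
                    ma = _mutate(rng, ma, locus, mutation_rate)
                    pa = _mutate(rng, pa, locus, mutation_rate)
                    geno[locus.name] = (ma, pa)
                offspring.append(
                    TrueIndividual(
                        id=f"G{gen}_{counter:04d}",
                        sex=sex,
                        genotype=geno,
                        ancestry_true=(
                            mother.ancestry_true + father.ancestry_true
                        )
                        / 2.0,
                        mother_id=mother.id,
                        father_id=father.id,
                        origin="enclosure_born",
                    )
                )
                counter += 1
        individuals.extend(offspring)
        pool = offspring if offspring else pool
    return individuals


def simulate_release_program(
    individuals: list[TrueIndividual],
    seed: int = 0,
    day_range: tuple[int, int] = (120, 270),
    weight_mean: float = 400.0,
    weight_sd: float = 60.0,
) -> list[TrueIndividual]:
    """Attach release covariates (day of year, weight in grams) to
    non-founder individuals, emulating enclosure-born juveniles released
    over a season.  Weight is mildly correlated with release day (animals
    released later have grown longer), matching the field observation."""
    rng = np.random.default_rng(seed)
    out = []
    lo, hi = day_range
    for ind in individuals:
        if ind.origin == "founder":
            out.append(ind)
            continue
        day = int(rng.integers(lo, hi + 1))
        frac = (day - lo) / max(hi - lo, 1)
        weight = rng.normal(weight_mean + 100.0 * (frac - 0.5), weight_sd)
        out.append(
            replace(ind, release_day=day, release_weight=float(max(weight, 50.0)))
        )
    return out


def _replicate_call(
    rng: np.random.Generator,
    truth: tuple[int, int],
    locus: Locus,
    error: ErrorModel,
) -> tuple[int, int] | None:
    if error.p_fail > 0 and rng.random() < error.p_fail:
        return None
    a, b = truth
    kept = []
    for allele in (a, b):
        if error.p_dropout > 0 and rng.random() < error.p_dropout:
            continue
        kept.append(allele)
    if not kept:
        return None
    if len(kept) == 1:
        call = [kept[0], kept[0]]
    else:
        call = list(kept)
    if error.p_false > 0 and rng.random() < error.p_false:
        i = int(rng.integers(2))
        step = locus.repeat_unit if rng.random() < 0.5 else -locus.repeat_unit
        moved = call[i] + step
        lo, hi = min(locus.allele_sizes), max(locus.allele_sizes)
        if moved < lo or moved > hi:
            moved = call[i] - step
        call[i] = moved
    call.sort()
    return (call[0], call[1])


def simulate_survey(
    individuals: list[TrueIndividual],
    design: SurveyDesign,
    error: ErrorModel,
    loci: list[Locus],
    seed: int = 0,
) -> tuple[list[ReplicateSet], dict[str, str]]:
    """Run one survey period over the living individuals.

    Each individual alive in the period is detected with
    ``design.detection_prob``; each detection yields one or more fecal
    samples, each amplified ``design.replicates_per_sample`` times per locus
    under the error model.  Returns the replicate sets plus the ground-truth
    sample-to-individual mapping used for recovery scoring.
    """
    rng = np.random.default_rng(seed)
    samples: list[ReplicateSet] = []
    truth: dict[str, str] = {}
    counter = 0
    for ind in individuals:
        alive = ind.alive_by_period.get(design.period_id, True)
        if not alive:
            continue
        if rng.random() >= design.detection_prob:
            continue
        for _ in range(design.samples_per_detected_individual):
            sample_id = f"{design.period_id}_S{counter:05d}"
            counter += 1
            calls: dict[str, list[tuple[int, int] | None]] = {}
            for locus in loci:
                reps: list[tuple[int, int] | None] = []
                for _ in range(design.replicates_per_sample):
                    if locus.name not in ind.genotype:
                        # female at the Y locus: never amplifies
                        reps.append(None)
                        continue
                    reps.append(
                        _replicate_call(
                            rng, ind.genotype[locus.name], locus, error
                        )
                    )
                calls[locus.name] = reps
            samples.append(ReplicateSet(sample_id, design.period_id, calls))
            truth[sample_id] = ind.id
    return samples, truth


def simulate_wright_fisher(
    n_e: int = 50,
    n_loci: int = 18,
    alleles_per_locus: int = 8,
    n_generations: int = 15,
    sample_size: int = 50,
    seed: int = 0,
) -> dict[str, list[tuple[int, int]]]:
    """Forward Wright–Fisher population at known effective size.

    Monoecious random mating with selfing allowed, so the effective size
    equals the census size exactly.  Unlinked loci start at uniform allele
    frequencies and drift for ``n_generations``; the final generation is
    sampled without replacement.  Returns ``{individual_id: [(a1, a2) per
    locus]}`` suitable for the LD effective-size estimator.
    """
    if sample_size > n_e:
        raise ValueError("cannot sample more individuals than the population")
    rng = np.random.default_rng(seed)
    loci = default_panel(n_loci, alleles_per_locus)
    autosomal = [l for l in loci if not l.is_sex_linked][:n_loci]
    # genotypes[g, l, c]: allele index of copy c at locus l in individual g
    geno = rng.integers(0, alleles_per_locus, size=(n_e, n_loci, 2))
    for _ in range(n_generations):
        mothers = rng.integers(0, n_e, size=n_e)
        fathers = rng.integers(0, n_e, size=n_e)
        mc = rng.integers(0, 2, size=(n_e, n_loci))
        fc = rng.integers(0, 2, size=(n_e, n_loci))
        nxt = np.empty_like(geno)
        rows = np.arange(n_loci)
        for i in range(n_e):
            nxt[i, :, 0] = geno[mothers[i], rows, mc[i]]
            nxt[i, :, 1] = geno[fathers[i], rows, fc[i]]
        geno = nxt
    picked = rng.choice(n_e, size=sample_size, replace=False)
    out: dict[str, list[tuple[int, int]]] = {}
    for rank, i in enumerate(picked):
        gens = []
        for li, locus in enumerate(autosomal):
            a = locus.allele_sizes[geno[i, li, 0]]
            b = locus.allele_sizes[geno[i, li, 1]]
            gens.append((min(a, b), max(a, b)))
        out[f"WF_{rank:03d}"] = gens
    return out


def simulate_survival_dataset(
    n: int = 1354,
    beta: dict[str, float] | None = None,
    intercept: float = -1.65,
    years: tuple[int, ...] = (2012, 2013, 2014, 2015, 2016),
    year_effects: dict[int, float] | None = None,
    seed: int = 0,
):
    """Release cohort with Bernoulli detection from a logistic model.

    Covariates mimic the release program: day of year uniform over the
    release season, weight correlated with day, sex balanced, individual
    homozygosity (HL) in [0, 1], CB ancestry percentage.  ``beta`` gives
    the log-odds effects on the standardized internal scale; defaults are
    the qualitative effect pattern of the monitoring analysis (later
    release day and higher weight help, homozygosity hurts).
    Returns a pandas DataFrame with a ``detected`` response.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if beta is None:
        beta = {
            "release_day": 0.010,
            "release_weight": 0.003,
            "sex": 0.0,
            "HL": -1.9,
            "CB": 0.0,
        }
    if year_effects is None:
        year_effects = {y: 0.0 for y in years}
    day = rng.integers(120, 271, size=n)
    weight = 250.0 + 1.2 * (day - 120) + rng.normal(0.0, 80.0, size=n)
    sex_female = rng.integers(0, 2, size=n)
    hl = rng.beta(2.0, 4.0, size=n)
    cb = rng.beta(2.0, 8.0, size=n) * 100.0
    year = rng.choice(years, size=n)
    lin = (
        intercept
        + beta["release_day"] * (day - 195)
        + beta["release_weight"] * (weight - weight.mean())
        + beta["sex"] * sex_female
        + beta["HL"] * hl
        + beta["CB"] * (cb - cb.mean()) / 100.0
        + np.array([year_effects[y] for y in year])
    )
    p = 1.0 / (1.0 + np.exp(-lin))
    detected = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {
            "detected": detected,
            "release_day": day,
            "release_weight": weight,
            "sex": np.where(sex_female == 1, "F", "M"),
            "HL": hl,
            "CB": cb,
            "year": year,
        }
    )


def apparent_homozygote_rate(p_dropout: float) -> float:
    """Closed-form chance a true heterozygote replicate reads as an
    apparent homozygote: exactly one of the two alleles drops out
    (per-allele independent dropout, no failure, no false alleles)."""
    return 2.0 * p_dropout * (1.0 - p_dropout)


def alleles_in_parents(
    offspring: TrueIndividual,
    by_id: dict[str, TrueIndividual],
    loci: list[Locus],
) -> bool:
    """Exhaustive Mendelian check: every autosomal offspring allele occurs
    in at least one parent (valid only for mutation_rate=0 pedigrees)."""
    mother = by_id[offspring.mother_id]
    father = by_id[offspring.father_id]
    for locus in loci:
        if locus.is_sex_linked:
            continue
        a, b = offspring.genotype[locus.name]
        parental = set(mother.genotype[locus.name]) | set(
            father.genotype[locus.name]
        )
        if a not in parental or b not in parental:
            return False
    return True
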