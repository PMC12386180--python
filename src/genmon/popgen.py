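"""Per-period genetic diversity and effective population size.

Implements the diversity battery of the monitoring report — observed
heterozygosity, unbiased expected heterozygosity, allelic richness rarefied
to a common sample size, and the individual homozygosity-by-loci index —
plus effective population size from inter-locus linkage disequilibrium
(Burrows composite r-squared with the random-mating sampling-bias
correction and its parametric chi-square confidence interval).

Reporting rules of the monitoring program: He and AR only for cohorts of
>= 5 individuals, Ne only for >= 7 (smaller cohorts yield infinite
estimates); rare alleles below minor allele frequency 0.05 are excluded
from each locus-pair comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

MIN_N_HE_AR = 5
MIN_N_NE = 7
DEFAULT_MAF = 0.05
RAREFACTION_N = 5  # individuals, i.e. 10 gene copies


@dataclass
class CohortSample:
    """Distinct individuals of one survey period, autosomal genotypes only."""

    period_id: str
    genotypes: dict[str, dict[str, tuple[int, int]]]

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("cohort needs at least one individual")

    @property
    def n(self) -> int:
        return len(self.genotypes)

    def loci(self) -> list[str]:
        names: set[str] = set()
        for geno in self.genotypes.values():
            names.update(geno)
        return sorted(names)

    def allele_counts(self, locus: str) -> dict[int, int]:
        counts: dict[int, int] = {}
        for geno in self.genotypes.values():
            pair = geno.get(locus)
            if pair is None:
                continue
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
        return counts

    def typed_n(self, locus: str) -> int:
        return sum(1 for g in self.genotypes.values() if locus in g)


def observed_het(cohort: CohortSample) -> tuple[dict[str, float], float]:
    """Per-locus and mean fraction of typed individuals heterozygous."""
    per_locus: dict[str, float] = {}
    for locus in cohort.loci():
        typed = [
            g[locus] for g in cohort.genotypes.values() if locus in g
        ]
        if not typed:
            continue
        per_locus[locus] = sum(1 for a, b in typed if a != b) / len(typed)
    mean = float(np.mean(list(per_locus.values()))) if per_locus else float("nan")
    return per_locus, mean


def unbiased_expected_het(
    cohort: CohortSample, min_n: int = MIN_N_HE_AR
) -> tuple[dict[str, float], float]:
    """Unbiased expected heterozygosity (2N/(2N-1))(1 - sum p_i^2).

    Suppressed (NaN) for cohorts below the reporting floor of ``min_n``
    individuals.
    """
    if cohort.n < min_n:
        return {}, float("nan")
    per_locus: dict[str, float] = {}
    for locus in cohort.loci():
        counts = cohort.allele_counts(locus)
        copies = sum(counts.values())
        if copies < 2:
            continue
        s2 = sum((c / copies) ** 2 for c in counts.values())
        per_locus[locus] = (copies / (copies - 1)) * (1.0 - s2)
    mean = float(np.mean(list(per_locus.values()))) if per_locus else float("nan")
    return per_locus, mean


def rarefied_allele_count(
    counts: dict[int, int], n_copies_target: int
) -> float:
    """Expected allele count in a random subsample of gene copies.

    Hypergeometric rarefaction: sum over alleles of the probability the
    allele appears at least once in a draw of ``n_copies_target`` copies.
    """
    total = sum(counts.values())
    if total < n_copies_target:
        return float("nan")
    denom = math.comb(total, n_copies_target)
    return sum(
        1.0 - math.comb(total - c, n_copies_target) / denom
        if total - c >= n_copies_target
        else 1.0
        for c in counts.values()
    )


def allelic_richness(
    cohort: CohortSample,
    rarefaction_n: int = RAREFACTION_N,
    min_n: int = MIN_N_HE_AR,
) -> tuple[dict[str, float], float]:
    """Per-locus and mean allelic richness rarefied to ``rarefaction_n``
    individuals (2x gene copies); suppressed below the reporting floor."""
    if rarefaction_n < 1:
        raise ValueError("rarefaction_n must be >= 1")
    if cohort.n < min_n:
        return {}, float("nan")
    target = 2 * rarefaction_n
    per_locus: dict[str, float] = {}
    for locus in cohort.loci():
        counts = cohort.allele_counts(locus)
        ar = rarefied_allele_count(counts, target)
        if not math.isnan(ar):
            per_locus[locus] = ar
    mean = float(np.mean(list(per_locus.values()))) if per_locus else float("nan")
    return per_locus, mean


def hl_individual(
    genotype: dict[str, tuple[int, int]],
    expected_het: dict[str, float],
) -> float:
    """Homozygosity by loci: HL = sum E_h / (sum E_h + sum E_j), where E_h
    runs over the individual's homozygous loci and E_j over heterozygous
    ones, weighting each locus by its expected heterozygosity.  0 when
    fully heterozygous, 1 when fully homozygous; untyped loci are skipped.
    """
    e_hom = 0.0
    e_het = 0.0
    n_typed = 0
    for locus, (a, b) in genotype.items():
        e = expected_het.get(locus)
        if e is None:
            continue
        n_typed += 1
        if a == b:
            e_hom += e
        else:
            e_het += e
    if n_typed == 0:
        raise ValueError("zero typed loci: HL undefined")
    if e_hom + e_het == 0:
        return 0.0
    return e_hom / (e_hom + e_het)


@dataclass
class NeEstimate:
    point: float  # may be math.inf
    ci_low: float
    ci_high: float
    n_pairs: int
    maf: float
    mean_r2: float
    expected_r2_sample: float
    harmonic_s: float
    suppressed: bool = False
    reason: str = ""


def _expected_r2(s: float) -> float:
    """Sampling component of r-squared under random mating.

    Piecewise second-order approximation: 1/S branch for samples of >= 30
    individuals, the small-sample recalibration below 30.
    """
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def _ne_from_r2prime(r2p: float, s: float) -> float:
    """Back-transform the drift component of r-squared to Ne (random
    mating); non-positive drift signal means no finite estimate."""
    if r2p <= 0:
        return math.inf
    if s >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        if disc < 0:
            disc = 0.0
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
    disc = 0.308**2 - 2.08 * r2p
    if disc < 0:
        disc = 0.0
    return (0.308 + math.sqrt(disc)) / (2.0 * r2p)


def _pair_r2(
    X: np.ndarray, Y: np.ndarray, maf: float
) -> tuple[list[float], int]:
    """Burrows composite r-squared values for one locus pair.

    ``X``/``Y`` are individuals x alleles dosage matrices (0/1/2) over the
    individuals typed at both loci.  Alleles with frequency < maf or
    > 1-maf in this subsample are excluded (per-pair filtering).
    """
    s = X.shape[0]
    if s < 2:
        return [], s
    pa = X.mean(axis=0) / 2.0
    pb = Y.mean(axis=0) / 2.0
    keep_a = np.where((pa >= maf) & (pa <= 1.0 - maf))[0]
    keep_b = np.where((pb >= maf) & (pb <= 1.0 - maf))[0]
    # drop one allele per locus: with k alleles only k-1 are independent
    if len(keep_a) > 1:
        keep_a = keep_a[:-1]
    if len(keep_b) > 1:
        keep_b = keep_b[:-1]
    if len(keep_a) == 0 or len(keep_b) == 0:
        return [], s
    Xc = X[:, keep_a] - 2.0 * pa[keep_a]
    Yc = Y[:, keep_b] - 2.0 * pb[keep_b]
    # Burrows composite disequilibrium with the n/(n-1) correction
    delta = (Xc.T @ Yc) / (2.0 * (s - 1))
    va = pa[keep_a] * (1.0 - pa[keep_a])
    vb = pb[keep_b] * (1.0 - pb[keep_b])
    r2 = (delta**2) / np.outer(va, vb)
    return [float(v) for v in r2.ravel()], s


def ne_ld(
    cohort: CohortSample,
    maf: float = DEFAULT_MAF,
    min_n: int = MIN_N_NE,
    alpha: float = 0.05,
) -> NeEstimate:
    """Effective population size from inter-locus linkage disequilibrium.

    Averages Burrows composite r-squared over all locus pairs and allele
    pairs (minor alleles below ``maf`` excluded per pair), subtracts the
    expected sampling component for the harmonic-mean sample size, and
    back-transforms the drift residual to Ne under random mating.  The
    parametric confidence interval treats the number of allele-pair
    comparisons as chi-square degrees of freedom on the mean r-squared.
    """
    if not 0.0 <= maf < 0.5:
        raise ValueError("maf must lie in [0, 0.5)")
    if cohort.n < min_n:
        return NeEstimate(
            math.nan, math.nan, math.nan, 0, maf, math.nan, math.nan,
            math.nan, suppressed=True,
            reason=f"N={cohort.n} below reporting floor {min_n}",
        )
    loci = cohort.loci()
    # dosage matrices per locus over all individuals (NaN row = untyped)
    inds = sorted(cohort.genotypes)
    dosage: dict[str, np.ndarray] = {}
    alleles: dict[str, list[int]] = {}
    for locus in loci:
        counts = cohort.allele_counts(locus)
        if len(counts) < 2:
            continue
        al = sorted(counts)
        alleles[locus] = al
        mat = np.full((len(inds), len(al)), np.nan)
        for i, ind in enumerate(inds):
            pair = cohort.genotypes[ind].get(locus)
            if pair is None:
                continue
            row = np.zeros(len(al))
            for a in pair:
                row[al.index(a)] += 1
            mat[i] = row
        dosage[locus] = mat
    usable = sorted(dosage)
    if len(usable) < 2:
        return NeEstimate(
            math.nan, math.nan, math.nan, 0, maf, math.nan, math.nan,
            math.nan, suppressed=True, reason="fewer than 2 usable loci",
        )
    r2_all: list[float] = []
    s_list: list[int] = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            Xf, Yf = dosage[usable[i]], dosage[usable[j]]
            both = ~np.isnan(Xf[:, 0]) & ~np.isnan(Yf[:, 0])
            vals, s = _pair_r2(Xf[both], Yf[both], maf)
            r2_all.extend(vals)
            s_list.extend([s] * len(vals))
    if not r2_all:
        return NeEstimate(
            math.nan, math.nan, math.nan, 0, maf, math.nan, math.nan,
            math.nan, suppressed=True,
            reason="no allele pairs pass the MAF filter",
        )
    mean_r2 = float(np.mean(r2_all))
    harm_s = float(len(s_list) / np.sum(1.0 / np.asarray(s_list)))
    e_r2 = _expected_r2(harm_s)
    r2p = mean_r2 - e_r2
    point = _ne_from_r2prime(r2p, harm_s)
    j = len(r2_all)
    lo_chi = stats.chi2.ppf(1.0 - alpha / 2.0, j)
    hi_chi = stats.chi2.ppf(alpha / 2.0, j)
    r2_lo = j * mean_r2 / lo_chi  # smaller r2 -> larger Ne
    r2_hi = j * mean_r2 / hi_chi
    ne_hi = _ne_from_r2prime(r2_lo - e_r2, harm_s)
    ne_lo = _ne_from_r2prime(r2_hi - e_r2, harm_s)
    ci_low, ci_high = sorted(
        (ne_lo, ne_hi), key=lambda v: (math.isinf(v), v)
    )
    if math.isinf(point):
        ci_high = math.inf
    return NeEstimate(
        point=point,
        ci_low=min(ci_low, point),
        ci_high=max(ci_high, point),
        n_pairs=j,
        maf=maf,
        mean_r2=mean_r2,
        expected_r2_sample=e_r2,
        harmonic_s=harm_s,
    )


def molecular_coancestry_ne(cohort: CohortSample) -> float:
    """Secondary, clearly descriptive estimator: effective size from mean
    molecular co-ancestry among distinct pairs (1/(2*fbar)).  Reported
    alongside the LD estimate only; the LD random-mating model is the
    primary output of the monitoring report."""
    inds = sorted(cohort.genotypes)
    if len(inds) < 2:
        return math.nan
    fvals = []
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            gi = cohort.genotypes[inds[i]]
            gj = cohort.genotypes[inds[j]]
            shared = set(gi) & set(gj)
            if not shared:
                continue
            per_locus = []
            for locus in shared:
                a1, a2 = gi[locus]
                b1, b2 = gj[locus]
                sim = (
                    (a1 == b1) + (a1 == b2) + (a2 == b1) + (a2 == b2)
                ) / 4.0
                per_locus.append(sim)
            fvals.append(float(np.mean(per_locus)))
    fbar = float(np.mean(fvals)) if fvals else math.nan
    if not fvals or fbar <= 0:
        return math.inf
    return 1.0 / (2.0 * fbar)
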