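# Methods

This note documents the models and procedures implemented in `genmon`,
the assumptions behind them, the parameter defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical and design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## System and data model

The monitored system is a reintroduced pygmy rabbit population assembled
from four source lineages — the native Columbia Basin (CB) remnant and
translocated animals from Nevada/Oregon/Idaho, Wyoming/northern Utah, and
southern Utah — bred in semi-wild enclosures and released into three
recovery areas (SBF/CRP, 1780 ha; Beezley Hills, 83 ha; Chester Butte,
893 ha). Monitoring is noninvasive: fecal pellets collected on winter and
summer surveys, genotyped at 18 autosomal microsatellite loci plus one
Y-linked locus across three PCR multiplexes. Alleles are integer
fragment sizes on a per-locus ladder congruent modulo the repeat unit.

Low-quantity fecal DNA makes single amplifications unreliable, so every
inference rests on replicated PCR (4–8 replicates per sample) filtered
through confirmation rules, and every downstream statistic operates on
the registry of distinct individuals, never on raw samples (which would
pseudo-replicate whatever animal defecated most).

## Consensus genotyping

Multi-tubes rule: an allele is confirmed once observed in ≥2 replicates;
a heterozygote needs exactly two confirmed alleles; a homozygote needs ≥3
apparent-homozygote calls of a single confirmed allele. Three or more
confirmed alleles at one locus are contradictory and the locus stays
unresolved — we never emit a three-allele call, a deliberately
conservative choice for identity work. Calls carrying alleles off the
locus ladder (the signature of sympatric cottontails) count as failed.
The species-ID assay itself is represented only as a per-sample
pass/cottontail/fail flag; its chemistry is out of scope.

Era gates mirror the two laboratory protocols: era A (2012–2017) requires
≥5 of the 7 first-multiplex autosomal loci before a sample proceeds, and
allows matching on ≥4 shared loci; era B (2018–2020) runs multiplexes 2–3
together and requires ≥8 confirmed loci. The sex locus never counts
toward a gate. Sex is called male on ≥2 Y-locus amplifications with
autosomal support, female on zero Y amplifications with autosomal
support, otherwise unknown — the autosomal guard keeps failed DNA from
reading as female. Replicates from repeated runs of one sample pool into
a single replicate set; later replicates are additive evidence.

## Identity matching

Per-locus probability-of-identity statistics under Hardy–Weinberg:
PID = 2(Σp²)² − Σp⁴ for unrelated pairs and
PIDsibs = 0.25 + 0.5Σp² + 0.5(Σp²)² − 0.25Σp⁴ for full siblings, with
multilocus values the product over compared loci. A match requires the
era's locus floor, cumulative PIDsibs < 0.01 over the shared loci, and
agreement up to: zero mismatches; one mismatch explainable as a single
stepwise mutation (one allele one repeat unit away, the other shared); or
two mismatches both consistent with allelic dropout in the query (query
an apparent homozygote whose allele is a subset of the registry
heterozygote). Anything else founds a new individual; two-mismatch
non-dropout cases are additionally flagged for manual review. Allele
frequencies for PID come from the registry of distinct individuals
(global table by default, per-period optional). Ties between registry
entries resolve to the entry with more compared loci; a residual tie is
flagged and never merged. One null-allele-prone locus participates in
matching but is excluded from all downstream statistics.

## Parentage

Strict exclusion: a dyad fails at a locus where offspring and candidate
share no allele; it survives zero exclusions, or exactly one whose
nearest-allele distance equals one repeat unit (single-step mutation). A
parent pair must further partition the offspring's alleles jointly at
every locus typed in all three animals, with at most one stepwise
mutation excused across the whole trio — stricter than one per dyad, so a
mutation cannot be excused twice. Multiple surviving pairs leave the
ambiguous role unknown with the ambiguity count reported; a single parent
is assigned when exactly one candidate of that sex survives. Likelihood
(LOD) scoring and simulation-based confidence are deliberately absent:
the decision rule here is purely exclusion-based, and recovery is exact
only when per-locus exclusion power is high (the test suite demonstrates
100% trio recovery at 17 uniform 8-allele loci, and honest ambiguity
under skewed frequencies). Candidate parents default to all known adults
of the right sex; restricting to earlier-detected animals is a caller
choice.

## Supervised admixture

The estimand is the admixture vector q over the four predefined clusters
given reference allele frequencies — a supervised quantity. Reference
frequencies are estimated from known-origin individuals with additive
smoothing f = (count + c)/(copies + c·k) over the union of alleles
observed anywhere at the locus (default pseudocount c = 0.5), so no
genotype has zero likelihood in any cluster. The likelihood treats allele
copies as independent draws from the mixture Σ_k q_k f_{k,l,a}
(loci independent, missing loci skipped, no imputation), maximised by EM
on the simplex. The log-likelihood is checked non-decreasing at every
iteration and the run aborts on a violation beyond 1e-8. Ten starts
(uniform plus nine Dirichlet(1) draws) guard against flat regions; the
best-likelihood run is reported, convergence at relative log-likelihood
change < 1e-8. This replaces MCMC clustering with prior-informed
admixture: the correlated-allele-frequency prior and location prior of
that approach are not replicated, which is the one documented divergence
from the original workflow. Classification uses the inclusive rule
q_CB ≥ 0.05, the threshold separating known non-CB animals' spurious CB
assignments (observed up to 4.89%) from real CB ancestry; no upper
cutoff is applied: the monitoring program's own summary tables print
conflicting upper bands, but only the >= 5% rule is operational.

## Diversity and effective population size

Per survey period the cohort is the distinct individuals detected
(wild-born, released and re-detected), autosomal loci only. Observed
heterozygosity is the fraction of typed individuals heterozygous;
unbiased expected heterozygosity is (2N/(2N−1))(1 − Σp²); allelic
richness is rarefied to 5 individuals (10 gene copies) by the
hypergeometric expectation Σ_a [1 − C(n−c_a, g)/C(n, g)]. He and AR are
suppressed for cohorts under 5 individuals; all means over loci are
unweighted arithmetic means. The homozygosity-by-loci index weights each
locus by its expected heterozygosity: HL = ΣE_hom/(ΣE_hom + ΣE_het),
0 for a fully heterozygous and 1 for a fully homozygous individual.

Effective population size uses the linkage-disequilibrium method under
random mating. For each locus pair, over the individuals typed at both:
Burrows composite disequilibrium Δ̂ per allele pair with the n/(n−1)
correction, r̂² = Δ̂²/(p_A q_A p_B q_B); alleles with sample frequency
below 0.05 are excluded per pair (not whole loci), and one allele per
locus is dropped as redundant (k−1 of k are independent). The sampling
component is subtracted piecewise — E[r̂²] = 1/S + 3.19/S² for S ≥ 30,
0.0018 + 0.907/S + 4.44/S² below — and the drift residual r′²
back-transforms as Ne = (1/3 + √(1/9 − 2.76r′²))/(2r′²) for S ≥ 30, with
the small-sample constants (0.308, 2.08) below. Non-positive r′² yields
an infinite estimate, carried as a distinguished value. The parametric
95% CI treats the number of allele-pair comparisons as chi-square degrees
of freedom on mean r̂². Ne is suppressed for cohorts under 7 individuals
(smaller cohorts produce infinite estimates). A molecular co-ancestry
estimator (1/(2f̄) over mean pairwise allele sharing) is available as a
clearly labelled secondary output only. Calibration: on Wright–Fisher
populations of true Ne = 50 (18 loci × 8 alleles, 50 sampled) the median
point estimate over 100 replicates is checked to lie in [35, 70] by both
the test suite and the acceptance script.

## Demographic summaries and comparisons

Minimum count is the number of distinct genotyped individuals detected in
a period; rabbits-per-burrow divides it by active burrow systems found;
density divides it by potential habitat (1780/83/893 ha per area,
consumed as precomputed hectares — no GIS). Rounding is presentation-only
(two decimals, three below 0.01) and never feeds back into computation.
Year-over-year comparisons use Welch's two-sample t-test — on per-locus
values for Ho/AR and per-individual values for CB% (the monitoring program
reports the test but not the replication unit; this is our choice) — and sex ratios use
the two-sided Fisher exact test on the raw male/female counts of the two
periods. Apparent survival is detection of a released animal in a later
survey, so it confounds mortality with emigration and non-detection; the
pooled rates are simple detected/at-risk percentages per cohort path.

## Apparent-survival models

Logistic regression of detection (0/1) on release day-of-year, sex,
release weight (g), HL and CB ancestry; juvenile models always include
release year as a categorical term with 2014 the reference level. The
candidate set is every subset of the five covariates — 32 models
including the null (the program describes this set as "30 combinations and the
null", which undercounts the 31 non-empty subsets by one; we implement
all of them) — and 32 year-anchored models for juveniles. Fits use standard
IRLS maximum likelihood (statsmodels GLM, binomial family); fits with
diverging coefficients (|β| > 15 or non-convergence, the separation
signature) are flagged and excluded from averaging. Model weights are
Akaike weights on AICc = −2lnL + 2k + 2k(k+1)/(n−k−1). Averaging is
natural: each parameter is averaged over the models containing it with
weights renormalised within that subset, with unconditional standard
errors √(Σw(se² + (β−β̄)²)) and both 85% and 95% normal-theory intervals
emitted (the program's protocol names 85% intervals for averaging while its
summary tables print 95%; we emit both). Rows missing a modelled covariate are dropped per model, which is
how missing adult release weights are handled; the with/without-weight
top-model comparison is then a filtered refit on the complete-weight
subset.

## The synthetic-data generator

What it emulates: four source clusters drawn from an F-model
(cluster frequencies ~ Dirichlet(base·(1−F)/F), F the `divergence`
parameter, so F→0 collapses the clusters and large F creates private
alleles); Mendelian pedigrees with father–son Y transmission, optional
stepwise mutation (≤0.01 per meiosis) and expected-ancestry propagation
as the parental mean; surveys with per-individual detection probability
and 4–8 replicates per sample; and a three-part per-replicate error
process — amplification failure (default 0.2), independent per-allele
dropout (default 0.15; one dropped allele of a heterozygote reads as an
apparent homozygote, both dropped as a failed replicate), and stepwise
false alleles (default 0.02, one repeat unit away). The error defaults
are fixture choices for moderately noisy fecal extracts — the monitoring
program does not publish its error rates. Expected (pedigree) ancestry,
not realised locus-level ancestry, is the recovery target, matching how
admixture estimates are interpreted against pedigrees. All randomness
flows from explicit per-call seeds; there is no global state.

The survival-dataset generator reproduces the released-juvenile cohort's
scale and structure: n = 1354, baseline detection ≈ 10% (the program's
pooled juvenile rate), release day uniform over the season, weight
correlated with day (r ≈ 0.5; the program reports 0.62) with an 80 g
residual spread consistent with juvenile weights of roughly 150–550 g,
and the reported effect pattern (day +0.010, weight +0.003 per g,
HL −1.9 on the log-odds scale).

What it does not emulate: spatial structure (burrow placement, dispersal,
survey coverage), null alleles, per-locus or per-sample error
heterogeneity, DNA-quality covariates, disease dynamics, and real
multiplex chemistry. Passing tests therefore demonstrate the statistical
machinery is correct under the stated error model, not that any
particular field dataset meets that model's assumptions.

A separate monoecious Wright–Fisher simulator (selfing allowed, so
effective size equals census size exactly) provides populations of known
Ne for calibrating the LD estimator; 15 generations of burn-in from
uniform frequencies is ample for unlinked-locus LD to equilibrate (LD
halves each generation under free recombination).

## Numerical choices and degenerate inputs

EM convergence: relative log-likelihood change < 1e-8 (tests use down to
1e-12), cap 2000 iterations; q renormalised each step, Σq = 1 maintained
to 1e-8. Frequency tables validate to Σp = 1 ± 1e-9. Identical samples
in Welch's test return t = 0, p = 1 rather than 0/0. Infinite Ne and
suppressed values (cohort floors) are distinguished values with recorded
reasons, never exceptions or overflows. Genepop export uses 3-digit
allele coding with an emitted recoding table for oversize alleles and
000000 for missing. Matching scans samples in sorted id order so registry
construction is order-independent and bit-reproducible; the pipeline
manifest hashes every stage output to make reruns checkable.

## Known limitations

Identity and parentage error rates degrade with relatedness and skewed
allele frequencies faster than the defaults suggest; the matcher's <5%
split+merge guarantee is demonstrated at the default error model only.
The supervised EM yields point estimates without credible intervals, and
its independence assumptions understate uncertainty for linked or
correlated clusters. The LD-Ne chi-square interval treats allele-pair
comparisons as independent, which understates interval width for
multiallelic loci. Apparent survival confounds detection and emigration
with mortality by construction; no capture–recapture correction is
attempted.
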