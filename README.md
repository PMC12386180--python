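# genmon

Noninvasive genetic-monitoring pipeline for microsatellite fecal-DNA data,
built around the long-term monitoring of the endangered Columbia Basin
pygmy rabbit (*Brachylagus idahoensis*) reintroduction in central
Washington. The package takes replicated, noisy PCR amplifications of
fecal pellet extracts all the way to the quantities a recovery program
reports each survey period: who was detected (individual identification),
who bred (parentage), how much native ancestry persists (admixture),
how diverse the population is (Ho, He, allelic richness, effective
population size), and what drives apparent survival of released animals
(AICc-averaged logistic models).

It is written for conservation geneticists and quantitative ecologists who
run or audit microsatellite-based monitoring programs. Because raw
genotypes from such programs are rarely shareable, the package ships a
ground-truthed synthetic-data generator that reproduces the statistical
structure of the system — four source lineages with distinct allele
frequencies, an admixed pedigree, a release/detection program, and a
per-replicate genotyping error process — so every stage is testable
end-to-end without field data.

## The statistics at the core

**Consensus genotyping (multi-tubes rule).** Each sample is amplified 4–8
times per locus; an allele is confirmed after 2 independent observations,
a homozygote after 3 apparent-homozygote calls. Era-specific multiplex
gates (≥5 of 7 first-multiplex loci in 2012–2017; ≥8 loci across
multiplexes 2–3 in 2018–2020) screen out low-quality extracts.

**Probability of identity.** Two samples are the same individual when they
agree at enough loci that full siblings would not match by chance:

    PID_locus      = 2(Σp_i²)² − Σp_i⁴
    PIDsibs_locus  = 0.25 + 0.5Σp_i² + 0.5(Σp_i²)² − 0.25Σp_i⁴

with the product over compared loci required to fall below 0.01. One
mismatching locus is tolerated if explainable as a single stepwise
mutation; two only if both look like allelic dropout in the query.

**Parentage by strict exclusion.** A candidate parent is excluded at a
locus where it shares no allele with the offspring; a parent pair must
additionally partition the offspring's alleles jointly, with at most one
stepwise mutation excused per trio.

**Supervised admixture.** With reference allele frequencies f_{k,l,a} for
the four source clusters held fixed, an individual's ancestry vector q
maximises L(q) = Π_j Σ_k q_k f_k(allele_j) over its allele copies, fitted
by EM (monotone log-likelihood, best of 10 starts). An individual
"contains Columbia Basin ancestry" when q_CB ≥ 0.05.

**Diversity and Ne.** Observed heterozygosity; unbiased expected
heterozygosity (2N/(2N−1))(1 − Σp²); allelic richness rarefied to 5
individuals by hypergeometric expectation; the GENHET-style
homozygosity-by-loci index HL = ΣE_hom/(ΣE_hom + ΣE_het); and effective
population size from inter-locus Burrows composite r², corrected for the
sampling component E[r²|S] and back-transformed under random mating, with
a parametric chi-square confidence interval (MAF 0.05; reported for
cohorts of ≥7).

**Apparent survival.** Logistic regression of later-survey detection on
release day, sex, release weight, HL and CB ancestry; all 32 covariate
subsets (juvenile models always carry release year, reference 2014),
ranked by AICc with natural (subset-renormalised) model averaging and
unconditional standard errors.

## Worked example

Simulate a population, run the full pipeline, and summarise:

```bash
$ genmon simulate --seed 3 --out genmon_out
wrote 107 samples to genmon_out

$ genmon match genmon_out/replicates.csv --registry-out registry.csv
winter_1: minimum count 107 ({'wild_born': 107})

$ genmon diversity registry.csv
N=107  Ho=0.613  He=0.686  AR=3.758
```

The minimum count (107) is the number of distinct genotypes among the
period's gated samples — the program's census floor. Ho below He reflects
the admixed-pedigree structure of the simulated cohort, and AR is the
expected allele count per locus in a random draw of 5 individuals.

On the published monitoring tables, the same summary machinery reproduces
the program's reported values:

```bash
$ genmon report | head -4
     period_id  minimum_count  males  females  rabbits_per_burrow density_presented   ho   ar
winter_2012_13             45     18       27                0.87              0.03 0.76 5.22
winter_2013_14             44     22       22                0.75              0.02 0.81 5.15
winter_2014_15             91     44       47                0.63              0.05 0.81 5.13
```

Densities are minimum count over potential habitat (1780 ha for the
Sagebrush Flat/CRP area), printed to two decimals (three below 0.01).

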