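"""File formats, configuration and the pipeline orchestrator.

All tables are comma-separated UTF-8 with a mandatory header row; alleles
are integer base pairs.  Genotypes interchange with other population-
genetics tools via Genepop format (3-digit allele coding, ``000000`` for
missing).  The orchestrator wires the stages together deterministically:
simulate -> consensus -> match -> parentage -> ancestry -> diversity ->
summaries, writing every stage output plus a manifest of seeds and
thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import ancestry as anc
from . import matching, parentage, popgen, summaries
from .consensus import consensus_genotype, era_rules, gate_sample
from .synthetic import (
    ErrorModel,
    Locus,
    ReplicateSet,
    SurveyDesign,
    generate_reference_clusters,
    simulate_pedigree,
    simulate_survey,
)

REPLICATE_COLUMNS = [
    "sample_id", "period_id", "replicate_no", "locus", "allele1", "allele2",
]
PANEL_COLUMNS = ["cluster", "locus", "allele", "freq"]


class SchemaError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and inputs of one pipeline run.

    Defaults are the monitoring program's published settings: PIDsibs
    matching threshold 0.01, CB-ancestry threshold 0.05, minor allele
    frequency 0.05 for the LD Ne model, rarefaction to 5 individuals,
    He/AR reported for cohorts of >= 5 and Ne for >= 7, and the
    potential-habitat areas per recovery area.
    """

    era: str = "A"
    pid_sibs_threshold: float = 0.01
    cb_threshold: float = 0.05
    maf: float = 0.05
    rarefaction_n: int = 5
    min_n_he_ar: int = 5
    min_n_ne: int = 7
    habitat_ha: dict = dataclasses.field(
        default_factory=lambda: {"SBF": 1780.0, "BH": 83.0, "CHB": 893.0}
    )
    seed: int = 0
    n_loci: int = 18
    alleles_per_locus: int = 8
    divergence: float = 0.4
    n_founders_per_cluster: int = 10
    n_generations: int = 2
    detection_prob: float = 0.9
    replicates_per_sample: int = 8
    p_fail: float = 0.2
    p_dropout: float = 0.15
    p_false: float = 0.02
    output_dir: str = "genmon_out"

    def validate(self) -> None:
        if not 0 < self.pid_sibs_threshold < 1:
            raise ValueError("pid_sibs_threshold outside (0, 1)")
        if not 0 <= self.cb_threshold <= 1:
            raise ValueError("cb_threshold outside [0, 1]")
        if not 0 <= self.maf < 0.5:
            raise ValueError("maf outside [0, 0.5)")
        if self.rarefaction_n < 1:
            raise ValueError("rarefaction_n must be >= 1")
        for site, ha in self.habitat_ha.items():
            if ha <= 0:
                raise ValueError(f"habitat_ha[{site}] must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_replicates(samples: list[ReplicateSet], path: str | Path) -> None:
    rows = []
    for s in samples:
        for locus, reps in sorted(s.calls.items()):
            for i, call in enumerate(reps, start=1):
                a1, a2 = ("", "") if call is None else call
                rows.append(
                    (s.sample_id, s.period_id, i, locus, a1, a2)
                )
    pd.DataFrame(rows, columns=REPLICATE_COLUMNS).to_csv(path, index=False)


def read_replicates(
    path: str | Path, loci: list[Locus] | None = None
) -> tuple[list[ReplicateSet], pd.DataFrame]:
    """Read a replicates table; returns the replicate sets plus a frame of
    flagged rows (alleles off the locus ladder) with their line numbers.
    Flagged rows are reported, never silently dropped — they stay in the
    replicate set as out-of-bin calls for the consensus caller to handle.
    """
    df = pd.read_csv(path)
    _require_columns(df, REPLICATE_COLUMNS, path)
    ladders = (
        {l.name: set(l.allele_sizes) for l in loci} if loci else {}
    )
    flagged = []
    grouped: dict[tuple[str, str], dict[str, list]] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        key = (str(row.sample_id), str(row.period_id))
        calls = grouped.setdefault(key, {})
        reps = calls.setdefault(str(row.locus), [])
        if pd.isna(row.allele1) or pd.isna(row.allele2):
            reps.append(None)
            continue
        a1, a2 = int(row.allele1), int(row.allele2)
        ladder = ladders.get(str(row.locus))
        if ladder is not None and (a1 not in ladder or a2 not in ladder):
            flagged.append(
                {"line": line_no, "sample_id": row.sample_id,
                 "locus": row.locus, "allele1": a1, "allele2": a2}
            )
        reps.append((min(a1, a2), max(a1, a2)))
    out = [
        ReplicateSet(sample_id=sid, period_id=pid, calls=calls)
        for (sid, pid), calls in grouped.items()
    ]
    return out, pd.DataFrame(
        flagged, columns=["line", "sample_id", "locus", "allele1", "allele2"]
    )


def write_panel(clusters, path: str | Path) -> None:
    rows = [
        (c.name, locus, allele, freq)
        for c in clusters
        for locus, table in sorted(c.freqs.items())
        for allele, freq in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)


def read_panel(path: str | Path) -> dict[str, dict[str, dict[int, float]]]:
    df = pd.read_csv(path)
    _require_columns(df, PANEL_COLUMNS, path)
    out: dict[str, dict[str, dict[int, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.cluster), {}).setdefault(
            str(row.locus), {}
        )[int(row.allele)] = float(row.freq)
    return out


def write_registry(
    registry: dict[str, matching.IndividualRecord], path: str | Path
) -> None:
    rows = []
    for ind_id, rec in sorted(registry.items()):
        for locus, (a, b) in sorted(rec.genotype.items()):
            rows.append(
                {
                    "individual_id": ind_id,
                    "sex": rec.sex,
                    "origin": rec.origin,
                    "first_detected_period": rec.first_detected_period,
                    "detected_periods": ";".join(
                        sorted(rec.detected_periods)
                    ),
                    "locus": locus,
                    "allele1": a,
                    "allele2": b,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_registry(path: str | Path) -> dict[str, matching.IndividualRecord]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["individual_id", "sex", "origin", "first_detected_period",
         "detected_periods", "locus", "allele1", "allele2"],
        path,
    )
    registry: dict[str, matching.IndividualRecord] = {}
    for row in df.itertuples(index=False):
        ind_id = str(row.individual_id)
        rec = registry.get(ind_id)
        if rec is None:
            periods = (
                set(str(row.detected_periods).split(";"))
                if pd.notna(row.detected_periods) and str(row.detected_periods)
                else set()
            )
            rec = matching.IndividualRecord(
                individual_id=ind_id,
                genotype={},
                sex=str(row.sex),
                origin=str(row.origin),
                first_detected_period=str(row.first_detected_period),
                detected_periods=periods,
            )
            registry[ind_id] = rec
        rec.genotype[str(row.locus)] = (int(row.allele1), int(row.allele2))
    return registry


def _code_allele(allele: int, mapping: dict[int, int]) -> str:
    if allele < 1000:
        return f"{allele:03d}"
    return f"{mapping[allele]:03d}"


def export_genepop(
    cohorts: dict[str, dict[str, dict[str, tuple[int, int]]]],
    loci: list[str],
    title: str = "genmon export",
) -> tuple[str, dict[int, int]]:
    """Genepop-format text: one population block per period, 3-digit
    allele coding, missing loci as 000000.  Alleles that do not fit in
    three digits are recoded; the mapping table is returned alongside.
    """
    if not cohorts:
        raise ValueError("no cohorts to export")
    big: set[int] = set()
    for genos in cohorts.values():
        for geno in genos.values():
            for pair in geno.values():
                big.update(a for a in pair if a >= 1000)
    mapping = {a: 900 + i for i, a in enumerate(sorted(big))}
    lines = [title]
    lines.extend(loci)
    for period in sorted(cohorts):
        lines.append("POP")
        for ind in sorted(cohorts[period]):
            geno = cohorts[period][ind]
            parts = []
            for locus in loci:
                pair = geno.get(locus)
                if pair is None:
                    parts.append("000000")
                else:
                    parts.append(
                        _code_allele(pair[0], mapping)
                        + _code_allele(pair[1], mapping)
                    )
            lines.append(f"{ind} ,  " + " ".join(parts))
    return "\n".join(lines) + "\n", mapping


def read_genepop(
    text: str,
) -> tuple[dict[str, dict[str, dict[str, tuple[int, int]]]], list[str]]:
    """Parse the subset of Genepop written by :func:`export_genepop`."""
    lines = [l.rstrip("\n") for l in text.strip().splitlines()]
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        loci.extend(
            s.strip() for s in lines[i].split(",") if s.strip()
        )
        i += 1
    cohorts: dict[str, dict[str, dict[str, tuple[int, int]]]] = {}
    pop_no = 0
    current: dict[str, dict[str, tuple[int, int]]] = {}
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_no += 1
            current = {}
            cohorts[f"pop_{pop_no}"] = current
            i += 1
            continue
        name, _, rest = lines[i].partition(",")
        alleles = rest.split()
        geno = {}
        for locus, code in zip(loci, alleles):
            a1, a2 = int(code[:3]), int(code[3:])
            if a1 == 0 and a2 == 0:
                continue
            geno[locus] = (min(a1, a2), max(a1, a2))
        current[name.strip()] = geno
        i += 1
    return cohorts, loci


def run_pipeline(config: PipelineConfig) -> dict:
    """End-to-end deterministic run on a simulated population.

    Returns the artifact dictionary (registry, parentage assignments,
    ancestry classifications, diversity summary, period summary frame,
    manifest) and writes each stage output as CSV under
    ``config.output_dir``.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clusters, loci = generate_reference_clusters(
        config.n_loci,
        config.alleles_per_locus,
        config.divergence,
        seed=config.seed,
    )
    individuals = simulate_pedigree(
        clusters,
        loci,
        n_founders_per_cluster=config.n_founders_per_cluster,
        n_generations=config.n_generations,
        seed=config.seed + 1,
    )
    design = SurveyDesign(
        period_id="winter_1",
        detection_prob=config.detection_prob,
        replicates_per_sample=config.replicates_per_sample,
    )
    error = ErrorModel(config.p_fail, config.p_dropout, config.p_false)
    samples, truth = simulate_survey(
        individuals, design, error, loci, seed=config.seed + 2
    )
    write_replicates(samples, out_dir / "replicates.csv")
    write_panel(clusters, out_dir / "panel.csv")

    rules = era_rules(config.era)
    registry: dict[str, matching.IndividualRecord] = {}
    consensus = []
    for s in samples:
        cg = consensus_genotype(s, loci, rules)
        if gate_sample(cg, rules):
            consensus.append(cg)
    min_count, breakdown, match_results = matching.register_and_count(
        consensus,
        registry,
        rules,
        loci,
        period_id=design.period_id,
        pid_threshold=config.pid_sibs_threshold,
    )
    write_registry(registry, out_dir / "registry.csv")

    down = matching.downstream_loci(loci)
    adults = [r for r in registry.values()]
    assignments = []
    for rec in adults:
        cand_mothers = [r for r in adults if r.sex == "F" and r is not rec]
        cand_fathers = [r for r in adults if r.sex == "M" and r is not rec]
        assignments.append(
            parentage.assign_parents(rec, cand_mothers, cand_fathers, down)
        )
    pd.DataFrame(
        [
            {
                "offspring": a.offspring_id,
                "mother": a.mother_id or "",
                "father": a.father_id or "",
                "accepted_mutation": a.accepted_mutation,
            }
            for a in assignments
        ]
    ).to_csv(out_dir / "parentage.csv", index=False)

    panel = anc.panel_from_clusters(clusters, loci)
    down_names = {l.name for l in down}
    estimates = []
    for ind_id, rec in sorted(registry.items()):
        geno = {
            n: g for n, g in rec.genotype.items() if n in down_names
        }
        if not geno:
            continue
        estimates.append(
            anc.estimate_admixture_em(
                geno, panel, seed=config.seed + 3, individual_id=ind_id
            )
        )
    cb = anc.classify_cb(estimates, threshold=config.cb_threshold)
    pd.DataFrame(
        [
            {"individual_id": e.individual_id, **e.as_dict(),
             "loglik": e.loglik, "converged": e.converged}
            for e in estimates
        ]
    ).to_csv(out_dir / "ancestry.csv", index=False)

    cohort = popgen.CohortSample(
        design.period_id,
        {
            i: {n: g for n, g in r.genotype.items() if n in down_names}
            for i, r in registry.items()
        },
    )
    _, ho = popgen.observed_het(cohort)
    _, he = popgen.unbiased_expected_het(cohort, config.min_n_he_ar)
    _, ar = popgen.allelic_richness(
        cohort, config.rarefaction_n, config.min_n_he_ar
    )
    ne = popgen.ne_ld(cohort, config.maf, config.min_n_ne)

    males = sum(1 for r in registry.values() if r.sex == "M")
    females = sum(1 for r in registry.values() if r.sex == "F")
    summary = summaries.summarize_period(
        design.period_id,
        min_count,
        males,
        females,
        habitat_ha=config.habitat_ha["SBF"],
        genetic={
            "ho": ho, "he": he, "ar": ar,
            "ne": ne.point, "ne_ci": (ne.ci_low, ne.ci_high),
            "mean_cb_pct": cb["mean_cb_pct"],
            "pct_containing_cb": cb["pct_containing_cb"],
        },
    )
    summary_df = summaries.summary_table([summary])
    summary_df.to_csv(out_dir / "period_summary.csv", index=False)

    fingerprint = hashlib.sha256()
    for name in sorted(
        ["replicates.csv", "panel.csv", "registry.csv", "parentage.csv",
         "ancestry.csv", "period_summary.csv"]
    ):
        fingerprint.update((out_dir / name).read_bytes())
    manifest = {
        "config": dataclasses.asdict(config),
        "n_samples": len(samples),
        "n_gated": len(consensus),
        "minimum_count": min_count,
        "origin_breakdown": breakdown,
        "output_hash": fingerprint.hexdigest(),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return {
        "registry": registry,
        "truth": truth,
        "assignments": assignments,
        "ancestry": estimates,
        "cb": cb,
        "summary": summary_df,
        "manifest": manifest,
        "match_results": match_results,
    }
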